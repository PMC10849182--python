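"""From alignments to a pooled log Y: the core statistic, step by step.

Generates a small synthetic world with selection S = 1 on each family's
preferred codon, calls polarized polymorphic sites against one outgroup,
builds per-gene 2×2 strata for the Gln→Lys pair, and pools them with the
Cochran–Mantel–Haenszel estimator.  The result is compared with the planted
expectation from the mutation–selection–drift model.
"""

import math

from codonsel import (
    build_strata,
    call_polymorphic_sites,
    cmh_pooled_log_y,
    compute_rscu,
)
from codonsel.y_statistic import cmh_log_y_se
from codonsel import (
    count_codons,
    pool_counts,
    select_extreme_codon_pairs,
)
from codonsel.genetic_code import all_directed_pairs
from codonsel.site_calls import calls_frame
from codonsel.synthetic import (
    SyntheticConfig,
    expected_log_y_truth,
    generate_dataset,
    selection_map,
)

cfg = SyntheticConfig(
    seed=42, genes=150, strains=30, codons_per_gene=250,
    S_by_codon=selection_map(1.0), theta=0.08,
)
alignments, truth, expression = generate_dataset(cfg)

calls = []
for aln in alignments:
    calls += call_polymorphic_sites(aln, "og1")
frame = calls_frame(calls)
print(frame["status"].value_counts().to_string())

profile = compute_rscu(
    pool_counts(
        [count_codons(next(iter(a.ingroup.values())), a.gene_id)
         for a in alignments]
    )
)

pair = next(p for p in all_directed_pairs() if p.label == "Q>K")
extremes = select_extreme_codon_pairs(pair, profile)
max_mut, min_mut = extremes
print(f"\nGln→Lys extreme codon mutations: max {max_mut}, min {min_mut}")

strata = build_strata(frame, pair, extremes)
estimate = cmh_pooled_log_y(strata, pair_label=pair.label)
se = cmh_log_y_se(strata)
planted = expected_log_y_truth(cfg, pair)
print(f"CMH-pooled log Y_pol over {estimate.strata_used} gene strata: "
      f"{estimate.log_y:.3f} ± {se:.3f} "
      f"({estimate.total_up} up / {estimate.total_down} down events)")
print(f"planted expectation log[P(S)/P(−S)] = {planted:.3f}")
print("A single pair carries few events, so its estimate is noisy; pooling "
      "across all directed pairs tightens the band (see the test suite).")
print("\nA positive log Y_pol means non-synonymous polymorphisms that "
      "increase RSCU are over-represented per ancestral-codon site, as "
      "planted selection predicts.")
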