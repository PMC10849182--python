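"""The whole analysis on a synthetic core genome, from FASTA on disk.

Writes a generated dataset (one FASTA per gene, expression TSV) to a
temporary directory, runs the full pipeline from those files, and prints the
headline results: per-class mean log Y tests, Spearman correlations with
log ΔRSCU, and synonymous divergence to each outgroup.
"""

import tempfile
from pathlib import Path

from codonsel import RunConfig, run_pipeline
from codonsel.synthetic import (
    SyntheticConfig,
    generate_dataset,
    selection_map,
    write_dataset,
)

cfg = SyntheticConfig(
    seed=7, genes=120, strains=25, codons_per_gene=250,
    S_by_codon=selection_map(0.8), theta=0.08, missing_rate=0.01,
)
alignments, truth, expression = generate_dataset(cfg)

with tempfile.TemporaryDirectory() as tmp:
    root = write_dataset(alignments, truth, expression, Path(tmp) / "data")
    bundle = run_pipeline(
        RunConfig(
            alignments_dir=root / "alignments",
            expression_tsv=root / "expression.tsv",
            output_dir=Path(tmp) / "results",
        )
    )

    pol = bundle.estimates.query("level == 'polymorphism'")
    print(f"{bundle.manifest['genes']} genes analysed; "
          f"{len(bundle.highly_expressed)} in the top CA decile")
    print(f"log Y_pol defined for {pol.log_y.notna().sum()} of {len(pol)} "
          "directed amino-acid pairs\n")

    print("headline tests (statistic, p, n):")
    for row in bundle.tests.itertuples():
        print(f"  {row.level:12s} {row.degeneracy:5s} {row.test:18s} "
              f"stat = {row.statistic:+.3f}  p = {row.p_value:.3g}  "
              f"n = {row.n}")

    print("\nsynonymous divergence to each outgroup:")
    for row in bundle.divergence.itertuples():
        print(f"  focal vs {row.species_b}: d_S = {row.d_s:.3f} "
              f"(d_N = {row.d_n:.3f})")

print("\nWith planted selection the 2-fold and 4-fold mean log Y_pol are "
      "positive; on real data a mean near zero is evidence that codon-usage "
      "selection does not shape non-synonymous variation.")
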