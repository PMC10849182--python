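"""End-to-end orchestration: alignments → usage → site calls → log Y → tests.

`run_pipeline` wires the stages together the way the full analysis is meant
to be run: codon counting on the ingroup consensus, correspondence analysis
to pick highly expressed genes, reference RSCU/w/CAI, polarized site calls
against the closest outgroup (and fixed differences against both), per-gene
strata pooled by Cochran–Mantel–Haenszel into per-pair log Y with ΔRSCU, and
the downstream tests.  Every intermediate can be written as TSV, with a
manifest recording configuration and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .codon_usage import (
    CodonCounts,
    CodonUsageProfile,
    compute_cai,
    compute_rscu,
    correspondence_analysis,
    count_codons,
    pool_counts,
    quantile_bins,
)
from .genetic_code import SENSE_CODONS, all_directed_pairs
from .inference import (
    PairObservation,
    TestReport,
    mean_log_y_test,
    spearman_log_y_vs_delta,
)
from .site_calls import (
    GeneAlignment,
    calls_frame,
    call_fixed_differences,
    call_polymorphic_sites,
    compute_ds,
    read_gene_alignment,
)
from .y_statistic import (
    DeltaRscuResult,
    YEstimate,
    build_strata,
    cmh_pooled_log_y,
    delta_rscu,
    estimates_frame,
    select_extreme_codon_pairs,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Configuration of a full run; all thresholds are fractions in (0,1)."""

    alignments_dir: str | Path | None = None
    expression_tsv: str | Path | None = None
    output_dir: str | Path | None = None
    outgroup_ids: Sequence[str] = ("og1", "og2")  # first = closest
    outgroup_prefix: str = "OUTGROUP|"
    coverage_threshold: float = 0.95
    top_fraction: float = 0.10
    cai_bins: int = 4
    expression_bins: int = 5
    ca_mode: str = "WCA-CA-AF"
    w_floor: float = 0.01
    sidedness: str = "two-sided"
    ds_jukes_cantor: bool = False
    marker_genes: Sequence[str] | None = None
    seed: int = 0

    def validate(self) -> None:
        for name in ("coverage_threshold", "top_fraction"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name}={v} must be in (0,1)")
        if len(self.outgroup_ids) < 1:
            raise ValueError("at least one outgroup id is required")


@dataclass
class ResultBundle:
    reference_profile: CodonUsageProfile
    outgroup_profile: CodonUsageProfile | None
    gene_scores: pd.DataFrame
    highly_expressed: list[str]
    poly_calls: pd.DataFrame
    div_calls: pd.DataFrame | None
    estimates: pd.DataFrame
    tests: pd.DataFrame
    divergence: pd.DataFrame
    manifest: dict
    failures: list[str] = field(default_factory=list)


def load_expression(path: str | Path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t")
    if not {"gene_id", "expression"}.issubset(df.columns):
        raise ValueError("expression TSV needs gene_id and expression columns")
    return dict(zip(df["gene_id"].astype(str), df["expression"].astype(float)))


def _pair_observations(
    estimates: list[YEstimate], deltas: dict[str, DeltaRscuResult],
    degeneracy: dict[str, str],
) -> list[PairObservation]:
    obs = []
    for e in estimates:
        d = deltas.get(e.pair_label)
        obs.append(
            PairObservation(
                pair_label=e.pair_label,
                log_y=e.log_y,
                log_delta_rscu=d.log_delta_rscu if d else math.nan,
                degeneracy_class=degeneracy.get(e.pair_label, ""),
            )
        )
    return obs


def run_pipeline(
    cfg: RunConfig,
    alignments: Sequence[GeneAlignment] | None = None,
    expression: Mapping[str, float] | None = None,
) -> ResultBundle:
    """Execute the full analysis and (optionally) write every intermediate.

    ``alignments`` may be passed in memory; otherwise one FASTA per gene is
    read from ``cfg.alignments_dir``.  Per-gene failures are logged, skipped
    and summarised; an empty usable gene set raises :class:`PipelineError`.
    """
    cfg.validate()
    failures: list[str] = []

    if alignments is None:
        if cfg.alignments_dir is None:
            raise PipelineError("no alignments supplied")
        paths = sorted(Path(cfg.alignments_dir).glob("*.fasta"))
        alignments = []
        for p in paths:
            try:
                alignments.append(
                    read_gene_alignment(p, outgroup_prefix=cfg.outgroup_prefix)
                )
            except Exception as exc:  # noqa: BLE001 - per-gene skip by design
                logger.warning("skipping %s: %s", p.name, exc)
                failures.append(f"{p.name}: {exc}")
    if not alignments:
        raise PipelineError("no usable gene alignments")

    if expression is None and cfg.expression_tsv is not None:
        expression = load_expression(cfg.expression_tsv)
    if expression is None:
        logger.warning("no expression data; CAI-only binning path taken")

    # --- codon usage on the ingroup consensus ---------------------------
    counts: dict[str, CodonCounts] = {}
    for aln in alignments:
        try:
            counts[aln.gene_id] = count_codons(aln.consensus(), aln.gene_id)
        except ValueError as exc:
            logger.warning("codon counting failed: %s", exc)
            failures.append(str(exc))
    if not counts:
        raise PipelineError("codon counting failed for every gene")

    af = pd.DataFrame(
        {g: [c.counts[k] for k in SENSE_CODONS] for g, c in counts.items()},
        index=SENSE_CODONS,
    ).T
    if cfg.ca_mode == "CA-RSCU":
        mat = pd.DataFrame(
            {g: compute_rscu(c).rscu for g, c in counts.items()}
        ).T[SENSE_CODONS]
    else:
        mat = af
    ca = correspondence_analysis(
        mat,
        mode=cfg.ca_mode,
        marker_genes=cfg.marker_genes,
        expression=expression,
        top_fraction=cfg.top_fraction,
    )
    highly_expressed = ca.highly_expressed

    reference_profile = compute_rscu(
        pool_counts([counts[g] for g in highly_expressed if g in counts]),
        source="highly_expressed",
    )

    # outgroup reference profile (closest outgroup, same gene set) for the
    # divergence-level ancestral RSCU
    closest = cfg.outgroup_ids[0]
    og_counts = []
    for aln in alignments:
        if aln.gene_id in highly_expressed and closest in aln.outgroups:
            try:
                og_counts.append(
                    count_codons(aln.outgroups[closest], aln.gene_id)
                )
            except ValueError:
                pass
    outgroup_profile = (
        compute_rscu(pool_counts(og_counts), source=f"outgroup:{closest}")
        if og_counts
        else None
    )

    # --- per-gene scores ------------------------------------------------
    scores = []
    for g, c in counts.items():
        s = compute_cai(c, reference_profile, w_floor=cfg.w_floor)
        s.expression = (expression or {}).get(g)
        scores.append(s)
    cai_map = {s.gene_id: s.cai for s in scores if math.isfinite(s.cai)}
    cai_cats = (
        quantile_bins(cai_map, cfg.cai_bins)
        if len(cai_map) >= cfg.cai_bins
        else {}
    )
    expr_map = {
        s.gene_id: s.expression for s in scores if s.expression is not None
    }
    expr_cats = (
        quantile_bins(expr_map, cfg.expression_bins)
        if len(expr_map) >= cfg.expression_bins
        else {}
    )
    for s in scores:
        s.category = cai_cats.get(s.gene_id)
    gene_scores = pd.DataFrame(
        [
            (s.gene_id, s.cai, s.expression, s.category,
             expr_cats.get(s.gene_id))
            for s in scores
        ],
        columns=["gene_id", "cai", "expression", "cai_category",
                 "expression_category"],
    )

    # --- site calls -----------------------------------------------------
    poly_calls = []
    div_calls = []
    two_outgroups = all(
        len(aln.outgroups) >= 2 for aln in alignments
    ) and len(cfg.outgroup_ids) >= 2
    for aln in alignments:
        try:
            poly_calls.extend(
                call_polymorphic_sites(
                    aln, closest, coverage_threshold=cfg.coverage_threshold
                )
            )
            if two_outgroups:
                div_calls.extend(
                    call_fixed_differences(
                        aln,
                        cfg.outgroup_ids[:2],
                        coverage_threshold=cfg.coverage_threshold,
                    )
                )
        except ValueError as exc:
            logger.warning("site calling failed for %s: %s", aln.gene_id, exc)
            failures.append(f"{aln.gene_id}: {exc}")

    # --- per-pair statistics --------------------------------------------
    poly_df = calls_frame(poly_calls)
    div_df = calls_frame(div_calls) if two_outgroups else None
    pairs = all_directed_pairs()
    degeneracy = {p.label: p.degeneracy_class for p in pairs}
    estimates: list[YEstimate] = []
    deltas_pol: dict[str, DeltaRscuResult] = {}
    deltas_div: dict[str, DeltaRscuResult] = {}
    for level, calls, anc_profile in (
        ("polymorphism", poly_df, reference_profile),
        ("divergence", div_df, outgroup_profile),
    ):
        if calls is None:
            continue
        for pair in pairs:
            extremes = select_extreme_codon_pairs(
                pair, anc_profile or reference_profile,
                derived_profile=reference_profile,
            )
            if extremes is None:
                estimates.append(
                    YEstimate(pair.label, level, math.nan, 0, 0, 0)
                )
                continue
            strata = build_strata(calls, pair, extremes, level=level)
            if strata:
                estimates.append(
                    cmh_pooled_log_y(strata, level=level,
                                     pair_label=pair.label)
                )
            else:
                estimates.append(
                    YEstimate(pair.label, level, math.nan, 0, 0, 0)
                )
            d = delta_rscu(
                pair, extremes,
                profile_ancestral=anc_profile or reference_profile,
                profile_derived=reference_profile,
            )
            if d is not None:
                (deltas_pol if level == "polymorphism" else deltas_div)[
                    pair.label] = d

    est_pol = [e for e in estimates if e.level == "polymorphism"]
    est_div = [e for e in estimates if e.level == "divergence"]
    est_df = pd.concat(
        [
            estimates_frame(est_pol, deltas_pol),
            estimates_frame(est_div, deltas_div) if est_div else pd.DataFrame(),
        ],
        ignore_index=True,
    )
    est_df["degeneracy"] = est_df["pair"].map(degeneracy)

    # --- downstream tests -----------------------------------------------
    reports: list[tuple[str, str, str, TestReport]] = []
    for level, ests, deltas in (
        ("polymorphism", est_pol, deltas_pol),
        ("divergence", est_div, deltas_div),
    ):
        if not ests:
            continue
        for klass in ("2fold", "4fold"):
            obs = [
                o
                for o in _pair_observations(ests, deltas, degeneracy)
                if degeneracy.get(o.pair_label) == klass
            ]
            try:
                reports.append(
                    (level, klass, "mean", mean_log_y_test(obs, cfg.sidedness))
                )
            except ValueError as exc:
                logger.warning("mean test skipped (%s %s): %s", level, klass, exc)
            try:
                reports.append(
                    (level, klass, "spearman", spearman_log_y_vs_delta(obs))
                )
            except ValueError as exc:
                logger.warning("spearman skipped (%s %s): %s", level, klass, exc)
    tests = pd.DataFrame(
        [
            {
                "level": lv, "degeneracy": kl, "test": r.test_name,
                "statistic": r.statistic, "p_value": r.p_value, "n": r.n,
                "estimate": repr(r.estimate),
            }
            for lv, kl, _name, r in reports
        ]
    )

    # --- synonymous divergence -----------------------------------------
    div_rows = []
    for og in cfg.outgroup_ids:
        foc_parts, og_parts = [], []
        for aln in alignments:
            if og in aln.outgroups:
                foc_parts.append(aln.consensus())
                og_parts.append(aln.outgroups[og])
        if foc_parts:
            summ = compute_ds(
                "".join(foc_parts), "".join(og_parts),
                species_pair=("focal", og),
                jukes_cantor=cfg.ds_jukes_cantor,
            )
            div_rows.append(
                ("focal", og, summ.syn_substitutions, summ.syn_sites,
                 summ.d_s, summ.d_n)
            )
    divergence = pd.DataFrame(
        div_rows,
        columns=["species_a", "species_b", "syn_substitutions", "syn_sites",
                 "d_s", "d_n"],
    )

    cfg_text = json.dumps(
        {k: str(v) for k, v in vars(cfg).items()}, sort_keys=True
    )
    manifest = {
        "package": "codonsel",
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": hashlib.sha256(cfg_text.encode()).hexdigest()[:16],
        "genes": len(counts),
        "highly_expressed": len(highly_expressed),
        "failures": len(failures),
        "ca_mode": cfg.ca_mode,
    }

    bundle = ResultBundle(
        reference_profile=reference_profile,
        outgroup_profile=outgroup_profile,
        gene_scores=gene_scores,
        highly_expressed=list(highly_expressed),
        poly_calls=poly_df,
        div_calls=div_df,
        estimates=est_df,
        tests=tests,
        divergence=divergence,
        manifest=manifest,
        failures=failures,
    )
    if cfg.output_dir is not None:
        _write_bundle(bundle, Path(cfg.output_dir))
    return bundle


def category_log_y_observations(
    calls: pd.DataFrame,
    counts: Mapping[str, CodonCounts],
    categories: Mapping[str, int],
    level: str = "polymorphism",
    per_category_rscu: bool = True,
    reference_profile: CodonUsageProfile | None = None,
) -> list[PairObservation]:
    """Per-category log Y and log ΔRSCU observations for the interaction model.

    Splits genes by ``categories`` (e.g. CAI or expression bins), and within
    each category recomputes the pooled RSCU profile from that category's
    genes (``per_category_rscu=True``, the default) or reuses a single
    global ``reference_profile``.  Each category's calls are restratified
    and CMH-pooled per directed pair; undefined log Y values propagate as
    NaN and are excluded by the downstream tests.
    """
    if not per_category_rscu and reference_profile is None:
        raise ValueError("global mode needs a reference_profile")
    pairs = all_directed_pairs()
    obs: list[PairObservation] = []
    for cat in sorted(set(categories.values())):
        genes = [g for g, c in categories.items() if c == cat]
        sub = calls[calls["gene_id"].isin(genes)]
        if per_category_rscu:
            cat_counts = [counts[g] for g in genes if g in counts]
            if not cat_counts:
                continue
            profile = compute_rscu(pool_counts(cat_counts),
                                   source=f"category {cat}")
        else:
            profile = reference_profile
        for pair in pairs:
            extremes = select_extreme_codon_pairs(pair, profile)
            if extremes is None:
                continue
            strata = build_strata(sub, pair, extremes, level=level)
            log_y = math.nan
            if strata:
                log_y = cmh_pooled_log_y(
                    strata, level=level, pair_label=pair.label
                ).log_y
            d = delta_rscu(pair, extremes, profile)
            obs.append(
                PairObservation(
                    pair_label=pair.label,
                    log_y=log_y,
                    log_delta_rscu=d.log_delta_rscu if d else math.nan,
                    degeneracy_class=pair.degeneracy_class,
                    category=cat,
                )
            )
    return obs


def _write_bundle(bundle: ResultBundle, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    bundle.reference_profile.as_frame().to_csv(
        outdir / "reference_rscu.tsv", sep="\t", index=False
    )
    if bundle.outgroup_profile is not None:
        bundle.outgroup_profile.as_frame().to_csv(
            outdir / "outgroup_rscu.tsv", sep="\t", index=False
        )
    bundle.gene_scores.to_csv(outdir / "gene_scores.tsv", sep="\t", index=False)
    bundle.poly_calls.to_csv(outdir / "site_calls_poly.tsv", sep="\t",
                             index=False)
    if bundle.div_calls is not None:
        bundle.div_calls.to_csv(outdir / "site_calls_div.tsv", sep="\t",
                                index=False)
    bundle.estimates.to_csv(outdir / "y_estimates.tsv", sep="\t", index=False)
    bundle.tests.to_csv(outdir / "tests.tsv", sep="\t", index=False)
    bundle.divergence.to_csv(outdir / "divergence.tsv", sep="\t", index=False)
    (outdir / "manifest.json").write_text(json.dumps(bundle.manifest, indent=2))
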