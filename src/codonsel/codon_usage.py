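"""Codon counting, RSCU, relative adaptiveness, CAI and correspondence analysis.

Relative synonymous codon usage (RSCU) is the observed count of a codon
divided by the count expected if all synonymous codons of its amino acid were
used equally; it averages 1 over each family.  Relative adaptiveness *w* is a
codon's RSCU divided by the family maximum, and the codon adaptation index
(CAI) of a gene is the geometric mean of *w* over its codons (Met, Trp and
stops excluded), scored against a reference profile built from highly
expressed genes.  Highly expressed genes are identified here the way codon
analyses usually do it: a correspondence analysis of the genes × codons
matrix, with the first principal axis oriented by marker genes (ribosomal
proteins) or by expression, and the top decile on that axis taken as the
reference set.

Six-fold degenerate amino acids (Leu, Ser, Arg) are treated as single
6-codon families for RSCU and CAI, following the convention of the seqinr
``uco`` function.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genetic_code import CODON_TO_AA, SENSE_CODONS, STANDARD_TABLE, CodonTable

logger = logging.getLogger(__name__)

#: Codons scored by CAI: sense codons of amino acids with >1 synonym.
CAI_CODONS = [c for c in SENSE_CODONS if STANDARD_TABLE.degeneracy[CODON_TO_AA[c]] > 1]

_FAMILIES: dict[str, list[str]] = {}
for _c in SENSE_CODONS:
    _FAMILIES.setdefault(CODON_TO_AA[_c], []).append(_c)


@dataclass
class CodonCounts:
    """Per-gene codon counts over the 61 sense codons."""

    gene_id: str
    counts: dict[str, int]
    skipped: int = 0  # codons containing ambiguity characters

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def count_codons(sequence: str, gene_id: str = "") -> CodonCounts:
    """Count sense codons in an in-frame coding sequence.

    A single terminal stop codon is dropped; internal stops or a length not
    divisible by 3 raise ``ValueError`` naming the gene.  Codons containing
    characters outside ACGT are skipped and tallied in ``skipped``.
    """
    seq = sequence.upper().replace("U", "T")
    if len(seq) % 3 != 0:
        raise ValueError(f"gene {gene_id!r}: length {len(seq)} not divisible by 3")
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    if codons and codons[-1] in STANDARD_TABLE.stop_codons:
        codons = codons[:-1]
    counts = {c: 0 for c in SENSE_CODONS}
    skipped = 0
    for i, codon in enumerate(codons):
        if codon in STANDARD_TABLE.stop_codons:
            raise ValueError(f"gene {gene_id!r}: internal stop {codon} at codon {i}")
        if codon in counts:
            counts[codon] += 1
        else:
            skipped += 1
    return CodonCounts(gene_id=gene_id, counts=counts, skipped=skipped)


def pool_counts(counts: Iterable[CodonCounts], label: str = "pooled") -> CodonCounts:
    """Sum codon counts over a gene set (used for reference-set RSCU)."""
    total = {c: 0 for c in SENSE_CODONS}
    skipped = 0
    for cc in counts:
        for c, n in cc.counts.items():
            total[c] += n
        skipped += cc.skipped
    return CodonCounts(gene_id=label, counts=total, skipped=skipped)


@dataclass
class CodonUsageProfile:
    """RSCU and relative adaptiveness *w* per codon.

    ``rscu[c]`` is NaN for codons of amino-acid families with zero observed
    counts; within each counted family max *w* = 1.
    """

    rscu: dict[str, float]
    w: dict[str, float]
    source: str = "all_genes"

    def as_frame(self) -> pd.DataFrame:
        rows = [
            (c, CODON_TO_AA[c], self.rscu[c], self.w[c])
            for c in SENSE_CODONS
        ]
        return pd.DataFrame(rows, columns=["codon", "aa", "rscu", "w"])


def compute_rscu(
    counts: CodonCounts | Mapping[str, float], source: str = "all_genes"
) -> CodonUsageProfile:
    """RSCU and *w* from (possibly pooled) codon counts.

    RSCU_c = n_c / (family_total / family_size).  Families with no counts get
    NaN for every member; *w* is RSCU divided by the family maximum.
    """
    raw = counts.counts if isinstance(counts, CodonCounts) else counts
    rscu: dict[str, float] = {}
    w: dict[str, float] = {}
    for aa, family in _FAMILIES.items():
        fam_total = sum(raw.get(c, 0) for c in family)
        if fam_total == 0:
            for c in family:
                rscu[c] = math.nan
                w[c] = math.nan
            continue
        expected = fam_total / len(family)
        vals = {c: raw.get(c, 0) / expected for c in family}
        top = max(vals.values())
        for c in family:
            rscu[c] = vals[c]
            w[c] = vals[c] / top if top > 0 else math.nan
    return CodonUsageProfile(rscu=rscu, w=w, source=source)


@dataclass
class GeneScore:
    """Per-gene codon adaptation index with optional expression and bin."""

    gene_id: str
    cai: float  # NaN when the gene has no scorable codons
    expression: float | None = None
    category: int | None = None


def compute_cai(
    gene: CodonCounts,
    profile: CodonUsageProfile,
    w_floor: float = 0.01,
) -> GeneScore:
    """CAI of a gene against a reference profile.

    Geometric mean of reference *w* over the gene's codons, excluding Met,
    Trp and stops.  Codons whose reference *w* is 0 (or whose family was
    absent from the reference set) contribute ``w_floor`` so a single
    unobserved codon cannot collapse the index to zero.
    """
    log_sum = 0.0
    n = 0
    for codon in CAI_CODONS:
        k = gene.counts.get(codon, 0)
        if k == 0:
            continue
        wc = profile.w.get(codon, math.nan)
        if not (wc > 0) or math.isnan(wc):  # zero or NaN reference w
            wc = w_floor
        log_sum += k * math.log(wc)
        n += k
    if n == 0:
        return GeneScore(gene_id=gene.gene_id, cai=math.nan)
    return GeneScore(gene_id=gene.gene_id, cai=math.exp(log_sum / n))


# ---------------------------------------------------------------------------
# Correspondence analysis
# ---------------------------------------------------------------------------


@dataclass
class CorrespondenceResult:
    """Gene coordinates on CA principal axes and the derived reference set."""

    axes: pd.DataFrame  # genes × axes, oriented
    inertia: np.ndarray  # explained-inertia fractions per axis
    highly_expressed: list[str]  # top decile of oriented axis 1
    mode: str = "CA-RSCU"
    dropped_rows: list[str] = field(default_factory=list)
    dropped_cols: list[str] = field(default_factory=list)


def _ca_core(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row principal coordinates and inertia fractions of a count/value matrix."""
    total = X.sum()
    P = X / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sv, _ = np.linalg.svd(S, full_matrices=False)
    keep = sv > 1e-12
    U, sv = U[:, keep], sv[keep]
    rows = (U * sv) / np.sqrt(r)[:, None]
    inertia = sv**2 / max((sv**2).sum(), 1e-300)
    return rows, inertia


def _wca_center(X: np.ndarray, groups: Sequence[int]) -> np.ndarray:
    """Center row profiles within column groups (amino-acid families).

    Each row profile value q_ij is replaced by its deviation from the value
    expected given the row's total mass in codon j's amino-acid group,
    removing amino-acid composition differences between genes (the
    within-group CA of ade4).  Returns a residual matrix on the chi-square
    scale ready for SVD with the original row/column masses.
    """
    total = X.sum()
    P = X / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    groups = np.asarray(groups)
    Q = P / r[:, None]  # row profiles
    resid = np.zeros_like(Q)
    for g in np.unique(groups):
        idx = np.where(groups == g)[0]
        cg = c[idx].sum()
        if cg <= 0:
            continue
        row_g = Q[:, idx].sum(axis=1)
        expected = np.outer(row_g, c[idx] / cg)
        resid[:, idx] = Q[:, idx] - expected
    return resid * np.sqrt(r)[:, None] / np.sqrt(c)[None, :]


def correspondence_analysis(
    matrix: pd.DataFrame,
    mode: str = "WCA-CA-AF",
    marker_genes: Iterable[str] | None = None,
    expression: Mapping[str, float] | None = None,
    top_fraction: float = 0.10,
    n_axes: int = 4,
) -> CorrespondenceResult:
    """Correspondence analysis of a genes × codons matrix.

    Parameters
    ----------
    matrix
        Genes (rows) × codons (columns); RSCU values for mode ``"CA-RSCU"``
        or absolute codon frequencies for ``"CA-AF"`` / ``"WCA-CA-AF"``.
    mode
        ``"CA-RSCU"``, ``"CA-AF"`` or ``"WCA-CA-AF"`` (within-amino-acid
        -group CA of the frequency matrix, the default).
    marker_genes, expression
        Used to orient axis 1 so high codon bias is positive: markers take
        precedence, else correlation with expression; with neither the axis
        is left unoriented with a warning.
    top_fraction
        Fraction of genes (ceiling) returned as ``highly_expressed``.

    Zero rows/columns are dropped with a logged warning.  Requires ≥ 2 genes.
    """
    if matrix.shape[0] < 2:
        raise ValueError("correspondence analysis needs at least 2 genes")
    if mode not in ("CA-RSCU", "CA-AF", "WCA-CA-AF"):
        raise ValueError(f"unknown CA mode {mode!r}")

    M = matrix.fillna(0.0).astype(float)
    row_ok = M.sum(axis=1) > 0
    col_ok = M.sum(axis=0) > 0
    dropped_rows = list(M.index[~row_ok])
    dropped_cols = list(M.columns[~col_ok])
    if dropped_rows or dropped_cols:
        logger.warning(
            "CA dropped %d zero rows and %d zero columns",
            len(dropped_rows),
            len(dropped_cols),
        )
    M = M.loc[row_ok, col_ok]
    X = M.to_numpy()

    if mode == "WCA-CA-AF":
        aa_groups = [hash(CODON_TO_AA.get(c, c)) for c in M.columns]
        # map to small ints
        uniq = {g: i for i, g in enumerate(dict.fromkeys(aa_groups))}
        S = _wca_center(X, [uniq[g] for g in aa_groups])
        U, sv, _ = np.linalg.svd(S, full_matrices=False)
        keep = sv > 1e-12
        U, sv = U[:, keep], sv[keep]
        r = (X / X.sum()).sum(axis=1)
        coords = (U * sv) / np.sqrt(r)[:, None]
        inertia = sv**2 / max((sv**2).sum(), 1e-300)
    else:
        coords, inertia = _ca_core(X)

    k = min(n_axes, coords.shape[1])
    axes = pd.DataFrame(
        coords[:, :k], index=M.index, columns=[f"axis{i+1}" for i in range(k)]
    )

    # Orient axis 1: markers first, then expression, else leave as is.
    sign = 0.0
    if marker_genes is not None:
        marks = [g for g in marker_genes if g in axes.index]
        if marks:
            sign = float(np.sign(axes.loc[marks, "axis1"].mean()))
    if sign == 0.0 and expression is not None:
        common = [g for g in axes.index if g in expression]
        if len(common) >= 3:
            expr = np.array([expression[g] for g in common])
            r_corr = np.corrcoef(axes.loc[common, "axis1"], expr)[0, 1]
            if not np.isnan(r_corr):
                sign = float(np.sign(r_corr))
    if sign == 0.0:
        logger.warning("axis 1 left unoriented: no markers or usable expression")
        sign = 1.0
    axes["axis1"] *= sign

    n_top = math.ceil(top_fraction * axes.shape[0])
    top = axes["axis1"].sort_values(ascending=False).index[:n_top]
    return CorrespondenceResult(
        axes=axes,
        inertia=inertia[:k],
        highly_expressed=list(top),
        mode=mode,
        dropped_rows=dropped_rows,
        dropped_cols=dropped_cols,
    )


def quantile_bins(values: Mapping[str, float], k: int) -> dict[str, int]:
    """Assign genes to ``k`` near-equal-occupancy categories (1 = lowest).

    Boundaries sit at empirical quantiles; ties are resolved by stable
    gene-id order so bin sizes differ by at most 1.  Raises when ``k`` < 2 or
    exceeds the number of genes.
    """
    if k < 2:
        raise ValueError("need at least 2 bins")
    genes = list(values)
    if k > len(genes):
        raise ValueError(f"k={k} exceeds number of genes ({len(genes)})")
    vals = np.array([values[g] for g in genes], dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("non-finite values in binning input")
    if np.all(vals == vals[0]):
        logger.warning("all values identical; splitting by stable gene-id order")
    order = np.lexsort((np.arange(len(genes)), vals))  # value, then input order
    n = len(genes)
    out: dict[str, int] = {}
    for rank, idx in enumerate(order):
        out[genes[idx]] = int(rank * k / n) + 1
    return out


def scores_frame(scores: Iterable[GeneScore]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.gene_id, s.cai, s.expression, s.category) for s in scores],
        columns=["gene_id", "cai", "expression", "category"],
    )
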