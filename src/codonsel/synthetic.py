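"""Synthetic codon-alignment generator with complete ground-truth bookkeeping.

Generates per-gene codon alignments of many ingroup strains plus two
outgroups under an explicit site-wise mutation–selection–drift model, so the
whole analysis pipeline (site calling, stratified log Y, ΔRSCU, power) can be
verified against planted truth:

* each site's ancestral codon is drawn from the within-family equilibrium
  p(c) ∝ e^{S_c} (the 2-fold case reduces to f = e^S/(e^S+1));
* segregating polymorphisms are planted biallelic at the codon level, one
  nucleotide apart, with per-path probability ∝ mutation bias × the expected
  polymorphism count P(ΔS, n) of the selection differential;
* derived-allele counts follow the neutral frequency spectrum (∝ 1/k);
* the focal lineage and both outgroups evolve from the ancestor with
  synonymous-biased substitution (configurable dN/dS), so realistic d_S
  (~0.15–0.27) is reachable without saturating non-synonymous sites;
* every emitted column has exactly one ground-truth record including the
  site status the polymorphism- and divergence-level callers should assign.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genetic_code import (
    CODON_TO_AA,
    CODONS,
    SENSE_CODONS,
    STANDARD_TABLE,
    DirectedAminoAcidPair,
)
from .popgen import expected_polymorphisms
from .site_calls import MISSING

# --- default stated world -------------------------------------------------

#: Approximate E. coli amino-acid composition (fractions; Met/Trp included).
DEFAULT_AA_COMPOSITION = {
    "A": 0.095, "R": 0.055, "N": 0.039, "D": 0.054, "C": 0.012,
    "Q": 0.044, "E": 0.058, "G": 0.074, "H": 0.023, "I": 0.060,
    "L": 0.107, "K": 0.044, "M": 0.028, "F": 0.039, "P": 0.044,
    "S": 0.058, "T": 0.054, "W": 0.015, "Y": 0.029, "V": 0.071,
}

#: Preferred codon per 2-fold/4-fold family in the synthetic world.  Chosen
#: so that as many directed amino-acid pairs as possible have a full
#: unpreferred→preferred vs preferred→unpreferred contrast (third-position
#: identity of the preferred codons of adjacent families would null the
#: contrast; with binary per-family fitness some null pairs are unavoidable).
DEFAULT_PREFERRED = {
    "F": "TTC", "Y": "TAT", "C": "TGC", "H": "CAC", "N": "AAT",
    "D": "GAC", "Q": "CAG", "K": "AAA", "E": "GAG",
    "P": "CCG", "A": "GCT", "T": "ACC", "G": "GGA", "V": "GTG",
}


def selection_map(S: float, preferred: Mapping[str, str] | None = None
                  ) -> dict[str, float]:
    """Codon → scaled selection coefficient: S for each family's preferred
    codon, 0 elsewhere (1/3/6-fold families neutral)."""
    pref = dict(DEFAULT_PREFERRED if preferred is None else preferred)
    out = {c: 0.0 for c in SENSE_CODONS}
    for aa, codon in pref.items():
        if CODON_TO_AA.get(codon) != aa:
            raise ValueError(f"preferred codon {codon} does not encode {aa}")
        out[codon] = S
    return out


@dataclass
class SyntheticConfig:
    """Stated world for the generator; all defaults emulate the target data
    structure: hundreds of core genes, tens of strains, ≤5% missing data,
    outgroups at synonymous divergence ~0.15–0.27."""

    seed: int
    genes: int = 200
    strains: int = 40
    codons_per_gene: int | tuple[int, int] = 300
    S_by_codon: Mapping[str, float] = field(
        default_factory=lambda: selection_map(0.0))
    mutation_bias: Mapping[tuple[str, str], float] = field(default_factory=dict)
    theta: float = 0.05          # ≈ polymorphic fraction of codon sites
    outgroup_divergence: float = 0.20  # per synonymous site, each outgroup
    focal_divergence: float = 0.05     # ingroup-branch substitutions
    outgroup_dnds: float = 0.05
    missing_rate: float = 0.01
    triallelic_noise: float = 0.0  # extra third-allele injection per poly site
    sfs: str = "neutral"           # derived-count spectrum: p(k) ∝ 1/k
    aa_composition: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AA_COMPOSITION))
    expression_mu: float = 10.0    # log RPKM scale, ~8.1–12 range
    expression_sd: float = 1.0
    expression_selection_beta: float = 0.0  # per-gene S multiplier exponent

    def validate(self) -> None:
        if not 0.0 <= self.theta < 0.5:
            raise ValueError(f"theta={self.theta} outside [0, 0.5): biallelic "
                             "planting would be violated")
        for name in ("outgroup_divergence", "focal_divergence", "missing_rate",
                     "triallelic_noise"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name}={v} outside [0,1)")
        if self.strains < 3:
            raise ValueError("need at least 3 strains")
        comp_tot = sum(self.aa_composition.values())
        if not math.isclose(comp_tot, 1.0, rel_tol=0.02):
            raise ValueError(
                f"amino-acid composition sums to {comp_tot:.3f}, not ~1"
            )


# --- precomputed code tables ----------------------------------------------

_SENSE_IDX = np.array([CODONS.index(c) for c in SENSE_CODONS])
_IS_SENSE = np.zeros(65, dtype=bool)
_IS_SENSE[_SENSE_IDX] = True

_NDIFF = np.zeros((65, 65), dtype=np.int8)
_SAME_AA = np.zeros((65, 65), dtype=bool)
for _i in range(64):
    for _j in range(64):
        _NDIFF[_i, _j] = sum(
            1 for p in (16, 4, 1) if (_i // p) % 4 != (_j // p) % 4
        )
        _SAME_AA[_i, _j] = (
            CODONS[_i] in CODON_TO_AA
            and CODON_TO_AA.get(CODONS[_i]) == CODON_TO_AA.get(CODONS[_j])
        )

_NEIGHBORS: list[list[tuple[int, int, str, str, bool]]] = [[] for _ in range(64)]
for _i in range(64):
    if CODONS[_i] not in CODON_TO_AA:
        continue
    for _pos in range(3):
        for _b in "TCAG":
            _alt = CODONS[_i][:_pos] + _b + CODONS[_i][_pos + 1:]
            if _alt == CODONS[_i] or _alt not in CODON_TO_AA:
                continue
            _j = CODONS.index(_alt)
            _NEIGHBORS[_i].append(
                (_j, _pos, CODONS[_i][_pos], _b, bool(_SAME_AA[_i, _j]))
            )


def _fixation_rate(dS: float) -> float:
    """Substitution rate relative to neutral for scaled advantage dS."""
    if abs(dS) < 1e-9:
        return 1.0
    return dS / -math.expm1(-dS)


@dataclass
class _Model:
    """Per-codon sampling tables derived from a SyntheticConfig."""

    eq_by_aa: dict[str, tuple[np.ndarray, np.ndarray]]  # aa -> (codes, probs)
    poly_targets: list[np.ndarray]      # per codon code: neighbor codes
    poly_q: list[np.ndarray]            # per codon code: per-path probability
    poly_total: np.ndarray              # per codon code: total poly prob
    sub_targets_focal: list[np.ndarray]
    sub_q_focal: list[np.ndarray]
    sub_total_focal: np.ndarray
    sub_targets_out: list[np.ndarray]
    sub_q_out: list[np.ndarray]
    sub_total_out: np.ndarray


def _bias(cfg: SyntheticConfig, b_from: str, b_to: str) -> float:
    return float(cfg.mutation_bias.get((b_from, b_to), 1.0))


def _syn_sites(code: int) -> float:
    from .site_calls import _syn_sites_of

    return _syn_sites_of(CODONS[code])


def _build_model(cfg: SyntheticConfig, s_scale: float = 1.0) -> _Model:
    S = {c: cfg.S_by_codon.get(c, 0.0) * s_scale for c in SENSE_CODONS}
    n = cfg.strains
    p_cache: dict[float, float] = {}

    def P(dS: float) -> float:
        key = round(dS, 12)
        if key not in p_cache:
            p_cache[key] = expected_polymorphisms(key, n)
        return p_cache[key]

    p0 = P(0.0)

    eq_by_aa: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    fams: dict[str, list[int]] = {}
    for c in SENSE_CODONS:
        fams.setdefault(CODON_TO_AA[c], []).append(CODONS.index(c))
    for aa, codes in fams.items():
        w = np.array([math.exp(S[CODONS[k]]) for k in codes])
        eq_by_aa[aa] = (np.array(codes), w / w.sum())

    # global normaliser: mean neutral path weight per sense codon
    mean_b = float(
        np.mean([
            sum(_bias(cfg, bf, bt) for (_t, _p, bf, bt, _s) in _NEIGHBORS[k])
            for k in _SENSE_IDX
        ])
    )
    theta_scale = cfg.theta / mean_b if mean_b > 0 else 0.0

    poly_targets, poly_q = [], []
    ftargets, fq = [], []
    otargets, oq = [], []
    poly_total = np.zeros(65)
    f_total = np.zeros(65)
    o_total = np.zeros(65)
    for k in range(64):
        nbrs = _NEIGHBORS[k]
        if not nbrs or CODONS[k] not in CODON_TO_AA:
            poly_targets.append(np.empty(0, dtype=int))
            poly_q.append(np.empty(0))
            ftargets.append(np.empty(0, dtype=int))
            fq.append(np.empty(0))
            otargets.append(np.empty(0, dtype=int))
            oq.append(np.empty(0))
            continue
        tgt = np.array([t for (t, _p, _bf, _bt, _s) in nbrs])
        bias = np.array([_bias(cfg, bf, bt) for (_t, _p, bf, bt, _s) in nbrs])
        dS = np.array([S[CODONS[t]] - S[CODONS[k]] for t in tgt])
        is_syn = np.array([s for (_t, _p, _bf, _bt, s) in nbrs])

        q = theta_scale * bias * np.array([P(d) for d in dS]) / p0
        poly_targets.append(tgt)
        poly_q.append(q)
        poly_total[k] = q.sum()

        # substitution model: realised synonymous divergence ≈ the configured
        # per-syn-site rate; non-synonymous paths scaled by dN/dS and the
        # relative fixation rate of the selection differential
        s_sites = _syn_sites(k)
        syn_w = bias * is_syn
        non_w = bias * ~is_syn * np.array([_fixation_rate(d) for d in dS])
        for (dv, targets_list, q_list, totals, omega) in (
            (cfg.focal_divergence, ftargets, fq, f_total, cfg.outgroup_dnds),
            (cfg.outgroup_divergence, otargets, oq, o_total, cfg.outgroup_dnds),
        ):
            p_syn = dv * s_sites
            p_non = omega * dv * (3.0 - s_sites)
            probs = np.zeros(len(nbrs))
            if syn_w.sum() > 0:
                probs += p_syn * syn_w / syn_w.sum()
            if non_w.sum() > 0:
                probs += p_non * non_w / non_w.sum()
            targets_list.append(tgt)
            q_list.append(probs)
            totals[k] = probs.sum()

    if poly_total.max() >= 0.9:
        raise ValueError(
            f"theta={cfg.theta} drives per-site polymorphism probability to "
            f"{poly_total.max():.2f}; biallelic planting impossible"
        )
    return _Model(eq_by_aa, poly_targets, poly_q, poly_total,
                  ftargets, fq, f_total, otargets, oq, o_total)


# --- ground truth ---------------------------------------------------------


@dataclass
class GroundTruth:
    """Per-site planted truth plus per-gene expression."""

    sites: pd.DataFrame
    expression: dict[str, float]
    config: SyntheticConfig

    def status_counts(self, level: str = "polymorphism") -> pd.Series:
        col = "exp_poly_status" if level == "polymorphism" else "exp_div_status"
        return self.sites[col].value_counts()


def _expected_poly_call(
    observed: dict[int, int], og: int, coverage: float, threshold: float = 0.95
) -> tuple[str, str | None, str | None, str | None]:
    """Status the polymorphism-level caller should assign, from known states."""
    if coverage < threshold:
        return "discarded", "low-coverage", None, None
    if og == MISSING:
        return "discarded", "outgroup-missing", None, None
    states = sorted(k for k, v in observed.items() if v > 0)
    if len(states) == 1:
        s = states[0]
        if not _IS_SENSE[s]:
            return "discarded", "stop-codon", None, None
        return "monomorphic", None, CODONS[s], None
    if len(states) > 2:
        return "discarded", "triallelic", None, None
    a, b = states
    if not (_IS_SENSE[a] and _IS_SENSE[b]):
        return "discarded", "stop-codon", None, None
    if _NDIFF[a, b] != 1:
        return "discarded", "multi-nucleotide", None, None
    if _SAME_AA[a, b]:
        return "discarded", "synonymous-only", None, None
    if og == a:
        return "polymorphic", None, CODONS[a], CODONS[b]
    if og == b:
        return "polymorphic", None, CODONS[b], CODONS[a]
    return "discarded", "outgroup-mismatch", None, None


def _expected_div_call(
    observed: dict[int, int], og1: int, og2: int, coverage: float,
    threshold: float = 0.95,
) -> tuple[str, str | None, str | None, str | None]:
    if coverage < threshold:
        return "discarded", "low-coverage", None, None
    if og1 == MISSING or og2 == MISSING:
        return "discarded", "outgroup-missing", None, None
    states = sorted(k for k, v in observed.items() if v > 0)
    if len(states) != 1:
        return "discarded", "ingroup-polymorphic", None, None
    if og1 != og2:
        return "discarded", "outgroup-conflict", None, None
    s, o = states[0], og1
    if not (_IS_SENSE[s] and _IS_SENSE[o]):
        return "discarded", "stop-codon", None, None
    if s == o:
        return "monomorphic", None, CODONS[s], None
    if _NDIFF[s, o] != 1:
        return "discarded", "multi-nucleotide", None, None
    if _SAME_AA[s, o]:
        return "discarded", "synonymous-only", None, None
    return "fixed_difference", None, CODONS[o], CODONS[s]


# --- the generator --------------------------------------------------------

_CODON_STRS = np.array(CODONS + ["NNN"])


def generate_dataset(cfg: SyntheticConfig):
    """Generate alignments, ground truth, and expression.

    Returns ``(alignments, truth, expression)`` where ``alignments`` is a
    list of :class:`~codonsel.site_calls.GeneAlignment` (strain ids
    ``strain_###``, outgroups ``og1``/``og2``), ``truth`` a
    :class:`GroundTruth`, and ``expression`` a gene→log-expression dict.
    """
    from .site_calls import GeneAlignment

    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.strains

    aas = sorted(cfg.aa_composition)
    comp = np.array([cfg.aa_composition[a] for a in aas])
    comp = comp / comp.sum()

    base_model = _build_model(cfg)

    # derived-count spectrum p(k) ∝ 1/k, k = 1..n-1
    ks = np.arange(1, n)
    sfs_p = (1.0 / ks) / (1.0 / ks).sum()

    strain_ids = [f"strain_{i:03d}" for i in range(n)]
    alignments: list[GeneAlignment] = []
    expression: dict[str, float] = {}
    records: list[tuple] = []

    for g in range(cfg.genes):
        gene_id = f"gene_{g:04d}"
        if isinstance(cfg.codons_per_gene, tuple):
            L = int(rng.integers(cfg.codons_per_gene[0],
                                 cfg.codons_per_gene[1] + 1))
        else:
            L = int(cfg.codons_per_gene)
        z = float(rng.normal())
        expression[gene_id] = cfg.expression_mu + cfg.expression_sd * z
        if cfg.expression_selection_beta != 0.0:
            model = _build_model(
                cfg, s_scale=math.exp(cfg.expression_selection_beta * z))
        else:
            model = base_model

        aa_idx = rng.choice(len(aas), size=L, p=comp)
        anc = np.zeros(L, dtype=np.int64)
        for ai in np.unique(aa_idx):
            codes, probs = model.eq_by_aa[aas[ai]]
            sel = aa_idx == ai
            anc[sel] = rng.choice(codes, size=int(sel.sum()), p=probs)

        # focal-branch substitutions -> ingroup base state
        base = anc.copy()
        u = rng.random(L)
        for j in np.nonzero(u < model.sub_total_focal[anc])[0]:
            q = model.sub_q_focal[anc[j]]
            base[j] = rng.choice(model.sub_targets_focal[anc[j]],
                                 p=q / q.sum())

        # outgroups evolve independently from the ancestor
        ogs = []
        for _ in range(2):
            og = anc.copy()
            u = rng.random(L)
            for j in np.nonzero(u < model.sub_total_out[anc])[0]:
                q = model.sub_q_out[anc[j]]
                og[j] = rng.choice(model.sub_targets_out[anc[j]],
                                   p=q / q.sum())
            ogs.append(og)
        og1, og2 = ogs

        # plant polymorphisms on top of the ingroup base state
        derived = np.full(L, -1, dtype=np.int64)
        derived_count = np.zeros(L, dtype=np.int64)
        noise_allele = np.full(L, -1, dtype=np.int64)
        M = np.tile(base, (n, 1))
        u = rng.random(L)
        poly_sites = np.nonzero(u < model.poly_total[base])[0]
        for j in poly_sites:
            q = model.poly_q[base[j]]
            tgt = int(rng.choice(model.poly_targets[base[j]], p=q / q.sum()))
            k = int(rng.choice(ks, p=sfs_p))
            carriers = rng.permutation(n)[:k]
            M[carriers, j] = tgt
            derived[j] = tgt
            derived_count[j] = k
            if cfg.triallelic_noise > 0 and rng.random() < cfg.triallelic_noise:
                others = [t for t in model.poly_targets[base[j]] if t != tgt]
                if others and k < n - 1:
                    extra = int(rng.choice(np.array(others)))
                    non_carriers = np.setdiff1d(np.arange(n), carriers)
                    victim = int(rng.choice(non_carriers))
                    M[victim, j] = extra
                    noise_allele[j] = extra

        # missing data
        if cfg.missing_rate > 0:
            mask = rng.random((n, L)) < cfg.missing_rate
            M[mask] = MISSING
        else:
            mask = np.zeros((n, L), dtype=bool)
        coverage = 1.0 - mask.mean(axis=0)

        # expected caller statuses
        conflict = og1 != og2
        mono = derived < 0
        exp_poly = [None] * L
        exp_div = [None] * L
        # fast vectorised path for clean monomorphic columns
        clean = mono & (coverage >= 0.95)
        for j in range(L):
            if clean[j] and noise_allele[j] < 0:
                exp_poly[j] = ("monomorphic", None, CODONS[base[j]], None)
                if conflict[j]:
                    exp_div[j] = ("discarded", "outgroup-conflict", None, None)
                else:
                    s, o = int(base[j]), int(og1[j])
                    if s == o:
                        exp_div[j] = ("monomorphic", None, CODONS[s], None)
                    elif _NDIFF[s, o] != 1:
                        exp_div[j] = ("discarded", "multi-nucleotide", None, None)
                    elif _SAME_AA[s, o]:
                        exp_div[j] = ("discarded", "synonymous-only", None, None)
                    else:
                        exp_div[j] = ("fixed_difference", None, CODONS[o],
                                      CODONS[s])
            else:
                col = M[:, j]
                observed: dict[int, int] = {}
                for v in col:
                    if v != MISSING:
                        observed[int(v)] = observed.get(int(v), 0) + 1
                exp_poly[j] = _expected_poly_call(observed, int(og1[j]),
                                                 coverage[j])
                exp_div[j] = _expected_div_call(observed, int(og1[j]),
                                                int(og2[j]), coverage[j])

        ingroup = {
            strain_ids[i]: "".join(_CODON_STRS[np.minimum(M[i], 64)])
            for i in range(n)
        }
        outgroups = {
            "og1": "".join(_CODON_STRS[og1]),
            "og2": "".join(_CODON_STRS[og2]),
        }
        alignments.append(GeneAlignment(gene_id, ingroup, outgroups))

        for j in range(L):
            ps, pr, pa, pd_ = exp_poly[j]
            ds, dr, da, dd = exp_div[j]
            records.append((
                gene_id, j, aas[aa_idx[j]], CODONS[anc[j]], CODONS[base[j]],
                CODONS[derived[j]] if derived[j] >= 0 else None,
                int(derived_count[j]), CODONS[og1[j]], CODONS[og2[j]],
                float(coverage[j]), ps, pr, pa, pd_, ds, dr, da, dd,
            ))

    sites = pd.DataFrame(
        records,
        columns=[
            "gene_id", "codon_index", "aa", "ancestral_codon", "base_codon",
            "derived_codon", "derived_count", "og1", "og2", "coverage",
            "exp_poly_status", "exp_poly_reason", "exp_poly_anc",
            "exp_poly_der", "exp_div_status", "exp_div_reason", "exp_div_anc",
            "exp_div_der",
        ],
    )
    return alignments, GroundTruth(sites, expression, cfg), expression


def expected_log_y_truth(
    cfg: SyntheticConfig, pair: DirectedAminoAcidPair, n: int | None = None
) -> float:
    """Planted expected log Y_pol for a directed pair under the config.

    Uses the extreme codon mutations the pipeline would select at the exact
    selection equilibrium, and the ratio of expected polymorphism counts
    (times any mutation-bias asymmetry between the two paths).
    """
    from .codon_usage import compute_rscu
    from .y_statistic import select_extreme_codon_pairs

    n = cfg.strains if n is None else n
    counts = {}
    comp = cfg.aa_composition
    fams: dict[str, list[str]] = {}
    for c in SENSE_CODONS:
        fams.setdefault(CODON_TO_AA[c], []).append(c)
    for aa, fam in fams.items():
        w = np.array([math.exp(cfg.S_by_codon.get(c, 0.0)) for c in fam])
        w = w / w.sum()
        for c, p in zip(fam, w):
            counts[c] = comp.get(aa, 0.0) * p * 1e6
    profile = compute_rscu(counts, source="equilibrium")
    extremes = select_extreme_codon_pairs(pair, profile)
    if extremes is None:
        return math.nan
    max_mut, min_mut = extremes

    def path_rate(m):
        dS = (cfg.S_by_codon.get(m.derived_codon, 0.0)
              - cfg.S_by_codon.get(m.ancestral_codon, 0.0))
        bf, bt = m.nucleotide_change
        return (float(cfg.mutation_bias.get((bf, bt), 1.0))
                * expected_polymorphisms(dS, n))

    return math.log(path_rate(max_mut) / path_rate(min_mut))


# --- on-disk form ---------------------------------------------------------


def write_dataset(
    alignments: Sequence,
    truth: GroundTruth,
    expression: Mapping[str, float],
    outdir: str | Path,
    outgroup_prefix: str = "OUTGROUP|",
) -> Path:
    """Write one FASTA per gene, expression.tsv, ground_truth.tsv and a
    config echo; returns the output directory."""
    outdir = Path(outdir)
    (outdir / "alignments").mkdir(parents=True, exist_ok=True)
    for aln in alignments:
        with open(outdir / "alignments" / f"{aln.gene_id}.fasta", "w") as fh:
            for sid, seq in aln.ingroup.items():
                fh.write(f">{sid}\n{seq}\n")
            for oid, seq in aln.outgroups.items():
                fh.write(f">{outgroup_prefix}{oid}\n{seq}\n")
    pd.DataFrame(
        sorted(expression.items()), columns=["gene_id", "expression"]
    ).to_csv(outdir / "expression.tsv", sep="\t", index=False)
    truth.sites.to_csv(outdir / "ground_truth.tsv", sep="\t", index=False)
    cfg = truth.config
    echo = {
        "seed": cfg.seed, "genes": cfg.genes, "strains": cfg.strains,
        "codons_per_gene": cfg.codons_per_gene, "theta": cfg.theta,
        "outgroup_divergence": cfg.outgroup_divergence,
        "focal_divergence": cfg.focal_divergence,
        "outgroup_dnds": cfg.outgroup_dnds,
        "missing_rate": cfg.missing_rate,
        "S_by_codon": {c: s for c, s in cfg.S_by_codon.items() if s != 0.0},
    }
    (outdir / "config.json").write_text(json.dumps(echo, indent=2))
    return outdir
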