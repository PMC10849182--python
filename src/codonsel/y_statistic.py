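"""Pooled codon-level odds ratios (log Y) and ΔRSCU for directed amino-acid pairs.

For a directed amino-acid change such as Gln → Lys, the statistic Y contrasts
the rate of non-synonymous changes along the codon mutation that most
increases RSCU (e.g. CAA → AAA, unpreferred Gln codon to preferred Lys codon)
with the rate along the mutation that most decreases it (CAG → AAG), each
normalized by its opportunity — the number of monomorphic (polymorphism
level) or three-species-identical (divergence level) sites of the respective
ancestral codon:

    Y = (N_up / N_up_opportunity) / (N_down / N_down_opportunity)

Per-gene 2×2 tables are pooled with the Cochran–Mantel–Haenszel estimator to
avoid Simpson's paradox, and results are reported as natural log Y.  ΔRSCU
is the ratio-of-ratios summary of how strongly the amino-acid change shifts
RSCU between its extreme codon mutations.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .codon_usage import CodonUsageProfile
from .genetic_code import (
    CodonMutation,
    DirectedAminoAcidPair,
)
from .site_calls import SiteCall

logger = logging.getLogger(__name__)


@dataclass
class PairStratum:
    """Per-gene 2×2 table for one directed amino-acid pair.

    ``up`` refers to the RSCU-increasing codon mutation (max), ``down`` to
    the RSCU-decreasing one (min); opportunities are monomorphic / fixed
    sites of the respective ancestral codons.
    """

    gene_id: str
    pair_label: str
    up_events: int
    down_events: int
    up_opportunity: int
    down_opportunity: int

    def __post_init__(self) -> None:
        if min(self.up_events, self.down_events,
               self.up_opportunity, self.down_opportunity) < 0:
            raise ValueError("negative cell count")

    @property
    def total(self) -> int:
        return (self.up_events + self.down_events
                + self.up_opportunity + self.down_opportunity)

    def is_empty(self) -> bool:
        return self.total == 0


@dataclass
class YEstimate:
    """CMH-pooled log Y for one pair at one level (polymorphism/divergence)."""

    pair_label: str
    level: str
    log_y: float  # NaN when the pooled numerator or denominator is zero
    strata_used: int
    total_up: int
    total_down: int

    @property
    def defined(self) -> bool:
        return not math.isnan(self.log_y)


@dataclass
class DeltaRscuResult:
    """ΔRSCU of a pair: ratio of the max mutation's RSCU ratio to the min's."""

    pair_label: str
    max_mutation: CodonMutation
    min_mutation: CodonMutation
    delta_rscu: float
    log_delta_rscu: float


def select_extreme_codon_pairs(
    pair: DirectedAminoAcidPair,
    profile: CodonUsageProfile,
    derived_profile: CodonUsageProfile | None = None,
    criterion: str = "ratio",
) -> tuple[CodonMutation, CodonMutation] | None:
    """Pick the RSCU-increasing (max) and RSCU-decreasing (min) codon mutations.

    Among the pair's single-step codon mutations, max maximizes and min
    minimizes RSCU_derived / RSCU_ancestral ("ratio" criterion; a "difference"
    criterion is available).  Ancestral-codon RSCU is looked up in ``profile``
    and derived-codon RSCU in ``derived_profile`` (defaults to ``profile``;
    the divergence-level analysis passes the outgroup profile for ancestral
    states).  Mutations with a zero or undefined ancestral RSCU are excluded
    under the ratio criterion; returns None when no valid mutation remains.
    Ties are broken lexicographically on the codon pair and logged.
    """
    if criterion not in ("ratio", "difference"):
        raise ValueError(f"unknown criterion {criterion!r}")
    dprof = derived_profile if derived_profile is not None else profile
    scored: list[tuple[float, CodonMutation]] = []
    for m in pair.codon_mutations:
        r_anc = profile.rscu.get(m.ancestral_codon, math.nan)
        r_der = dprof.rscu.get(m.derived_codon, math.nan)
        if math.isnan(r_anc) or math.isnan(r_der):
            continue
        if criterion == "ratio":
            if r_anc <= 0:
                continue
            scored.append((r_der / r_anc, m))
        else:
            scored.append((r_der - r_anc, m))
    if not scored:
        return None
    scored.sort(key=lambda t: (-t[0], t[1].ancestral_codon, t[1].derived_codon))
    if len(scored) > 1 and scored[0][0] == scored[-1][0]:
        logger.warning("pair %s: all RSCU ratios tie; lexicographic tie-break",
                       pair.label)
    max_mut = scored[0][1]
    min_mut = min(scored, key=lambda t: (t[0], t[1].ancestral_codon,
                                         t[1].derived_codon))[1]
    return max_mut, min_mut


def build_strata(
    calls: Iterable[SiteCall],
    pair: DirectedAminoAcidPair,
    extremes: tuple[CodonMutation, CodonMutation],
    level: str = "polymorphism",
) -> list[PairStratum]:
    """Per-gene 2×2 tables for one pair from classified site calls.

    ``level`` selects the event status: "polymorphism" counts polymorphic
    calls, "divergence" counts fixed differences; opportunities come from
    monomorphic calls of the respective ancestral codons at the same level.
    Genes with all four cells zero are omitted.
    """
    if level not in ("polymorphism", "divergence"):
        raise ValueError(f"unknown level {level!r}")
    event_status = "polymorphic" if level == "polymorphism" else "fixed_difference"
    max_mut, min_mut = extremes
    if isinstance(calls, pd.DataFrame):
        return _build_strata_frame(calls, pair, max_mut, min_mut, event_status)
    per_gene: dict[str, list[int]] = {}
    for c in calls:
        if c.status == event_status:
            key = (c.ancestral_codon, c.derived_codon)
            if key == (max_mut.ancestral_codon, max_mut.derived_codon):
                per_gene.setdefault(c.gene_id, [0, 0, 0, 0])[0] += 1
            elif key == (min_mut.ancestral_codon, min_mut.derived_codon):
                per_gene.setdefault(c.gene_id, [0, 0, 0, 0])[1] += 1
        elif c.status == "monomorphic":
            if c.ancestral_codon == max_mut.ancestral_codon:
                per_gene.setdefault(c.gene_id, [0, 0, 0, 0])[2] += 1
            elif c.ancestral_codon == min_mut.ancestral_codon:
                per_gene.setdefault(c.gene_id, [0, 0, 0, 0])[3] += 1
    return [
        PairStratum(g, pair.label, *cells)
        for g, cells in per_gene.items()
        if sum(cells) > 0
    ]


def _build_strata_frame(
    df: pd.DataFrame, pair, max_mut, min_mut, event_status: str
) -> list[PairStratum]:
    """Vectorised stratum construction from a calls_frame table."""
    ev = df[df["status"] == event_status]
    mono = df[df["status"] == "monomorphic"]
    up = (
        ev[(ev["ancestral"] == max_mut.ancestral_codon)
           & (ev["derived"] == max_mut.derived_codon)]
        .groupby("gene_id").size()
    )
    down = (
        ev[(ev["ancestral"] == min_mut.ancestral_codon)
           & (ev["derived"] == min_mut.derived_codon)]
        .groupby("gene_id").size()
    )
    up_opp = mono[mono["ancestral"] == max_mut.ancestral_codon].groupby(
        "gene_id").size()
    down_opp = mono[mono["ancestral"] == min_mut.ancestral_codon].groupby(
        "gene_id").size()
    cells = pd.DataFrame(
        {"up": up, "down": down, "up_opp": up_opp, "down_opp": down_opp}
    ).fillna(0).astype(int)
    return [
        PairStratum(str(g), pair.label, int(r.up), int(r.down),
                    int(r.up_opp), int(r.down_opp))
        for g, r in cells.iterrows()
        if r.sum() > 0
    ]


def cmh_pooled_log_y(
    strata: Sequence[PairStratum], level: str = "polymorphism",
    pair_label: str | None = None,
) -> YEstimate:
    """Cochran–Mantel–Haenszel pooled odds ratio across gene strata.

    pooled OR = Σ_i (up_i · down_opp_i / T_i) / Σ_i (down_i · up_opp_i / T_i)
    with T_i the stratum total.  With a single stratum this is exactly the
    simple odds ratio.  No continuity correction is applied: when either sum
    is zero log Y is NaN (undefined), mirroring pairs dropped from the
    divergence-level analysis.
    """
    strata = [s for s in strata if not s.is_empty()]
    if not strata:
        raise ValueError("no strata supplied")
    num = sum(s.up_events * s.down_opportunity / s.total for s in strata)
    den = sum(s.down_events * s.up_opportunity / s.total for s in strata)
    log_y = math.log(num / den) if num > 0 and den > 0 else math.nan
    return YEstimate(
        pair_label=pair_label or strata[0].pair_label,
        level=level,
        log_y=log_y,
        strata_used=len(strata),
        total_up=sum(s.up_events for s in strata),
        total_down=sum(s.down_events for s in strata),
    )


def cmh_log_y_se(strata: Sequence[PairStratum]) -> float:
    """Robins–Breslow–Greenland standard error of the CMH pooled log OR.

    Valid whatever the true ORs; NaN when either pooled sum is zero.
    """
    strata = [s for s in strata if not s.is_empty()]
    if not strata:
        raise ValueError("no strata supplied")
    P = [(s.up_events + s.down_opportunity) / s.total for s in strata]
    Q = [(s.down_events + s.up_opportunity) / s.total for s in strata]
    R = [s.up_events * s.down_opportunity / s.total for s in strata]
    S = [s.down_events * s.up_opportunity / s.total for s in strata]
    sr, ss = sum(R), sum(S)
    if sr <= 0 or ss <= 0:
        return math.nan
    var = (
        sum(p * r for p, r in zip(P, R)) / (2 * sr**2)
        + sum(p * s_ + q * r for p, q, r, s_ in zip(P, Q, R, S)) / (2 * sr * ss)
        + sum(q * s_ for q, s_ in zip(Q, S)) / (2 * ss**2)
    )
    return math.sqrt(var)


def unstratified_log_y(strata: Sequence[PairStratum]) -> float:
    """Diagnostic: odds ratio of the cell sums, ignoring gene structure."""
    a = sum(s.up_events for s in strata)
    b = sum(s.down_events for s in strata)
    c = sum(s.up_opportunity for s in strata)
    d = sum(s.down_opportunity for s in strata)
    if a * d > 0 and b * c > 0:
        return math.log((a * d) / (b * c))
    return math.nan


def delta_rscu(
    pair: DirectedAminoAcidPair,
    extremes: tuple[CodonMutation, CodonMutation],
    profile_ancestral: CodonUsageProfile,
    profile_derived: CodonUsageProfile | None = None,
) -> DeltaRscuResult | None:
    """ΔRSCU = (RSCU_der(max)/RSCU_anc(max)) / (RSCU_der(min)/RSCU_anc(min)).

    Ancestral-codon RSCU values come from ``profile_ancestral`` and derived
    from ``profile_derived`` (defaulting to the same profile, as at the
    polymorphism level; the divergence analysis passes the outgroup profile
    as ancestral).  Returns None on a zero/undefined denominator.
    """
    dprof = profile_derived if profile_derived is not None else profile_ancestral
    max_mut, min_mut = extremes
    try:
        num = dprof.rscu[max_mut.derived_codon] / profile_ancestral.rscu[
            max_mut.ancestral_codon]
        den = dprof.rscu[min_mut.derived_codon] / profile_ancestral.rscu[
            min_mut.ancestral_codon]
    except (KeyError, ZeroDivisionError):
        return None
    if not (num > 0 and den > 0) or math.isnan(num) or math.isnan(den):
        return None
    d = num / den
    return DeltaRscuResult(
        pair_label=pair.label,
        max_mutation=max_mut,
        min_mutation=min_mut,
        delta_rscu=d,
        log_delta_rscu=math.log(d),
    )


def estimates_frame(
    estimates: Iterable[YEstimate],
    deltas: Mapping[str, DeltaRscuResult] | None = None,
) -> pd.DataFrame:
    """Tidy per-pair table of log Y (and ΔRSCU when supplied)."""
    rows = []
    for e in estimates:
        d = (deltas or {}).get(e.pair_label)
        rows.append(
            {
                "pair": e.pair_label,
                "level": e.level,
                "log_y": e.log_y,
                "strata_used": e.strata_used,
                "total_up": e.total_up,
                "total_down": e.total_down,
                "max_mutation": str(d.max_mutation) if d else None,
                "min_mutation": str(d.min_mutation) if d else None,
                "delta_rscu": d.delta_rscu if d else math.nan,
                "log_delta_rscu": d.log_delta_rscu if d else math.nan,
            }
        )
    return pd.DataFrame(rows)
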