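"""Polarized codon-level site classification and synonymous divergence.

Works on per-gene codon-aware alignments of many ingroup strains plus one or
two outgroup sequences.  Each codon column is classified as monomorphic,
polymorphic, fixed difference, or discarded with a reason, applying the
filters used for codon-level polymorphism statistics:

* ingroup coverage ≥ 95% unambiguous codons (gaps and ambiguity characters
  count as missing);
* biallelism at the *codon* level — exactly two codon haplotypes;
* the two states one nucleotide apart and the change non-synonymous;
* polarization by an outgroup codon that matches one of the two states
  (that state is called ancestral).

Fixed differences between the ingroup and the outgroups additionally require
the ingroup to be monomorphic and the two outgroups to agree.  Synonymous
divergence d_S is computed by unweighted Nei–Gojobori (1986) counting, with
an optional Jukes–Cantor correction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .genetic_code import CODON_TO_AA, CODONS, STANDARD_TABLE

MISSING = 64  # sentinel codon code for gap / ambiguous codon

_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("TCAG"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i
_BASE_CODE[ord("U")] = 0
_BASE_CODE[ord("u")] = 0

_IS_STOP = np.zeros(65, dtype=bool)
for _c in STANDARD_TABLE.stop_codons:
    _IS_STOP[CODONS.index(_c)] = True

_AA_CODE = np.full(65, 255, dtype=np.uint8)
for _i, _c in enumerate(CODONS):
    if _c in CODON_TO_AA:
        _AA_CODE[_i] = ord(CODON_TO_AA[_c])


def encode_codons(seq: str) -> np.ndarray:
    """Encode an in-frame DNA string as codon codes 0–63 (64 = missing)."""
    if len(seq) % 3 != 0:
        raise ValueError(f"sequence length {len(seq)} not divisible by 3")
    b = _BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    b = b.reshape(-1, 3)
    bad = (b == 255).any(axis=1)
    codes = (b[:, 0].astype(np.int16) * 16 + b[:, 1] * 4 + b[:, 2]).astype(np.uint8)
    codes[bad] = MISSING
    return codes


def decode_codon(code: int) -> str:
    return CODONS[code] if code < MISSING else "NNN"


@dataclass
class GeneAlignment:
    """In-frame codon alignment of ingroup strains plus ordered outgroups."""

    gene_id: str
    ingroup: dict[str, str]
    outgroups: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.ingroup.values()} | {
            len(s) for s in self.outgroups.values()
        }
        if len(lengths) > 1:
            raise ValueError(f"gene {self.gene_id}: unequal sequence lengths")
        (length,) = lengths or {0}
        if length % 3 != 0:
            raise ValueError(f"gene {self.gene_id}: length {length} not in frame")
        self._length = length // 3

    @property
    def length(self) -> int:
        """Alignment length in codons."""
        return self._length

    def ingroup_matrix(self) -> np.ndarray:
        """(n_strains, n_codons) codon-code matrix, strain order preserved."""
        return np.vstack([encode_codons(s) for s in self.ingroup.values()])

    def outgroup_codes(self, outgroup_id: str) -> np.ndarray:
        if outgroup_id not in self.outgroups:
            raise ValueError(
                f"gene {self.gene_id}: outgroup {outgroup_id!r} not present"
            )
        return encode_codons(self.outgroups[outgroup_id])

    def consensus(self) -> str:
        """Majority-rule codon consensus of the ingroup (ties: first seen)."""
        M = self.ingroup_matrix()
        out = []
        for j in range(M.shape[1]):
            col = M[:, j][M[:, j] != MISSING]
            if col.size == 0:
                out.append("NNN")
                continue
            vals, counts = np.unique(col, return_counts=True)
            out.append(CODONS[int(vals[np.argmax(counts)])])
        return "".join(out)


def read_gene_alignment(
    path: str | Path, outgroup_prefix: str = "OUTGROUP|", gene_id: str | None = None
) -> GeneAlignment:
    """Read a per-gene FASTA; records whose id starts with ``outgroup_prefix``
    become outgroups (prefix stripped), the rest are ingroup strains."""
    path = Path(path)
    ingroup: dict[str, str] = {}
    outgroups: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if rec.id.startswith(outgroup_prefix):
            outgroups[rec.id[len(outgroup_prefix):]] = seq
        else:
            ingroup[rec.id] = seq
    return GeneAlignment(gene_id or path.stem, ingroup, outgroups)


@dataclass
class SiteCall:
    """Classified alignment column."""

    gene_id: str
    codon_index: int
    status: str  # monomorphic | polymorphic | fixed_difference | discarded
    discard_reason: str | None = None
    ancestral_codon: str | None = None
    derived_codon: str | None = None
    coverage_fraction: float = 1.0


def _ndiff(a: int, b: int) -> int:
    n = 0
    for div in (16, 4, 1):
        if (a // div) % 4 != (b // div) % 4:
            n += 1
    return n


def call_polymorphic_sites(
    aln: GeneAlignment, outgroup_id: str, coverage_threshold: float = 0.95
) -> list[SiteCall]:
    """Classify every codon column for the polymorphism-level analysis.

    Returns one :class:`SiteCall` per column.  Monomorphic calls populate the
    per-codon opportunity denominators; polymorphic calls are retained only
    for biallelic, single-nucleotide, non-synonymous changes polarizable by
    the outgroup.
    """
    M = aln.ingroup_matrix()
    og = aln.outgroup_codes(outgroup_id)
    n = M.shape[0]
    present = M != MISSING
    coverage = present.sum(axis=0) / n

    calls: list[SiteCall] = []
    for j in range(aln.length):
        cov = float(coverage[j])
        if cov < coverage_threshold:
            calls.append(
                SiteCall(aln.gene_id, j, "discarded", "low-coverage",
                         coverage_fraction=cov)
            )
            continue
        col = M[present[:, j], j]
        states = np.unique(col)
        if og[j] == MISSING:
            calls.append(
                SiteCall(aln.gene_id, j, "discarded", "outgroup-missing",
                         coverage_fraction=cov)
            )
            continue
        if states.size == 1:
            s = int(states[0])
            if _IS_STOP[s]:
                calls.append(
                    SiteCall(aln.gene_id, j, "discarded", "stop-codon",
                             coverage_fraction=cov)
                )
            else:
                calls.append(
                    SiteCall(aln.gene_id, j, "monomorphic",
                             ancestral_codon=CODONS[s], coverage_fraction=cov)
                )
            continue
        if states.size > 2:
            calls.append(
                SiteCall(aln.gene_id, j, "discarded", "triallelic",
                         coverage_fraction=cov)
            )
            continue
        a, b = int(states[0]), int(states[1])
        if _IS_STOP[a] or _IS_STOP[b]:
            calls.append(
                SiteCall(aln.gene_id, j, "discarded", "stop-codon",
                         coverage_fraction=cov)
            )
            continue
        if _ndiff(a, b) != 1:
            calls.append(
                SiteCall(aln.gene_id, j, "discarded", "multi-nucleotide",
                         coverage_fraction=cov)
            )
            continue
        if _AA_CODE[a] == _AA_CODE[b]:
            calls.append(
                SiteCall(aln.gene_id, j, "discarded", "synonymous-only",
                         coverage_fraction=cov)
            )
            continue
        if og[j] == a:
            anc, der = a, b
        elif og[j] == b:
            anc, der = b, a
        else:
            calls.append(
                SiteCall(aln.gene_id, j, "discarded", "outgroup-mismatch",
                         coverage_fraction=cov)
            )
            continue
        calls.append(
            SiteCall(aln.gene_id, j, "polymorphic",
                     ancestral_codon=CODONS[anc], derived_codon=CODONS[der],
                     coverage_fraction=cov)
        )
    return calls


def call_fixed_differences(
    aln: GeneAlignment,
    outgroup_ids: Sequence[str] | None = None,
    coverage_threshold: float = 0.95,
) -> list[SiteCall]:
    """Classify codon columns for the divergence-level analysis.

    A retained fixed difference needs a monomorphic ingroup, two agreeing
    outgroups, and a single-nucleotide non-synonymous change between the
    ingroup and outgroup states.  Columns where all three species share the
    state are monomorphic and populate the fixed-site denominators.
    """
    ids = list(outgroup_ids) if outgroup_ids is not None else list(aln.outgroups)
    if len(ids) < 2:
        raise ValueError(f"gene {aln.gene_id}: two outgroups required, got {ids}")
    og1 = aln.outgroup_codes(ids[0])
    og2 = aln.outgroup_codes(ids[1])
    M = aln.ingroup_matrix()
    n = M.shape[0]
    present = M != MISSING
    coverage = present.sum(axis=0) / n

    calls: list[SiteCall] = []
    for j in range(aln.length):
        cov = float(coverage[j])
        if cov < coverage_threshold:
            calls.append(SiteCall(aln.gene_id, j, "discarded", "low-coverage",
                                  coverage_fraction=cov))
            continue
        if og1[j] == MISSING or og2[j] == MISSING:
            calls.append(SiteCall(aln.gene_id, j, "discarded", "outgroup-missing",
                                  coverage_fraction=cov))
            continue
        col = M[present[:, j], j]
        states = np.unique(col)
        if states.size != 1:
            calls.append(SiteCall(aln.gene_id, j, "discarded", "ingroup-polymorphic",
                                  coverage_fraction=cov))
            continue
        if og1[j] != og2[j]:
            calls.append(SiteCall(aln.gene_id, j, "discarded", "outgroup-conflict",
                                  coverage_fraction=cov))
            continue
        s = int(states[0])
        o = int(og1[j])
        if _IS_STOP[s] or _IS_STOP[o]:
            calls.append(SiteCall(aln.gene_id, j, "discarded", "stop-codon",
                                  coverage_fraction=cov))
            continue
        if s == o:
            calls.append(SiteCall(aln.gene_id, j, "monomorphic",
                                  ancestral_codon=CODONS[s], coverage_fraction=cov))
            continue
        if _ndiff(s, o) != 1:
            calls.append(SiteCall(aln.gene_id, j, "discarded", "multi-nucleotide",
                                  coverage_fraction=cov))
            continue
        if _AA_CODE[s] == _AA_CODE[o]:
            calls.append(SiteCall(aln.gene_id, j, "discarded", "synonymous-only",
                                  coverage_fraction=cov))
            continue
        calls.append(SiteCall(aln.gene_id, j, "fixed_difference",
                              ancestral_codon=CODONS[o], derived_codon=CODONS[s],
                              coverage_fraction=cov))
    return calls


def calls_frame(calls: Iterable[SiteCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (c.gene_id, c.codon_index, c.status, c.discard_reason,
             c.ancestral_codon, c.derived_codon, c.coverage_fraction)
            for c in calls
        ],
        columns=["gene_id", "codon_index", "status", "discard_reason",
                 "ancestral", "derived", "coverage"],
    )


# ---------------------------------------------------------------------------
# Nei–Gojobori synonymous divergence
# ---------------------------------------------------------------------------


@dataclass
class DivergenceSummary:
    """Synonymous substitutions per synonymous site between two sequences."""

    species_pair: tuple[str, str]
    syn_substitutions: float
    syn_sites: float
    d_s: float
    nonsyn_substitutions: float = 0.0
    nonsyn_sites: float = 0.0
    d_n: float = float("nan")
    codons_compared: int = 0
    corrected: bool = False


@lru_cache(maxsize=None)
def _syn_sites_of(codon: str) -> float:
    """NG86 synonymous site count of a sense codon.

    At each position, the fraction of the three possible nucleotide changes
    that are synonymous; changes to stop codons count as non-synonymous.
    """
    aa = CODON_TO_AA[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        for b in "TCAG":
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if CODON_TO_AA.get(alt) == aa:
                syn += 1
        s += syn / 3.0
    return s


@lru_cache(maxsize=None)
def _path_counts(ca: str, cb: str) -> tuple[float, float]:
    """(syn, nonsyn) substitution counts between two sense codons.

    Multi-hit codons are averaged over minimal mutational pathways; pathways
    passing through a stop codon are excluded unless all do.
    """
    diffs = [i for i in range(3) if ca[i] != cb[i]]
    if not diffs:
        return 0.0, 0.0
    paths: list[tuple[float, float, bool]] = []  # (syn, nonsyn, hits_stop)
    for order in itertools.permutations(diffs):
        cur = ca
        syn = nonsyn = 0.0
        stop_hit = False
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
            if nxt in STANDARD_TABLE.stop_codons:
                stop_hit = True
                nonsyn += 1.0
            elif CODON_TO_AA.get(nxt) == CODON_TO_AA.get(cur):
                syn += 1.0
            else:
                nonsyn += 1.0
            cur = nxt
        paths.append((syn, nonsyn, stop_hit))
    valid = [p for p in paths if not p[2]] or paths
    syn = sum(p[0] for p in valid) / len(valid)
    nonsyn = sum(p[1] for p in valid) / len(valid)
    return syn, nonsyn


def compute_ds(
    seq_a: str,
    seq_b: str,
    species_pair: tuple[str, str] = ("a", "b"),
    jukes_cantor: bool = False,
) -> DivergenceSummary:
    """Unweighted Nei–Gojobori d_S between two in-frame coding sequences.

    Codons containing gaps, ambiguity characters or stops in either sequence
    are skipped.  With ``jukes_cantor=True`` the proportions are corrected by
    d = -3/4 · ln(1 - 4p/3).
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences differ in length")
    ca_codes = encode_codons(seq_a)
    cb_codes = encode_codons(seq_b)
    S = N = Sd = Nd = 0.0
    used = 0
    for x, y in zip(ca_codes, cb_codes):
        if x == MISSING or y == MISSING or _IS_STOP[x] or _IS_STOP[y]:
            continue
        cx, cy = CODONS[int(x)], CODONS[int(y)]
        S += (_syn_sites_of(cx) + _syn_sites_of(cy)) / 2.0
        N += 3.0 - (_syn_sites_of(cx) + _syn_sites_of(cy)) / 2.0
        sd, nd = _path_counts(cx, cy)
        Sd += sd
        Nd += nd
        used += 1

    def _rate(subs: float, sites: float) -> float:
        if sites <= 0:
            return float("nan")
        p = subs / sites
        if not jukes_cantor:
            return p
        if p >= 0.75:
            return float("inf")
        return -0.75 * np.log(1.0 - 4.0 * p / 3.0)

    return DivergenceSummary(
        species_pair=species_pair,
        syn_substitutions=Sd,
        syn_sites=S,
        d_s=_rate(Sd, S),
        nonsyn_substitutions=Nd,
        nonsyn_sites=N,
        d_n=_rate(Nd, N),
        codons_compared=used,
        corrected=jukes_cantor,
    )
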