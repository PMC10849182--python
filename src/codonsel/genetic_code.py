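"""Standard bacterial genetic code and single-step amino-acid pair enumeration.

The standard genetic code (NCBI translation table 1, identical in codon
assignments to the bacterial table 11 used by *E. coli* and *S. pneumoniae*)
maps 61 sense codons to 20 amino acids.  Synonymous-codon selection analyses
compare amino acids of matched degeneracy, so this module classifies each
amino acid by family size and enumerates every *directed* amino-acid pair
(A→B and B→A counted separately) whose codons are connected by a single
non-synonymous nucleotide change, restricted to the 2-fold and 4-fold
degenerate families.  Met and Trp (1 codon), Ile (3 codons) and the 6-fold
amino acids Leu, Ser, Arg never enter the enumeration.

Codons are DNA, uppercase (T, not U).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

NUCLEOTIDES = "TCAG"

#: All 64 codons in TCAG order (TTT, TTC, TTA, TTG, TCT, ...).
CODONS = ["".join(c) for c in itertools.product(NUCLEOTIDES, repeat=3)]

# Standard code as a 64-character string in TCAG order; '*' = stop.
_AA_STRING = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"

STOP_CODONS = frozenset(c for c, a in zip(CODONS, _AA_STRING) if a == "*")
CODON_TO_AA = {c: a for c, a in zip(CODONS, _AA_STRING) if a != "*"}
SENSE_CODONS = [c for c in CODONS if c not in STOP_CODONS]

#: codon string -> integer index 0..63 (TCAG positional encoding).
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}


def _degeneracy() -> dict[str, int]:
    fam: dict[str, int] = {}
    for aa in CODON_TO_AA.values():
        fam[aa] = fam.get(aa, 0) + 1
    return fam


@dataclass(frozen=True)
class CodonTable:
    """Codon ↔ amino-acid map with degeneracy classes.

    Attributes
    ----------
    codon_to_aa : dict
        Maps each of the 61 sense codons to its one-letter amino acid.
    stop_codons : frozenset
        The 3 stop codons (TAA, TAG, TGA).
    degeneracy : dict
        Amino acid → synonymous family size (1, 2, 3, 4 or 6).
    """

    codon_to_aa: dict[str, str] = field(default_factory=lambda: dict(CODON_TO_AA))
    stop_codons: frozenset[str] = STOP_CODONS
    degeneracy: dict[str, int] = field(default_factory=_degeneracy)

    def family(self, aa: str) -> list[str]:
        """Synonymous codons of ``aa``, in TCAG order."""
        return [c for c in CODONS if self.codon_to_aa.get(c) == aa]

    def aa_of(self, codon: str) -> str | None:
        return self.codon_to_aa.get(codon)

    def is_sense(self, codon: str) -> bool:
        return codon in self.codon_to_aa

    def amino_acids_with_degeneracy(self, k: int) -> list[str]:
        return sorted(a for a, d in self.degeneracy.items() if d == k)


STANDARD_TABLE = CodonTable()


@dataclass(frozen=True)
class CodonMutation:
    """An ancestral→derived codon change at a single nucleotide position.

    ``position`` is 1-based (1–3) and marks the differing nucleotide.
    """

    ancestral_codon: str
    derived_codon: str
    position: int

    def __post_init__(self) -> None:
        diffs = [
            i + 1
            for i in range(3)
            if self.ancestral_codon[i] != self.derived_codon[i]
        ]
        if diffs != [self.position]:
            raise ValueError(
                f"{self.ancestral_codon}->{self.derived_codon} does not differ "
                f"exactly at position {self.position}"
            )
        for codon in (self.ancestral_codon, self.derived_codon):
            if codon not in CODON_TO_AA:
                raise ValueError(f"{codon} is not a sense codon")

    def reverse(self) -> "CodonMutation":
        return CodonMutation(self.derived_codon, self.ancestral_codon, self.position)

    @property
    def nucleotide_change(self) -> tuple[str, str]:
        i = self.position - 1
        return self.ancestral_codon[i], self.derived_codon[i]

    def __str__(self) -> str:  # e.g. "CAA>AAA"
        return f"{self.ancestral_codon}>{self.derived_codon}"


@dataclass(frozen=True)
class DirectedAminoAcidPair:
    """A directed amino-acid change A→B reachable by one nucleotide mutation.

    ``degeneracy_class`` is ``"2fold"`` or ``"4fold"``; both amino acids have
    that family size.  ``codon_mutations`` lists every (ancestral codon,
    derived codon) combination one nucleotide apart.
    """

    ancestral_aa: str
    derived_aa: str
    degeneracy_class: str
    codon_mutations: tuple[CodonMutation, ...]

    @property
    def label(self) -> str:
        return f"{self.ancestral_aa}>{self.derived_aa}"

    def reverse(self, table: CodonTable = STANDARD_TABLE) -> "DirectedAminoAcidPair":
        return DirectedAminoAcidPair(
            self.derived_aa,
            self.ancestral_aa,
            self.degeneracy_class,
            tuple(m.reverse() for m in self.codon_mutations),
        )


_CLASS_SIZE = {"2fold": 2, "4fold": 4}


def _mutations_between(
    aa_from: str, aa_to: str, table: CodonTable
) -> list[CodonMutation]:
    out = []
    for ca in table.family(aa_from):
        for cb in table.family(aa_to):
            diffs = [i for i in range(3) if ca[i] != cb[i]]
            if len(diffs) == 1:
                out.append(CodonMutation(ca, cb, diffs[0] + 1))
    return out


def single_step_codon_mutations(
    pair: DirectedAminoAcidPair, table: CodonTable = STANDARD_TABLE
) -> list[CodonMutation]:
    """All single-nucleotide codon changes realising ``pair``.

    For pairs whose families differ at codon position 1 or 2 this yields one
    mutation per ancestral codon (2 for 2-folds, 4 for 4-folds); families
    that differ only at the wobble position (e.g. Gln CAA/CAG vs His CAT/CAC)
    yield all cross combinations.
    """
    return _mutations_between(pair.ancestral_aa, pair.derived_aa, table)


def enumerate_directed_pairs(
    table: CodonTable = STANDARD_TABLE, degeneracy_class: str = "2fold"
) -> list[DirectedAminoAcidPair]:
    """Every directed amino-acid pair of the requested degeneracy class.

    A pair A→B is listed when both A and B have the class's family size and
    at least one codon of A is a single nucleotide away from a codon of B.
    For the standard code this gives 30 directed 2-fold pairs and 12 directed
    4-fold pairs.

    Raises
    ------
    ValueError
        If ``degeneracy_class`` is not ``"2fold"`` or ``"4fold"``.
    """
    if degeneracy_class not in _CLASS_SIZE:
        raise ValueError(
            f"unknown degeneracy class {degeneracy_class!r}; "
            "expected '2fold' or '4fold'"
        )
    size = _CLASS_SIZE[degeneracy_class]
    aas = table.amino_acids_with_degeneracy(size)
    pairs = []
    for aa_a, aa_b in itertools.permutations(aas, 2):
        muts = _mutations_between(aa_a, aa_b, table)
        if muts:
            pairs.append(
                DirectedAminoAcidPair(aa_a, aa_b, degeneracy_class, tuple(muts))
            )
    return pairs


def all_directed_pairs(
    table: CodonTable = STANDARD_TABLE,
) -> list[DirectedAminoAcidPair]:
    """2-fold then 4-fold directed pairs (30 + 12 for the standard code)."""
    return enumerate_directed_pairs(table, "2fold") + enumerate_directed_pairs(
        table, "4fold"
    )


def translate(seq: str, table: CodonTable = STANDARD_TABLE) -> str:
    """Translate an in-frame DNA string; stops become ``*``, ambiguity ``X``."""
    aas = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i : i + 3].upper()
        if codon in table.stop_codons:
            aas.append("*")
        else:
            aas.append(table.codon_to_aa.get(codon, "X"))
    return "".join(aas)
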