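"""Polarized site classification, filters, and Nei–Gojobori divergence."""

import itertools

import pytest
from Bio.Seq import Seq

from codonsel.genetic_code import CODON_TO_AA, CODONS, STANDARD_TABLE
from codonsel.site_calls import (
    GeneAlignment,
    call_fixed_differences,
    call_polymorphic_sites,
    calls_frame,
    compute_ds,
    read_gene_alignment,
)


def _aln(columns, outgroup_cols, n_strains=10, outgroup2_cols=None):
    """Build a GeneAlignment from per-site lists of per-strain codons."""
    ingroup = {
        f"s{i:02d}": "".join(col[i] for col in columns) for i in range(n_strains)
    }
    outgroups = {"og1": "".join(outgroup_cols)}
    if outgroup2_cols is not None:
        outgroups["og2"] = "".join(outgroup2_cols)
    return GeneAlignment("gene", ingroup, outgroups)


class TestPolymorphicSites:
    def test_classification_matrix(self):
        """One column per filter rule, classified in a single pass."""
        cols = [
            ["CAA"] * 9 + ["AAA"],          # biallelic non-syn, og matches CAA
            ["CAG"] * 10,                   # monomorphic
            ["CAA"] * 5 + ["AAG"] * 5,      # two nucleotides apart
            ["GAA"] * 5 + ["GAG"] * 5,      # synonymous pair
            ["CAA"] * 9 + ["AAA"],          # og matches neither
            ["CAA"] * 4 + ["AAA"] * 3 + ["GAA"] * 3,  # triallelic
            ["NNN"] * 3 + ["AAA"] * 7,      # 70% coverage
            ["AAA"] * 9 + ["AAG"],          # derived state as og -> flip
        ]
        og = ["CAA", "CAG", "CAA", "GAA", "GGG", "CAA", "AAA", "AAG"]
        calls = call_polymorphic_sites(_aln(cols, og), "og1")
        assert len(calls) == len(cols)

        c = calls[0]
        assert (c.status, c.ancestral_codon, c.derived_codon) == (
            "polymorphic", "CAA", "AAA"
        )
        assert calls[1].status == "monomorphic"
        assert calls[1].ancestral_codon == "CAG"
        assert calls[2].discard_reason == "multi-nucleotide"
        assert calls[3].discard_reason == "synonymous-only"
        assert calls[4].discard_reason == "outgroup-mismatch"
        assert calls[5].discard_reason == "triallelic"
        assert calls[6].discard_reason == "low-coverage"
        assert calls[6].coverage_fraction == pytest.approx(0.7)
        # synonymous AAA/AAG? no: AAA=Lys, AAG=Lys — synonymous
        assert calls[7].discard_reason == "synonymous-only"

    def test_polarization_flips_with_outgroup(self):
        cols = [["CAA"] * 9 + ["AAA"]]
        anc = call_polymorphic_sites(_aln(cols, ["CAA"]), "og1")[0]
        der = call_polymorphic_sites(_aln(cols, ["AAA"]), "og1")[0]
        assert (anc.ancestral_codon, anc.derived_codon) == ("CAA", "AAA")
        assert (der.ancestral_codon, der.derived_codon) == ("AAA", "CAA")

    def test_outgroup_missing_discards(self):
        calls = call_polymorphic_sites(_aln([["CAA"] * 10], ["NNN"]), "og1")
        assert calls[0].discard_reason == "outgroup-missing"

    def test_absent_outgroup_rejected(self):
        with pytest.raises(ValueError, match="og9"):
            call_polymorphic_sites(_aln([["CAA"] * 10], ["CAA"]), "og9")

    def test_every_column_accounted(self, small_world):
        _cfg, alns, _truth, _expr = small_world
        aln = alns[0]
        calls = call_polymorphic_sites(aln, "og1")
        assert len(calls) == aln.length
        df = calls_frame(calls)
        assert df["status"].isin(
            ["monomorphic", "polymorphic", "discarded"]
        ).all()


class TestFixedDifferences:
    def test_classification_matrix(self):
        cols = [
            ["AAA"] * 10,  # og both CAA -> fixed difference CAA->AAA
            ["CAG"] * 10,  # all three identical -> monomorphic
            ["AAA"] * 10,  # outgroups disagree -> conflict
            ["CAA"] * 9 + ["AAA"],  # ingroup polymorphic
            ["AAG"] * 10,  # og both AAA: synonymous fixed change
            ["AGG"] * 10,  # og both CAA: two nucleotides
        ]
        og1 = ["CAA", "CAG", "CAA", "CAA", "AAA", "CAA"]
        og2 = ["CAA", "CAG", "CAG", "CAA", "AAA", "CAA"]
        calls = call_fixed_differences(_aln(cols, og1, outgroup2_cols=og2))
        c = calls[0]
        assert (c.status, c.ancestral_codon, c.derived_codon) == (
            "fixed_difference", "CAA", "AAA"
        )
        assert calls[1].status == "monomorphic"
        assert calls[2].discard_reason == "outgroup-conflict"
        assert calls[3].discard_reason == "ingroup-polymorphic"
        assert calls[4].discard_reason == "synonymous-only"
        assert calls[5].discard_reason == "multi-nucleotide"

    def test_requires_two_outgroups(self):
        with pytest.raises(ValueError, match="two outgroups"):
            call_fixed_differences(_aln([["CAA"] * 10], ["CAA"]))


def _ng86_site_oracle(codon):
    """Brute-force synonymous site count: enumerate all 9 changes."""
    aa = str(Seq(codon).translate())
    syn = 0
    for pos, b in itertools.product(range(3), "TCAG"):
        if b == codon[pos]:
            continue
        alt = codon[:pos] + b + codon[pos + 1:]
        alt_aa = str(Seq(alt).translate())
        if alt_aa == aa and alt_aa != "*":
            syn += 1
    return syn / 3.0


class TestComputeDs:
    def test_identical_sequences(self):
        assert compute_ds("AAACCC", "AAACCC").d_s == 0.0

    def test_single_synonymous_substitution(self):
        """AAA vs AAG: one synonymous substitution over 1/3 syn sites."""
        s = compute_ds("AAA", "AAG")
        expected_sites = (_ng86_site_oracle("AAA") + _ng86_site_oracle("AAG")) / 2
        assert s.syn_substitutions == 1.0
        assert s.syn_sites == pytest.approx(expected_sites)
        assert s.d_s == pytest.approx(1.0 / expected_sites)  # = 3.0
        assert s.d_s == pytest.approx(3.0)

    def test_nonsynonymous_only(self):
        s = compute_ds("AAA", "CAA")
        assert s.d_s == 0.0 and s.nonsyn_substitutions == 1.0

    def test_syn_sites_match_brute_force_all_codons(self):
        from codonsel.site_calls import _syn_sites_of

        for codon in CODONS:
            if codon in STANDARD_TABLE.stop_codons:
                continue
            assert _syn_sites_of(codon) == pytest.approx(
                _ng86_site_oracle(codon)
            ), codon

    def test_two_hit_codon_pathway_average(self):
        """TTT vs TTA is 1 step; CTT vs CTG syn; check a 2-diff codon pair
        against explicit pathway enumeration."""
        # AAA (Lys) vs AGG (Arg): paths AAA->AGA->AGG and AAA->AAG->AGG
        # AAA->AGA nonsyn, AGA->AGG syn;  AAA->AAG syn, AAG->AGG nonsyn
        s = compute_ds("AAA", "AGG")
        assert s.syn_substitutions == pytest.approx(1.0)
        assert s.nonsyn_substitutions == pytest.approx(1.0)

    def test_ambiguous_codons_skipped(self):
        s = compute_ds("AAANNN", "AAGAAA")
        assert s.codons_compared == 1

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compute_ds("AAA", "AAAAAA")

    def test_jukes_cantor_correction_larger(self):
        raw = compute_ds("AAA" * 30 + "GGG" * 10, "AAG" * 30 + "GGG" * 10)
        jc = compute_ds(
            "AAA" * 30 + "GGG" * 10, "AAG" * 30 + "GGG" * 10, jukes_cantor=True
        )
        assert jc.d_s > raw.d_s > 0


def test_fasta_round_trip(tmp_path, small_world):
    _cfg, alns, _truth, _expr = small_world
    aln = alns[0]
    path = tmp_path / "gene.fasta"
    with open(path, "w") as fh:
        for sid, seq in aln.ingroup.items():
            fh.write(f">{sid}\n{seq}\n")
        for oid, seq in aln.outgroups.items():
            fh.write(f">OUTGROUP|{oid}\n{seq}\n")
    back = read_gene_alignment(path)
    assert back.ingroup == aln.ingroup
    assert back.outgroups == aln.outgroups
    assert back.length == aln.length
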