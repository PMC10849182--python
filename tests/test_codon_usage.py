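"""RSCU, CAI, correspondence analysis and quantile binning."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from codonsel.codon_usage import (
    CodonCounts,
    compute_cai,
    compute_rscu,
    correspondence_analysis,
    count_codons,
    pool_counts,
    quantile_bins,
)
from codonsel.genetic_code import CODON_TO_AA, SENSE_CODONS, STANDARD_TABLE

_FAMS = {}
for c in SENSE_CODONS:
    _FAMS.setdefault(CODON_TO_AA[c], []).append(c)


class TestCountCodons:
    def test_terminal_stop_dropped(self):
        cc = count_codons("ATGAAATAA")
        assert cc.counts["ATG"] == 1 and cc.counts["AAA"] == 1
        assert cc.total == 2 and cc.skipped == 0

    def test_empty_sequence(self):
        assert count_codons("").total == 0

    def test_ambiguity_skipped(self):
        cc = count_codons("AAANNA")
        assert cc.counts["AAA"] == 1 and cc.skipped == 1

    def test_frame_violation_names_gene(self):
        with pytest.raises(ValueError, match="geneX"):
            count_codons("AAAA", gene_id="geneX")

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError, match="internal stop"):
            count_codons("TAAAAA", gene_id="g")


class TestRscu:
    def test_two_fold_percentages(self):
        """Counts 73/27 in a 2-fold family give RSCU 1.46/0.54."""
        prof = compute_rscu({"AAA": 73, "AAG": 27})
        assert prof.rscu["AAA"] == pytest.approx(1.46)
        assert prof.rscu["AAG"] == pytest.approx(0.54)
        assert prof.w["AAA"] == 1.0
        assert prof.w["AAG"] == pytest.approx(0.54 / 1.46)

    def test_uniform_four_fold(self):
        prof = compute_rscu({c: 5 for c in _FAMS["A"]})
        assert all(prof.rscu[c] == pytest.approx(1.0) for c in _FAMS["A"])

    def test_zero_count_boundary(self):
        prof = compute_rscu({"CAA": 0, "CAG": 10})
        assert prof.rscu["CAA"] == 0.0 and prof.rscu["CAG"] == 2.0

    def test_absent_family_undefined(self):
        prof = compute_rscu({"AAA": 3})
        assert math.isnan(prof.rscu["CAA"])

    @given(
        st.dictionaries(
            st.sampled_from(SENSE_CODONS),
            st.integers(min_value=0, max_value=500),
            min_size=5,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_family_normalization(self, counts):
        """Family RSCU sums to the family size whenever any member is seen."""
        prof = compute_rscu(counts)
        for aa, fam in _FAMS.items():
            tot = sum(counts.get(c, 0) for c in fam)
            if tot > 0:
                assert sum(prof.rscu[c] for c in fam) == pytest.approx(len(fam))
                assert max(prof.w[c] for c in fam) == pytest.approx(1.0)


class TestCai:
    def _profile(self):
        # Lys AAA preferred (w=1), AAG w=0.25; Gln CAG preferred, CAA w=1/4
        return compute_rscu({"AAA": 80, "AAG": 20, "CAA": 20, "CAG": 80})

    def test_all_preferred_codons(self):
        prof = self._profile()
        gene = CodonCounts("g", {"AAA": 10, "CAG": 5})
        assert compute_cai(gene, prof).cai == pytest.approx(1.0)

    def test_geometric_mean(self):
        prof = self._profile()
        gene = CodonCounts("g", {"AAA": 4, "AAG": 4})
        assert compute_cai(gene, prof).cai == pytest.approx(
            math.sqrt(1.0 * 0.25)
        )

    def test_empty_gene_undefined(self):
        assert math.isnan(compute_cai(CodonCounts("g", {}), self._profile()).cai)

    def test_met_trp_excluded(self):
        prof = self._profile()
        gene = CodonCounts("g", {"AAA": 3, "ATG": 50, "TGG": 50})
        assert compute_cai(gene, prof).cai == pytest.approx(1.0)

    def test_length_scaling_invariance(self):
        prof = self._profile()
        g1 = CodonCounts("g", {"AAA": 3, "AAG": 1, "CAA": 2})
        g2 = CodonCounts("g", {"AAA": 30, "AAG": 10, "CAA": 20})
        assert compute_cai(g1, prof).cai == pytest.approx(compute_cai(g2, prof).cai)

    def test_w_floor_for_unobserved_codon(self):
        prof = compute_rscu({"AAA": 10, "AAG": 0})
        gene = CodonCounts("g", {"AAG": 1})
        assert compute_cai(gene, prof, w_floor=0.01).cai == pytest.approx(0.01)


class TestCorrespondenceAnalysis:
    # 6×8 count fixture; reference coordinates computed with R ade4
    # dudi.coa (axis signs are arbitrary).
    X = np.array(
        [
            [12, 3, 8, 5, 2, 9, 1, 4],
            [3, 15, 2, 11, 7, 1, 5, 2],
            [10, 2, 9, 4, 3, 8, 2, 5],
            [2, 12, 3, 10, 8, 2, 6, 1],
            [7, 7, 6, 6, 5, 5, 3, 3],
            [11, 4, 7, 6, 1, 10, 2, 4],
        ],
        dtype=float,
    )
    ADE4_AXIS1 = np.array(
        [0.4979481149, -0.6829749990, 0.4700812605,
         -0.6571667522, -0.0264991322, 0.4293764299]
    )
    ADE4_AXIS2 = np.array(
        [0.0430765813, 0.0880932346, -0.1414335893,
         -0.0678387636, -0.0721752943, 0.1366723095]
    )
    ADE4_INERTIA = np.array([0.9469395592, 0.0350414226, 0.0126654577])

    def _frame(self):
        return pd.DataFrame(
            self.X,
            index=[f"g{i}" for i in range(6)],
            columns=list("ABCDEFGH"),
        )

    def test_matches_ade4_reference(self):
        res = correspondence_analysis(self._frame(), mode="CA-AF")
        for got, ref in (
            (res.axes["axis1"].to_numpy(), self.ADE4_AXIS1),
            (res.axes["axis2"].to_numpy(), self.ADE4_AXIS2),
        ):
            assert np.allclose(got, ref, atol=1e-8) or np.allclose(
                got, -ref, atol=1e-8
            )
        assert np.allclose(res.inertia[:3], self.ADE4_INERTIA, atol=1e-8)

    def test_identical_genes_equal_coordinates(self):
        df = self._frame()
        df.loc["g1"] = df.loc["g0"]
        res = correspondence_analysis(df, mode="CA-AF")
        assert res.axes.loc["g0", "axis1"] == pytest.approx(
            res.axes.loc["g1", "axis1"]
        )

    def test_cluster_separation_and_marker_orientation(self):
        rng = np.random.default_rng(0)
        # two clusters with opposite codon preference within Lys/Gln families
        rows = {}
        for i in range(20):
            biased = i < 10
            rows[f"g{i:02d}"] = {
                "AAA": rng.poisson(80 if biased else 20),
                "AAG": rng.poisson(20 if biased else 80),
                "CAG": rng.poisson(70 if biased else 30),
                "CAA": rng.poisson(30 if biased else 70),
            }
        df = pd.DataFrame(rows).T.fillna(0)
        markers = [f"g{i:02d}" for i in range(3)]  # known biased genes
        res = correspondence_analysis(df, mode="CA-AF", marker_genes=markers)
        ax = res.axes["axis1"]
        assert ax[:10].mean() > 0 > ax[10:].mean()  # marker side positive
        assert len(res.highly_expressed) == 2  # ceil(0.1 * 20)
        assert set(res.highly_expressed) <= {f"g{i:02d}" for i in range(10)}

    def test_wca_mode_runs_and_separates(self):
        rng = np.random.default_rng(1)
        rows = {}
        for i in range(12):
            biased = i < 6
            rows[f"g{i}"] = {
                "AAA": rng.poisson(80 if biased else 20),
                "AAG": rng.poisson(20 if biased else 80),
                "GAA": rng.poisson(60),
                "GAG": rng.poisson(40),
            }
        df = pd.DataFrame(rows).T
        res = correspondence_analysis(
            df, mode="WCA-CA-AF", marker_genes=["g0"]
        )
        ax = res.axes["axis1"]
        assert ax[:6].mean() > ax[6:].mean()

    def test_zero_row_dropped(self):
        df = self._frame()
        df.loc["gz"] = 0.0
        res = correspondence_analysis(df, mode="CA-AF")
        assert "gz" in res.dropped_rows
        assert "gz" not in res.axes.index

    def test_needs_two_genes(self):
        with pytest.raises(ValueError):
            correspondence_analysis(self._frame().iloc[:1], mode="CA-AF")


class TestQuantileBins:
    def test_even_split(self):
        bins = quantile_bins({f"g{i}": float(i) for i in range(1, 11)}, 5)
        sizes = pd.Series(bins).value_counts()
        assert set(sizes) == {2}
        assert bins["g1"] == 1 and bins["g10"] == 5

    def test_nine_values_four_bins(self):
        bins = quantile_bins({f"g{i}": float(i) for i in range(1, 10)}, 4)
        sizes = pd.Series(bins).value_counts().sort_index()
        assert list(sizes) == [3, 2, 2, 2]

    def test_degenerate_ties_stable(self):
        bins = quantile_bins({f"g{i}": 1.0 for i in range(6)}, 2)
        assert [bins[f"g{i}"] for i in range(6)] == [1, 1, 1, 2, 2, 2]

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            quantile_bins({"a": 1.0, "b": 2.0}, 3)


def test_pool_counts_sums():
    a = count_codons("AAACAA", "a")
    b = count_codons("AAAGAA", "b")
    pooled = pool_counts([a, b])
    assert pooled.counts["AAA"] == 2 and pooled.counts["CAA"] == 1
    assert pooled.total == 4
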