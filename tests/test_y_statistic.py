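"""Extreme codon-pair selection, per-gene strata, CMH pooling, ΔRSCU."""

import math

import numpy as np
import pytest
from statsmodels.stats.contingency_tables import StratifiedTable

from codonsel.codon_usage import CodonUsageProfile
from codonsel.site_calls import SiteCall
from codonsel.y_statistic import (
    PairStratum,
    build_strata,
    cmh_log_y_se,
    cmh_pooled_log_y,
    delta_rscu,
    select_extreme_codon_pairs,
    unstratified_log_y,
)
from conftest import pair


def _profile(rscu, fill=1.0):
    from codonsel.genetic_code import SENSE_CODONS

    full = {c: fill for c in SENSE_CODONS}
    full.update(rscu)
    w = {c: 1.0 for c in full}
    return CodonUsageProfile(rscu=full, w=w, source="test")


class TestExtremeSelection:
    def test_pro_thr_printed_example(self):
        """CCC→ACC (0.05→1.75) is max, CCG→ACG (2.85→0.17) is min."""
        prof = _profile({"CCC": 0.05, "CCG": 2.85, "ACC": 1.75, "ACG": 0.17})
        mx, mn = select_extreme_codon_pairs(pair("P>T"), prof)
        assert str(mx) == "CCC>ACC"
        assert str(mn) == "CCG>ACG"

    def test_gln_lys_from_usage_percentages(self):
        prof = _profile({"CAA": 0.38, "CAG": 1.62, "AAA": 1.46, "AAG": 0.54})
        mx, mn = select_extreme_codon_pairs(pair("Q>K"), prof)
        assert str(mx) == "CAA>AAA"
        assert str(mn) == "CAG>AAG"

    def test_tie_broken_lexicographically(self):
        prof = _profile({})
        mx, mn = select_extreme_codon_pairs(pair("Q>K"), prof)
        assert str(mx) == "CAA>AAA"  # first in codon order
        assert str(mn) == "CAA>AAA" or str(mn) == "CAG>AAG"

    def test_zero_ancestral_rscu_excluded(self):
        prof = _profile({"CAA": 0.0, "CAG": 2.0, "AAA": 1.0, "AAG": 1.0})
        mx, mn = select_extreme_codon_pairs(pair("Q>K"), prof)
        assert str(mx) == "CAG>AAG" and str(mn) == "CAG>AAG"

    def test_all_invalid_returns_none(self):
        prof = _profile({"CAA": 0.0, "CAG": 0.0, "AAA": 1.0, "AAG": 1.0})
        assert select_extreme_codon_pairs(pair("Q>K"), prof) is None


class TestBuildStrata:
    def _calls(self):
        calls = []
        for _ in range(2):
            calls.append(SiteCall("g1", 0, "polymorphic",
                                  ancestral_codon="CAA", derived_codon="AAA"))
        calls.append(SiteCall("g1", 1, "polymorphic",
                              ancestral_codon="CAG", derived_codon="AAG"))
        calls += [SiteCall("g1", i, "monomorphic", ancestral_codon="CAA")
                  for i in range(10)]
        calls += [SiteCall("g1", i, "monomorphic", ancestral_codon="CAG")
                  for i in range(20)]
        # irrelevant gene with no matching sites is omitted
        calls.append(SiteCall("g2", 0, "monomorphic", ancestral_codon="GGG"))
        return calls

    def _extremes(self):
        prof = _profile({"CAA": 0.38, "CAG": 1.62, "AAA": 1.46, "AAG": 0.54})
        return select_extreme_codon_pairs(pair("Q>K"), prof)

    def test_constructed_counts(self):
        strata = build_strata(self._calls(), pair("Q>K"), self._extremes())
        assert len(strata) == 1
        s = strata[0]
        assert (s.up_events, s.down_events, s.up_opportunity,
                s.down_opportunity) == (2, 1, 10, 20)

    def test_frame_path_equals_list_path(self):
        from codonsel.site_calls import calls_frame

        calls = self._calls()
        a = build_strata(calls, pair("Q>K"), self._extremes())
        b = build_strata(calls_frame(calls), pair("Q>K"), self._extremes())
        key = lambda s: s.gene_id
        assert [(s.gene_id, s.up_events, s.down_events, s.up_opportunity,
                 s.down_opportunity) for s in sorted(a, key=key)] == \
               [(s.gene_id, s.up_events, s.down_events, s.up_opportunity,
                 s.down_opportunity) for s in sorted(b, key=key)]

    def test_planted_counts_recovered(self, clean_world):
        """Strata from caller output equal the generator's bookkeeping."""
        from codonsel.site_calls import call_polymorphic_sites, calls_frame

        cfg, alns, truth, _expr = clean_world
        calls = []
        for a in alns:
            calls += call_polymorphic_sites(a, "og1")
        df = calls_frame(calls)
        extremes = self._extremes()
        mx, mn = extremes
        strata = build_strata(df, pair("Q>K"), extremes)
        gt = truth.sites
        exp_up = gt[(gt.exp_poly_status == "polymorphic")
                    & (gt.exp_poly_anc == mx.ancestral_codon)
                    & (gt.exp_poly_der == mx.derived_codon)].shape[0]
        assert sum(s.up_events for s in strata) == exp_up


class TestCmh:
    def test_single_stratum_is_simple_odds_ratio(self):
        est = cmh_pooled_log_y([PairStratum("g", "Q>K", 2, 1, 10, 20)])
        assert est.log_y == pytest.approx(math.log(4.0), abs=1e-12)
        assert est.strata_used == 1

    def test_duplicate_strata_invariance(self):
        s = PairStratum("g", "Q>K", 2, 1, 10, 20)
        one = cmh_pooled_log_y([s])
        two = cmh_pooled_log_y([s, PairStratum("h", "Q>K", 2, 1, 10, 20)])
        assert one.log_y == pytest.approx(two.log_y)

    def test_multi_stratum_hand_computed(self):
        """Pooled OR = Σ aᵢdᵢ/Tᵢ ÷ Σ bᵢcᵢ/Tᵢ, computed by hand."""
        strata = [PairStratum("g1", "x", 1, 4, 10, 10),
                  PairStratum("g2", "x", 4, 1, 100, 10)]
        num = 1 * 10 / 25 + 4 * 10 / 115
        den = 4 * 10 / 25 + 1 * 100 / 115
        est = cmh_pooled_log_y(strata)
        assert est.log_y == pytest.approx(math.log(num / den), abs=1e-12)

    def test_matches_statsmodels(self):
        strata = [PairStratum("g1", "x", 1, 4, 10, 10),
                  PairStratum("g2", "x", 4, 1, 100, 10),
                  PairStratum("g3", "x", 3, 2, 50, 40)]
        tables = [
            np.array([[s.up_events, s.up_opportunity],
                      [s.down_events, s.down_opportunity]])
            for s in strata
        ]
        st = StratifiedTable(tables)
        est = cmh_pooled_log_y(strata)
        assert math.exp(est.log_y) == pytest.approx(st.oddsratio_pooled)
        assert cmh_log_y_se(strata) == pytest.approx(st.logodds_pooled_se)

    def test_order_and_zero_stratum_invariance(self):
        strata = [PairStratum("g1", "x", 1, 4, 10, 10),
                  PairStratum("g2", "x", 4, 1, 100, 10)]
        fwd = cmh_pooled_log_y(strata).log_y
        rev = cmh_pooled_log_y(strata[::-1]).log_y
        padded = cmh_pooled_log_y(strata + [PairStratum("g3", "x", 0, 0, 0, 0)])
        assert fwd == pytest.approx(rev) == pytest.approx(padded.log_y)

    def test_undefined_without_pseudocounts(self):
        est = cmh_pooled_log_y([PairStratum("g", "x", 0, 1, 10, 20)])
        assert math.isnan(est.log_y) and not est.defined

    def test_swapping_directions_negates(self):
        strata = [PairStratum("g1", "x", 1, 4, 10, 10),
                  PairStratum("g2", "x", 4, 1, 100, 10)]
        swapped = [PairStratum(s.gene_id, s.pair_label, s.down_events,
                               s.up_events, s.down_opportunity,
                               s.up_opportunity) for s in strata]
        assert cmh_pooled_log_y(strata).log_y == pytest.approx(
            -cmh_pooled_log_y(swapped).log_y
        )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cmh_pooled_log_y([])

    def test_unstratified_diagnostic(self):
        strata = [PairStratum("g", "x", 2, 1, 10, 20)]
        assert unstratified_log_y(strata) == pytest.approx(math.log(4.0))


class TestDeltaRscu:
    def _qk(self):
        prof = _profile({"CAA": 0.38, "CAG": 1.62, "AAA": 1.46, "AAG": 0.54})
        return prof, select_extreme_codon_pairs(pair("Q>K"), prof)

    def test_gln_lys_value(self):
        prof, extremes = self._qk()
        res = delta_rscu(pair("Q>K"), extremes, prof)
        expected = (1.46 / 0.38) / (0.54 / 1.62)
        assert res.delta_rscu == pytest.approx(expected)
        assert res.delta_rscu == pytest.approx(11.53, abs=0.01)
        assert res.log_delta_rscu == pytest.approx(math.log(expected))

    def test_uniform_rscu_gives_one(self):
        prof = _profile({})
        extremes = select_extreme_codon_pairs(pair("Q>K"), prof)
        assert delta_rscu(pair("Q>K"), extremes, prof).delta_rscu == \
            pytest.approx(1.0)

    def test_swapping_extremes_inverts(self):
        prof, (mx, mn) = self._qk()
        fwd = delta_rscu(pair("Q>K"), (mx, mn), prof)
        rev = delta_rscu(pair("Q>K"), (mn, mx), prof)
        assert fwd.delta_rscu == pytest.approx(1.0 / rev.delta_rscu)

    def test_zero_denominator_undefined(self):
        prof, extremes = self._qk()
        bad = _profile({"CAA": 0.38, "CAG": 0.0, "AAA": 1.46, "AAG": 0.54})
        assert delta_rscu(pair("Q>K"), extremes, bad) is None
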