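"""Selection rules, proximity, VEC calling, core-flank contrast, enrichment."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from pgcreprog import classify
from pgcreprog.classify import (
    SelectionRule,
    annotate_iap_proximity,
    core_vs_flank_profile,
    identify_vecs,
    overlap_enrichment,
    resistance_vs_distance,
    select_late_demethylaters,
    select_resistant,
)
from pgcreprog.errors import ConfigurationError
from conftest import make_calls


@pytest.fixture
def median_matrix():
    cols = ["E6.5", "E9.5", "E10.5", "E11.5", "E13.5_male", "E13.5_female"]
    data = {
        "dmr": [50, 50, 49, 48, 1, 1],
        "bulk_cgi": [30, 10, 4, 2, 0.5, 0.4],
        "iap_cgi": [80, 80, 79, 81, 80, 78],
        "vec_m": [60, 50, 40, 35, 30, 10],
        "gap": [50, np.nan, 50, 50, 50, 50],
        "erased": [10, 5, 1, 0.5, 0, 0],
    }
    return pd.DataFrame(data, index=cols).T


class TestSelectLateDemethylaters:
    def test_dmr_selected_bulk_not(self, median_matrix):
        res = select_late_demethylaters(median_matrix)
        assert "dmr" in res.selected
        assert "bulk_cgi" not in res.selected

    def test_missing_stage_value_excluded_and_reported(self, median_matrix):
        res = select_late_demethylaters(median_matrix)
        assert "gap" not in res.selected
        assert "gap" in res.excluded_missing

    def test_threshold_100_vacuous(self, median_matrix):
        res = select_late_demethylaters(median_matrix, SelectionRule(threshold=100))
        assert res.selected == frozenset()

    def test_absent_stage_named_in_error(self, median_matrix):
        rule = SelectionRule(stages=("E16.5",))
        with pytest.raises(ConfigurationError, match="E16.5"):
            select_late_demethylaters(median_matrix, rule)

    def test_raising_threshold_never_enlarges_selection(self, median_matrix):
        prev = None
        for thr in (10, 25, 40, 60, 90):
            sel = select_late_demethylaters(median_matrix, SelectionRule(threshold=thr)).selected
            if prev is not None:
                assert sel <= prev
            prev = sel

    def test_adding_stage_never_enlarges_selection(self, median_matrix):
        stages = ("E6.5", "E9.5", "E10.5", "E11.5")
        prev = None
        for k in range(1, len(stages) + 1):
            sel = select_late_demethylaters(
                median_matrix, SelectionRule(stages=stages[:k])
            ).selected
            if prev is not None:
                assert sel <= prev
            prev = sel

    def test_single_stage_rule_equals_select_resistant(self, median_matrix):
        a = select_late_demethylaters(
            median_matrix, SelectionRule(stages=("E13.5",), sex="male")
        ).selected
        b = select_resistant(median_matrix, "male").selected
        assert a == b


class TestSelectResistant:
    def test_iap_proximal_cgi_selected_in_both_sexes(self, median_matrix):
        for sex in ("male", "female"):
            assert "iap_cgi" in select_resistant(median_matrix, sex).selected

    def test_erased_not_selected(self, median_matrix):
        assert "erased" not in select_resistant(median_matrix, "male").selected

    def test_exactly_25_not_selected(self):
        m = pd.DataFrame({"E13.5_male": [25.0, 25.01]}, index=["at", "above"])
        sel = select_resistant(m, "male").selected
        assert sel == {"above"}


class TestIapProximity:
    def _features(self, rows):
        return pd.DataFrame(
            rows, columns=["chrom", "start", "end", "feature_id", "feature_class", "strand"]
        )

    def test_overlapping_distance_zero(self):
        feats = self._features([("chr1", 100, 200, "a", "CGI", "+")])
        iaps = self._features([("chr1", 150, 500, "i", "IAP", "+")])
        prox = annotate_iap_proximity(feats, iaps)
        assert prox.loc["a", "distance"] == 0
        assert prox.loc["a", "proximal"]

    @pytest.mark.parametrize("gap,expect", [(1999, True), (2000, False)])
    def test_strict_cutoff(self, gap, expect):
        feats = self._features([("chr1", 0, 100, "a", "CGI", "+")])
        iaps = self._features([("chr1", 100 + gap, 100 + gap + 50, "i", "IAP", "+")])
        prox = annotate_iap_proximity(feats, iaps, cutoff_bp=2000)
        assert prox.loc["a", "distance"] == gap
        assert bool(prox.loc["a", "proximal"]) is expect

    def test_no_iaps_infinite_sentinel(self):
        feats = self._features([("chr1", 0, 100, "a", "CGI", "+")])
        prox = annotate_iap_proximity(feats, feats.iloc[:0])
        assert np.isinf(prox.loc["a", "distance"])
        assert not prox["proximal"].any()


class TestResistanceVsDistance:
    def test_protection_decaying_with_distance_monotone(self, annotation):
        # simulate a single E13.5 sample where IAP-context protection decays
        # linearly with distance, then bin resistant fractions by distance
        from pgcreprog.stages import StageSpec
        from pgcreprog.synthetic import DynamicsProfile, ground_truth_levels

        spec = StageSpec("E13.5", "male", divisions=8)
        truth = ground_truth_levels(annotation, DynamicsProfile(), spec)
        matrix = pd.DataFrame({"E13.5_male": truth["true_fraction"] * 100})
        prox = annotate_iap_proximity(
            annotation.features, annotation.by_class("IAP")
        )
        proms = truth.index[truth["feature_class"] == "promoter"]
        table = resistance_vs_distance(
            matrix.loc[proms], prox.loc[proms], [0, 500, 1000, 2000, 4000], "male"
        )
        fracs = table["resistant_fraction"].to_numpy()
        assert (np.diff(fracs) <= 1e-12).all()

    def test_all_proximal_protected(self):
        matrix = pd.DataFrame({"E13.5_male": [80.0, 90.0]}, index=["a", "b"])
        prox = pd.DataFrame(
            {"distance": [0.0, 10.0], "proximal": [True, True]},
            index=pd.Index(["a", "b"], name="feature_id"),
        )
        table = resistance_vs_distance(matrix, prox, [0, 2000], "male")
        assert table["resistant_fraction"].iloc[0] == 1.0

    def test_none_resistant_all_zero(self):
        matrix = pd.DataFrame({"E13.5_male": [1.0, 2.0]}, index=["a", "b"])
        prox = pd.DataFrame(
            {"distance": [100.0, 3000.0], "proximal": [True, False]},
            index=pd.Index(["a", "b"], name="feature_id"),
        )
        table = resistance_vs_distance(matrix, prox, [0, 2000, 4000], "male")
        assert (table["resistant_fraction"] == 0).all()


class TestIdentifyVecs:
    def _prox(self, ids, proximal):
        return pd.DataFrame(
            {"distance": [0.0 if p else 1e9 for p in proximal], "proximal": proximal},
            index=pd.Index(ids, name="feature_id"),
        )

    def test_male_only_resistant_is_male_biased_vec(self, median_matrix):
        prox = self._prox(list(median_matrix.index), [False] * len(median_matrix))
        vecs = identify_vecs({"vec_m"}, set(), prox, median_matrix)
        assert "vec_m" in vecs.index
        assert vecs.loc["vec_m", "sex_bias"] == 1
        assert vecs.loc["vec_m", "methylation_range"] == pytest.approx(50.0)

    def test_iap_proximal_resistant_excluded(self, median_matrix):
        ids = list(median_matrix.index)
        prox = self._prox(ids, [fid == "iap_cgi" for fid in ids])
        vecs = identify_vecs({"iap_cgi", "vec_m"}, {"iap_cgi"}, prox, median_matrix)
        assert "iap_cgi" not in vecs.index
        assert "vec_m" in vecs.index
        # disjoint from the proximal set by construction
        assert not set(vecs.index) & set(prox.index[prox["proximal"]])

    def test_erased_in_both_sexes_not_a_vec(self, median_matrix):
        prox = self._prox(list(median_matrix.index), [False] * len(median_matrix))
        vecs = identify_vecs(set(), set(), prox, median_matrix)
        assert len(vecs) == 0


class TestCoreVsFlank:
    def test_protected_core_positive_difference(self):
        rows = [("chr1", p, "+", "CG", 9, 1) for p in range(1000, 1500, 20)]
        rows += [("chr1", p, "+", "CG", 1, 9) for p in range(0, 1000, 20)]
        rows += [("chr1", p, "+", "CG", 1, 9) for p in range(1500, 2500, 20)]
        prof = core_vs_flank_profile({"s": make_calls(rows)}, ("chr1", 1000, 1500), 1000)
        assert prof.loc["s", "difference"] > 0

    def test_uniform_methylation_zero_difference(self):
        rows = [("chr1", p, "+", "CG", 5, 5) for p in range(0, 3000, 20)]
        prof = core_vs_flank_profile({"s": make_calls(rows)}, ("chr1", 1000, 1500), 1000)
        assert prof.loc["s", "difference"] == pytest.approx(0.0)

    def test_bulk_core_and_flank_within_sampling_error(self):
        rng = np.random.default_rng(3)
        rows = []
        for p in range(0, 4000, 10):
            meth = rng.binomial(30, 0.71)
            rows.append(("chr1", p, "+", "CG", meth, 30 - meth))
        prof = core_vs_flank_profile({"s": make_calls(rows)}, ("chr1", 1500, 2500), 1500)
        # each side pools >100 CpGs at 30x; binomial SE on the difference
        n = 100 * 30
        se = 100 * np.sqrt(2 * 0.71 * 0.29 / n)
        assert abs(prof.loc["s", "difference"]) < 4 * se

    def test_no_cpgs_in_flank_missing(self):
        rows = [("chr1", p, "+", "CG", 5, 5) for p in range(1000, 1500, 20)]
        prof = core_vs_flank_profile({"s": make_calls(rows)}, ("chr1", 1000, 1500), 500)
        assert np.isnan(prof.loc["s", "flank_percent"])


class TestOverlapEnrichment:
    def test_selected_equals_background_ratio_one(self):
        bg = set("abcdefgh")
        res = overlap_enrichment(bg, bg, {"a", "b"})
        assert res.ratio == pytest.approx(1.0)

    def test_no_hits_anywhere_undefined(self):
        res = overlap_enrichment({"a"}, {"a", "b"}, set())
        assert not res.defined or np.isnan(res.ratio)

    def test_selected_not_subset_rejected(self):
        with pytest.raises(ConfigurationError):
            overlap_enrichment({"z"}, {"a", "b"}, {"a"})

    def test_all_hits_in_selected_matches_enumeration_oracle(self):
        # N=10 features, K=3 site-bearing, select n=3 and capture all hits;
        # exact tail probability by enumerating all C(10,3) subsets
        background = [f"f{i}" for i in range(10)]
        sites = set(background[:3])
        selected = set(background[:3])
        res = overlap_enrichment(selected, background, sites)
        k_obs = len(selected & sites)
        n = len(selected)
        count = sum(
            1
            for combo in itertools.combinations(background, n)
            if len(set(combo) & sites) >= k_obs
        )
        oracle = count / math.comb(len(background), n)
        assert res.p_value == pytest.approx(oracle)
        assert res.ratio == pytest.approx((3 / 3) / (3 / 10))
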