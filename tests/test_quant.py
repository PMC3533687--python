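"""Quantification: tiling, weighted percentages, summaries, conversion."""

import numpy as np
import pandas as pd
import pytest

from pgcreprog import quant
from pgcreprog.quant import (
    MethylationMatrix,
    cg_density_correlation,
    conversion_efficiency,
    feature_methylation,
    global_summary,
    methylation_distribution,
    probe_methylation,
    tile_genome,
)
from conftest import make_calls


def brute_force_percent(calls, chrom, start, end, context="CG"):
    """Per-CpG summation oracle for one interval."""
    meth = unmeth = 0
    for _, row in calls.iterrows():
        if (
            row["context"] == context
            and row["chrom"] == chrom
            and start <= row["pos"] < end
        ):
            meth += row["count_methylated"]
            unmeth += row["count_unmethylated"]
    total = meth + unmeth
    return (100.0 * meth / total if total else None), total


class TestTileGenome:
    @pytest.mark.parametrize(
        "length,window,n_probes,last_len",
        [(10_000, 5_000, 2, 5_000), (10_001, 5_000, 3, 1), (4_999, 5_000, 1, 4_999)],
    )
    def test_window_partition(self, length, window, n_probes, last_len):
        probes = tile_genome({"chr1": length}, window)
        assert len(probes) == n_probes
        assert probes.iloc[-1]["end"] - probes.iloc[-1]["start"] == last_len
        # spans partition the chromosome
        assert (probes["end"] - probes["start"]).sum() == length
        assert probes.iloc[0]["start"] == 0

    def test_bad_window(self):
        with pytest.raises(ValueError):
            tile_genome({"chr1": 100}, 0)


class TestProbeMethylation:
    def test_simple_percentage(self):
        calls = {"s1": make_calls([("chr1", 10, "+", "CG", 3, 1)])}
        probes = tile_genome({"chr1": 100}, 100)
        mat = probe_methylation(calls, probes, min_total_count=1)
        assert mat.percent.iloc[0, 0] == pytest.approx(75.0)

    def test_probe_without_cpgs_is_missing_not_zero(self):
        calls = {"s1": make_calls([("chr1", 10, "+", "CG", 5, 5)])}
        probes = tile_genome({"chr1": 200}, 100)
        mat = probe_methylation(calls, probes, min_total_count=1)
        assert np.isnan(mat.percent.iloc[1, 0])
        per_sample, _ = global_summary(mat)
        assert per_sample["s1"] == pytest.approx(50.0)

    def test_below_minimum_flagged_missing(self):
        calls = {"s1": make_calls([("chr1", 10, "+", "CG", 2, 2)])}
        probes = tile_genome({"chr1": 100}, 100)
        mat = probe_methylation(calls, probes, min_total_count=10)
        assert np.isnan(mat.percent.iloc[0, 0])
        assert mat.counts.iloc[0, 0] == 4

    def test_empty_probe_set_rejected(self):
        with pytest.raises(ValueError):
            probe_methylation({"s1": make_calls([])}, pd.DataFrame(), 1)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 200
        calls = make_calls(
            [
                (
                    rng.choice(["chr1", "chr2"]),
                    int(rng.integers(0, 1000)),
                    "+",
                    "CG",
                    int(rng.integers(0, 20)),
                    int(rng.integers(0, 20)),
                )
                for _ in range(n)
            ]
        )
        probes = tile_genome({"chr1": 1000, "chr2": 1000}, int(rng.integers(37, 341)))
        mat = probe_methylation({"s": calls}, probes, min_total_count=1)
        for _, probe in probes.sample(25, random_state=seed, replace=True).iterrows():
            expect, total = brute_force_percent(
                calls, probe["chrom"], probe["start"], probe["end"]
            )
            got = mat.percent.loc[probe["probe_id"], "s"]
            if expect is None:
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expect)

    def test_merging_adjacent_probes_is_count_weighted(self):
        a = (30, 40)  # meth, total
        b = (1, 60)
        combined = quant.merge_probe_counts(a[0], a[1], b[0], b[1])
        assert combined == pytest.approx(100 * 31 / 100)
        # not the unweighted mean of the two percentages
        assert combined != pytest.approx((75.0 + 100 / 60) / 2)


class TestGlobalSummary:
    def test_mean_and_replicate_median(self):
        percent = pd.DataFrame(
            {"E9.5_mixed_r1": [40.0, 60.0], "E9.5_mixed_r2": [28.0, 32.0]},
            index=["p1", "p2"],
        )
        mat = MethylationMatrix(
            percent, percent * 0 + 100, quant.sample_metadata(percent.columns)
        )
        per_sample, per_stage = global_summary(mat)
        assert per_sample["E9.5_mixed_r1"] == pytest.approx(50.0)
        assert per_stage["E9.5"] == pytest.approx((50 + 30) / 2)

    def test_all_zero_floor(self):
        percent = pd.DataFrame({"s": [0.0, 0.0]}, index=["a", "b"])
        mat = MethylationMatrix(percent, percent + 10, quant.sample_metadata(["s"]))
        per_sample, _ = global_summary(mat)
        assert per_sample["s"] == 0.0

    def test_all_missing_sample_named_in_error(self):
        percent = pd.DataFrame({"bad_sample": [np.nan, np.nan]}, index=["a", "b"])
        mat = MethylationMatrix(percent, percent * 0, quant.sample_metadata(percent.columns))
        with pytest.raises(ValueError, match="bad_sample"):
            global_summary(mat)


class TestDistribution:
    def test_constant_matrix(self):
        percent = pd.DataFrame({"s": [50.0] * 10})
        mat = MethylationMatrix(percent, percent * 0 + 100, quant.sample_metadata(["s"]))
        dist = methylation_distribution(mat)
        assert (dist["s"] == 50.0).all()

    def test_uniform_levels_match_sorted_array_oracle(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 100, size=5000)
        percent = pd.DataFrame({"s": vals})
        mat = MethylationMatrix(percent, percent * 0 + 100, quant.sample_metadata(["s"]))
        grid = (5, 25, 50, 75, 95)
        dist = methylation_distribution(mat, grid)
        s = np.sort(vals)
        for p in grid:
            oracle = s[min(int(np.ceil(p / 100 * len(s))) - 1, len(s) - 1)]
            assert dist.loc[p, "s"] == pytest.approx(oracle, abs=1.5)
            assert dist.loc[p, "s"] == pytest.approx(p, abs=3.0)
        assert (np.diff(dist["s"]) >= 0).all()

    def test_demethylated_stage_dominated_downward(self, calls, annotation):
        probes = tile_genome(annotation.chrom_lengths, 5000)
        mat = probe_methylation(calls, probes)
        dist = methylation_distribution(mat, (10, 25, 50, 75, 90))
        early = dist["E6.5_mixed_r1"]
        late = dist["E13.5_female_r1"]
        assert (late <= early).all()


class TestConversionEfficiency:
    def test_zero_failure_rate_gives_fraction_one(self):
        calls = {
            "s": make_calls(
                [("chr1", i * 10, "+", "CHH", 0, 30) for i in range(10)]
            )
        }
        probes = tile_genome({"chr1": 100}, 100)
        frac, _ = conversion_efficiency(calls, probes, min_total_count=20)
        assert frac["s"] == 1.0

    def test_single_methylated_chh_fails_probe(self):
        calls = {
            "s": make_calls([("chr1", 10, "+", "CHH", 1, 999)])
        }
        probes = tile_genome({"chr1": 100}, 100)
        frac, table = conversion_efficiency(calls, probes, min_total_count=20)
        assert frac["s"] == 0.0
        assert not table["fully_converted"].iloc[0]

    def test_failure_rate_matches_poisson_thinning_oracle(self):
        # 200 CHH observations per probe at failure rate 0.002:
        # P(zero methylated) = (1 - 0.002)^200 ~ e^-0.4
        rng = np.random.default_rng(12)
        n_probes, per_probe, eps = 500, 200, 0.002
        rows = []
        for i in range(n_probes):
            meth = rng.binomial(per_probe, eps)
            rows.append(("chr1", i * 100 + 5, "+", "CHH", meth, per_probe - meth))
        probes = tile_genome({"chr1": n_probes * 100}, 100)
        frac, _ = conversion_efficiency({"s": make_calls(rows)}, probes, 20)
        expected = np.exp(-0.4)
        se = np.sqrt(expected * (1 - expected) / n_probes)
        assert abs(frac["s"] - expected) < 4 * se

    def test_no_qualifying_probes_raises(self):
        calls = {"s": make_calls([("chr1", 10, "+", "CHH", 0, 3)])}
        probes = tile_genome({"chr1": 100}, 100)
        with pytest.raises(ValueError):
            conversion_efficiency(calls, probes, min_total_count=20)


class TestCgDensityCorrelation:
    def test_proportional_gives_one(self):
        percent = pd.DataFrame({"s": [10.0, 20.0, 30.0, 40.0]}, index=list("abcd"))
        mat = MethylationMatrix(percent, percent * 0 + 100, quant.sample_metadata(["s"]))
        counts = pd.Series([1, 2, 3, 4], index=list("abcd"))
        res = cg_density_correlation(mat, counts)
        assert res.loc["s", "r"] == pytest.approx(1.0)

    def test_constant_methylation_flagged_undefined(self):
        percent = pd.DataFrame({"s": [50.0, 50.0, 50.0]}, index=list("abc"))
        mat = MethylationMatrix(percent, percent * 0 + 100, quant.sample_metadata(["s"]))
        res = cg_density_correlation(mat, pd.Series([1, 2, 3], index=list("abc")))
        assert not res.loc["s", "defined"]
        assert np.isnan(res.loc["s", "r"])

    def test_correlation_decays_over_time_course(self, calls, annotation):
        probes = tile_genome(annotation.chrom_lengths, 5000)
        mat = probe_methylation(calls, probes)
        cpg_counts = {}
        for _, p in probes.iterrows():
            sites = annotation.cpgs[p["chrom"]]
            cpg_counts[p["probe_id"]] = int(
                ((sites >= p["start"]) & (sites < p["end"])).sum()
            )
        res = cg_density_correlation(mat, pd.Series(cpg_counts))
        assert abs(res.loc["E13.5_male_r1", "r"]) < abs(res.loc["E6.5_mixed_r1", "r"])


class TestFeatureMethylation:
    def test_fully_methylated_feature(self, annotation):
        fid = annotation.by_class("CGI").iloc[0]
        calls = {
            "s": make_calls(
                [(fid["chrom"], int(p), "+", "CG", 10, 0) for p in
                 annotation.feature_cpgs(fid["feature_id"])]
            )
        }
        mat = feature_methylation(calls, annotation, min_total_count=1)
        assert mat.percent.loc[fid["feature_id"], "s"] == pytest.approx(100.0)

    def test_imprinted_dmr_balanced_alleles_exactly_fifty(self, annotation):
        dmr = annotation.by_class("DMR_mat").iloc[0]
        sites = annotation.feature_cpgs(dmr["feature_id"])
        # one methylated allele, one unmethylated, error-free balanced coverage
        calls = {
            "s": make_calls(
                [(dmr["chrom"], int(p), "+", "CG", 15, 15) for p in sites]
            )
        }
        mat = feature_methylation(calls, annotation, min_total_count=1)
        assert mat.percent.loc[dmr["feature_id"], "s"] == pytest.approx(50.0)

    def test_both_strands_of_dyad_counted(self, annotation):
        cgi = annotation.by_class("CGI").iloc[0]
        p = int(annotation.feature_cpgs(cgi["feature_id"])[0])
        calls = {
            "s": make_calls(
                [
                    (cgi["chrom"], p, "+", "CG", 4, 0),
                    (cgi["chrom"], p + 1, "-", "CG", 0, 4),
                ]
            )
        }
        mat = feature_methylation(calls, annotation, min_total_count=1)
        assert mat.percent.loc[cgi["feature_id"], "s"] == pytest.approx(50.0)
        assert mat.counts.loc[cgi["feature_id"], "s"] == 8

    def test_iap_class_stays_above_bulk_at_every_stage(self, calls, annotation):
        mat = feature_methylation(calls, annotation)
        med = mat.stage_medians()
        cls = annotation.features.set_index("feature_id")["feature_class"]
        by_class = med.groupby(cls).median()
        for col in med.columns:
            assert by_class.loc["IAP", col] > by_class.loc["exon", col]

    def test_percentages_bounded(self, calls, annotation):
        mat = feature_methylation(calls, annotation)
        vals = mat.percent.to_numpy()
        finite = np.isfinite(vals)
        assert ((vals[finite] >= 0) & (vals[finite] <= 100)).all()
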