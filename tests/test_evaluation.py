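import numpy as np
import pytest

import rverdict as rv
from rverdict.evaluation import (
    PCA_OPERATING_POINT,
    bias_dispersion,
    group_comparison,
    repeatability_stats,
    t2_distribution_compare,
)


class TestBiasDispersion:
    def test_perfect_estimates(self):
        truth = np.random.default_rng(0).uniform(0.5, 1.0, (50, 8))
        rep = bias_dispersion(truth, truth.copy())
        assert rep.pooled_bias == pytest.approx(0.0, abs=1e-12)
        assert rep.pooled_dispersion == pytest.approx(0.0, abs=1e-12)

    def test_uniform_ten_percent_overestimate(self):
        rng = np.random.default_rng(1)
        lo, hi = rv.DEFAULT_RANGES.lower, rv.DEFAULT_RANGES.upper
        truth = rng.uniform(lo + 0.2 * (hi - lo), hi, (200, 8))
        rep = bias_dispersion(truth, truth * 1.1)
        assert rep.pooled_bias == pytest.approx(10.0, abs=1e-9)
        assert rep.pooled_dispersion == pytest.approx(0.0, abs=1e-9)

    def test_small_truth_fractions_excluded(self):
        truth = np.tile(rv.DEFAULT_RANGES.lower + 1e-3, (10, 1))
        est = truth * 3
        rep = bias_dispersion(truth, est)
        # fraction and radius truths near the lower bound fall below 5% of
        # their range width and are excluded from percent-of-truth stats;
        # T1 cannot (its lower bound already exceeds 5% of its width)
        per = rep.per_parameter
        for name in ("f0_ic", "f0_ees", "r"):
            assert per.loc[name, "n_used"] == 0
        assert per.loc["t1", "n_used"] == 10

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            bias_dispersion(np.empty((0, 8)), np.empty((0, 8)))


class TestRepeatability:
    def test_identity_scans(self):
        x = np.linspace(1, 2, 30)
        out = repeatability_stats(x, x.copy())
        assert out["r2"] == 1.0 and out["icc"] == 1.0 and out["cv"] == 0.0
        assert out["bland_altman"]["mean_diff"] == 0.0

    def test_constant_offset_bland_altman(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(1, 2, 50)
        out = repeatability_stats(x, x + 0.3)
        assert out["bland_altman"]["mean_diff"] == pytest.approx(0.3)
        assert out["r2"] == pytest.approx(1.0, abs=1e-9)

    def test_uncorrelated_noise_gives_near_zero_icc(self):
        # permutation-style oracle: independent vectors should show no
        # agreement beyond sampling error at n = 100
        rng = np.random.default_rng(3)
        x = rng.normal(1.0, 0.2, 100)
        y = rng.normal(1.0, 0.2, 100)
        out = repeatability_stats(x, y)
        assert abs(out["icc"]) < 0.25

    def test_icc_matches_direct_anova_formula(self):
        # independent route: ICC(2,1) from the two-way ANOVA mean squares
        rng = np.random.default_rng(4)
        x = rng.uniform(1, 2, 40)
        y = x + rng.normal(0, 0.05, 40)
        out = repeatability_stats(x, y)
        data = np.stack([x, y], axis=1)
        n, k = data.shape
        grand = data.mean()
        msr = k * ((data.mean(axis=1) - grand) ** 2).sum() / (n - 1)
        msc = n * ((data.mean(axis=0) - grand) ** 2).sum() / (k - 1)
        sst = ((data - grand) ** 2).sum()
        mse = (sst - msr * (n - 1) - msc * (k - 1)) / ((n - 1) * (k - 1))
        icc21 = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        assert out["icc"] == pytest.approx(icc21, abs=1e-6)


class TestGroupComparison:
    def test_null_type_one_error_controlled(self):
        # 1000 simulated null datasets: corrected pairwise false-positive
        # rate stays at or below the nominal level
        rng = np.random.default_rng(5)
        false_pos = 0
        n_pairs = 0
        for _ in range(1000):
            groups = {g: rng.normal(0, 1, 12) for g in ("benign", "3+3", "3+4", ">=4+3")}
            out = group_comparison(groups)
            false_pos += int(out["pairwise"]["significant"].sum())
            n_pairs += len(out["pairwise"])
        assert false_pos / 1000 <= 0.05 * 6 * 1.5  # family-wise margin
        assert false_pos / n_pairs <= 0.05

    def test_separated_groups_detected(self):
        rng = np.random.default_rng(6)
        groups = {
            "benign": rng.normal(0, 1, 20),
            "3+4": rng.normal(5, 1, 20),
        }
        out = group_comparison(groups)
        assert out["pairwise"]["p_bonferroni"].iloc[0] < 0.001

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            group_comparison({"benign": np.ones(5)})


class TestT2DistributionCompare:
    def test_identical_maps(self):
        a = np.random.default_rng(7).uniform(40, 90, (6, 6, 2))
        out = t2_distribution_compare(a, a.copy())
        assert out["p"] == pytest.approx(1.0)
        assert out["median_a"] == out["median_b"]

    def test_shifted_maps_significant(self):
        a = np.random.default_rng(8).uniform(40, 90, 500)
        out = t2_distribution_compare(a, a + 100.0)
        assert out["p"] < 1e-10
        assert out["iqr_a"][0] < out["iqr_a"][1]

    def test_mask_applied(self):
        a = np.ones((4, 4))
        b = np.full((4, 4), 2.0)
        mask = np.zeros((4, 4), bool)
        mask[:2] = True
        out = t2_distribution_compare(a, b, mask)
        assert out["median_a"] == 1.0 and out["median_b"] == 2.0


class TestDegeneracyReportShape:
    def test_perfect_fitter_zero_sd(self, scheme):
        # noiseless signals and a fitter that returns the generating truth:
        # every held-parameter distribution collapses to a point
        from rverdict.evaluation import degeneracy_report
        from rverdict.simulate import degeneracy_grid

        grids = degeneracy_grid(PCA_OPERATING_POINT, rv.DEFAULT_RANGES, levels=2)
        queue = [grids[h] for h in grids]

        def perfect_fitter(signals, sch):
            return queue.pop(0)

        df = degeneracy_report(
            perfect_fitter, PCA_OPERATING_POINT, snr=np.inf, levels=2, scheme=scheme
        )
        assert set(df.index) == {n for n in rv.RVERDICT_PARAM_NAMES if n != "s0"}
        np.testing.assert_allclose(df["sd"], 0.0, atol=1e-12)
        assert len(df) == 7
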