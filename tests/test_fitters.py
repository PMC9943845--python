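import numpy as np
import pytest

import rverdict as rv
from rverdict.fit_dnn import normalize_input
from rverdict.fit_nlls import NllsContext
from rverdict.models import RVERDICT_PARAM_NAMES


class TestDnnTraining:
    def test_fixed_seed_gives_identical_weights(self, scheme):
        ts = rv.sample_training_set(rv.DEFAULT_RANGES, scheme, 2000, 35.0, seed=1)
        hyper = rv.DnnHyperparams(hidden=(32, 32, 32), epochs=10)
        a = rv.train(ts, hyper, seed=5)
        b = rv.train(ts, hyper, seed=5)
        for wa, wb in zip(a.model.coefs_, b.model.coefs_):
            np.testing.assert_array_equal(wa, wb)

    def test_noiseless_interpolation_sanity(self, scheme, noiseless_dnn):
        # training inputs should be recovered far better than range width
        ts = rv.sample_training_set(rv.DEFAULT_RANGES, scheme, 2000, np.inf, seed=303)
        pred = rv.predict(noiseless_dnn, ts.signals, scheme)
        err = np.abs(pred - ts.targets) / rv.DEFAULT_RANGES.width
        med = np.median(err, axis=0)
        # all parameters well below range width; the directly encoded
        # fractions much tighter (S0/T1/T2 are weakly identified by the
        # protocol's narrow TE/TR span even without noise)
        assert np.all(med < 0.30)
        for name in ("f0_ic", "f0_ees"):
            assert med[rv.RVERDICT_PARAM_NAMES.index(name)] < 0.12

    def test_metadata_recorded(self, trained_dnn):
        md = trained_dnn.metadata
        assert md["snr"] == 35.0 and "scheme_hash" in md
        assert np.isfinite(trained_dnn.final_loss)


class TestDnnPredict:
    def test_outputs_within_ranges_and_simplex(self, trained_dnn, scheme):
        rng = np.random.default_rng(0)
        sig = rng.uniform(0, 1.2, (200, 10))
        pred = rv.predict(trained_dnn, sig, scheme)
        assert np.all(pred >= rv.DEFAULT_RANGES.lower - 1e-12)
        assert np.all(pred <= rv.DEFAULT_RANGES.upper + 1e-12)
        i_ic = RVERDICT_PARAM_NAMES.index("f0_ic")
        i_ees = RVERDICT_PARAM_NAMES.index("f0_ees")
        assert np.all(pred[:, i_ic] + pred[:, i_ees] <= 1.0 + 1e-12)

    def test_all_zero_row_is_finite(self, trained_dnn, scheme):
        pred = rv.predict(trained_dnn, np.zeros((1, 10)), scheme)
        assert np.all(np.isfinite(pred))

    def test_batch_partition_invariance(self, trained_dnn, scheme):
        ts = rv.sample_training_set(rv.DEFAULT_RANGES, scheme, 64, 35.0, seed=3)
        whole = rv.predict(trained_dnn, ts.signals, scheme)
        parts = np.vstack(
            [rv.predict(trained_dnn, ts.signals[i : i + 16], scheme) for i in range(0, 64, 16)]
        )
        np.testing.assert_allclose(whole, parts, rtol=1e-10)

    def test_shape_mismatch_rejected(self, trained_dnn, scheme):
        with pytest.raises(ValueError):
            rv.predict(trained_dnn, np.ones((5, 7)), scheme)

    def test_parameter_recovery_noiseless_midrange(self, noiseless_dnn, scheme):
        # held-out noiseless mid-range signals: fraction and radius errors
        # within 10% of range width (pure-inversion estimator; the
        # noise-trained one shrinks towards the conditional mean)
        rng = np.random.default_rng(9)
        lo, hi = rv.DEFAULT_RANGES.lower, rv.DEFAULT_RANGES.upper
        truth = rng.uniform(lo + 0.3 * (hi - lo), lo + 0.7 * (hi - lo), (300, 8))
        ok = truth[:, 4] + truth[:, 5] <= 1
        truth = truth[ok]
        clean = rv.rverdict_signal_matrix(truth, scheme)
        pred = rv.predict(noiseless_dnn, clean, scheme)
        for name in ("f0_ic", "f0_ees", "r"):
            j = RVERDICT_PARAM_NAMES.index(name)
            err = np.abs(pred[:, j] - truth[:, j]) / (hi[j] - lo[j])
            assert np.mean(err) <= 0.10, name

    def test_estimator_round_trip_file(self, trained_dnn, scheme, tmp_path):
        p = tmp_path / "est.joblib"
        rv.save_estimator(trained_dnn, p)
        loaded = rv.load_estimator(p)
        sig = np.full((3, 10), 0.5)
        np.testing.assert_array_equal(
            rv.predict(loaded, sig, scheme), rv.predict(trained_dnn, sig, scheme)
        )


class TestInputNormalisation:
    def test_rverdict_mode_divides_by_b0_mean(self, scheme):
        sig = np.arange(10, dtype=float)[None, :] + 1.0
        x = normalize_input(sig, scheme, "rverdict")
        b0_mean = sig[0, scheme.b0_indices].mean()
        np.testing.assert_allclose(x[0], sig[0] / b0_mean)

    def test_verdict_mode_uses_paired_b0(self, scheme):
        sig = np.arange(10, dtype=float)[None, :] + 1.0
        x = normalize_input(sig, scheme, "verdict")
        pairs = scheme.b0_pair_index()
        np.testing.assert_allclose(x[0], sig[0, scheme.nonzero_indices] / sig[0, pairs])


class TestNlls:
    def test_noiseless_midrange_recovery(self, scheme):
        lo, hi = rv.DEFAULT_RANGES.lower, rv.DEFAULT_RANGES.upper
        mid = (lo + hi) / 2
        mid[4], mid[5] = 0.4, 0.4
        clean = rv.rverdict_signal_matrix(mid[None, :], scheme)[0]
        res = rv.fit_voxel_nlls(clean, scheme, "rverdict")
        assert res.converged
        assert abs(res.params[4] - 0.4) < 1e-3 and abs(res.params[5] - 0.4) < 1e-3
        assert abs(res.params[6] - mid[6]) < 0.1

    def test_degenerate_pure_intracellular(self, scheme):
        p = np.array([1.0, 2700.0, 70.0, 530.0, 0.99, 0.005, 8.0, 2.0])
        clean = rv.rverdict_signal_matrix(p[None, :], scheme)[0]
        res = rv.fit_voxel_nlls(clean, scheme, "rverdict")
        assert res.params[4] >= 0.95

    def test_single_grid_point_starts_at_midpoint(self, scheme):
        ctx = NllsContext(scheme, "rverdict", rv.DEFAULT_RANGES, grid_points=1)
        assert ctx.grid.shape[0] == 1
        np.testing.assert_allclose(
            ctx.grid[0], (rv.DEFAULT_RANGES.lower + rv.DEFAULT_RANGES.upper) / 2
        )

    def test_all_zero_signal_flagged(self, scheme):
        res = rv.fit_voxel_nlls(np.zeros(10), scheme, "rverdict")
        assert not res.ok and np.all(np.isnan(res.params))

    def test_residual_never_worse_than_grid(self, scheme):
        # refined residual must improve on the best grid start
        ts = rv.sample_training_set(rv.DEFAULT_RANGES, scheme, 5, 35.0, seed=12)
        ctx = NllsContext(scheme, "rverdict")
        for sig in ts.signals:
            res = rv.fit_voxel_nlls(sig, scheme, "rverdict", ctx=ctx)
            grid_sse = ((ctx.grid_signals - sig[None, :]) ** 2).sum(axis=1)
            assert res.residual <= np.sqrt(grid_sse.min()) + 1e-9

    def test_analytic_jacobian_matches_finite_differences(self, scheme, pca_point):
        ctx = NllsContext(scheme, "rverdict")
        p0 = pca_point.to_array()
        jac = ctx.jacobian(p0)
        num = np.zeros_like(jac)
        for j in range(8):
            h = 1e-6 * max(1.0, abs(p0[j]))
            pp, pm = p0.copy(), p0.copy()
            pp[j] += h
            pm[j] -= h
            num[:, j] = (ctx.forward(pp) - ctx.forward(pm)) / (2 * h)
        np.testing.assert_allclose(jac, num, atol=1e-7)

    def test_verdict_model_noiseless_recovery(self, scheme):
        p = np.array([0.35, 0.45, 9.0])
        clean = rv.verdict_signal_matrix(p[None, :], scheme)[0]
        res = rv.fit_voxel_nlls(clean, scheme, "verdict")
        np.testing.assert_allclose(res.params, p, atol=1e-3)
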