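import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import rverdict as rv
from rverdict.models import RVERDICT_PARAM_NAMES


def _rvp(**kw):
    base = dict(
        s0=1.0, t1=2700.0, t2_ic=70.0, t2_vasc_ees=530.0,
        f0_ic=0.4, f0_ees=0.4, r=8.0, d_ees=2.0,
    )
    base.update(kw)
    return rv.RVerdictParams(**base)


class TestParamTypes:
    def test_fraction_sum_violation_rejected(self):
        with pytest.raises(ValueError):
            rv.VerdictParams(f_ic=0.7, f_ees=0.5, r=8.0)
        with pytest.raises(ValueError):
            _rvp(f0_ic=0.7, f0_ees=0.5)

    def test_fvasc_always_derived(self):
        p = rv.VerdictParams(f_ic=0.4, f_ees=0.4, r=8.0)
        assert p.f_vasc == pytest.approx(0.2)
        assert _rvp(f0_ic=0.6, f0_ees=0.4).f0_vasc == 0.0

    def test_array_round_trip(self, pca_point):
        assert rv.RVerdictParams.from_array(pca_point.to_array()) == pca_point


class TestDerivedQuantities:
    def test_fvasc_clipping(self):
        assert rv.derived_fvasc(0.4, 0.4) == pytest.approx(0.2)
        assert rv.derived_fvasc(1.0, 0.0) == 0.0
        assert rv.derived_fvasc(0.7, 0.5) == 0.0

    def test_cellularity(self):
        assert rv.derived_cellularity(0.4, 8.0) == pytest.approx(7.8125e-4)
        assert rv.derived_cellularity(0.0, 5.0) == 0.0
        # halving R at fixed f_ic multiplies cellularity by 8
        assert rv.derived_cellularity(0.4, 4.0) == pytest.approx(
            8 * rv.derived_cellularity(0.4, 8.0)
        )


class TestVerdictSignal:
    def test_is_mixture_of_compartment_signals(self, scheme):
        p = rv.VerdictParams(f_ic=0.4, f_ees=0.4, r=8.0)
        got = rv.verdict_signal(p, scheme)
        for k, m in enumerate(mm for mm in scheme if mm.b > 0):
            expect = (
                0.2 * rv.signal_stick_powder(m.b_internal, rv.D_VASC)
                + 0.4 * rv.signal_sphere_gpd(m, 8.0, rv.D_IC)
                + 0.4 * rv.signal_ees(m.b_internal, 2.0)
            )
            assert got[k] == pytest.approx(expect, rel=1e-12)

    def test_degenerate_mixture_is_pure_sphere(self, scheme):
        p = rv.VerdictParams(f_ic=1.0, f_ees=0.0, r=8.0)
        got = rv.verdict_signal(p, scheme)
        sphere = [rv.signal_sphere_gpd(m, 8.0, rv.D_IC) for m in scheme if m.b > 0]
        np.testing.assert_allclose(got, sphere, rtol=1e-12)

    def test_values_in_unit_interval(self, scheme):
        got = rv.verdict_signal(rv.VerdictParams(0.3, 0.5, 6.0), scheme)
        assert np.all((got > 0) & (got <= 1))


class TestRVerdictSignal:
    def test_b0_rows_follow_relaxation_only_expression(self, scheme, pca_point):
        got = rv.rverdict_signal(pca_point, scheme)
        p = pca_point
        for i in scheme.b0_indices:
            m = scheme.measurements[i]
            expect = (
                p.s0
                * (1 - np.exp(-m.tr / p.t1))
                * (
                    (p.f0_vasc + p.f0_ees) * np.exp(-m.te / p.t2_vasc_ees)
                    + p.f0_ic * np.exp(-m.te / p.t2_ic)
                )
            )
            assert got[i] == pytest.approx(expect, rel=1e-12)

    def test_reduces_to_verdict_when_relaxation_factors_vanish(self, scheme, pca_point):
        # TE/T2 -> 0 and TR/T1 -> inf turns the joint model into the plain
        # mixture (realised via T2 -> inf, T1 -> 0+ since TE >= Delta+delta)
        p = _rvp(t1=1e-9, t2_ic=1e12, t2_vasc_ees=1e12)
        got = rv.rverdict_signal(p, scheme)
        vp = rv.VerdictParams(p.f0_ic, p.f0_ees, p.r, d_ees=p.d_ees)
        want = rv.verdict_signal(vp, scheme)
        np.testing.assert_allclose(got[scheme.nonzero_indices], want, rtol=1e-9)
        np.testing.assert_allclose(got[scheme.b0_indices], 1.0, rtol=1e-9)

    def test_shell_normalisation_cancels_shared_t2(self, scheme, pca_point):
        # equal compartment T2s: dividing shells by their paired b = 0 rows
        # recovers the relaxation-free model exactly
        p = _rvp(t2_ic=530.0, t2_vasc_ees=530.0, s0=1.03, t1=1800.0)
        sig = rv.rverdict_signal(p, scheme)
        ratio = sig[scheme.nonzero_indices] / sig[scheme.b0_pair_index()]
        vp = rv.VerdictParams(p.f0_ic, p.f0_ees, p.r, d_ees=p.d_ees)
        np.testing.assert_allclose(ratio, rv.verdict_signal(vp, scheme), rtol=1e-12)

    @settings(max_examples=30, deadline=None)
    @given(
        te_scale=st.floats(1.0, 2.0),
        tr_scale=st.floats(1.0, 2.0),
    )
    def test_monotone_in_te_and_tr(self, scheme, pca_point, te_scale, tr_scale):
        def signal(te_s, tr_s):
            mod = rv.AcquisitionScheme(
                [
                    rv.Measurement(m.b, m.delta, m.Delta, m.te * te_s, m.tr * tr_s)
                    for m in scheme
                ]
            )
            return rv.rverdict_signal(pca_point, mod)

        base = signal(1.0, 1.0)
        assert np.all(signal(te_scale, 1.0) <= base + 1e-15)   # decreasing in TE
        assert np.all(signal(1.0, tr_scale) >= base - 1e-15)   # increasing in TR

    def test_matrix_path_matches_scalar_path(self, scheme, pca_point):
        arr = np.stack([pca_point.to_array(), _rvp(f0_ic=0.2, r=5.0).to_array()])
        mat = rv.rverdict_signal_matrix(arr, scheme)
        np.testing.assert_allclose(mat[0], rv.rverdict_signal(pca_point, scheme))
        np.testing.assert_allclose(
            mat[1], rv.rverdict_signal(_rvp(f0_ic=0.2, r=5.0), scheme)
        )
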