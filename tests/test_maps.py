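import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neuroquant.io_core import AcquisitionSeries, ImageVolume, ParametricMap, PetFrame
from neuroquant.maps import (
    AslModelConstants,
    compute_k1,
    compute_suv,
    fit_adc_direction,
    fit_inversion_recovery,
    k1_from_r1,
    mean_adc,
)
from neuroquant.phantom import PAPER_BVALUES, PAPER_TI_SCHEDULE

VS = (0.5, 0.5, 1.0)


def series_from_stack(stack, values, kind):
    frames = [
        ImageVolume(voxels=stack[..., k], voxel_size=VS) for k in range(stack.shape[-1])
    ]
    return AcquisitionSeries(frames=frames, axis_kind=kind, axis_values=values)


def dwi_series(signal_of_b, shape=(4, 4, 2), bvalues=PAPER_BVALUES):
    b = np.asarray(bvalues, dtype=float)
    stack = np.broadcast_to(signal_of_b(b), shape + (b.size,)).copy()
    return series_from_stack(stack, b, "bvalue")


def ir_series(c, s0, t1, shape=(4, 4, 2), tis=PAPER_TI_SCHEDULE):
    ti = np.asarray(tis, dtype=float)
    sig = c + s0 * (1.0 - 2.0 * np.exp(-ti / t1))
    stack = np.broadcast_to(sig, shape + (ti.size,)).copy()
    return series_from_stack(stack, ti, "inversion_time")


class TestAdcFit:
    def test_noiseless_exact_recovery(self):
        s = dwi_series(lambda b: 1000.0 * np.exp(-7e-4 * b))
        fit = fit_adc_direction(s, mask=np.ones((4, 4, 2), bool))
        np.testing.assert_allclose(fit.values, 7e-4, rtol=1e-6)

    def test_constant_signal_gives_zero_adc(self):
        s = dwi_series(lambda b: np.full_like(b, 500.0))
        fit = fit_adc_direction(s, mask=np.ones((4, 4, 2), bool))
        np.testing.assert_allclose(fit.values, 0.0, atol=1e-15)

    def test_loglinear_equals_nls_at_zero_noise(self):
        s = dwi_series(lambda b: 800.0 * np.exp(-1.1e-3 * b))
        mask = np.ones((4, 4, 2), bool)
        a = fit_adc_direction(s, mask=mask, method="loglinear")
        b = fit_adc_direction(s, mask=mask, method="nls")
        np.testing.assert_allclose(a.values, b.values, rtol=1e-8)

    def test_negative_adc_clamped_and_flagged(self):
        s = dwi_series(lambda b: 100.0 * np.exp(+1e-4 * b))  # rising signal
        fit = fit_adc_direction(s, mask=np.ones((4, 4, 2), bool))
        assert (fit.values[fit.mask] == 0).all()
        assert fit.clamped[fit.mask].all()

    def test_too_few_bvalues_rejected(self):
        s = dwi_series(lambda b: 1000.0 * np.exp(-7e-4 * b), bvalues=(0.0, 1000.0))
        with pytest.raises(ValueError, match="3"):
            fit_adc_direction(s, mask=np.ones((4, 4, 2), bool))

    def test_empty_mask_rejected(self):
        s = dwi_series(lambda b: 1000.0 * np.exp(-7e-4 * b))
        with pytest.raises(ValueError, match="mask"):
            fit_adc_direction(s, mask=np.zeros((4, 4, 2), bool))

    def test_mask_only_shrinks(self):
        rng = np.random.default_rng(0)
        stack = rng.uniform(100, 1000, (4, 4, 2, 7))
        stack[0, 0, 0, 3] = -1.0  # unfittable voxel
        s = series_from_stack(stack, np.asarray(PAPER_BVALUES), "bvalue")
        mask = np.ones((4, 4, 2), bool)
        fit = fit_adc_direction(s, mask=mask)
        assert (~fit.mask | mask).all()
        assert not fit.mask[0, 0, 0]


class TestMeanAdc:
    def _map(self, value, mask=None):
        m = np.ones((3, 3, 2), bool) if mask is None else mask
        return ParametricMap(values=np.full((3, 3, 2), value), quantity="ADC", mask=m,
                             voxel_size=VS)

    def test_idempotent_on_identical_maps(self):
        m = self._map(7e-4)
        out = mean_adc([m, m, m])
        np.testing.assert_array_equal(out.values, m.values)

    def test_arithmetic_mean(self):
        out = mean_adc([self._map(6e-4), self._map(7e-4), self._map(8e-4)])
        np.testing.assert_allclose(out.values, 7e-4, rtol=1e-12)

    def test_mask_intersection(self):
        partial = np.ones((3, 3, 2), bool)
        partial[1, 1, 1] = False
        out = mean_adc([self._map(7e-4), self._map(7e-4, partial)])
        assert not out.mask[1, 1, 1]
        assert out.mask.sum() == partial.sum()

    def test_grid_mismatch_rejected(self):
        other = ParametricMap(
            values=np.full((4, 4, 2), 7e-4), quantity="ADC",
            mask=np.ones((4, 4, 2), bool), voxel_size=VS,
        )
        with pytest.raises(ValueError, match="grid"):
            mean_adc([self._map(7e-4), other])


class TestInversionRecoveryFit:
    def test_noiseless_exact_recovery(self):
        s = ir_series(c=0.0, s0=100.0, t1=1.8)
        fit = fit_inversion_recovery(s, mask=np.ones((4, 4, 2), bool))
        np.testing.assert_allclose(fit.t1, 1.8, rtol=1e-6)
        np.testing.assert_allclose(fit.s0, 100.0, rtol=1e-6)
        np.testing.assert_allclose(fit.c, 0.0, atol=1e-6)
        assert not fit.at_bounds.any()
        assert fit.converged_fraction == 1.0

    def test_nonzero_bias_recovered(self):
        s = ir_series(c=12.5, s0=80.0, t1=2.4)
        fit = fit_inversion_recovery(s, mask=np.ones((4, 4, 2), bool))
        np.testing.assert_allclose(fit.t1, 2.4, rtol=1e-6)
        np.testing.assert_allclose(fit.c, 12.5, rtol=1e-6)

    def test_fully_recovered_signal_flagged_at_bound(self):
        """A constant signal (no inversion recovery visible) pins T1 at a
        bound of the admissible range and is flagged."""
        ti = np.asarray(PAPER_TI_SCHEDULE)
        stack = np.broadcast_to(np.full(ti.size, 120.0), (3, 3, 2, ti.size)).copy()
        s = series_from_stack(stack, ti, "inversion_time")
        fit = fit_inversion_recovery(s, mask=np.ones((3, 3, 2), bool))
        assert fit.at_bounds.all()
        assert not fit.t1_map().mask.any()

    def test_magnitude_mode_restores_polarity(self):
        ti = np.asarray(PAPER_TI_SCHEDULE)
        sig = 0.0 + 100.0 * (1.0 - 2.0 * np.exp(-ti / 1.8))
        stack = np.broadcast_to(np.abs(sig), (3, 3, 2, ti.size)).copy()
        s = series_from_stack(stack, ti, "inversion_time")
        fit = fit_inversion_recovery(s, mask=np.ones((3, 3, 2), bool), magnitude=True)
        np.testing.assert_allclose(fit.t1, 1.8, rtol=1e-4)

    def test_short_schedule_rejected(self):
        s = ir_series(0.0, 100.0, 1.8, tis=(0.1, 0.5, 1.0, 2.0))
        with pytest.raises(ValueError, match="5"):
            fit_inversion_recovery(s, mask=np.ones((4, 4, 2), bool))


class TestK1:
    def _r1(self, value, mask=None):
        m = np.ones((3, 3, 2), bool) if mask is None else mask
        return ParametricMap(values=np.full((3, 3, 2), value), quantity="R1", mask=m,
                             voxel_size=VS)

    def test_zero_perfusion_limit(self):
        k1 = compute_k1(self._r1(0.55), self._r1(0.55))
        np.testing.assert_array_equal(k1.values, 0.0)

    def test_worked_value(self):
        """T1ns=1.9 s, T1s=1.8 s with defaults: independent arithmetic gives
        0.95 * 0.5 * ((1/1.8 - 1/1.9) / (1/1.9)) ~= 2.639e-2 1/s."""
        expected = 0.95 * 0.5 * ((1 / 1.8 - 1 / 1.9) / (1 / 1.9))
        assert expected == pytest.approx(2.639e-2, abs=5e-6)
        k1 = compute_k1(self._r1(1 / 1.8), self._r1(1 / 1.9))
        np.testing.assert_allclose(k1.values, expected, rtol=1e-12)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(lam=st.floats(0.1, 10.0), r1ns=st.floats(0.2, 2.0), dr=st.floats(0.0, 0.5))
    def test_scale_invariance(self, lam, r1ns, dr):
        """K1 is unchanged when both R1 maps are scaled by a common factor."""
        base = k1_from_r1(r1ns + dr, r1ns)
        scaled = k1_from_r1(lam * (r1ns + dr), lam * r1ns)
        assert np.isclose(base, scaled, rtol=1e-12)

    def test_monotone_in_selective_rate(self):
        vals = [float(k1_from_r1(0.5 + d, 0.5)) for d in (0.0, 0.05, 0.1, 0.2)]
        assert vals == sorted(vals)

    def test_negative_k1_clamped_and_flagged(self):
        k1 = compute_k1(self._r1(0.50), self._r1(0.55))
        assert (k1.values == 0).all()
        assert k1.clamped.all()

    def test_grid_mismatch_rejected(self):
        other = ParametricMap(values=np.full((4, 4, 2), 0.5), quantity="R1",
                              mask=np.ones((4, 4, 2), bool), voxel_size=VS)
        with pytest.raises(ValueError, match="grid"):
            compute_k1(self._r1(0.5), other)


class TestSuv:
    def _frame(self, conc, a_inj=5.0, bw=20.0, interval=None):
        vol = ImageVolume(voxels=np.full((3, 3, 2), conc), voxel_size=VS)
        return PetFrame(activity_concentration=vol, injected_activity=a_inj,
                        body_weight=bw, injection_to_scan_interval=interval)

    def test_arithmetic(self):
        suv = compute_suv(self._frame(100.0, a_inj=5.0, bw=20.0))
        np.testing.assert_allclose(suv.values, 100.0 / (5000.0 / 20.0), rtol=1e-12)

    def test_invariant_under_common_scaling(self):
        a = compute_suv(self._frame(100.0, a_inj=5.0))
        b = compute_suv(self._frame(300.0, a_inj=15.0))
        np.testing.assert_allclose(a.values, b.values, rtol=1e-12)

    def test_decay_correction_30min(self):
        """A 30 min uptake interval shrinks the injected activity by
        2^(-30/109.77), raising the SUV by the inverse factor."""
        plain = compute_suv(self._frame(100.0))
        corrected = compute_suv(self._frame(100.0, interval=30.0))
        factor = 2.0 ** (30.0 / 109.77)
        np.testing.assert_allclose(corrected.values, plain.values * factor, rtol=1e-12)

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ValueError):
            self._frame(100.0, bw=0.0)
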