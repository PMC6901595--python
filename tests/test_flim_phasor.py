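"""Lifetime phasor transform, calibration, E-filter, fraction decomposition
and biexponential fit, checked against closed forms and brute-force
numerical integration."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

import melphasor as mp
from melphasor.synthetic_data import expected_decay_fractions

from conftest import single_exp_spec, with_shape


def wrapped_phasor_by_integration(tau, period_ns, omega_ns):
    """Brute-force numerical integration of the periodically wrapped decay."""
    norm = 1.0 - math.exp(-period_ns / tau)
    f = lambda t: math.exp(-t / tau) / norm
    den = quad(f, 0, period_ns, limit=200)[0]
    g = quad(lambda t: f(t) * math.cos(omega_ns * t), 0, period_ns, limit=200)[0]
    s = quad(lambda t: f(t) * math.sin(omega_ns * t), 0, period_ns, limit=200)[0]
    return g / den, s / den


class TestSingleExpPhasor:
    def test_limits(self, acq):
        w = acq.omega_ns
        near_zero = mp.single_exp_phasor(1e-9, w)
        assert near_zero.g == pytest.approx(1.0) and near_zero.s == pytest.approx(
            0.0, abs=1e-6
        )
        near_inf = mp.single_exp_phasor(1e9, w)
        assert near_inf.g == pytest.approx(0.0) and near_inf.s == pytest.approx(
            0.0, abs=1e-6
        )

    def test_symmetry_point(self, acq):
        tau = 1.0 / acq.omega_ns
        assert mp.single_exp_phasor(tau, acq.omega_ns) == pytest.approx((0.5, 0.5))

    def test_invalid_lifetime(self, acq):
        with pytest.raises(ValueError):
            mp.single_exp_phasor(-1.0, acq.omega_ns)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(tau=st.floats(min_value=1e-3, max_value=1e3))
    def test_universal_circle_membership(self, tau):
        """Every analytic single-exponential phasor satisfies
        (g - 1/2)^2 + s^2 = 1/4 to machine precision."""
        w = 2 * math.pi * 80e6 * 1e-9
        g, s = mp.single_exp_phasor(tau, w)
        assert (g - 0.5) ** 2 + s**2 == pytest.approx(0.25, abs=1e-14)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        tau1=st.floats(min_value=0.05, max_value=20),
        delta=st.floats(min_value=0.01, max_value=10),
    )
    def test_phase_increases_with_lifetime(self, tau1, delta):
        w = 2 * math.pi * 80e6 * 1e-9
        p1 = mp.single_exp_phasor(tau1, w)
        p2 = mp.single_exp_phasor(tau1 + delta, w)
        assert p2.s / p2.g > p1.s / p1.g  # s/g = omega*tau is increasing


class TestTransform:
    def test_delta_decay_maps_to_one_zero(self, acq):
        fine = dataclasses.replace(acq, n_time_bins=4096)
        counts = np.zeros((1, 1, 4096))
        counts[0, 0, 0] = 1000
        stack = mp.FLIMStack(counts, fine.bin_width_ns, fine.rep_rate_hz)
        field = mp.flim_phasor_transform(stack, intensity_threshold=1)
        assert field.g[0, 0] == pytest.approx(1.0, abs=1e-5)
        assert field.s[0, 0] == pytest.approx(0.0, abs=1e-2)

    def test_uniform_counts_map_to_origin(self, acq):
        """A flat histogram over the full period is the background
        convention: exactly (0, 0)."""
        counts = np.full((2, 2, acq.n_time_bins), 7.0)
        stack = mp.FLIMStack(counts, acq.bin_width_ns, acq.rep_rate_hz)
        field = mp.flim_phasor_transform(stack, intensity_threshold=1)
        np.testing.assert_allclose(field.g, 0.0, atol=1e-10)
        np.testing.assert_allclose(field.s, 0.0, atol=1e-10)

    def test_noiseless_exponential_matches_closed_form(self, acq):
        """tau = 1/omega at 4096 bins lands within 2e-3 of (0.5, 0.5), cross-
        checked against the numerical-integration oracle."""
        tau = 1.0 / acq.omega_ns
        fine = dataclasses.replace(acq, n_time_bins=4096)
        d = mp.generate_decay(
            [(single_exp_spec(tau), 1.0)], 1e6, fine, seed=0, noiseless=True
        )
        stack = mp.FLIMStack(
            d.counts.reshape(1, 1, -1), fine.bin_width_ns, fine.rep_rate_hz
        )
        field = mp.flim_phasor_transform(stack, intensity_threshold=1)
        assert math.hypot(field.g[0, 0] - 0.5, field.s[0, 0] - 0.5) < 2e-3
        gq, sq = wrapped_phasor_by_integration(tau, acq.period_ns, acq.omega_ns)
        assert math.hypot(field.g[0, 0] - gq, field.s[0, 0] - sq) < 2e-3

    def test_threshold_masks_dim_pixels(self, acq):
        counts = np.zeros((2, 2, acq.n_time_bins))
        counts[0, 0, :2] = [15, 4]    # 19 photons: below default threshold
        counts[1, 1, 0] = 50
        stack = mp.FLIMStack(counts, acq.bin_width_ns, acq.rep_rate_hz)
        field = mp.flim_phasor_transform(stack)
        assert not field.mask[0, 0] and field.mask[1, 1]
        assert not field.mask[0, 1]   # zero-count pixel always masked

    def test_all_below_threshold_warns_empty_mask(self, acq):
        counts = np.ones((2, 2, acq.n_time_bins)) * 1e-3
        stack = mp.FLIMStack(counts, acq.bin_width_ns, acq.rep_rate_hz)
        with pytest.warns(UserWarning, match="threshold"):
            field = mp.flim_phasor_transform(stack)
        assert not field.mask.any()

    def test_intensity_normalization(self, acq, eumelanin):
        """Scaling every count by a constant leaves (g, s) unchanged."""
        d = mp.generate_decay([(eumelanin, 1.0)], 1e5, acq, seed=1, noiseless=True)
        base = mp.decay_phasor(d)
        scaled = mp.DecayHistogram(d.counts * 13, acq.bin_width_ns, acq.rep_rate_hz)
        assert mp.decay_phasor(scaled) == pytest.approx(base)

    def test_shot_noise_halves_sd_when_photons_quadruple(self, acq, eumelanin):
        expect100 = 100 * expected_decay_fractions(eumelanin, acq)
        rng = np.random.Generator(np.random.Philox(5))
        t = (np.arange(acq.n_time_bins) + 0.5) * acq.bin_width_ns
        cos_t, sin_t = np.cos(acq.omega_ns * t), np.sin(acq.omega_ns * t)

        def sd_at(scale):
            reps = rng.poisson(expect100 * scale, size=(500, acq.n_time_bins))
            tot = reps.sum(axis=1)
            g = reps @ cos_t / tot
            s = reps @ sin_t / tot
            return math.sqrt(g.var(ddof=1) + s.var(ddof=1))

        ratio = sd_at(1) / sd_at(4)
        assert ratio == pytest.approx(2.0, rel=0.10)


class TestCalibration:
    def test_identity_when_reference_already_analytic(self, acq, uniform_field):
        ref = mp.CalibrationRef(
            tau_ref_ns=4.1,
            measured=mp.single_exp_phasor(4.1, acq.omega_ns),
            omega_ns=acq.omega_ns,
        )
        out = mp.calibrate(uniform_field, ref)
        np.testing.assert_allclose(out.g, uniform_field.g, atol=1e-12)
        np.testing.assert_allclose(out.s, uniform_field.s, atol=1e-12)

    def test_rotated_reference_inverts_rotation(self, acq, uniform_field):
        target = mp.single_exp_phasor(4.1, acq.omega_ns)
        rot = 0.1
        measured = mp.PhasorPoint(
            target.g * math.cos(rot) - target.s * math.sin(rot),
            target.g * math.sin(rot) + target.s * math.cos(rot),
        )
        ref = mp.CalibrationRef(4.1, measured, acq.omega_ns)
        out = mp.calibrate(uniform_field, ref)
        z = (uniform_field.g + 1j * uniform_field.s) * np.exp(-1j * rot)
        np.testing.assert_allclose(out.g, z.real, atol=1e-12)
        np.testing.assert_allclose(out.s, z.imag, atol=1e-12)

    def test_calibration_invariant_on_reference(self, acq):
        ref = mp.CalibrationRef(
            tau_ref_ns=4.1,
            measured=mp.PhasorPoint(0.3, 0.25),
            omega_ns=acq.omega_ns,
        )
        z = (0.3 + 0.25j) * ref.scale * np.exp(1j * ref.rotation)
        target = mp.single_exp_phasor(4.1, acq.omega_ns)
        assert abs(z - (target.g + 1j * target.s)) < 1e-12

    def test_zero_modulus_reference_rejected(self, acq):
        with pytest.raises(ValueError, match="modulus"):
            mp.CalibrationRef(4.1, mp.PhasorPoint(0.0, 0.0), acq.omega_ns)

    def test_phase_delay_restored_to_universal_circle(self, acq):
        """A simulated instrument delay shifts every decay; after reference
        calibration >= 99% of pixels sit within 3 shot-noise SDs of the
        universal circle."""
        shape = (48, 48)
        a = with_shape(acq, shape)
        delay_bins = 10  # ~0.49 ns
        layout = mp.make_uniform_layout(shape, f_eu=1.0, photons_per_pixel=1000)
        stack, _ = mp.generate_flim_stack(
            layout, single_exp_spec(2.0), single_exp_spec(2.0), a, seed=21
        )
        delayed = mp.FLIMStack(
            np.roll(stack.counts, delay_bins, axis=2), a.bin_width_ns, a.rep_rate_hz
        )
        field = mp.flim_phasor_transform(delayed)
        ref_decay = mp.generate_decay(
            [(single_exp_spec(4.1), 1.0)], 1.0, a, seed=0, noiseless=True
        )
        ref_measured = mp.decay_phasor(
            mp.DecayHistogram(
                np.roll(ref_decay.counts, delay_bins), a.bin_width_ns, a.rep_rate_hz
            )
        )
        cal = mp.calibrate(
            field, mp.CalibrationRef(4.1, ref_measured, a.omega_ns)
        )
        signed = np.hypot(cal.g[cal.mask] - 0.5, cal.s[cal.mask]) - 0.5
        sd = signed.std(ddof=1)
        assert (np.abs(signed) <= 3 * sd).mean() >= 0.99


class TestEFilter:
    def _field(self, g, s=None):
        g = np.asarray(g, dtype=float)
        s = g.copy() if s is None else np.asarray(s, dtype=float)
        return mp.PhasorField(
            g=g,
            s=s,
            intensity=np.ones_like(g),
            mask=np.ones_like(g, dtype=bool),
        )

    def test_constant_field_unchanged(self):
        field = self._field(np.full((7, 7), 0.4))
        out = mp.efilter(field)
        np.testing.assert_array_equal(out.g, field.g)

    def test_outlier_replaced_borders_untouched(self):
        g = np.full((7, 7), 0.4)
        g[3, 3] = 0.9
        field = self._field(g)
        out = mp.efilter(field, kernel=3)
        assert out.g[3, 3] == 0.4
        assert np.array_equal(out.g[0, :], g[0, :])
        assert np.array_equal(out.g[:, 0], g[:, 0])
        assert np.array_equal(out.g[-1, :], g[-1, :])

    def test_even_kernel_rejected(self, uniform_field):
        with pytest.raises(ValueError):
            mp.efilter(uniform_field, kernel=4)

    def test_masked_neighbors_excluded(self):
        g = np.full((5, 5), 0.4)
        g[2, 1] = 99.0  # masked-out garbage value
        field = self._field(g)
        field.mask[2, 1] = False
        out = mp.efilter(field, kernel=3)
        assert out.g[2, 2] == 0.4          # garbage neighbor ignored
        assert out.g[2, 1] == 99.0         # masked pixel passes through

    def test_variance_reduction_on_noisy_fields(self, acq, eumelanin):
        """One filter pass shrinks the interior per-pixel phasor SD,
        replicate over 100 noisy fields."""
        shape = (12, 12)
        a = with_shape(acq, shape)
        layout = mp.make_uniform_layout(shape, f_eu=1.0, photons_per_pixel=200)
        before, after = [], []
        for rep in range(100):
            stack, _ = mp.generate_flim_stack(
                layout, eumelanin, eumelanin, a, seed=3000 + rep
            )
            field = mp.flim_phasor_transform(stack, intensity_threshold=1)
            filt = mp.efilter(field)
            inner = np.s_[1:-1, 1:-1]
            before.append(field.g[inner].std() + field.s[inner].std())
            after.append(filt.g[inner].std() + filt.s[inner].std())
        assert np.mean(after) < np.mean(before)


class TestFractionDecompose:
    def _point_field(self, g, s):
        return mp.PhasorField(
            g=np.array([[g]]),
            s=np.array([[s]]),
            intensity=np.array([[1.0]]),
            mask=np.array([[True]]),
        )

    def test_endmember_maps_to_unit_fraction(self, endmember_pair):
        field = self._point_field(*endmember_pair.a)
        fm = mp.fraction_decompose(field, endmember_pair)
        assert fm.f_a[0, 0] == pytest.approx(1.0)
        assert fm.residual[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_midpoint_maps_to_half(self, endmember_pair):
        mid_g = (endmember_pair.a.g + endmember_pair.b.g) / 2
        mid_s = (endmember_pair.a.s + endmember_pair.b.s) / 2
        fm = mp.fraction_decompose(self._point_field(mid_g, mid_s), endmember_pair)
        assert fm.f_a[0, 0] == pytest.approx(0.5)

    def test_degenerate_pair_rejected(self):
        with pytest.raises(ValueError):
            mp.EndmemberPair(a=mp.PhasorPoint(0.5, 0.3), b=mp.PhasorPoint(0.5, 0.3))

    def test_mixture_recovery_at_known_fraction(self, acq, endmember_pair):
        """Photon fraction 0.7 of endmember A at 5,000 photons/pixel is
        recovered as mean f_A = 0.70 +- 0.02 over 1,000 pixels."""
        shape = (25, 40)
        a = with_shape(acq, shape)
        layout = mp.make_uniform_layout(shape, f_eu=0.7, photons_per_pixel=5000)
        stack, gt = mp.generate_flim_stack(
            layout, mp.EUMELANIN, mp.PHEOMELANIN, a, seed=14
        )
        field = mp.flim_phasor_transform(stack)
        fm = mp.fraction_decompose(field, endmember_pair)
        assert np.nanmean(fm.f_a) == pytest.approx(0.70, abs=0.02)

    def test_mixture_linearity_residual_shrinks_with_photons(
        self, acq, endmember_pair
    ):
        """Two-component mixtures sit on the chord AB up to shot noise; the
        perpendicular residual shrinks as photons grow."""
        shape = (10, 10)
        a = with_shape(acq, shape)
        rms = []
        for photons in (500, 50000):
            layout = mp.make_uniform_layout(shape, f_eu=0.5, photons_per_pixel=photons)
            stack, _ = mp.generate_flim_stack(
                layout, mp.EUMELANIN, mp.PHEOMELANIN, a, seed=15
            )
            fm = mp.fraction_decompose(
                mp.flim_phasor_transform(stack), endmember_pair
            )
            rms.append(float(np.sqrt(np.nanmean(fm.residual**2))))
        assert rms[1] < rms[0] / 3


class TestTwoExponentialFit:
    def test_degenerate_single_exponential(self, acq):
        d = mp.generate_decay(
            [(single_exp_spec(2.0), 1.0)], 1e6, acq, seed=0, noiseless=True
        )
        fit = mp.fit_two_exponential(d)
        assert fit.tau_avg_intensity_ns == pytest.approx(2.0, rel=0.001)

    def test_biexponential_parameter_recovery(self, acq):
        """Noiseless 0.8/3.0 ns, equal amplitudes: all parameters within 1%."""
        spec = mp.EndmemberSpec(
            "bi", ((0.8, 0.5), (3.0, 0.5)), 550.0, 30.0
        )
        d = mp.generate_decay([(spec, 1.0)], 1e6, acq, seed=0, noiseless=True)
        fit = mp.fit_two_exponential(d)
        assert fit.tau1_ns == pytest.approx(0.8, rel=0.01)
        assert fit.tau2_ns == pytest.approx(3.0, rel=0.01)
        assert fit.a1 == pytest.approx(0.5, abs=0.01)

    def test_intensity_weighted_average_formula(self):
        """a2 = 0 collapses the closed formula to tau1 exactly."""
        assert mp.ExponentialFit.intensity_weighted_lifetime(
            [1.3, 5.0], [1.0, 0.0]
        ) == pytest.approx(1.3)
        # hand arithmetic: (0.5*0.64 + 0.5*9) / (0.5*0.8 + 0.5*3)
        assert mp.ExponentialFit.intensity_weighted_lifetime(
            [0.8, 3.0], [0.5, 0.5]
        ) == pytest.approx(4.82 / 1.9)

    def test_empty_decay_rejected(self, acq):
        d = mp.DecayHistogram(
            np.zeros(acq.n_time_bins), acq.bin_width_ns, acq.rep_rate_hz
        )
        with pytest.raises(ValueError):
            mp.fit_two_exponential(d)
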