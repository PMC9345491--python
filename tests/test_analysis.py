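"""Modulation ratio, chi mapping, curve/kernel fitting, LHI and population stats."""

import numpy as np
import pytest

from sdpc.analysis import (
    LHIMap,
    ModulationResult,
    OrientationMap,
    TuningCurve,
    chi_to_f1f0,
    compute_f1f0,
    compute_lhi,
    curve_from_rectified_sine,
    detect_pinwheels,
    fit_log_gabor,
    fit_rectified_sine,
    log_gabor_quadrature,
    measure_tuning_curve,
    pinwheel_density,
    population_summary,
)
from sdpc.stimuli import GratingSpec, make_drift_sequence, make_grating


def pinwheel_map(g, centers, charges=None):
    """Orientation map theta = 1/2 sum_i q_i * atan2(y - y_i, x - x_i), degrees."""
    charges = charges or [1] * len(centers)
    rows, cols = np.meshgrid(np.arange(g), np.arange(g), indexing="ij")
    th = np.zeros((g, g))
    for (r0, c0), q in zip(centers, charges):
        th += 0.5 * q * np.degrees(np.arctan2(rows - r0, cols - c0))
    return th.ravel() % 180.0


class TestChiMapping:
    def test_branches_agree_at_minus_one(self):
        """chi = -1 is the simple/complex boundary: F1F0 = 1 from both branches."""
        assert chi_to_f1f0(-1.0) == pytest.approx(1.0, abs=1e-12)
        eps = 1e-8
        assert abs(chi_to_f1f0(-1 + eps) - chi_to_f1f0(-1 - eps)) < 1e-6

    def test_continuity_at_branch_point(self):
        left = chi_to_f1f0(-1.0 - 1e-13)
        right = chi_to_f1f0(-1.0 + 1e-13)
        assert abs(left - 1.0) < 1e-12
        assert abs(right - 1.0) < 1e-6

    def test_linear_branch(self):
        assert chi_to_f1f0(-2.0) == pytest.approx(0.5)
        assert chi_to_f1f0(-4.0) == pytest.approx(0.25)

    def test_half_rectified_value(self):
        assert chi_to_f1f0(0.0) == pytest.approx(np.pi / 2)

    def test_full_rectification_limit(self):
        assert chi_to_f1f0(1.0) == pytest.approx(2.0)
        assert chi_to_f1f0(1 - 1e-7) == pytest.approx(2.0, abs=1e-2)

    def test_undefined_above_one(self):
        with pytest.raises(ValueError):
            chi_to_f1f0(1.5)

    def test_monotone_decreasing_in_chi(self):
        chis = np.linspace(-3, 0.99, 200)
        vals = [chi_to_f1f0(c) for c in chis]
        assert np.all(np.diff(vals) > 0)   # F1F0 grows with chi (more rectification)


class TestComputeF1F0:
    def test_constant_curve_is_complex(self):
        c = TuningCurve(np.full(32, 2.0), np.arange(32) * 11.25, "drift")
        m = compute_f1f0(c)
        assert m.f1 == pytest.approx(0.0, abs=1e-12)
        assert m.f1f0 == pytest.approx(0.0, abs=1e-12)
        assert m.classification == "complex"

    def test_raised_cosine_has_unit_ratio(self):
        ax = np.arange(32) * 11.25
        c = TuningCurve(1 + np.cos(np.deg2rad(ax)), ax, "drift")
        m = compute_f1f0(c)
        assert m.f1f0 == pytest.approx(1.0, rel=1e-10)

    def test_half_rectified_cosine_gives_pi_over_two(self):
        ax = np.arange(64) * 360 / 64
        c = TuningCurve(np.maximum(np.cos(np.deg2rad(ax)), 0), ax, "drift")
        assert compute_f1f0(c).f1f0 == pytest.approx(np.pi / 2, rel=1e-3)

    def test_zero_curve_flagged_nonresponsive(self):
        c = TuningCurve(np.zeros(32), np.arange(32), "drift")
        assert compute_f1f0(c).classification == "nonresponsive"

    def test_measurement_matches_theory_across_chi(self):
        """f1/f0 measured on curves synthesised from the rectified-sine model
        agrees with the closed-form mapping within 1% for chi in [-3, 0.9]."""
        for chi in np.arange(-3.0, 0.95, 0.1):
            curve = curve_from_rectified_sine(a=1.0, b=chi, phi0_deg=77.0, n=256)
            measured = compute_f1f0(curve).f1f0
            assert measured == pytest.approx(chi_to_f1f0(chi), rel=0.01)


class TestRectifiedSineFit:
    def test_parameter_recovery_with_noise(self):
        rng = np.random.default_rng(0)
        curve = curve_from_rectified_sine(2.0, 1.0, 30.0, n=64, rng=rng, noise_sigma=0.01)
        fit = fit_rectified_sine(curve)
        assert fit.chi == pytest.approx(0.5, abs=0.05)
        assert fit.phi0 == pytest.approx(30.0, abs=3.0)

    def test_noiseless_self_fit_is_exact(self):
        curve = curve_from_rectified_sine(1.5, -0.3, 120.0, n=64)
        fit = fit_rectified_sine(curve)
        assert fit.fit_residual < 1e-8

    def test_unclipped_regime_reduces_to_cosine_regression(self):
        curve = curve_from_rectified_sine(1.0, -1.5, 45.0, n=64)   # b <= -|a|: never clips
        fit = fit_rectified_sine(curve)
        assert fit.chi <= -1.0 + 1e-6
        # plain cosine regression: recover amplitude and offset directly
        r = curve.responses
        assert fit.a == pytest.approx(1.0, abs=1e-6)
        assert -fit.b == pytest.approx(r.mean(), abs=1e-6)

    def test_all_zero_curve_rejected(self):
        with pytest.raises(ValueError):
            fit_rectified_sine(TuningCurve(np.zeros(16), np.arange(16), "drift"))


class TestLogGaborFit:
    def test_parameter_recovery_on_synthetic_kernel(self):
        h = log_gabor_quadrature(15, theta=45.0, f0=0.2, sigma_theta=0.4, sigma_f=0.45)
        kernel = (np.cos(np.deg2rad(60)) * h.real + np.sin(np.deg2rad(60)) * h.imag)
        fit = fit_log_gabor(kernel)
        err = min(abs(fit.theta - 45.0), 180 - abs(fit.theta - 45.0))
        assert err < 3.0
        assert fit.f0 == pytest.approx(0.2, rel=0.10)

    def test_rotation_equivariance(self):
        h0 = log_gabor_quadrature(15, 20.0, 0.22, 0.4, 0.45)
        h90 = log_gabor_quadrature(15, 110.0, 0.22, 0.4, 0.45)
        t0 = fit_log_gabor(h0.real).theta
        t90 = fit_log_gabor(h90.real).theta
        d = (t90 - t0) % 180.0
        assert min(d, 180 - d) == pytest.approx(90.0, abs=4.0) or d == pytest.approx(90, abs=4)

    def test_negated_kernel_flips_phase_not_orientation(self):
        h = log_gabor_quadrature(15, 30.0, 0.2, 0.4, 0.45)
        k = 0.8 * h.real + 0.6 * h.imag
        f1, f2 = fit_log_gabor(k), fit_log_gabor(-k)
        dth = abs(f1.theta - f2.theta) % 180
        assert min(dth, 180 - dth) < 2.0
        dphi = (f2.phi - f1.phi) % 360
        assert dphi == pytest.approx(180.0, abs=5.0)

    def test_grating_kernel_orientation_matches_stimulus_convention(self):
        """A grating rendered at theta fits to preferred orientation theta."""
        for theta in (0.0, 30.0, 115.0):
            g = make_grating(GratingSpec(theta, 0.0, 0.2, size=15, mask_diameter=13))
            fit = fit_log_gabor(g)
            err = min(abs(fit.theta - theta), 180 - abs(fit.theta - theta))
            assert err < 4.0

    def test_zero_kernel_rejected(self):
        with pytest.raises(ValueError):
            fit_log_gabor(np.zeros((7, 7)))


class TestLHI:
    def test_homogeneous_map_gives_one_everywhere(self):
        omap = OrientationMap("grid_toroidal", np.full(100, 30.0))
        lhi = compute_lhi(omap, sigma=1.0)
        np.testing.assert_allclose(lhi.values, 1.0, atol=1e-12)

    def test_pinwheel_center_has_low_lhi(self):
        g = 16
        omap = OrientationMap("grid_toroidal", pinwheel_map(g, [(8, 8)]))
        lhi = compute_lhi(omap, sigma=1.0)
        assert lhi.values.reshape(g, g)[8, 8] < 0.2

    def test_matches_bruteforce_double_loop(self):
        rng = np.random.default_rng(1)
        g = 8
        theta = rng.uniform(0, 180, g * g)
        lhi = compute_lhi(OrientationMap("grid_toroidal", theta), sigma=1.0).values.reshape(g, g)
        z = np.exp(2j * np.deg2rad(theta)).reshape(g, g)
        sigma = 1.0
        for r in range(g):
            for c in range(g):
                acc, k = 0.0 + 0j, 0.0
                for dr in range(-3, 4):
                    for dc in range(-3, 4):
                        if dr * dr + dc * dc > 9:
                            continue
                        w = np.exp(-(dr * dr + dc * dc) / (2 * sigma ** 2))
                        acc += w * z[(r + dr) % g, (c + dc) % g]
                        k += w
                assert abs(lhi[r, c] - abs(acc) / k) < 1e-10

    def test_global_orientation_shift_invariance(self):
        rng = np.random.default_rng(2)
        theta = rng.uniform(0, 180, 81)
        a = compute_lhi(OrientationMap("grid_toroidal", theta)).values
        b = compute_lhi(OrientationMap("grid_toroidal", (theta + 37.0) % 180)).values
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_bounded_between_zero_and_one(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            theta = rng.uniform(0, 180, 64)
            v = compute_lhi(OrientationMap("grid_toroidal", theta)).values
            assert np.all(v >= 0) and np.all(v <= 1 + 1e-12)

    def test_ring_topology(self):
        theta = np.linspace(0, 180, 12, endpoint=False)
        v = compute_lhi(OrientationMap("ring_circular", theta), sigma=1.0).values
        assert v.shape == (12,)
        np.testing.assert_allclose(v, v[0])   # uniform gradient: same LHI everywhere

    def test_no_topology_rejected(self):
        with pytest.raises(ValueError):
            compute_lhi(OrientationMap("none", np.zeros(10)))


class TestPinwheels:
    def test_homogeneous_map_has_none(self):
        lhi = compute_lhi(OrientationMap("grid_toroidal", np.full(64, 90.0)))
        assert detect_pinwheels(lhi).count == 0

    def test_single_pinwheel_detected_at_singularity(self):
        g = 16
        lhi = compute_lhi(OrientationMap("grid_toroidal", pinwheel_map(g, [(8, 8)])))
        rep = detect_pinwheels(lhi)
        assert rep.count == 1
        assert rep.positions[0] == (8, 8)

    def test_two_separated_pinwheels(self):
        g = 20
        omap = OrientationMap("grid_toroidal",
                              pinwheel_map(g, [(5, 5), (15, 15)], charges=[1, -1]))
        rep = detect_pinwheels(compute_lhi(omap))
        assert rep.count == 2
        assert set(rep.positions) == {(5, 5), (15, 15)}

    def test_count_invariant_under_toroidal_translation(self):
        g = 16
        th = pinwheel_map(g, [(4, 4), (12, 12)], charges=[1, -1]).reshape(g, g)
        base = detect_pinwheels(compute_lhi(OrientationMap("grid_toroidal", th.ravel()))).count
        rolled = np.roll(th, (3, 5), axis=(0, 1)).ravel()
        assert detect_pinwheels(compute_lhi(OrientationMap("grid_toroidal", rolled))).count == base

    def test_ring_topology_rejected(self):
        lhi = LHIMap(np.ones(10), "ring_circular")
        with pytest.raises(ValueError):
            detect_pinwheels(lhi)


class TestPinwheelDensity:
    def test_zero_count_zero_density(self):
        from sdpc.analysis import PinwheelReport

        rep = pinwheel_density(PinwheelReport([], 0), m_units=100, mean_hwhh=36.0)
        assert rep.density == 0.0

    def test_worked_arithmetic(self):
        from sdpc.analysis import PinwheelReport

        rep = pinwheel_density(PinwheelReport([(0, 0)] * 4, 4), m_units=100, mean_hwhh=36.0)
        assert rep.column_size == pytest.approx(25.0)
        assert rep.density == pytest.approx(1.0)   # 4 / (100 / 25)

    def test_density_linear_in_count(self):
        from sdpc.analysis import PinwheelReport

        r1 = pinwheel_density(PinwheelReport([], 3), 100, 36.0)
        r2 = pinwheel_density(PinwheelReport([], 6), 100, 36.0)
        assert r2.density == pytest.approx(2 * r1.density)


class TestIdealizedUnits:
    """The constructions the pooling architecture is meant to realise."""

    def _gabor_pair(self, size, theta, f0):
        even = make_grating(GratingSpec(theta, 0.0, f0, size=size, mask_diameter=size - 2))
        odd = make_grating(GratingSpec(theta, 90.0, f0, size=size, mask_diameter=size - 2))
        return even, odd

    def test_rectified_linear_unit_is_simple(self):
        even, _ = self._gabor_pair(21, 30.0, 0.15)
        seq = make_drift_sequence(GratingSpec(30.0, 0, 0.15, size=21, mask_diameter=19), 32)
        resp = np.maximum([(f * even).sum() for f in seq.frames], 0.0)
        m = compute_f1f0(TuningCurve(resp, seq.stimulus_axis, "drift"))
        assert m.f1f0 > 1.0
        assert m.classification == "simple"

    def test_max_over_quadrature_pair_is_complex(self):
        even, odd = self._gabor_pair(21, 30.0, 0.15)
        seq = make_drift_sequence(GratingSpec(30.0, 0, 0.15, size=21, mask_diameter=19), 32)
        resp = np.maximum.reduce([
            np.maximum([(f * even).sum() for f in seq.frames], 0.0),
            np.maximum([(f * odd).sum() for f in seq.frames], 0.0),
            np.maximum([-(f * even).sum() for f in seq.frames], 0.0),
            np.maximum([-(f * odd).sum() for f in seq.frames], 0.0),
        ])
        m = compute_f1f0(TuningCurve(resp, seq.stimulus_axis, "drift"))
        assert m.f1f0 < 1.0
        assert m.classification == "complex"


class _StandInGaborModel:
    """A one-unit linear-rectified model exposing the infer() contract."""

    def __init__(self, kernel):
        self.kernel = kernel

    def infer(self, frames):
        resp = np.maximum([(f * self.kernel).sum() for f in frames], 0.0)
        gamma = np.asarray(resp)[:, None, None, None]

        class S:
            pass

        s = S()
        s.gamma = [gamma]
        return s


class TestMeasureTuningCurve:
    def test_matched_drifting_grating_gives_half_rectified_sinusoid(self):
        f0, theta = 0.15, 40.0
        kernel = make_grating(GratingSpec(theta, 0.0, f0, size=21, mask_diameter=19))
        model = _StandInGaborModel(kernel)
        seq = make_drift_sequence(GratingSpec(theta, 0.0, f0, size=21, mask_diameter=19), 32)
        curve = measure_tuning_curve(model, (0, 0), seq, whiten_stimuli=False)
        fit = fit_rectified_sine(curve)
        assert fit.fit_residual / np.sum(curve.responses ** 2) < 1e-3
        assert abs(fit.chi) < 0.1          # linear + rectification: chi ~ 0

    def test_zero_contrast_gives_zero_curve(self):
        kernel = make_grating(GratingSpec(0, 0, 0.15, size=21))
        model = _StandInGaborModel(kernel)
        seq = make_drift_sequence(GratingSpec(0, 0, 0.15, size=21, contrast=0.0), 16)
        with pytest.warns(UserWarning, match="never active"):
            curve = measure_tuning_curve(model, (0, 0), seq, whiten_stimuli=False)
        assert np.all(curve.responses == 0)
        assert len(curve.responses) == 16


class TestPopulationSummary:
    def _mods(self, ratios):
        return [ModulationResult(1.0, r, r, "simple" if r > 1 else "complex")
                for r in ratios]

    def test_r_percentage(self):
        s = population_summary(self._mods([0.5, 1.5]), self._mods([1.5, 1.5]))
        assert s.r_phase == pytest.approx(50.0)
        assert s.r_orientation == pytest.approx(0.0)

    def test_identical_chi_samples_give_half_p(self):
        mods = self._mods([0.5, 1.5, 0.8])
        s = population_summary(mods, mods, chi_drift=[0.1, 0.2, 0.3],
                               chi_rotate=[0.1, 0.2, 0.3])
        assert s.signed_rank_p == pytest.approx(0.5)

    def test_regression_slope_recovery(self):
        rng = np.random.default_rng(4)
        mods = self._mods([0.5] * 200)
        lhi = rng.uniform(0, 1, 200)
        hwhh = 60.0 - 20.0 * lhi + rng.normal(0, 1.0, 200)
        s = population_summary(mods, mods, lhi=lhi, hwhh=hwhh)
        assert s.lhi_hwhh_slope == pytest.approx(-20.0, rel=0.10)
        assert s.lhi_hwhh_p < 0.01

    def test_nonresponsive_units_excluded(self):
        mods_d = self._mods([0.5, 1.5]) + [ModulationResult(0, 0, float("nan"), "nonresponsive")]
        mods_r = self._mods([1.5, 1.5]) + [ModulationResult(0, 0, float("nan"), "nonresponsive")]
        s = population_summary(mods_d, mods_r)
        assert s.n_responsive == 2 and s.n_nonresponsive == 1
        assert s.r_phase == pytest.approx(50.0)

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            population_summary([], [])
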