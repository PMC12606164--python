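"""Curve segmentation, characteristic points and averaged-curve construction."""

import numpy as np
import pytest

from ligfit.curves import (
    AveragedCurve,
    CharacteristicPoints,
    NoInflectionError,
    StressStretchCurve,
    ToeForm,
    average_characteristic_points,
    build_averaged_curve,
    characteristic_points,
    find_inflection,
    linear_region,
    second_derivative,
)
from ligfit.synthetic import LIGAMENTS, GeneratorConfig, specimen_curve


class TestCurveValidation:
    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="11 samples"):
            StressStretchCurve([1.0, 1.1, 1.2], [0.0, 1.0, 2.0])

    def test_non_monotone_stretch_rejected(self):
        lam = np.linspace(1, 1.5, 12)
        lam[5] = lam[3]
        with pytest.raises(ValueError, match="strictly increasing"):
            StressStretchCurve(lam, np.zeros(12))

    def test_nonzero_first_stress_rejected(self):
        lam = np.linspace(1, 1.5, 12)
        with pytest.raises(ValueError, match="first stress"):
            StressStretchCurve(lam, np.ones(12))

    def test_point_ordering_enforced(self):
        with pytest.raises(ValueError):
            CharacteristicPoints((1.2, 5.0), (1.1, 8.0), (1.5, 10.0))
        with pytest.raises(ValueError):
            CharacteristicPoints((1.1, 5.0), (1.2, 4.0), (1.5, 10.0))


class TestSecondDerivative:
    def test_quadratic_constant_curvature(self):
        x = np.linspace(1, 2, 21)
        d2 = second_derivative(x, x**2)
        np.testing.assert_allclose(d2[1:-1], 2.0, rtol=1e-9)
        assert np.isnan(d2[0]) and np.isnan(d2[-1])

    def test_linear_zero(self):
        x = np.linspace(0, 1, 15)
        np.testing.assert_allclose(second_derivative(x, 3 * x + 1)[1:-1], 0.0, atol=1e-10)

    def test_cubic_exact_on_uniform_grid(self):
        # three-point central differences are exact through cubic terms
        x = np.linspace(1, 2, 31)
        np.testing.assert_allclose(second_derivative(x, x**3)[1:-1], 6 * x[1:-1], rtol=1e-9)

    def test_second_order_convergence(self):
        """O(h^2) on a smooth non-polynomial function under grid refinement."""
        errs = []
        for n in (41, 81, 161):
            x = np.linspace(0, 1, n)
            d2 = second_derivative(x, np.sin(3 * x))
            errs.append(np.max(np.abs(d2[1:-1] + 9 * np.sin(3 * x[1:-1]))))
        assert errs[0] / errs[1] == pytest.approx(4.0, rel=0.15)
        assert errs[1] / errs[2] == pytest.approx(4.0, rel=0.15)

    def test_nonuniform_grid_quadratic(self):
        rng = np.random.default_rng(0)
        x = np.sort(rng.uniform(0, 1, 25))
        np.testing.assert_allclose(second_derivative(x, 5 * x**2)[1:-1], 10.0, rtol=1e-8)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            second_derivative([0, 1], [0, 1])


class TestInflection:
    def test_sigmoid_inflection_recovered(self):
        """Analytic inflection of a logistic curve found within one spacing."""
        lam = np.linspace(1.0, 1.5, 101)
        lam0 = 1.23
        P = 10.0 / (1 + np.exp(-40 * (lam - lam0)))
        P -= P[0]
        curve = StressStretchCurve(lam, P)
        assert find_inflection(curve, smooth_window=5) == pytest.approx(
            lam0, abs=lam[1] - lam[0])

    def test_pure_quadratic_has_no_inflection(self):
        lam = np.linspace(1.0, 1.5, 51)
        curve = StressStretchCurve(lam, 4 * (lam - 1) ** 2)
        with pytest.raises(NoInflectionError):
            find_inflection(curve, smooth_window=5)

    def test_fully_linear_curve_propagates_error(self):
        lam = np.linspace(1.0, 1.5, 51)
        curve = StressStretchCurve(lam, 7 * (lam - 1))
        with pytest.raises(NoInflectionError):
            linear_region(curve)

    def test_generator_inflection_inside_linear_region(self, all_stats):
        curve = specimen_curve(all_stats.mean_points(), GeneratorConfig(noise_sd_rel=0.0))
        lam0 = find_inflection(curve)
        ptI, ptII = all_stats.mean_points().ptI, all_stats.mean_points().ptII
        assert ptI[0] - 0.01 < lam0 < ptII[0] + 0.01


class TestSegmentationRoundTrip:
    @pytest.mark.parametrize("name", sorted(LIGAMENTS))
    def test_clean_recovery_within_five_spacings(self, name):
        """Noise-free generator curves: transitions recovered to a few samples."""
        pts = LIGAMENTS[name].mean_points()
        curve = specimen_curve(pts, GeneratorConfig(noise_sd_rel=0.0))
        h = curve.lam[1] - curve.lam[0]
        rec = characteristic_points(curve)
        assert abs(rec.ptI[0] - pts.ptI[0]) <= 5 * h
        assert abs(rec.ptII[0] - pts.ptII[0]) <= 5 * h
        assert rec.fail == pytest.approx((pts.fail[0], pts.fail[1]), rel=1e-9)

    @pytest.mark.parametrize("name,bound", [("ISL+SSL", 2.5), ("PLL", 3.0),
                                            ("LF", 4.0), ("CL", 5.0), ("ALL", 5.5)])
    def test_noisy_recovery_median(self, name, bound):
        """1% multiplicative noise: median transition error over 60 seeds.

        The 1% acceptance band systematically overshoots the II transition
        by about 0.01 P_II / (m - m_subfailure) in stretch, which for the
        stiff ALL cohort is itself ~3 grid spacings; the bound reflects the
        per-ligament structural floor plus noise.
        """
        pts = LIGAMENTS[name].mean_points()
        errs = []
        for s in range(60):
            cfg = GeneratorConfig(seed=s, noise_sd_rel=0.01)
            curve = specimen_curve(pts, cfg, rng=np.random.default_rng(900 + s))
            h = curve.lam[1] - curve.lam[0]
            try:
                rec = characteristic_points(curve)
                errs.append(max(abs(rec.ptI[0] - pts.ptI[0]),
                                abs(rec.ptII[0] - pts.ptII[0])) / h)
            except ValueError:
                errs.append(np.inf)
        assert np.median(errs) <= bound

    def test_interior_maximum_defines_failure(self):
        lam = np.linspace(1.0, 1.6, 61)
        P = np.where(lam < 1.5, lam - 1.0, 0.5 - 2 * (lam - 1.5))
        P[0] = 0.0
        curve = StressStretchCurve(lam, 10 * P)
        k = int(np.argmax(curve.P))
        rec_fail_lam = curve.lam[k]
        assert rec_fail_lam == pytest.approx(1.5, abs=0.011)


class TestAveraging:
    def test_identical_points_zero_sd(self):
        p = CharacteristicPoints((1.1, 2.0), (1.3, 5.0), (1.5, 8.0))
        stats = average_characteristic_points([p, p])
        assert stats.sd_ptI == (0.0, 0.0)
        assert stats.mean == p

    def test_hand_arithmetic(self):
        a = CharacteristicPoints((1.1, 2.0), (1.3, 4.0), (1.6, 8.0))
        b = CharacteristicPoints((1.3, 4.0), (1.5, 6.0), (1.8, 10.0))
        stats = average_characteristic_points([a, b])
        assert stats.mean.ptI == pytest.approx((1.2, 3.0))
        assert stats.sd_ptI == pytest.approx((np.sqrt(2) * 0.1, np.sqrt(2)))

    def test_single_specimen_rejected(self):
        p = CharacteristicPoints((1.1, 2.0), (1.3, 5.0), (1.5, 8.0))
        with pytest.raises(ValueError):
            average_characteristic_points([p])


class TestAveragedCurve:
    @pytest.mark.parametrize("form", [ToeForm.EXPONENTIAL, ToeForm.POLYNOMIAL])
    def test_exact_interpolation_all(self, all_stats, form):
        pts = all_stats.mean_points()
        avg = build_averaged_curve(pts, form)
        assert avg(1.0) == pytest.approx(0.0, abs=1e-12)
        assert avg(pts.ptI[0]) == pytest.approx(pts.ptI[1], rel=1e-12)
        assert avg(pts.ptII[0]) == pytest.approx(pts.ptII[1], rel=1e-12)
        assert avg(pts.fail[0]) == pytest.approx(pts.fail[1], rel=1e-12)

    @pytest.mark.parametrize("name", sorted(LIGAMENTS))
    def test_toe_forms_agree_at_interpolation_points(self, name):
        pts = LIGAMENTS[name].mean_points()
        e = build_averaged_curve(pts, "exponential")
        p = build_averaged_curve(pts, "polynomial")
        for lam, P in (pts.ptI, pts.ptII, pts.fail):
            assert e(lam) == pytest.approx(p(lam), rel=1e-10)

    @pytest.mark.parametrize("name", sorted(LIGAMENTS))
    def test_slope_continuity_at_II(self, name):
        pts = LIGAMENTS[name].mean_points()
        avg = build_averaged_curve(pts, "exponential")
        lII = pts.ptII[0]
        left = avg.derivative(lII - 1e-9)
        right = avg.sub_slope
        assert left == pytest.approx(right, rel=1e-6)

    @pytest.mark.parametrize("form", ["exponential", "polynomial"])
    def test_all_curve_monotone(self, all_stats, form):
        """The stiff-ligament reconstruction rises monotonically to failure."""
        assert build_averaged_curve(all_stats.mean_points(), form).is_monotone()

    def test_lf_polynomial_known_non_monotone(self):
        """LF's quadratic-through-origin interpolant dips below zero initially.

        Exact interpolation forces a negative initial slope, so the
        polynomial toe is not a valid monotone reconstruction for LF; the
        exponential form is.
        """
        pts = LIGAMENTS["LF"].mean_points()
        assert not build_averaged_curve(pts, "polynomial").is_monotone()
        lam = np.linspace(1.0, pts.ptII[0], 300)
        e = build_averaged_curve(pts, "exponential")
        assert np.all(np.diff(e(lam)) >= 0)

    def test_collinear_points_fall_back_to_line(self):
        pts = CharacteristicPoints((1.1, 1.0), (1.2, 2.0), (1.4, 4.5))
        with pytest.warns(UserWarning, match="collinear"):
            avg = build_averaged_curve(pts, "exponential")
        assert avg.toe_form is ToeForm.POLYNOMIAL
        assert avg.toe_params[0] == 0.0
        assert avg(1.15) == pytest.approx(1.5, rel=1e-12)
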