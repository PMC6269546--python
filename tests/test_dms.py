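"""Peak fitting, behavior classification, turn-around and separation."""

import numpy as np
import pytest

from dmsprops import dms, synthetic
from dmsprops.records import Behavior, Conditions, DispersionCurve, Ionogram, PeakFit


def _gauss_ionogram(center=-5.0, sigma=1.2, amp=100.0, baseline=0.0, n=41,
                    lo=-10.0, hi=0.0, sv=1000.0):
    cv = np.linspace(lo, hi, n)
    return Ionogram("m", sv, cv, baseline + amp * np.exp(-((cv - center) ** 2) / (2 * sigma**2)))


def _curve(sv, cv, sigma=None, mol="m"):
    sv = np.asarray(sv, dtype=float)
    if sigma is None:
        sigma = np.full(sv.size, 1.0)
    return DispersionCurve(mol, Conditions(), sv, np.asarray(cv, dtype=float),
                           np.asarray(sigma, dtype=float))


class TestFitPeak:
    def test_exact_recovery_on_noiseless_gaussian(self):
        fit = dms.fit_peak(_gauss_ionogram())
        assert fit.converged
        assert fit.cv_opt == pytest.approx(-5.0, abs=1e-6)
        assert fit.sigma == pytest.approx(1.2, abs=1e-6)

    def test_flat_signal_flags_not_raises(self):
        ig = Ionogram("m", 1000.0, np.linspace(-5, 5, 21), np.full(21, 3.0))
        fit = dms.fit_peak(ig)
        assert not fit.converged and "flat" in fit.message

    def test_location_scale_equivariance(self):
        base = dms.fit_peak(_gauss_ionogram())
        shifted = dms.fit_peak(_gauss_ionogram(center=-5.0 + 2.5, lo=-7.5, hi=2.5))
        assert shifted.cv_opt == pytest.approx(base.cv_opt + 2.5, abs=1e-6)
        scaled = dms.fit_peak(_gauss_ionogram(amp=700.0))
        assert scaled.cv_opt == pytest.approx(base.cv_opt, abs=1e-6)
        assert scaled.sigma == pytest.approx(base.sigma, abs=1e-6)

    def test_median_error_under_noise(self):
        """Median |CV_opt error| over 500 noisy synthetic peaks < 0.05 V."""
        params = synthetic.sample_curve_params("B", np.random.default_rng(11))
        curve = synthetic.simulate_dispersion(params, synthetic.DEFAULT_SV_GRID, 0.0, seed=0)
        errors = []
        seed = 11
        while len(errors) < 500:
            seed += 1
            igs = synthetic.simulate_ionograms(
                curve, (curve.cv.min() - 6, curve.cv.max() + 6), 0.1, 1.0,
                noise_frac=0.02, seed=seed,
            )
            for ig, cv_true in zip(igs, curve.cv):
                fit = dms.fit_peak(ig)
                if fit.converged:
                    errors.append(abs(fit.cv_opt - cv_true))
        assert np.median(errors[:500]) < 0.05


class TestBuildDispersionCurve:
    def _fit(self, cv_opt):
        return PeakFit(cv_opt, 1.0, 100.0, 0.0, 0.1, True)

    def test_sorted_by_sv(self):
        fits = [(3000.0, self._fit(-3.0)), (1000.0, self._fit(-1.0)), (2000.0, self._fit(-2.0))]
        c = dms.build_dispersion_curve(fits, Conditions(), "m")
        assert np.array_equal(c.sv, [1000.0, 2000.0, 3000.0])
        assert np.array_equal(c.cv, [-1.0, -2.0, -3.0])

    def test_duplicate_sv_rejected(self):
        fits = [(1000.0, self._fit(-1.0)), (1000.0, self._fit(-1.1))]
        with pytest.raises(ValueError, match="1000"):
            dms.build_dispersion_curve(fits, Conditions())

    def test_nonconverged_dropped(self):
        bad = PeakFit(float("nan"), float("nan"), 0, 0, 0, False, "flat")
        fits = [(1000.0, self._fit(-1.0)), (1500.0, bad), (2000.0, self._fit(-2.0))]
        assert len(dms.build_dispersion_curve(fits, Conditions())) == 2

    def test_zero_converged_is_error(self):
        bad = PeakFit(0, 0, 0, 0, 0, False)
        with pytest.raises(ValueError):
            dms.build_dispersion_curve([(1000.0, bad)], Conditions())


class TestClassifyBehavior:
    def test_strictly_decreasing_is_a(self):
        call = dms.classify_behavior(_curve([1000, 2000, 3000, 4000], [0, -2, -5, -9]))
        assert call.behavior is Behavior.A and call.turn_sv is None

    def test_strictly_increasing_is_c(self):
        call = dms.classify_behavior(_curve([1000, 2000, 3000, 4000], [0, 1, 3, 6]))
        assert call.behavior is Behavior.C

    def test_v_shape_is_b_with_turn_near_minimum(self):
        call = dms.classify_behavior(
            _curve([1000, 2000, 3000, 4000, 5000], [0, -4, -6, -3, 2])
        )
        assert call.behavior is Behavior.B
        assert 2000 < call.turn_sv < 4000

    def test_constant_curve_is_hard_sphere_limit(self):
        call = dms.classify_behavior(_curve([1000, 2000, 3000, 4000], [0.1, 0.1, 0.1, 0.1]))
        assert call.behavior is Behavior.C

    def test_wiggly_curve_is_complex(self):
        call = dms.classify_behavior(
            _curve([1, 2, 3, 4, 5, 6, 7], [0, -3, 1, -4, 2, -2, 3])
        )
        assert call.behavior is Behavior.COMPLEX

    @pytest.mark.parametrize("behavior", ["A", "B", "C"])
    def test_noiseless_generator_sweep(self, behavior, rng):
        """Every noiseless generator draw of a known type is classified as
        that type (100 draws each)."""
        for i in range(100):
            p = synthetic.sample_curve_params(behavior, rng)
            c = synthetic.simulate_dispersion(p, synthetic.DEFAULT_SV_GRID, 0.0, seed=i)
            assert dms.classify_behavior(c).behavior.value == behavior

    def test_noisy_generator_accuracy(self):
        """>= 95/100 correct type calls at 0.2 V CV noise."""
        rng = np.random.default_rng(7)
        correct = 0
        for i in range(100):
            behavior = ["A", "B", "C"][i % 3]
            p = synthetic.sample_curve_params(behavior, rng)
            c = synthetic.simulate_dispersion(p, synthetic.DEFAULT_SV_GRID, 0.2, seed=1000 + i)
            correct += dms.classify_behavior(c).behavior.value == behavior
        assert correct >= 95

    def test_complex_generator_draws_never_called_monotone(self, rng):
        for i in range(50):
            p = synthetic.sample_curve_params("complex", rng)
            c = synthetic.simulate_dispersion(p, synthetic.DEFAULT_SV_GRID, 0.0, seed=i)
            assert dms.classify_behavior(c).behavior not in (Behavior.A, Behavior.C)


class TestTurnaround:
    def test_symmetric_v_is_exact(self):
        c = _curve([1000, 2000, 3000], [-1.0, -5.0, -1.0])
        assert dms.turnaround_point(c) == pytest.approx(2000.0, abs=1e-9)

    def test_monotone_curve_has_none(self):
        assert dms.turnaround_point(_curve([1000, 2000, 3000, 4000], [0, -2, -4, -7])) is None

    def test_sampled_parabola_vertex_recovered(self):
        """Vertex between grid points recovered to 1e-6 of the closed form."""
        sv = np.arange(500.0, 4001.0, 250.0)
        vertex, a = 2310.7, 1e-5
        cv = a * (sv - vertex) ** 2 - 6.0
        t = dms.turnaround_point(_curve(sv, cv))
        assert t == pytest.approx(vertex, abs=1e-6)


class TestSeparationScore:
    def test_identical_curves_score_zero(self):
        c = _curve([1000, 2000, 3000, 4000], [0, -2, -4, -3])
        score, _ = dms.separation_score(c, c)
        assert score == 0.0

    def test_constant_offset_arithmetic(self):
        sv = [1000, 2000, 3000, 4000]
        c1 = _curve(sv, [0, -1, -2, -3])
        c2 = _curve(sv, [2, 1, 0, -1])
        score, _ = dms.separation_score(c1, c2)
        assert score == pytest.approx(2.0 / np.sqrt(2.0))

    def test_symmetry(self):
        c1 = _curve([1000, 2000, 3000, 4000], [0, -2, -4, -3])
        c2 = _curve([1500, 2500, 3500, 4500], [1, -1, -2, 0])
        s12 = dms.separation_score(c1, c2)
        s21 = dms.separation_score(c2, c1)
        assert s12 == s21

    def test_shift_above_2500_localized(self):
        sv = np.arange(500.0, 4001.0, 250.0)
        cv1 = -3.0 * sv / 4000.0
        cv2 = cv1 + np.where(sv > 2500.0, 3.0, 0.0)
        _, sv_at_max = dms.separation_score(_curve(sv, cv1), _curve(sv, cv2))
        assert sv_at_max >= 2500.0

    def test_no_overlap_is_error(self):
        c1 = _curve([1000, 1100, 1200], [0, -1, -2])
        c2 = _curve([3000, 3100, 3200], [0, 1, 2])
        with pytest.raises(ValueError):
            dms.separation_score(c1, c2)
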