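import numpy as np
import pytest
from scipy.integrate import quad

import fbpakin as fk
from fbpakin.input_function import FitError, cumulative_plasma_integral
from fbpakin.tac_data import ValidationError

GRID = np.array([0.5, 1, 3, 5, 10, 20, 30, 50], dtype=float)
TRUE = fk.BiExpParams(50.0, 10.0, 0.5, 0.02)


def make_input(values=None, interpolation="linear", times=GRID):
    v = TRUE(times) if values is None else values
    series = fk.BloodSampleSeries(times, v, v)
    biexp = fk.fit_biexponential(times, v)
    return fk.PlasmaInput(series, biexp, interpolation)


class TestParentFraction:
    cfg = fk.StudyConfig()

    @pytest.mark.parametrize(
        "t,expected",
        [
            (20.0, 0.97676),  # measured metabolite fraction 2.324%
            (50.0, 0.96034),  # measured 3.966%
            (35.0, 0.96855),  # linear interpolation midpoint
            (5.0, 0.97676),  # held constant before first measurement
            (90.0, 0.96034),  # held constant after last measurement
        ],
    )
    def test_values(self, t, expected):
        assert fk.parent_fraction(t, self.cfg) == pytest.approx(expected)

    def test_negative_time_rejected(self):
        with pytest.raises(ValidationError):
            fk.parent_fraction(-1.0, self.cfg)

    def test_correction_scales_plasma_only(self):
        s = fk.BloodSampleSeries([50.0], [80.0], [100.0])
        out = fk.correct_for_metabolites(s, self.cfg)
        assert out.plasma[0] == pytest.approx(96.034)
        assert out.whole_blood[0] == 80.0

    def test_correction_is_invertible(self):
        s = fk.BloodSampleSeries(GRID, TRUE(GRID), TRUE(GRID))
        corrected = fk.correct_for_metabolites(s, self.cfg)
        back = corrected.plasma / fk.parent_fraction(GRID, self.cfg)
        np.testing.assert_allclose(back, s.plasma, rtol=1e-14)

    def test_zero_plasma_stays_zero(self):
        s = fk.BloodSampleSeries(GRID, np.zeros_like(GRID), np.zeros_like(GRID))
        out = fk.correct_for_metabolites(s, self.cfg)
        assert np.all(out.plasma == 0)


class TestBiexpFit:
    def test_noiseless_recovery(self):
        fit = fk.fit_biexponential(GRID, TRUE(GRID))
        assert fit.a1 == pytest.approx(TRUE.a1, rel=1e-3)
        assert fit.a2 == pytest.approx(TRUE.a2, rel=1e-3)
        assert fit.lambda1 == pytest.approx(TRUE.lambda1, rel=1e-3)
        assert fit.lambda2 == pytest.approx(TRUE.lambda2, rel=1e-3)

    def test_single_exponential_limit(self):
        mono = fk.BiExpParams(50.0, 0.0, 0.5, 0.02)
        fit = fk.fit_biexponential(GRID, mono(GRID))
        # the fitted curve must reproduce the mono-exponential everywhere
        t = np.linspace(0.5, 50, 200)
        np.testing.assert_allclose(fit(t), mono(t), rtol=1e-4, atol=1e-8)

    def test_too_few_points(self):
        with pytest.raises(ValidationError):
            fk.fit_biexponential([1.0, 2.0, 3.0], [3.0, 2.0, 1.0])

    def test_fast_term_ordering_invariant(self):
        fit = fk.fit_biexponential(GRID, TRUE(GRID))
        assert fit.lambda1 >= fit.lambda2 > 0

    def test_integral_noise_robustness(self):
        """Median error of the 0-60 min input integral stays below 5% at 10% noise."""
        rng = np.random.default_rng(42)
        exact = TRUE.integral(0.0, 0.5) + 0.0  # placeholder, replaced below
        # oracle: fine trapezoid over the true curve (linear rise handled by
        # the same (0,0) anchoring used for the sampled curve)
        tt = np.concatenate([[0.0], GRID, np.arange(51, 61)])
        dense = np.linspace(0, 60, 60001)
        truth_curve = np.interp(dense, np.concatenate([[0.0], GRID]),
                                np.concatenate([[0.0], TRUE(GRID)]))
        tail = dense > 50
        truth_curve[tail] = TRUE(dense[tail])
        exact = np.trapezoid(truth_curve, dense)
        errors = []
        for _ in range(200):
            noisy = TRUE(GRID) * (1.0 + 0.1 * rng.standard_normal(GRID.size))
            noisy = np.clip(noisy, 1e-6, None)
            try:
                pin = make_input(noisy)
            except (FitError, ValidationError):
                continue
            est = cumulative_plasma_integral(pin, 60.0)
            errors.append(abs(est - exact) / exact)
        assert np.median(errors) < 0.05


class TestEvaluatePlasma:
    def test_sample_values_reproduced_linear_mode(self):
        pin = make_input()
        np.testing.assert_allclose(
            fk.evaluate_plasma(pin, GRID), TRUE(GRID), rtol=1e-12)

    def test_zero_at_origin(self):
        pin = make_input()
        assert fk.evaluate_plasma(pin, 0.0) == 0.0

    @pytest.mark.parametrize("mode", ["linear", "model"])
    def test_continuous_and_nonnegative(self, mode):
        pin = make_input(interpolation=mode)
        t = np.linspace(0, 130, 2601)
        v = fk.evaluate_plasma(pin, t)
        assert np.all(v >= 0)
        # no jump larger than the local slope allows
        assert np.max(np.abs(np.diff(v))) < 5.0

    def test_monotone_decreasing_extrapolation(self):
        pin = make_input()
        t = np.linspace(50, 200, 500)
        v = fk.evaluate_plasma(pin, t)
        assert np.all(np.diff(v) <= 1e-12)

    def test_extrapolated_value_closed_form(self):
        # last sample at 50 min; value at 120 min follows the fitted model
        pin = make_input()
        scale = TRUE(50.0) / pin.biexp(50.0)
        expected = scale * pin.biexp(120.0)
        assert fk.evaluate_plasma(pin, 120.0) == pytest.approx(expected, rel=1e-12)
        # for the exact-sample fit this is the true curve value ~0.907
        assert expected == pytest.approx(10 * np.exp(-0.02 * 120) + 50 * np.exp(-0.5 * 120),
                                         rel=1e-3)

    def test_model_mode_matches_true_curve(self):
        pin = make_input(interpolation="model")
        t = np.linspace(0.5, 120, 400)
        np.testing.assert_allclose(fk.evaluate_plasma(pin, t), TRUE(t), rtol=1e-3)


class TestPlasmaIntegral:
    @pytest.mark.parametrize("mode", ["linear", "model"])
    def test_against_quadrature(self, mode):
        pin = make_input(interpolation=mode)
        for T in (3.0, 27.0, 50.0, 90.0):
            oracle = quad(lambda s: fk.evaluate_plasma(pin, s), 0, T,
                          points=list(GRID[GRID < T]), limit=300)[0]
            est = cumulative_plasma_integral(pin, T)
            assert est == pytest.approx(oracle, rel=1e-7)

    def test_running_integral_is_monotone(self):
        pin = make_input()
        t = np.linspace(0, 150, 500)
        cum = cumulative_plasma_integral(pin, t)
        assert np.all(np.diff(cum) >= 0)
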