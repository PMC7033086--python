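import numpy as np
import pytest

import fbpakin as fk
from fbpakin.graphical import SingularDesignError, frame_cumulative_integral
from fbpakin.simulate import plasma_concentration, tissue_concentration
from fbpakin.tac_data import ValidationError

RATES_1T = fk.RateConstants(0.1, 0.2)  # Vt = 0.5
RATES_2T = fk.RateConstants(0.1, 0.15, 0.05, 0.1)  # Vt = 1.0


def fine_1t_data(dt=0.005, t_end=60.0):
    """Pointwise-sampled 1-tissue data where the graphical relations are exact."""
    starts = np.arange(0.0, t_end, dt)
    sched = fk.FrameSchedule(starts, np.full(starts.size, dt))
    tac = fk.TissueTAC("fine", sched, tissue_concentration(RATES_1T, sched.midpoints))
    ts = np.arange(dt, t_end + 2.0, dt)
    cp = plasma_concentration(ts)
    series = fk.BloodSampleSeries(ts, cp, cp)
    biexp = fk.BiExpParams(60.0 * np.exp(0.3 * 0.5), 9.293 * np.exp(0.0149 * 0.5),
                           0.30, 0.0149, 0.5)
    return tac, fk.PlasmaInput(series, biexp, "linear")


class TestCumulativeIntegral:
    def test_constant_curve(self):
        np.testing.assert_allclose(
            fk.cumulative_integral([1.0, 2.0, 3.0], [1.0, 1.0, 1.0]),
            [0.5, 1.5, 2.5])

    def test_linear_curve_exact(self):
        np.testing.assert_allclose(
            fk.cumulative_integral([1.0, 2.0], [1.0, 2.0]), [0.5, 2.0])

    def test_exponential_against_analytic(self):
        t = np.arange(0.0, 5.0001, 0.01)
        cum = fk.cumulative_integral(t, np.exp(-t))
        assert cum[-1] == pytest.approx(1 - np.exp(-5), abs=1e-4)

    def test_unsorted_times_rejected(self):
        with pytest.raises(ValidationError):
            fk.cumulative_integral([1.0, 0.5], [1.0, 1.0])

    def test_frame_aware_integral_beats_midpoint_trapezoid(self, schedule):
        """Frame-duration weighting recovers the true integral of a frame-averaged TAC."""
        tac = fk.simulate_tissue_tac(RATES_2T, schedule, voi_name="x")
        from scipy.integrate import quad
        exact = quad(lambda s: tissue_concentration(RATES_2T, s), 0,
                     schedule.midpoints[-1], limit=200)[0]
        aware = frame_cumulative_integral(tac)[-1]
        naive = fk.cumulative_integral(tac.times, tac.activity)[-1]
        assert abs(aware - exact) < abs(naive - exact)
        assert aware == pytest.approx(exact, rel=0.01)


class TestVtFromRates:
    def test_one_tissue(self):
        assert fk.vt_from_rates(RATES_1T) == pytest.approx(0.5)

    def test_two_tissue(self):
        assert fk.vt_from_rates(RATES_2T) == pytest.approx(1.0)

    def test_fast_k4_limit(self):
        r = fk.RateConstants(0.1, 0.2, 0.05, 1e6)
        assert fk.vt_from_rates(r) == pytest.approx(0.5, rel=1e-6)

    def test_k2_zero_rejected(self):
        with pytest.raises(ValidationError):
            fk.RateConstants(0.1, 0.0)

    def test_irreversible_trapping_rejected(self):
        with pytest.raises(ValidationError):
            fk.RateConstants(0.1, 0.2, 0.05, 0.0)


class TestNoiselessRecovery:
    """All three estimators recover the closed-form Vt on noiseless data."""

    @pytest.mark.parametrize("rates,vt", [(RATES_1T, 0.5), (RATES_2T, 1.0)])
    def test_all_models_within_3pct(self, rates, vt, schedule, plasma_input):
        tac = fk.simulate_tissue_tac(rates, schedule, voi_name="sim")
        logan = fk.find_t_star(tac, plasma_input, "logan").fit
        ma1 = fk.find_t_star(tac, plasma_input, "ma1").fit
        ma2 = fk.fit_ma2(tac, plasma_input, 20.0)
        for fit in (logan, ma1, ma2):
            assert fit.vt == pytest.approx(vt, rel=0.03), fit.model

    def test_one_tissue_within_2pct(self, schedule, plasma_input):
        tac = fk.simulate_tissue_tac(RATES_1T, schedule, voi_name="sim")
        assert fk.fit_logan(tac, plasma_input, 20.0).vt == pytest.approx(0.5, rel=0.02)
        assert fk.fit_ma1(tac, plasma_input, 20.0).vt == pytest.approx(0.5, rel=0.02)
        assert fk.fit_ma2(tac, plasma_input, 20.0).vt == pytest.approx(0.5, rel=0.02)

    def test_fixture_organs_recovered(self, noiseless_study, plasma_input):
        truth = noiseless_study.truth.set_index("organ")["true_vt"]
        for name, tac in noiseless_study.tacs.items():
            rates = fk.DEFAULT_ORGANS[name]
            if rates.k4 < 0.05:  # slow-equilibration organs are exempt
                continue
            for fit in (
                fk.find_t_star(tac, plasma_input, "logan").fit,
                fk.find_t_star(tac, plasma_input, "ma1").fit,
                fk.fit_ma2(tac, plasma_input, 20.0),
            ):
                assert fit.vt == pytest.approx(truth[name], rel=0.03), (name, fit.model)

    def test_ma2_gamma4_estimates_k1(self, schedule, plasma_input):
        tac = fk.simulate_tissue_tac(RATES_2T, schedule, voi_name="sim")
        fit = fk.fit_ma2(tac, plasma_input, 20.0)
        assert fit.k1_estimate == pytest.approx(RATES_2T.K1, rel=0.05)

    def test_logan_ma1_equivalent_when_exact(self):
        """On exactly linear data the two rearrangements give one slope."""
        tac, pin = fine_1t_data()
        logan = fk.fit_logan(tac, pin, 20.0)
        ma1 = fk.fit_ma1(tac, pin, 20.0)
        assert logan.vt == pytest.approx(ma1.vt, rel=1e-6)
        assert logan.vt == pytest.approx(0.5, rel=1e-3)


class TestDegenerateInputs:
    def test_identity_guard(self, schedule, plasma_input):
        cp = fk.evaluate_plasma(plasma_input, schedule.midpoints)
        tac = fk.TissueTAC("plasma-like", schedule, cp)
        for fitter in (fk.fit_logan, fk.fit_ma1):
            fit = fitter(tac, plasma_input, 20.0)
            assert fit.vt == 1.0
            assert fit.intercept == 0.0
            assert "identity-input" in fit.warnings

    def test_zero_tissue_curve(self, schedule, plasma_input):
        tac = fk.TissueTAC("empty", schedule, np.zeros(schedule.n_frames))
        with pytest.raises((SingularDesignError, ValidationError)):
            fk.fit_ma2(tac, plasma_input, 20.0)

    def test_logan_zero_activity_names_frame(self, schedule, plasma_input):
        act = np.ones(schedule.n_frames)
        act[-1] = 0.0
        tac = fk.TissueTAC("bad", schedule, act)
        with pytest.raises(ValidationError, match="frame"):
            fk.fit_logan(tac, plasma_input, 20.0)

    def test_too_few_frames_after_tstar(self, schedule, plasma_input):
        tac = fk.simulate_tissue_tac(RATES_1T, schedule)
        with pytest.raises(ValidationError):
            fk.fit_logan(tac, plasma_input, 50.0)


class TestInvariances:
    @pytest.mark.parametrize("scale", [1e-3, 1.0, 1000.0])
    def test_vt_invariant_to_common_rescaling(self, scale, schedule, plasma_input):
        """Rescaling C and Cp together (e.g. kBq -> Bq) leaves Vt unchanged."""
        tac = fk.simulate_tissue_tac(RATES_2T, schedule, voi_name="sim")
        ref = fk.fit_ma2(tac, plasma_input, 20.0).vt
        s = plasma_input.samples
        scaled_series = fk.BloodSampleSeries(
            s.sample_times, s.whole_blood * scale, s.plasma * scale)
        scaled_pin = fk.PlasmaInput(
            scaled_series,
            fk.BiExpParams(plasma_input.biexp.a1 * scale, plasma_input.biexp.a2 * scale,
                           plasma_input.biexp.lambda1, plasma_input.biexp.lambda2,
                           plasma_input.biexp.t_fit_start),
            plasma_input.interpolation)
        scaled_tac = fk.TissueTAC("sim", schedule, tac.activity * scale)
        for fitter in (fk.fit_logan, fk.fit_ma1):
            assert fitter(scaled_tac, scaled_pin, 20.0).vt == pytest.approx(
                fitter(tac, plasma_input, 20.0).vt, rel=1e-9)
        assert fk.fit_ma2(scaled_tac, scaled_pin, 20.0).vt == pytest.approx(ref, rel=1e-9)


class TestTStarSearch:
    def test_exactly_linear_data_gives_earliest_midpoint(self):
        """For one-tissue kinetics the Logan relation is exact at all times,
        so the 1% search accepts the first candidate."""
        tac, pin = fine_1t_data()
        res = fk.find_t_star(tac, pin, "logan")
        assert res.converged
        # convergence is essentially immediate: within the bolus rise,
        # long before the first whole-body frame midpoint (3.79 min)
        assert res.t_star < 0.1

    def test_frame_averaged_one_tissue_converges_early(self, schedule, plasma_input):
        tac = fk.simulate_tissue_tac(RATES_1T, schedule)
        res = fk.find_t_star(tac, plasma_input, "logan")
        assert res.converged
        # frame-averaging distorts only the earliest whole-body frames
        assert res.t_star <= schedule.midpoints[1]

    def test_slow_equilibration_delays_t_star(self, schedule, plasma_input):
        slow = fk.RateConstants(0.1, 0.15, 0.05, 0.02)
        fast = fk.RateConstants(0.1, 0.15, 0.05, 0.2)
        t_slow = fk.find_t_star(
            fk.simulate_tissue_tac(slow, schedule), plasma_input, "logan").t_star
        t_fast = fk.find_t_star(
            fk.simulate_tissue_tac(fast, schedule), plasma_input, "logan").t_star
        assert t_slow > t_fast

    def test_unattainable_tolerance_flags_not_converged(self, schedule, plasma_input):
        rng = np.random.default_rng(7)
        tac = fk.simulate_tissue_tac(RATES_2T, schedule, noise_cv=0.05, rng=rng)
        res = fk.find_t_star(tac, plasma_input, "logan", max_rel_error=0.0)
        assert not res.converged
        # latest feasible t* still leaves the minimum 3 points
        assert res.fit.n_points_used == 3

    def test_ma2_has_no_auto_search(self, schedule, plasma_input):
        tac = fk.simulate_tissue_tac(RATES_1T, schedule)
        with pytest.raises(ValidationError):
            fk.find_t_star(tac, plasma_input, "ma2")
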