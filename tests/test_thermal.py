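import numpy as np
import pytest

import phenoshift as ps
from phenoshift.calendar import SEP1_PREV_OFFSET, covariate_matrix
from phenoshift.thermal import (
    UniChillParams,
    UniForcParams,
    chilling_rate,
    forcing_rate,
    predict_event_day,
    predict_event_days,
    rmse_objective,
)


class TestForcingRate:
    def test_half_at_midpoint(self):
        assert forcing_rate(10.0, -1.0, 10.0) == pytest.approx(0.5)

    def test_closed_form_value(self):
        # b_f=-1: R_f(c_f + ln 3) = 1/(1 + 1/3) = 0.75
        assert forcing_rate(10.0 + np.log(3), -1.0, 10.0) == pytest.approx(0.75)

    def test_monotone_increasing(self):
        assert forcing_rate(6.0, -0.5, 8.0) < forcing_rate(12.0, -0.5, 8.0)
        x = np.linspace(-20, 40, 200)
        r = forcing_rate(x, -0.5, 8.0)
        assert np.all(np.diff(r) > 0)
        assert np.all((r > 0) & (r < 1))

    def test_nonnegative_slope_rejected(self):
        with pytest.raises(ValueError, match="b_f"):
            forcing_rate(10.0, 0.5, 10.0)


class TestChillingRate:
    def test_half_at_midpoint(self):
        assert chilling_rate(5.0, 0.3, 0.2, 5.0) == pytest.approx(0.5)

    def test_closed_form_logistic_limit(self):
        # a_c=0, b_c=1: R_c(c_c + ln 9) = 1/(1+9) = 0.1
        assert chilling_rate(5.0 + np.log(9), 0.0, 1.0, 5.0) == pytest.approx(0.1)

    def test_bell_shape_decays_at_extremes(self):
        # a_c=0.1, b_c=0, |x - c_c| = 20 -> exponent 40, rate essentially 0
        assert chilling_rate(25.0, 0.1, 0.0, 5.0) < 0.02
        assert chilling_rate(-15.0, 0.1, 0.0, 5.0) < 0.02


class TestPredictEventDay:
    def test_constant_rate_crossing(self, constant_rate_setup):
        X, offsets = constant_rate_setup
        p = UniForcParams(t1=60, b_f=-1.0, c_f=10.0, F_star=5.0)
        assert predict_event_day(p, X, offsets) == pytest.approx(69.0)

    def test_interpolation_midpoint(self, constant_rate_setup):
        X, offsets = constant_rate_setup
        p = UniForcParams(t1=60, b_f=-1.0, c_f=10.0, F_star=4.75)
        assert predict_event_day(p, X, offsets) == pytest.approx(68.5)

    def test_unreachable_threshold_is_no_event(self, constant_rate_setup):
        X, offsets = constant_rate_setup
        p = UniForcParams(t1=60, b_f=-1.0, c_f=10.0, F_star=1e6)
        assert np.isnan(predict_event_day(p, X, offsets))

    def test_continuous_in_t1(self, constant_rate_setup):
        X, offsets = constant_rate_setup
        days = [
            predict_event_day(
                UniForcParams(t1=t, b_f=-1.0, c_f=10.0, F_star=5.0), X, offsets
            )
            for t in np.linspace(59.0, 61.0, 21)
        ]
        assert np.max(np.abs(np.diff(days))) < 0.2  # no jumps

    def test_interpolated_day_within_discrete_day(self, climate_temps, uniforc_truth):
        years = list(range(1801, 1861))
        X, offs = covariate_matrix(climate_temps, years, 0, 250)
        cont = predict_event_days(uniforc_truth, X, offs)
        # discrete threshold day: first day the running sum reaches F*
        from phenoshift.thermal import forcing_rate as fr

        R = fr(X, uniforc_truth.b_f, uniforc_truth.c_f)
        R[:, offs < uniforc_truth.t1] = 0.0
        S = np.cumsum(R, axis=1)
        tb = offs[np.argmax(S >= uniforc_truth.F_star, axis=1)]
        assert np.all(cont > tb - 1) and np.all(cont <= tb)
        assert np.all(np.abs(cont - tb) < 1)

    def test_warming_never_delays_uniforc(self, climate_temps, uniforc_truth):
        years = list(range(1801, 1831))
        X, offs = covariate_matrix(climate_temps, years, 0, 250)
        prev = predict_event_days(uniforc_truth, X, offs)
        for delta in (0.5, 1.0, 2.0, 4.0):
            cur = predict_event_days(uniforc_truth, X + delta, offs)
            assert np.all(cur <= prev + 1e-9)
            prev = cur

    def test_chilling_completion_never_advances_under_warming(self, climate_temps):
        # with a_c >= 0 and b_c > 0, warmth slows chilling accumulation
        p = UniChillParams(
            t0=SEP1_PREV_OFFSET, a_c=0.0, b_c=1.0, c_c=5.0, C_star=15.0,
            b_f=-0.5, c_f=9.0, F_star=1e9,  # forcing never completes
        )
        years = list(range(1801, 1821))
        X, offs = covariate_matrix(climate_temps, years, SEP1_PREV_OFFSET, 250)

        def completion(Xm):
            from phenoshift.thermal import chilling_rate as cr

            R = cr(Xm, p.a_c, p.b_c, p.c_c)
            S = np.cumsum(R, axis=1)
            reached = S[:, -1] >= p.C_star
            j = np.argmax(S >= p.C_star, axis=1)
            return np.where(reached, offs[j].astype(float), np.inf)

        base = completion(X)
        for delta in (0.5, 1.0, 2.0):
            assert np.all(completion(X + delta) >= base)

    def test_unichill_no_event_when_chilling_unmet(self, climate_temps):
        p = UniChillParams(
            t0=SEP1_PREV_OFFSET, a_c=0.0, b_c=1.0, c_c=5.0, C_star=1e6,
            b_f=-0.5, c_f=9.0, F_star=5.0,
        )
        years = list(range(1801, 1806))
        X, offs = covariate_matrix(climate_temps, years, SEP1_PREV_OFFSET, 250)
        assert np.all(np.isnan(predict_event_days(p, X, offs)))

    def test_coverage_gap_is_error(self, uniforc_truth):
        X = np.full((1, 50), 10.0)
        X[0, 30] = np.nan
        with pytest.raises(ValueError, match="missing"):
            predict_event_days(uniforc_truth, X, np.arange(10, 60))


class TestParameterValidation:
    def test_uniforc_sign_constraints(self):
        with pytest.raises(ValueError):
            UniForcParams(t1=20, b_f=0.3, c_f=10.0, F_star=30.0)
        with pytest.raises(ValueError):
            UniForcParams(t1=20, b_f=-0.3, c_f=-1.0, F_star=30.0)
        with pytest.raises(ValueError):
            UniForcParams(t1=20, b_f=-0.3, c_f=10.0, F_star=0.0)

    def test_unichill_t0_restricted(self):
        with pytest.raises(ValueError, match="t0"):
            UniChillParams(
                t0=-100, a_c=0.0, b_c=1.0, c_c=5.0, C_star=40.0,
                b_f=-0.5, c_f=9.0, F_star=18.0,
            )

    def test_free_parameter_counts(self):
        assert ps.UniForcParams.n_free == 4
        assert ps.UniChillParams.n_free == 7


class TestRmseObjective:
    def test_perfect_predictions(self, constant_rate_setup):
        X, offsets = constant_rate_setup
        p = UniForcParams(t1=60, b_f=-1.0, c_f=10.0, F_star=5.0)
        assert rmse_objective(p, X, offsets, np.array([69.0])) == pytest.approx(0.0)

    def test_constant_residual(self, constant_rate_setup):
        X, offsets = constant_rate_setup
        X2 = np.vstack([X, X])
        p = UniForcParams(t1=60, b_f=-1.0, c_f=10.0, F_star=5.0)
        obs = np.array([67.0, 71.0])  # residuals +2, -2
        assert rmse_objective(p, X2, offsets, obs) == pytest.approx(2.0)

    def test_matches_generating_noise(self, climate_temps, uniforc_truth):
        years = list(range(1801, 1930))
        ev = ps.simulate_events_mechanistic(
            climate_temps, uniforc_truth, years, noise_sd=2.0, seed=13
        )
        X, offs = covariate_matrix(climate_temps, ev.years, 0, 250)
        r = rmse_objective(uniforc_truth, X, offs, ev.days)
        assert r == pytest.approx(2.0, abs=0.35)

    def test_empty_observations_rejected(self, constant_rate_setup):
        X, offsets = constant_rate_setup
        p = UniForcParams(t1=60, b_f=-1.0, c_f=10.0, F_star=5.0)
        with pytest.raises(ValueError, match="no observed"):
            rmse_objective(p, X[:0], offsets, np.array([]))
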