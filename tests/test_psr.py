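import numpy as np
import pytest

import phenoshift as ps
from phenoshift.calendar import covariate_matrix
from phenoshift.psr import bspline_basis, difference_matrix, fit_psr, psr_aic


@pytest.fixture(scope="module")
def bump_events(climate_temps):
    """Events driven by a smooth Gaussian-bump daily coefficient curve.

    alpha(d) peaks at -0.3 day per degC-day over offsets 60-100; the response
    is intercept + sum_d alpha(d) x(d) + noise.
    """
    years = list(range(1801, 1930))
    X, offs = covariate_matrix(climate_temps, years, -213, 140)
    alpha = -0.3 * np.exp(-0.5 * ((offs - 80) / 10.0) ** 2)
    rng = np.random.default_rng(17)
    y = 130.0 + X @ alpha + rng.normal(0, 2.0, len(years))
    ev = ps.PhenologySeries(
        "bump", {yr: int(np.rint(d)) for yr, d in zip(years, y)}
    )
    return ev, offs, alpha


class TestPsrAic:
    def test_closed_form(self):
        # n=100, RSS=100, edf=6: 100 ln(1) + 2*(6+1) = 14
        assert psr_aic(100, 100.0, 6.0) == pytest.approx(14.0)


class TestFitPsr:
    def test_lambda_zero_matches_direct_least_squares(self, climate_temps):
        """Unpenalised PSR equals the normal-equation solve on the projected basis."""
        ev = ps.simulate_events_linear(
            climate_temps, range(1801, 1930), [(-50, 10)], [-6.0], 120.0, 2.0, seed=2
        )
        fit = fit_psr(climate_temps, ev, knot_spacing=40.0, lam=0.0)
        X, offs = covariate_matrix(climate_temps, ev.years, -213, ev.last_event_day)
        B = bspline_basis(offs, knot_spacing=40.0)
        U = np.column_stack([np.ones(len(ev)), X @ B])
        beta, _, _, _ = np.linalg.lstsq(U, ev.days, rcond=None)
        np.testing.assert_allclose(fit.fitted, U @ beta, atol=1e-6)
        assert fit.edf == pytest.approx(U.shape[1], abs=1e-6)

    def test_lambda_zero_with_oversized_basis_rejected(self, toy_temps):
        ev = ps.simulate_events_linear(
            toy_temps, range(1901, 1921), [(-30, 10)], [-4.0], 115.0, 2.0, seed=3
        )
        with pytest.raises(ValueError, match="singular"):
            fit_psr(toy_temps, ev, knot_spacing=4.0, lam=0.0)

    def test_infinite_smoothing_linearises_curve(self, climate_temps):
        """Order-2 penalty: lambda -> inf drives alpha(d) into its null space
        (a straight line) and edf toward the null-space dimension."""
        ev = ps.simulate_events_linear(
            climate_temps, range(1801, 1930), [(-50, 10)], [-6.0], 120.0, 2.0, seed=2
        )
        fit = fit_psr(climate_temps, ev, lam=1e12)
        # the coefficient curve collapses onto its least-squares line (the
        # penalty null space maps to a line through the Greville abscissae,
        # so tiny boundary deviations from exact straightness remain)
        slope, icpt = np.polyfit(fit.offsets, fit.coef, 1)
        line = icpt + slope * fit.offsets
        assert np.max(np.abs(fit.coef - line)) < 0.02 * np.abs(fit.coef).max()
        interior = np.diff(fit.coef, n=2)[5:-5]
        assert np.max(np.abs(interior)) < 1e-4
        # intercept + the 2-dim penalty null space ~ 3 effective dof
        assert fit.edf == pytest.approx(3.0, abs=0.1)

    def test_edf_monotone_in_lambda(self, climate_temps):
        ev = ps.simulate_events_linear(
            climate_temps, range(1801, 1930), [(-50, 10)], [-6.0], 120.0, 2.0, seed=2
        )
        edfs = [
            fit_psr(climate_temps, ev, lam=L).edf
            for L in (1e-2, 1e0, 1e2, 1e4, 1e6)
        ]
        assert all(a >= b - 1e-8 for a, b in zip(edfs, edfs[1:]))

    def test_bump_recovery(self, climate_temps, bump_events):
        ev, gen_offs, alpha = bump_events
        fit = fit_psr(climate_temps, ev)
        # align the generator curve onto the fitted span
        lo = np.searchsorted(gen_offs, fit.offsets[0])
        truth = alpha[lo : lo + len(fit.offsets)]
        peak_fit = fit.offsets[np.argmin(fit.coef)]
        assert abs(peak_fit - 80) <= 10
        ise = np.trapezoid((fit.coef - truth) ** 2, fit.offsets)
        ise_null = np.trapezoid(truth**2, fit.offsets)
        assert ise < 0.25 * ise_null
        assert fit.coef[np.argmin(np.abs(fit.offsets - 80))] < -0.15

    def test_sign_pattern_recovery(self, climate_temps):
        """Negative spring and positive autumn coefficients are recovered with
        the right signs over their supports (forcing vs chilling signature)."""
        years = list(range(1801, 1930))
        X, offs = covariate_matrix(climate_temps, years, -213, 140)
        alpha = (
            -0.25 * np.exp(-0.5 * ((offs - 70) / 12.0) ** 2)   # spring forcing
            + 0.15 * np.exp(-0.5 * ((offs + 90) / 15.0) ** 2)  # autumn chilling
        )
        rng = np.random.default_rng(23)
        y = 125.0 + X @ alpha + rng.normal(0, 2.0, len(years))
        ev = ps.PhenologySeries(
            "two-sign", {yr: int(np.rint(d)) for yr, d in zip(years, y)}
        )
        fit = fit_psr(climate_temps, ev)
        spring = (fit.offsets > 55) & (fit.offsets < 85)
        autumn = (fit.offsets > -105) & (fit.offsets < -75)
        assert fit.coef[spring].mean() < 0
        assert fit.coef[autumn].mean() > 0

    def test_intercept_absorbs_temperature_shift(self, climate_temps):
        ev = ps.simulate_events_linear(
            climate_temps, range(1801, 1930), [(-50, 10)], [-6.0], 120.0, 2.0, seed=2
        )
        fit = fit_psr(climate_temps, ev, lam=10.0)
        shifted = ps.DailyTemperatureSeries(climate_temps.data + 1.0)
        fit2 = fit_psr(shifted, ev, lam=10.0)
        np.testing.assert_allclose(fit.fitted, fit2.fitted, atol=1e-6)
        np.testing.assert_allclose(fit.coef, fit2.coef, atol=1e-6)
        shift = fit.intercept - fit2.intercept
        assert shift == pytest.approx(np.sum(fit.coef), abs=1e-4)

    def test_ci_halfwidths_nonnegative_and_curve_spans_covariates(
        self, climate_temps, bump_events
    ):
        ev, _, _ = bump_events
        fit = fit_psr(climate_temps, ev)
        assert np.all(fit.ci_halfwidth >= 0)
        assert len(fit.coef) == len(fit.offsets)
        assert fit.offsets[0] == -213 and fit.offsets[-1] == ev.last_event_day

    def test_white_noise_response_aic_close_to_null(self, climate_temps):
        rng = np.random.default_rng(37)
        years = range(1801, 1930)
        ev = ps.PhenologySeries(
            "noise", {y: int(d) for y, d in zip(years, rng.normal(110, 8, 129))}
        )
        fit = fit_psr(climate_temps, ev)
        null = ps.null_model_aic(ev)
        # GCV shrinks toward heavy smoothing; PSR should not claim strong
        # support over the null for a structureless response
        assert fit.aic > null - 10.0


class TestBasisAndPenalty:
    def test_difference_matrix_order2(self):
        D = difference_matrix(5, 2)
        assert D.shape == (3, 5)
        np.testing.assert_array_equal(D[0], [1, -2, 1, 0, 0])

    def test_basis_partition_of_unity(self):
        offs = np.arange(-50, 51)
        B = bspline_basis(offs)
        np.testing.assert_allclose(B.sum(axis=1), 1.0, atol=1e-10)
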