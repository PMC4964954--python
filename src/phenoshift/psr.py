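"""Penalised B-spline signal regression (PSR) on daily temperatures.

The event day y_i is regressed on the whole daily-temperature vector x_i(d)
over the covariate span (1 June of the preceding year up to the species'
latest event day).  The coefficient-per-day curve alpha(d) is expanded in a
cubic B-spline basis, alpha = B theta, and roughness is controlled by
penalising d-th order differences of the basis coefficients:

    min_theta ||y - beta0 - X B theta||^2 + lambda ||D_d theta||^2.

The smoothing parameter lambda is chosen by generalised cross-validation,
model complexity is reported as the effective degrees of freedom
edf = tr(hat matrix), and pointwise approximate 95% confidence intervals on
alpha(d) come from the Bayesian posterior covariance of the penalised fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

from .calendar import (
    JUN1_PREV_OFFSET,
    DailyTemperatureSeries,
    PhenologySeries,
    covariate_matrix,
)
from .windows import regression_aic

__all__ = ["PSRFit", "fit_psr", "psr_aic", "bspline_basis", "difference_matrix"]


def bspline_basis(offsets: np.ndarray, knot_spacing: float = 4.0,
                  degree: int = 3) -> np.ndarray:
    """Cubic B-spline design matrix over a day-offset grid.

    Interior knots are placed every ``knot_spacing`` days across the span,
    with the usual degree-fold boundary-knot repetition.
    """
    offsets = np.asarray(offsets, dtype=float)
    lo, hi = offsets[0], offsets[-1]
    n_int = max(int(np.floor((hi - lo) / knot_spacing)) - 1, 1)
    interior = np.linspace(lo, hi, n_int + 2)[1:-1]
    knots = np.concatenate(
        [np.full(degree + 1, lo), interior, np.full(degree + 1, hi)]
    )
    return BSpline.design_matrix(offsets, knots, degree).toarray()


def difference_matrix(size: int, order: int = 2) -> np.ndarray:
    """d-th order difference operator D_d with shape (size - d, size)."""
    return np.diff(np.eye(size), n=order, axis=0)


@dataclass
class PSRFit:
    offsets: np.ndarray          # day-index grid of the covariate span
    coef: np.ndarray             # alpha(d): days of change per degC per day
    ci_halfwidth: np.ndarray     # pointwise 95% CI half-widths on alpha(d)
    intercept: float
    lam: float                   # selected smoothing parameter
    edf: float                   # trace of the hat matrix
    r2: float
    rss: float
    n: int
    gcv: float
    basis_size: int
    penalty_order: int
    fitted: np.ndarray
    aic: float = field(init=False)

    def __post_init__(self):
        self.aic = psr_aic(self.n, self.rss, self.edf)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.intercept + np.atleast_2d(X) @ self.coef


def psr_aic(n: int, rss: float, edf: float) -> float:
    """AIC with the effective degrees of freedom in place of k (shared
    Gaussian-ML convention: n ln(RSS/n) + 2(edf + 1))."""
    return regression_aic(n, rss, edf)


def _solve_penalised(U, y, P, lam):
    """Solve (U'U + lam P) b = U'y; return coefficients and edf."""
    A = U.T @ U + lam * P
    try:
        Ainv = np.linalg.inv(A)
    except np.linalg.LinAlgError:
        Ainv = np.linalg.pinv(A)
    b = Ainv @ (U.T @ y)
    edf = float(np.trace(U @ Ainv @ U.T))
    return b, Ainv, edf


def fit_psr(
    temps: DailyTemperatureSeries,
    events: PhenologySeries,
    start_offset: int = JUN1_PREV_OFFSET,
    knot_spacing: float = 4.0,
    degree: int = 3,
    penalty_order: int = 2,
    lam: float | None = None,
    lam_grid: np.ndarray | None = None,
) -> PSRFit:
    """Fit the signal regression; lambda from GCV unless given explicitly.

    With ``lam=0`` and more basis functions than years the normal equations
    are singular; a positive lambda (or a smaller basis) is then required.
    """
    years = events.years
    y = events.days
    n = len(y)
    X, offsets = covariate_matrix(temps, years, start_offset, events.last_event_day)
    B = bspline_basis(offsets, knot_spacing, degree)
    nb = B.shape[1]
    if n < nb / 2:
        import warnings

        warnings.warn(
            f"only {n} years for {nb} basis functions; fit may be unstable",
            stacklevel=2,
        )
    # design on basis-projected covariates, intercept unpenalised
    U = np.column_stack([np.ones(n), X @ B])
    D = difference_matrix(nb, penalty_order)
    P = np.zeros((nb + 1, nb + 1))
    P[1:, 1:] = D.T @ D

    if lam is None:
        if lam_grid is None:
            lam_grid = np.logspace(-2, 8, 41)
        best = None
        for L in lam_grid:
            b, Ainv, edf = _solve_penalised(U, y, P, L)
            resid = y - U @ b
            rss = float(resid @ resid)
            denom = max(n - edf, 1e-8)
            gcv = n * rss / denom**2
            if best is None or gcv < best[0]:
                best = (gcv, L, b, Ainv, edf, rss)
        gcv, lam, b, Ainv, edf, rss = best
    else:
        if lam == 0 and nb + 1 > n:
            raise ValueError(
                "lambda = 0 with more basis functions than years is singular; "
                "use lambda > 0 or a coarser basis"
            )
        b, Ainv, edf = _solve_penalised(U, y, P, lam)
        resid = y - U @ b
        rss = float(resid @ resid)
        gcv = n * rss / max(n - edf, 1e-8) ** 2

    fitted = U @ b
    syy = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / syy if syy > 0 else np.nan
    coef = B @ b[1:]

    # Bayesian posterior covariance of the penalised fit -> pointwise CIs
    sigma2 = rss / max(n - edf, 1e-8)
    Vb = sigma2 * Ainv  # Bayesian posterior covariance of the penalised fit
    var_alpha = np.einsum("ij,jk,ik->i", B, Vb[1:, 1:], B)
    ci = 1.96 * np.sqrt(np.maximum(var_alpha, 0.0))

    return PSRFit(
        offsets=offsets,
        coef=coef,
        ci_halfwidth=ci,
        intercept=float(b[0]),
        lam=float(lam),
        edf=edf,
        r2=float(r2),
        rss=rss,
        n=n,
        gcv=float(gcv),
        basis_size=nb,
        penalty_order=penalty_order,
        fitted=fitted,
    )
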