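"""Single and double sliding time-window regression.

The scan regresses annual event day on the mean temperature within every
candidate window of consecutive days — starts from 1 June of the preceding
year, durations 2-120 days (10-120 for the second window of the double
model), windows ending no later than the species' latest observed event —
and keeps the window(s) maximising R^2.

AIC convention (shared with every other model family in the package): a
Gaussian likelihood with the ML variance estimate gives

    AIC = n * ln(RSS / n) + 2 * (k + 1),

where k counts the structural parameters and the +1 is the residual
variance.  The searched window start and duration count as parameters, so
k = 4 for the single-window model (intercept, slope, start, duration),
k = 7 for the double, and k = 1 for the intercept-only null model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calendar import (
    JUN1_PREV_OFFSET,
    DailyTemperatureSeries,
    PhenologySeries,
    covariate_matrix,
)

__all__ = [
    "WindowSpec",
    "WindowFit",
    "scan_single_window",
    "scan_double_window",
    "regression_aic",
    "null_model_aic",
    "akaike_weights",
]


@dataclass(frozen=True)
class WindowSpec:
    start: int      # day-index offset of the first day (inclusive)
    duration: int   # number of days (both endpoints included)

    @property
    def end(self) -> int:
        return self.start + self.duration - 1


@dataclass
class WindowFit:
    windows: list[WindowSpec]
    intercept: float
    slopes: list[float]          # days per degC, one per window
    r2: float
    rss: float
    n: int
    k: int
    aic: float = field(init=False)
    overlapping: bool = False    # double model: second window overlaps first

    def __post_init__(self):
        self.aic = regression_aic(self.n, self.rss, self.k)

    def predict(self, window_means: np.ndarray) -> np.ndarray:
        window_means = np.atleast_2d(window_means)
        return self.intercept + window_means @ np.asarray(self.slopes)


def regression_aic(n: int, rss: float, k: int) -> float:
    """AIC under the shared Gaussian-ML convention: n ln(RSS/n) + 2(k+1)."""
    if rss <= 0:
        raise ValueError("RSS must be positive for the Gaussian AIC")
    return n * np.log(rss / n) + 2.0 * (k + 1)


def null_model_aic(events: PhenologySeries) -> float:
    """Intercept-only model (k = 1): the Table-1 style 'Null' column."""
    y = events.days
    rss = float(np.sum((y - y.mean()) ** 2))
    return regression_aic(len(y), rss, 1)


def akaike_weights(aics) -> np.ndarray:
    aics = np.asarray(aics, dtype=float)
    d = aics - aics.min()
    w = np.exp(-d / 2.0)
    return w / w.sum()


def _prepare(temps, events, start_min):
    years = events.years
    if len(years) < 10:
        raise ValueError("need at least 10 species-years for a window scan")
    y = events.days
    end_max = events.last_event_day
    X, offsets = covariate_matrix(temps, years, start_min, end_max)
    csum = np.cumsum(X, axis=1)  # csum[:, j] = sum of cols 0..j
    return years, y, X, offsets, csum, end_max


def _means_for_duration(csum, duration, n_starts):
    """Window means for all windows of one duration: (n_years, n_starts)."""
    hi = csum[:, duration - 1 : duration - 1 + n_starts]
    lo = np.zeros_like(hi)
    if n_starts > 1:
        lo[:, 1:] = csum[:, : n_starts - 1]
    return (hi - lo) / duration


def scan_single_window(
    temps: DailyTemperatureSeries,
    events: PhenologySeries,
    start_min: int = JUN1_PREV_OFFSET,
    durations=range(2, 121),
) -> WindowFit:
    """Exhaustive OLS scan of event day on single-window mean temperature.

    Returns the maximum-R^2 fit; ties are broken toward the shortest
    duration, then the latest start (parsimony).
    """
    years, y, X, offsets, csum, end_max = _prepare(temps, events, start_min)
    n = len(y)
    yc = y - y.mean()
    syy = float(yc @ yc)
    if syy == 0:
        raise ValueError("event days have zero variance")

    best = None  # (r2, duration, -start_offset_index, slope, intercept, rss, spec)
    for L in durations:
        n_starts = len(offsets) - L + 1
        if n_starts <= 0:
            continue
        M = _means_for_duration(csum, L, n_starts)
        Mc = M - M.mean(axis=0)
        sxx = np.einsum("ij,ij->j", Mc, Mc)
        sxy = yc @ Mc
        valid = sxx > 0
        r2 = np.zeros(n_starts)
        r2[valid] = (sxy[valid] ** 2) / (sxx[valid] * syy)
        # within a duration, break exact R^2 ties toward the latest start
        top = np.flatnonzero(r2 >= r2.max())
        j = int(top[-1])
        if not valid[j]:
            continue
        cand = (r2[j], -L, j)
        if best is None or cand > best[0]:
            slope = sxy[j] / sxx[j]
            intercept = y.mean() - slope * M[:, j].mean()
            rss = syy * (1.0 - r2[j])
            best = (cand, slope, intercept, rss, WindowSpec(int(offsets[j]), L))
    if best is None:
        raise ValueError("no candidate window had temperature variance")
    (r2, negL, _), slope, intercept, rss, spec = best
    return WindowFit([spec], float(intercept), [float(slope)], float(r2),
                     float(rss), n, k=4)


def scan_double_window(
    temps: DailyTemperatureSeries,
    events: PhenologySeries,
    fixed_first: WindowSpec,
    start_min: int = JUN1_PREV_OFFSET,
    durations=range(10, 121),
) -> WindowFit:
    """Two-covariate OLS: the fixed first window plus an earlier second window.

    The second window is searched over starts from 1 June of the preceding
    year up to (but not including) the first window's start; overlap with the
    first window is permitted but flagged.  Candidates identical to the first
    window are impossible because the start must be strictly earlier.
    """
    years, y, X, offsets, csum, end_max = _prepare(temps, events, start_min)
    n = len(y)
    yc = y - y.mean()
    syy = float(yc @ yc)

    # first-window mean and the residual of y after regressing on it
    i0 = int(fixed_first.start - offsets[0])
    if i0 < 0 or fixed_first.end > offsets[-1]:
        raise ValueError("fixed first window outside the covariate span")
    f = X[:, i0 : i0 + fixed_first.duration].mean(axis=1)
    fc = f - f.mean()
    sff = float(fc @ fc)
    if sff == 0:
        raise ValueError("first-window temperatures have zero variance")
    beta_f = float(yc @ fc) / sff
    r = yc - beta_f * fc  # residual, already centred
    srr = float(r @ r)

    max_start_idx = int(fixed_first.start - offsets[0])  # strictly earlier starts
    best = None
    for L in durations:
        n_starts = min(len(offsets) - L + 1, max_start_idx)
        if n_starts <= 0:
            continue
        M = _means_for_duration(csum, L, n_starts)
        Mc = M - M.mean(axis=0)
        # residualise candidates on the first-window mean
        g = (fc @ Mc) / sff
        Rm = Mc - np.outer(fc, g)
        s_mm = np.einsum("ij,ij->j", Rm, Rm)
        s_mr = r @ Rm
        valid = s_mm > 1e-12
        gain = np.zeros(n_starts)
        gain[valid] = (s_mr[valid] ** 2) / s_mm[valid]
        top = np.flatnonzero(gain >= gain.max())
        j = int(top[-1])
        if not valid[j]:
            continue
        rss = srr - gain[j]
        r2 = 1.0 - rss / syy
        cand = (r2, -L, j)
        if best is None or cand > best[0]:
            best = (cand, j, L, M[:, j])
    if best is None:
        raise ValueError("no valid second-window candidate")
    (_, _, _), j, L, m = best
    second = WindowSpec(int(offsets[j]), L)
    # refit the two-covariate OLS exactly for clean coefficients
    Z = np.column_stack([np.ones(n), f, m])
    coef, _, _, _ = np.linalg.lstsq(Z, y, rcond=None)
    resid = y - Z @ coef
    rss = float(resid @ resid)
    r2 = 1.0 - rss / syy
    fit = WindowFit(
        [fixed_first, second],
        float(coef[0]),
        [float(coef[1]), float(coef[2])],
        float(r2),
        rss,
        n,
        k=7,
    )
    fit.overlapping = second.end >= fixed_first.start
    return fit
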