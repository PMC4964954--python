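"""UniForc and UniChill thermal-time phenology models.

UniForc accumulates daily forcing units R_f(x_t) = 1 / (1 + exp(b_f (x_t - c_f)))
from a start day t_1 and predicts the event on the first day the cumulative sum
reaches the threshold F*.  UniChill prepends a sequential chilling phase: from a
fixed start t_0 (1 Sep or 1 Nov of the preceding year) chilling units
R_c(x_t) = 1 / (1 + exp(a_c (x_t - c_c)^2 + b_c (x_t - c_c))) accumulate until
they reach C*, and forcing begins the following day.

Threshold crossings are made continuous by linear interpolation of the
cumulative sums within the crossing day, which smooths the otherwise
integer-valued objective and makes heuristic optimisation tractable.  The
forcing start day is likewise treated as continuous via fractional weighting
of the first active day.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .calendar import NOV1_PREV_OFFSET, SEP1_PREV_OFFSET

__all__ = [
    "NO_EVENT",
    "UniForcParams",
    "UniChillParams",
    "forcing_rate",
    "chilling_rate",
    "predict_event_day",
    "predict_event_days",
    "rmse_objective",
    "DEFAULT_HORIZON",
    "NO_EVENT_PENALTY",
]

#: Sentinel for "thresholds not met by the horizon".
NO_EVENT = math.nan

#: Reporting horizon (ordinal day) used for projections and as the default
#: accumulation cut-off.
DEFAULT_HORIZON = 250

#: Extra residual (days) added to (horizon - observed) when a fitted parameter
#: draw predicts no event for an observed year, keeping RMSE finite while
#: penalising such draws.
NO_EVENT_PENALTY = 30.0


@dataclass(frozen=True)
class UniForcParams:
    """Forcing-only model: 4 free parameters (t_1, b_f, c_f, F*)."""

    t1: float        # day forcing starts (day-index offset; continuous)
    b_f: float       # forcing slope, < 0 (per degC)
    c_f: float       # forcing midpoint, > 0 (degC)
    F_star: float    # forcing threshold (units)

    model_tag = "uniforc"
    n_free = 4

    def __post_init__(self):
        if not self.b_f < 0:
            raise ValueError(f"b_f must be < 0, got {self.b_f}")
        if not self.c_f > 0:
            raise ValueError(f"c_f must be > 0, got {self.c_f}")
        if not self.F_star > 0:
            raise ValueError(f"F* must be > 0, got {self.F_star}")

    def free_values(self) -> np.ndarray:
        return np.array([self.t1, self.b_f, self.c_f, self.F_star])


@dataclass(frozen=True)
class UniChillParams:
    """Sequential chilling-then-forcing model: 7 free parameters.

    t_0 is fixed (1 Sep = offset -121 or 1 Nov = -60 of the preceding year)
    and is not counted as estimated.
    """

    t0: int          # chilling start offset; SEP1_PREV_OFFSET or NOV1_PREV_OFFSET
    a_c: float       # chilling quadratic coefficient (per degC^2)
    b_c: float       # chilling linear coefficient (per degC)
    c_c: float       # chilling midpoint (degC)
    C_star: float    # chilling threshold (units)
    b_f: float
    c_f: float
    F_star: float

    n_free = 7

    def __post_init__(self):
        if self.t0 not in (SEP1_PREV_OFFSET, NOV1_PREV_OFFSET):
            raise ValueError(
                f"t0 must be Sep 1 ({SEP1_PREV_OFFSET}) or Nov 1 "
                f"({NOV1_PREV_OFFSET}); got {self.t0}"
            )
        if not self.C_star > 0:
            raise ValueError(f"C* must be > 0, got {self.C_star}")
        if not self.b_f < 0:
            raise ValueError(f"b_f must be < 0, got {self.b_f}")
        if not self.c_f > 0:
            raise ValueError(f"c_f must be > 0, got {self.c_f}")
        if not self.F_star > 0:
            raise ValueError(f"F* must be > 0, got {self.F_star}")

    @property
    def model_tag(self) -> str:
        return "unichill_sep1" if self.t0 == SEP1_PREV_OFFSET else "unichill_nov1"

    def free_values(self) -> np.ndarray:
        return np.array(
            [self.a_c, self.b_c, self.c_c, self.C_star, self.b_f, self.c_f, self.F_star]
        )


def forcing_rate(x, b_f: float, c_f: float):
    """Daily forcing units at temperature x: logistic, increasing, in (0, 1)."""
    if not b_f < 0:
        raise ValueError(f"b_f must be < 0, got {b_f}")
    x = np.asarray(x, dtype=float)
    out = 1.0 / (1.0 + np.exp(np.clip(b_f * (x - c_f), -700, 700)))
    return out if out.ndim else float(out)


def chilling_rate(x, a_c: float, b_c: float, c_c: float):
    """Daily chilling units at temperature x: logistic of a quadratic in (x - c_c).

    Equals 0.5 at x = c_c; with a_c > 0 it is bell-like (cold and hot extremes
    both contribute little); with a_c = 0 it reduces to a plain logistic.
    """
    x = np.asarray(x, dtype=float)
    u = x - c_c
    out = 1.0 / (1.0 + np.exp(np.clip(a_c * u * u + b_c * u, -700, 700)))
    return out if out.ndim else float(out)


def _crossing_days(S: np.ndarray, R: np.ndarray, offsets: np.ndarray,
                   threshold: float) -> np.ndarray:
    """Continuous day at which each row's cumulative sum S first reaches threshold.

    S[i, j] is the cumulative accumulation at the *end* of day offsets[j]; R is
    the per-day increment.  The crossing within day d is located by linear
    interpolation: day = d - 1 + (threshold - S_{d-1}) / R_d, which always lies
    in (d - 1, d].  Rows that never reach the threshold get NaN.
    """
    n, m = S.shape
    hit = S >= threshold
    j = np.argmax(hit, axis=1)
    reached = hit[np.arange(n), j]
    prev = np.where(j > 0, S[np.arange(n), np.maximum(j - 1, 0)], 0.0)
    rate = R[np.arange(n), j]
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = (threshold - prev) / rate
    day = offsets[j] - 1.0 + frac
    day[~reached] = np.nan
    return day


def predict_event_days(
    params,
    X: np.ndarray,
    offsets: np.ndarray,
    horizon: int = DEFAULT_HORIZON,
) -> np.ndarray:
    """Continuous predicted event day for each row of an offset-aligned
    temperature matrix; NaN (NO_EVENT) where thresholds are unmet by *horizon*.

    X has shape (n_years, n_days) with column j holding the temperature on
    day ``offsets[j]`` of each event year.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    offsets = np.asarray(offsets)
    if X.shape[1] != len(offsets):
        raise ValueError("X columns must align with offsets")
    keep = offsets <= horizon
    X = X[:, keep]
    offsets = offsets[keep]
    if np.isnan(X).any():
        raise ValueError("temperature matrix contains missing days")

    if isinstance(params, UniChillParams):
        if offsets[0] > params.t0:
            raise ValueError(
                f"covariates start at offset {offsets[0]}, after chilling start {params.t0}"
            )
        Rc = chilling_rate(X, params.a_c, params.b_c, params.c_c)
        Rc[:, offsets < params.t0] = 0.0
        Sc = np.cumsum(Rc, axis=1)
        # continuous chilling-completion day; forcing starts the next day
        t_chill = _crossing_days(Sc, Rc, offsets, params.C_star)
        t1 = t_chill + 1.0
    else:
        t1 = np.full(X.shape[0], float(params.t1))
        if offsets[0] > math.floor(params.t1):
            raise ValueError(
                f"covariates start at offset {offsets[0]}, after forcing start {params.t1}"
            )

    Rf = forcing_rate(X, params.b_f, params.c_f)
    # fractional first-day weighting: day d contributes weight
    # clip(d - t1 + 1, 0, 1), so an integer t1 starts with a full day t1 and a
    # fractional t1 starts with a partial day, keeping predictions continuous
    # in t1.
    w = np.clip(offsets[None, :] - t1[:, None] + 1.0, 0.0, 1.0)
    Rf = Rf * w
    Sf = np.cumsum(Rf, axis=1)
    day = _crossing_days(Sf, Rf, offsets, params.F_star)
    day[~np.isfinite(t1)] = np.nan  # chilling never completed
    day[day > horizon] = np.nan
    return day


def predict_event_day(
    params,
    X_row: np.ndarray,
    offsets: np.ndarray,
    horizon: int = DEFAULT_HORIZON,
) -> float:
    """Single-year convenience wrapper around :func:`predict_event_days`."""
    return float(predict_event_days(params, X_row, offsets, horizon)[0])


def rmse_objective(
    params,
    X: np.ndarray,
    offsets: np.ndarray,
    observed: np.ndarray,
    horizon: int = DEFAULT_HORIZON,
) -> float:
    """Root-mean-square error (days) between predicted and observed event days.

    Years where the parameters predict no event contribute the penalty
    residual (horizon - observed) + NO_EVENT_PENALTY, keeping the objective
    finite and still informative for heuristic search.
    """
    observed = np.asarray(observed, dtype=float)
    if observed.size == 0:
        raise ValueError("no observed years to match")
    pred = predict_event_days(params, X, offsets, horizon)
    resid = pred - observed
    miss = np.isnan(pred)
    resid[miss] = (horizon - observed[miss]) + NO_EVENT_PENALTY
    return float(np.sqrt(np.mean(resid**2)))
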