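"""Maximum-fit estimation of the thermal-time models and model comparison.

The RMSE objective of the UniForc/UniChill models is piecewise smooth with
many local minima and a degree of parameter redundancy, so it is minimised
heuristically in two phases: (1) a broad multi-start simulated-annealing
sweep over the parameter box, then (2) particle-swarm refinement of the
swarm seeded from the best annealing solutions.  Both phases are
deterministic given the seed.

Cross-family comparison uses the shared Gaussian-ML AIC convention
(see :mod:`phenoshift.windows`): AIC = n ln(RSS/n) + 2(k+1) with k = 4 for
UniForc and k = 7 for UniChill (the fixed chilling start t_0 is not counted).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calendar import (
    NOV1_PREV_OFFSET,
    SEP1_PREV_OFFSET,
    DailyTemperatureSeries,
    PhenologySeries,
    covariate_matrix,
)
from .thermal import (
    DEFAULT_HORIZON,
    UniChillParams,
    UniForcParams,
    rmse_objective,
)
from .windows import akaike_weights, regression_aic

__all__ = [
    "FitResult",
    "DEFAULT_BOUNDS",
    "fit_mechanistic",
    "compare_models",
    "params_from_vector",
]

#: Default parameter boxes.  Wide enough to cover sigmoid forcing functions
#: with thresholds anywhere in the plausible 0-25 degC range and bell- or
#: trough-shaped chilling functions.
DEFAULT_BOUNDS = {
    "uniforc": {
        "t1": (-60.0, 120.0),
        "b_f": (-3.0, -0.01),
        "c_f": (0.1, 25.0),
        "F_star": (0.5, 200.0),
    },
    "unichill": {
        "a_c": (-1.0, 1.0),
        "b_c": (-2.0, 2.0),
        "c_c": (-5.0, 20.0),
        "C_star": (0.5, 150.0),
        "b_f": (-3.0, -0.01),
        "c_f": (0.1, 25.0),
        "F_star": (0.5, 200.0),
    },
}

_PARAM_NAMES = {
    "uniforc": ["t1", "b_f", "c_f", "F_star"],
    "unichill_sep1": ["a_c", "b_c", "c_c", "C_star", "b_f", "c_f", "F_star"],
    "unichill_nov1": ["a_c", "b_c", "c_c", "C_star", "b_f", "c_f", "F_star"],
}

_K = {"uniforc": 4, "unichill_sep1": 7, "unichill_nov1": 7}


def params_from_vector(model_tag: str, theta: np.ndarray):
    """Build a parameter object from the free-parameter vector of a model."""
    theta = np.asarray(theta, dtype=float)
    if model_tag == "uniforc":
        return UniForcParams(*theta)
    t0 = SEP1_PREV_OFFSET if model_tag == "unichill_sep1" else NOV1_PREV_OFFSET
    return UniChillParams(t0, *theta)


@dataclass
class FitResult:
    model_tag: str
    params: object
    rmse: float
    rss: float
    n: int
    k: int
    n_starts: int
    seed: int
    objective_trace: list[float] = field(default_factory=list)
    aic: float = field(init=False)

    def __post_init__(self):
        self.aic = regression_aic(self.n, self.rss, self.k)

    @property
    def param_dict(self) -> dict[str, float]:
        names = _PARAM_NAMES[self.model_tag]
        return dict(zip(names, self.params.free_values()))


def _bounds_array(model_tag: str, bounds: dict | None) -> tuple[list[str], np.ndarray]:
    names = _PARAM_NAMES[model_tag]
    family = "uniforc" if model_tag == "uniforc" else "unichill"
    merged = dict(DEFAULT_BOUNDS[family])
    if bounds:
        merged.update(bounds)
    arr = np.array([merged[nm] for nm in names], dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("bounds must be finite")
    return names, arr


def _simulated_annealing(obj, x0, lo, hi, rng, n_iter=150, t0=2.0, t_end=0.01):
    """Compact bound-constrained SA chain with geometric cooling."""
    x = x0.copy()
    fx = obj(x)
    best_x, best_f = x.copy(), fx
    scale0 = 0.15 * (hi - lo)
    cool = (t_end / t0) ** (1.0 / max(n_iter - 1, 1))
    T = t0
    for _ in range(n_iter):
        step = rng.normal(0.0, scale0 * max(T / t0, 0.05))
        xn = np.clip(x + step, lo, hi)
        fn = obj(xn)
        if fn < fx or rng.random() < np.exp(-(fn - fx) / max(T, 1e-12)):
            x, fx = xn, fn
            if fx < best_f:
                best_x, best_f = x.copy(), fx
        T *= cool
    return best_x, best_f


def _particle_swarm(obj, seeds, lo, hi, rng, n_particles=30, n_iter=120,
                    w=0.72, c1=1.49, c2=1.49):
    """Standard global-best PSO, swarm seeded from the SA solutions."""
    dim = len(lo)
    pos = np.empty((n_particles, dim))
    n_seed = min(len(seeds), n_particles)
    pos[:n_seed] = seeds[:n_seed]
    if n_particles > n_seed:
        pos[n_seed:] = lo + (hi - lo) * rng.random((n_particles - n_seed, dim))
    vel = 0.1 * (hi - lo) * rng.normal(size=(n_particles, dim))
    fvals = np.array([obj(p) for p in pos])
    pbest, pbest_f = pos.copy(), fvals.copy()
    g = int(np.argmin(pbest_f))
    gbest, gbest_f = pbest[g].copy(), float(pbest_f[g])
    for _ in range(n_iter):
        r1 = rng.random((n_particles, dim))
        r2 = rng.random((n_particles, dim))
        vel = w * vel + c1 * r1 * (pbest - pos) + c2 * r2 * (gbest - pos)
        pos = np.clip(pos + vel, lo, hi)
        fvals = np.array([obj(p) for p in pos])
        improved = fvals < pbest_f
        pbest[improved] = pos[improved]
        pbest_f[improved] = fvals[improved]
        g = int(np.argmin(pbest_f))
        if pbest_f[g] < gbest_f:
            gbest, gbest_f = pbest[g].copy(), float(pbest_f[g])
    return gbest, gbest_f


def fit_mechanistic(
    model_tag: str,
    temps: DailyTemperatureSeries,
    events: PhenologySeries,
    bounds: dict | None = None,
    n_starts: int = 200,
    seed: int = 0,
    horizon: int = DEFAULT_HORIZON,
    x0: np.ndarray | None = None,
    sa_iters: int = 150,
    pso_iters: int = 120,
) -> FitResult:
    """Two-phase heuristic minimisation of the RMSE objective.

    ``x0`` optionally injects an extra start (e.g. UniForc estimates mapped
    into the UniChill box, which the search uses as a warm start).
    """
    if model_tag not in _K:
        raise ValueError(f"unknown model tag {model_tag!r}")
    names, barr = _bounds_array(model_tag, bounds)
    lo, hi = barr[:, 0], barr[:, 1]

    years = events.years
    y = events.days
    start_offset = SEP1_PREV_OFFSET if model_tag != "uniforc" else min(
        int(np.floor(lo[0])), 0
    )
    X, offsets = covariate_matrix(temps, years, start_offset, horizon)

    def obj(theta):
        try:
            p = params_from_vector(model_tag, theta)
        except ValueError:
            return 1e6
        return rmse_objective(p, X, offsets, y, horizon)

    rng = np.random.default_rng(seed)
    from scipy.stats import qmc

    starts = qmc.scale(
        qmc.LatinHypercube(d=len(lo), seed=rng).random(n_starts), lo, hi
    )
    if x0 is not None:
        starts = np.vstack([np.clip(np.asarray(x0, float), lo, hi), starts])

    f0 = np.array([obj(s) for s in starts])
    order = np.argsort(f0)
    n_sa = min(max(5, n_starts // 10), len(starts))
    trace = []
    sa_results = []
    for i in order[:n_sa]:
        bx, bf = _simulated_annealing(obj, starts[i], lo, hi, rng, n_iter=sa_iters)
        sa_results.append((bf, bx))
        trace.append(float(bf))
    sa_results.sort(key=lambda t: t[0])
    if not np.isfinite([f for f, _ in sa_results]).any() or sa_results[0][0] >= 1e6:
        raise RuntimeError(
            "no parameter draw produced any predicted event; widen the bounds"
        )
    seeds = np.array([x for _, x in sa_results])
    gx, gf = _particle_swarm(obj, seeds, lo, hi, rng, n_iter=pso_iters)
    if sa_results[0][0] < gf:  # PSO must never lose to its own seeds
        gx, gf = sa_results[0][1], sa_results[0][0]
    trace.append(float(gf))

    params = params_from_vector(model_tag, gx)
    rss = gf**2 * len(y)
    return FitResult(
        model_tag=model_tag,
        params=params,
        rmse=float(gf),
        rss=float(rss),
        n=len(y),
        k=_K[model_tag],
        n_starts=n_starts,
        seed=seed,
        objective_trace=trace,
    )


def compare_models(fits: dict[str, tuple[float, int]] | list) -> "pd.DataFrame":
    """Delta-AIC and Akaike weights across model families.

    Accepts either a mapping name -> (aic, n) or a list of objects with
    ``aic`` and ``n`` attributes plus a name (``model_tag`` or class name).
    All models must be fitted to the same species-years.
    """
    import pandas as pd

    rows = []
    if isinstance(fits, dict):
        for name, (aic, n) in fits.items():
            rows.append((name, float(aic), int(n)))
    else:
        for f in fits:
            name = getattr(f, "model_tag", type(f).__name__)
            rows.append((name, float(f.aic), int(f.n)))
    ns = {n for _, _, n in rows}
    if len(ns) > 1:
        raise ValueError(f"fits cover different numbers of years: {sorted(ns)}")
    names = [r[0] for r in rows]
    aics = np.array([r[1] for r in rows])
    delta = aics - aics.min()
    w = akaike_weights(aics)
    return pd.DataFrame(
        {"model": names, "aic": aics, "delta_aic": delta, "akaike_weight": w}
    ).set_index("model")
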