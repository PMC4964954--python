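"""Posterior sampling of thermal-time model parameters.

The likelihood treats each observed event day as Normal(predicted day,
sigma^2) with the continuous (interpolated) model prediction.  Following the
model simplifications used for uncertainty propagation, the forcing midpoint
c_f is fixed at its maximum-likelihood estimate (and for UniChill the
chilling midpoint c_c as well, with the chilling slope b_c constrained
positive), which removes the worst parameter redundancies.

Free parameters per model:
    uniforc:   t_1, b_f, F*, sigma          (c_f fixed)
    unichill:  a_c, b_c, C*, b_f, F*, sigma (c_f and c_c fixed; b_c > 0)

Sampler: component-wise adaptive random-walk Metropolis run as several
independent chains.  Positivity-constrained parameters (F*, C*, b_c, sigma,
and -b_f) are proposed on the log scale with the Jacobian included, so sign
constraints hold by construction.  Priors are weakly informative normals
centred on the MLE, sd = 10 |MLE| + 1, truncated to the sign constraints,
with a Half-Normal(10) prior on sigma; all are recorded in the result.
Chains are thinned so the pooled retained sample is exactly ``n_retain``
(1000 by default) draws, and Geweke / Heidelberger-Welch / Gelman-Rubin
diagnostics are attached; if they fail, the schedule is extended and the
chains rerun longer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calendar import (
    SEP1_PREV_OFFSET,
    DailyTemperatureSeries,
    PhenologySeries,
    covariate_matrix,
)
from .diagnostics import ConvergenceReport, convergence_diagnostics
from .fit import FitResult
from .thermal import (
    DEFAULT_HORIZON,
    NO_EVENT_PENALTY,
    UniChillParams,
    UniForcParams,
    predict_event_days,
)

__all__ = ["PosteriorSamples", "McmcSchedule", "run_mcmc"]


@dataclass(frozen=True)
class McmcSchedule:
    """Burn-in / sampling schedule.  Defaults are the full-length schedules
    (10k + 50k for the forcing-only model, 50k + 200k for chilling+forcing);
    tests and quick runs pass shorter ones."""

    burn_in: int
    iterations: int
    chains: int = 4

    @classmethod
    def default_for(cls, model_tag: str) -> "McmcSchedule":
        if model_tag == "uniforc":
            return cls(burn_in=10_000, iterations=50_000)
        return cls(burn_in=50_000, iterations=200_000)


@dataclass
class PosteriorSamples:
    model_tag: str
    draws: pd.DataFrame            # n_retain rows, one column per free parameter
    fixed: dict[str, float]        # c_f (and c_c) fixed at the MLE
    priors: dict[str, dict]
    schedule: McmcSchedule
    seed: int
    diagnostics: ConvergenceReport
    acceptance_rates: dict[str, float]
    chains: dict[str, np.ndarray] = field(repr=False, default_factory=dict)

    def __len__(self) -> int:
        return len(self.draws)

    def param_objects(self) -> list:
        """Materialise each retained draw as a model parameter object."""
        out = []
        for _, row in self.draws.iterrows():
            if self.model_tag == "uniforc":
                out.append(
                    UniForcParams(row["t1"], row["b_f"], self.fixed["c_f"], row["F_star"])
                )
            else:
                t0 = self.fixed["t0"]
                out.append(
                    UniChillParams(
                        int(t0), row["a_c"], row["b_c"], self.fixed["c_c"],
                        row["C_star"], row["b_f"], self.fixed["c_f"], row["F_star"],
                    )
                )
        return out


# -- internal parameterisation ----------------------------------------------
# Sampling happens in an unconstrained space z; each free parameter is either
# identity-mapped or log-mapped (for strictly positive / negative quantities).

def _transforms(model_tag: str):
    # name -> (to_z, from_z, log_jacobian(z))
    if model_tag == "uniforc":
        return {
            "t1": "id",
            "b_f": "neglog",   # b_f < 0: z = log(-b_f)
            "F_star": "log",
            "sigma": "log",
        }
    return {
        "a_c": "id",
        "b_c": "log",          # constrained positive in the Bayesian stage
        "C_star": "log",
        "b_f": "neglog",
        "F_star": "log",
        "sigma": "log",
    }


def _to_z(kind, v):
    if kind == "id":
        return v
    if kind == "log":
        return np.log(v)
    return np.log(-v)


def _from_z(kind, z):
    if kind == "id":
        return z
    if kind == "log":
        return np.exp(z)
    return -np.exp(z)


def run_mcmc(
    model_tag: str,
    temps: DailyTemperatureSeries,
    events: PhenologySeries,
    mle: FitResult,
    schedule: McmcSchedule | None = None,
    seed: int = 0,
    n_retain: int = 1000,
    horizon: int = DEFAULT_HORIZON,
    max_extensions: int = 2,
    prior_sd_factor: float = 10.0,
) -> PosteriorSamples:
    """Sample the posterior of the free parameters of a fitted model.

    ``mle`` supplies initial values and the fixed c_f / c_c.  The schedule is
    automatically extended (chains rerun longer, up to ``max_extensions``
    times) when the convergence diagnostics fail.
    """
    if schedule is None:
        schedule = McmcSchedule.default_for(model_tag)
    mle_params = mle.param_dict
    sigma0 = max(mle.rmse, 0.5)

    if model_tag == "uniforc":
        fixed = {"c_f": mle_params["c_f"]}
        init = {
            "t1": mle_params["t1"],
            "b_f": mle_params["b_f"],
            "F_star": mle_params["F_star"],
            "sigma": sigma0,
        }
        start_offset = min(int(np.floor(init["t1"])) - 30, 0)
    elif model_tag in ("unichill_sep1", "unichill_nov1"):
        t0 = SEP1_PREV_OFFSET if model_tag == "unichill_sep1" else -60
        fixed = {"c_f": mle_params["c_f"], "c_c": mle_params["c_c"], "t0": t0}
        init = {
            "a_c": mle_params["a_c"],
            "b_c": max(mle_params["b_c"], 0.05),  # constrained positive
            "C_star": mle_params["C_star"],
            "b_f": mle_params["b_f"],
            "F_star": mle_params["F_star"],
            "sigma": sigma0,
        }
        start_offset = t0
    else:
        raise ValueError(f"unknown model tag {model_tag!r}")

    trans = _transforms(model_tag)
    names = list(trans)
    y = events.days
    X, offsets = covariate_matrix(temps, events.years, start_offset, horizon)

    # weakly informative priors centred on the MLE, truncated by the transform
    priors = {}
    for nm in names:
        if nm == "sigma":
            priors[nm] = {"dist": "halfnormal", "scale": 10.0}
        else:
            mu = init[nm]
            priors[nm] = {
                "dist": "normal",
                "mu": mu,
                "sd": prior_sd_factor * (abs(mu) + 0.1),
            }

    def make_params(v: dict):
        if model_tag == "uniforc":
            return UniForcParams(v["t1"], v["b_f"], fixed["c_f"], v["F_star"])
        return UniChillParams(
            fixed["t0"], v["a_c"], v["b_c"], fixed["c_c"], v["C_star"],
            v["b_f"], fixed["c_f"], v["F_star"],
        )

    def log_post(zvec: np.ndarray) -> float:
        v = {nm: _from_z(trans[nm], z) for nm, z in zip(names, zvec)}
        lp = 0.0
        for nm, z in zip(names, zvec):
            pr = priors[nm]
            x = v[nm]
            if pr["dist"] == "halfnormal":
                lp += -0.5 * (x / pr["scale"]) ** 2
            else:
                lp += -0.5 * ((x - pr["mu"]) / pr["sd"]) ** 2
            if trans[nm] != "id":  # log-Jacobian of the (neg)log transform
                lp += z
        try:
            p = make_params(v)
        except ValueError:
            return -np.inf
        pred = predict_event_days(p, X, offsets, horizon)
        miss = np.isnan(pred)
        pred = np.where(miss, horizon + NO_EVENT_PENALTY, pred)
        sig = v["sigma"]
        resid = y - pred
        lp += -len(y) * np.log(sig) - 0.5 * np.sum(resid**2) / sig**2
        if not np.isfinite(lp):
            return -np.inf
        return float(lp)

    z0 = np.array([_to_z(trans[nm], init[nm]) for nm in names])
    if not np.isfinite(log_post(z0)):
        raise ValueError(
            "non-finite posterior at the initial values; re-fit the model first"
        )

    rng_master = np.random.default_rng(seed)
    chain_seeds = rng_master.integers(0, 2**31 - 1, size=schedule.chains)
    per_chain = int(np.ceil(n_retain / schedule.chains))

    def run_schedule(burn, iters):
        all_chains = np.empty((schedule.chains, iters, len(names)))
        acc = np.zeros(len(names))
        tot = 0
        d = len(names)
        for c in range(schedule.chains):
            rng = np.random.default_rng(chain_seeds[c])
            z = z0 + 0.05 * rng.standard_normal(d)
            lp = log_post(z)
            while not np.isfinite(lp):
                z = z0 + 0.01 * rng.standard_normal(d)
                lp = log_post(z)
            step = np.full(d, 0.1)
            n_total = burn + iters
            acc_window = np.zeros(d)
            # burn-in history feeds an adapted joint proposal (empirical
            # covariance, 2.38/sqrt(d) scaling) that handles the strong
            # correlations the component-wise sweeps mix through slowly
            zbuf = np.empty((burn, d))
            chol = None
            for it in range(n_total):
                for j in rng.permutation(d):
                    zprop = z.copy()
                    zprop[j] += step[j] * rng.standard_normal()
                    lpp = log_post(zprop)
                    if np.log(rng.random()) < lpp - lp:
                        z, lp = zprop, lpp
                        acc_window[j] += 1
                        if it >= burn:
                            acc[j] += 1
                if chol is not None:
                    zprop = z + (2.38 / np.sqrt(d)) * (chol @ rng.standard_normal(d))
                    lpp = log_post(zprop)
                    if np.log(rng.random()) < lpp - lp:
                        z, lp = zprop, lpp
                if it < burn:
                    zbuf[it] = z
                    # adapt scales toward ~40% acceptance; refresh the joint
                    # proposal covariance from the accumulated history
                    if (it + 1) % 100 == 0:
                        rate = acc_window / 100.0
                        step *= np.exp(np.clip(rate - 0.4, -0.5, 0.5))
                        step = np.clip(step, 1e-4, 5.0)
                        acc_window[:] = 0.0
                    if (it + 1) in (burn // 2, burn) and it + 1 >= 200:
                        cov = np.cov(zbuf[(it + 1) // 2 : it + 1].T)
                        try:
                            chol = np.linalg.cholesky(
                                np.atleast_2d(cov) + 1e-9 * np.eye(d)
                            )
                        except np.linalg.LinAlgError:
                            chol = None
                else:
                    all_chains[c, it - burn] = z
            tot += iters
        acc_rates = {nm: float(a / (schedule.chains * iters)) for nm, a in
                     zip(names, acc)}
        return all_chains, acc_rates

    burn, iters = schedule.burn_in, schedule.iterations
    for attempt in range(max_extensions + 1):
        zchains, acc_rates = run_schedule(burn, iters)
        # back-transform for diagnostics and retained draws
        vchains = {
            nm: np.stack(
                [_from_z(trans[nm], zchains[c, :, j]) for c in range(schedule.chains)]
            )
            for j, nm in enumerate(names)
        }
        report = convergence_diagnostics(vchains)
        if report.converged or attempt == max_extensions:
            break
        burn, iters = burn * 2, iters * 2  # "we ran the chains longer"

    thin = max(iters // per_chain, 1)
    rows = []
    for c in range(schedule.chains):
        kept = zchains[c, thin - 1 :: thin][:per_chain]
        rows.append(kept)
    pooled = np.concatenate(rows, axis=0)[:n_retain]
    draws = pd.DataFrame(
        {nm: _from_z(trans[nm], pooled[:, j]) for j, nm in enumerate(names)}
    )
    final_schedule = McmcSchedule(burn, iters, schedule.chains)
    return PosteriorSamples(
        model_tag=model_tag,
        draws=draws,
        fixed=fixed,
        priors=priors,
        schedule=final_schedule,
        seed=seed,
        diagnostics=report,
        acceptance_rates=acc_rates,
        chains=vchains,
    )
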