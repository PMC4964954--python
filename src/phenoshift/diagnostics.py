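"""MCMC convergence diagnostics: Geweke, Heidelberger-Welch, Gelman-Rubin.

All three follow the standard single- and multi-chain definitions.  The
spectral density of a chain at frequency zero — the long-run variance needed
by the Geweke z-score and the Heidelberger-Welch tests — is estimated with a
Bartlett lag-window applied to the empirical autocovariances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "spectrum0_ar",
    "geweke_z",
    "heidelberger_welch",
    "gelman_rubin",
    "ConvergenceReport",
    "convergence_diagnostics",
]

_MIN_LEN = 50


def spectrum0_ar(x: np.ndarray, bandwidth: int | None = None) -> float:
    """Long-run variance (spectral density at frequency zero) of a chain.

    Bartlett lag-window estimator: S(0) = gamma_0 + 2 sum_k w_k gamma_k with
    triangular weights over lags up to ~1.5 n^(1/3).  Unlike an AR-based
    estimate this stays finite for strongly trending chains, so trends still
    show up in the diagnostics that divide by it.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < _MIN_LEN:
        raise ValueError(f"chain too short ({n} < {_MIN_LEN}) for a spectral estimate")
    xc = x - x.mean()
    g0 = float(xc @ xc) / n
    if g0 == 0:
        return 0.0
    if bandwidth is None:
        bandwidth = max(int(1.5 * n ** (1 / 3)), 1)
    s0 = g0
    for k in range(1, bandwidth + 1):
        gk = float(xc[:-k] @ xc[k:]) / n
        s0 += 2.0 * (1.0 - k / (bandwidth + 1)) * gk
    return max(s0, 1e-12 * g0)


def geweke_z(x: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke's convergence z-score: compare the mean of the first 10% of the
    chain with the mean of the last 50%, scaled by spectral variance estimates."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    a = x[: int(first * n)]
    b = x[int((1 - last) * n):]
    va = spectrum0_ar(a) / len(a)
    vb = spectrum0_ar(b) / len(b)
    denom = np.sqrt(va + vb)
    if denom == 0:
        return 0.0
    return float((a.mean() - b.mean()) / denom)


def heidelberger_welch(
    x: np.ndarray, alpha: float = 0.05, eps: float = 0.1
) -> dict:
    """Heidelberger & Welch stationarity and half-width tests.

    Stationarity: a Cramer-von-Mises test on the standardised cumulative-sum
    (Brownian-bridge) process, applied to the full chain and then to chains
    with the first 10%, 20%, ... 50% discarded until it passes.  Half-width:
    the 95% confidence half-width of the mean of the retained chain must be
    below ``eps`` times the |mean|.
    """
    x = np.asarray(x, dtype=float)
    n0 = len(x)
    if n0 < _MIN_LEN:
        raise ValueError(
            f"chain too short ({n0} < {_MIN_LEN}) for the stationarity test"
        )
    passed = False
    start_frac = 0.0
    for frac in (0.0, 0.1, 0.2, 0.3, 0.4, 0.5):
        y = x[int(frac * n0):]
        n = len(y)
        if n < _MIN_LEN:
            break
        s0 = spectrum0_ar(y)
        if s0 == 0:  # constant chain is trivially stationary
            passed, start_frac = True, frac
            break
        t = np.arange(1, n + 1)
        csum = np.cumsum(y)
        bridge = (csum - t * y.mean()) / np.sqrt(n * s0)
        cvm = float(np.mean(bridge**2))
        # 5% critical value of the Cramer-von Mises limiting distribution
        if cvm < 0.461:
            passed, start_frac = True, frac
            break
    if not passed:
        return {
            "stationarity": False,
            "start_fraction": None,
            "halfwidth_ok": False,
            "mean": float(np.mean(x)),
            "halfwidth": np.nan,
        }
    y = x[int(start_frac * n0):]
    s0 = spectrum0_ar(y)
    hw = 1.96 * np.sqrt(s0 / len(y))
    m = float(np.mean(y))
    hw_ok = bool(hw <= eps * abs(m)) if m != 0 else bool(hw == 0)
    return {
        "stationarity": True,
        "start_fraction": start_frac,
        "halfwidth_ok": hw_ok,
        "mean": m,
        "halfwidth": float(hw),
    }


def gelman_rubin(chains: np.ndarray) -> float:
    """Split-R-hat over parallel chains (each row one chain).

    Chains are split in half, then R-hat = sqrt(var_hat+ / W) with the usual
    between/within decomposition; values near 1 indicate convergence.
    """
    chains = np.atleast_2d(np.asarray(chains, dtype=float))
    if chains.shape[0] < 2:
        raise ValueError("Gelman-Rubin requires at least 2 chains")
    n = chains.shape[1]
    half = n // 2
    split = np.vstack([chains[:, :half], chains[:, half : 2 * half]])
    m, n = split.shape
    means = split.mean(axis=1)
    B = n * np.var(means, ddof=1)
    W = np.mean(np.var(split, axis=1, ddof=1))
    if W == 0:
        return 1.0 if B == 0 else np.inf
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


@dataclass
class ConvergenceReport:
    geweke: dict[str, float]
    heidelberger: dict[str, dict]
    rhat: dict[str, float]

    @property
    def converged(self) -> bool:
        ok_g = all(abs(z) < 2.0 for z in self.geweke.values() if not np.isnan(z))
        ok_h = all(
            h["stationarity"] is not False for h in self.heidelberger.values()
        )
        ok_r = all(r < 1.1 for r in self.rhat.values())
        return ok_g and ok_h and ok_r


def convergence_diagnostics(
    chains: dict[str, np.ndarray]
) -> ConvergenceReport:
    """Run all three diagnostics on a dict parameter -> (n_chains, n_iter) array.

    Geweke and Heidelberger-Welch are single-chain diagnostics and are
    evaluated on the first chain; split-R-hat uses all chains.
    """
    geweke = {}
    heidel = {}
    rhat = {}
    for name, arr in chains.items():
        arr = np.atleast_2d(np.asarray(arr, dtype=float))
        try:
            geweke[name] = geweke_z(arr[0])
        except ValueError:  # chain segment too short; leave undetermined
            geweke[name] = float("nan")
        try:
            heidel[name] = heidelberger_welch(arr[0])
        except ValueError:
            heidel[name] = {
                "stationarity": None, "start_fraction": None,
                "halfwidth_ok": None, "mean": float(np.mean(arr[0])),
                "halfwidth": float("nan"),
            }
        if arr.shape[0] >= 2:
            rhat[name] = gelman_rubin(arr)
    return ConvergenceReport(geweke, heidel, rhat)
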