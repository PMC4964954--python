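"""Climate-change projection of event-date distributions and species order.

A delta ensemble (n samples of 12 monthly temperature changes) is added to a
baseline daily series to give n projected series.  Each posterior parameter
draw is paired with a different projected series (index-aligned after
independent seeded shuffles), the thermal-time model is run forward over the
projected years, and the resulting event-day ensemble is summarised by its
median (excluding no-event cells) and the proportion of projections with no
event by the reporting horizon (ordinal day 250).

The first projected year is dropped because its covariates (from 1 June of
the preceding year) fall before the baseline starts, so a 30-year baseline
yields a 29-year projected phenology series per ensemble member.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calendar import DailyTemperatureSeries, covariate_matrix
from .thermal import DEFAULT_HORIZON, predict_event_days

__all__ = [
    "ProjectionEnsemble",
    "ProjectionSummary",
    "apply_deltas",
    "project_phenology",
    "pairwise_precedence",
    "summarize",
]


@dataclass
class ProjectionEnsemble:
    species: str
    days: np.ndarray          # (n_members, n_years); NaN = no event
    years: np.ndarray         # projected event years
    draw_ids: np.ndarray      # posterior-draw index per member
    delta_ids: np.ndarray     # delta-sample index per member

    def __post_init__(self):
        if self.days.shape[0] != len(self.draw_ids) or self.days.shape[0] != len(
            self.delta_ids
        ):
            raise ValueError("one draw id and one delta id per ensemble member")


@dataclass
class ProjectionSummary:
    species: str
    median_day: float             # NaN when every cell is no-event
    no_event_proportion: float
    quantiles: dict[float, float]
    n_members: int
    n_years: int
    all_no_event: bool


def apply_deltas(
    baseline: DailyTemperatureSeries, deltas: np.ndarray
) -> list[DailyTemperatureSeries]:
    """One projected series per delta sample: every day's temperature is the
    baseline plus that sample's change for the day's calendar month."""
    deltas = np.asarray(deltas, dtype=float)
    if deltas.ndim != 2 or deltas.shape[1] != 12:
        raise ValueError("deltas must be an (n_samples, 12) matrix")
    if not np.isfinite(deltas).all():
        raise ValueError("delta samples must be finite for all 12 months")
    return [baseline.shifted(row) for row in deltas]


def project_phenology(
    posterior_params: list,
    projected: list[DailyTemperatureSeries],
    species: str = "",
    horizon: int = DEFAULT_HORIZON,
    seed: int | None = None,
    start_offset: int = -213,
) -> ProjectionEnsemble:
    """Drive one posterior draw through one projected series each.

    ``posterior_params`` is a list of UniForc/UniChill parameter objects (one
    per retained draw) and must match ``projected`` in length; pairing is
    index-aligned after independent shuffles when a seed is given.
    """
    n = len(posterior_params)
    if n != len(projected):
        raise ValueError(
            f"posterior size {n} != projected-series ensemble size {len(projected)}"
        )
    draw_ids = np.arange(n)
    delta_ids = np.arange(n)
    if seed is not None:
        rng = np.random.default_rng(seed)
        draw_ids = rng.permutation(n)
        delta_ids = rng.permutation(n)

    base = projected[0]
    first_year = base.start.year + 1  # first year with a preceding June
    last_year = base.end.year
    years = np.arange(first_year, last_year + 1)

    days = np.empty((n, len(years)))
    for i in range(n):
        params = posterior_params[draw_ids[i]]
        series = projected[delta_ids[i]]
        t_start = getattr(params, "t0", None)
        if t_start is None:
            t_start = int(np.floor(params.t1))
        s0 = min(int(t_start), start_offset)
        X, offsets = covariate_matrix(series, years, s0, horizon)
        days[i] = predict_event_days(params, X, offsets, horizon)
    return ProjectionEnsemble(species, days, years, draw_ids, delta_ids)


def pairwise_precedence(a: ProjectionEnsemble, b: ProjectionEnsemble) -> dict:
    """Proportion of (member, year) cells where species A's event precedes B's.

    Comparisons are cellwise (same ensemble member, same year) so that climate
    variability is shared within each comparison.  Cells with any no-event or
    an exact tie are tallied separately; the four fractions sum to 1.
    """
    if a.days.shape != b.days.shape:
        raise ValueError("ensembles must share the same (members, years) shape")
    total = a.days.size
    miss = np.isnan(a.days) | np.isnan(b.days)
    both = ~miss
    a_first = np.sum((a.days < b.days) & both)
    b_first = np.sum((a.days > b.days) & both)
    ties = np.sum((a.days == b.days) & both)
    out = {
        "a_first": a_first / total,
        "b_first": b_first / total,
        "ties": ties / total,
        "no_event": np.sum(miss) / total,
    }
    assert abs(sum(out.values()) - 1.0) < 1e-12
    return out


def summarize(
    ensemble: ProjectionEnsemble,
    horizon: int = DEFAULT_HORIZON,
    quantiles=(0.05, 0.25, 0.5, 0.75, 0.95),
) -> ProjectionSummary:
    """Median event day (excluding no-event cells) and the proportion of
    projections with no event by the horizon."""
    days = ensemble.days
    if days.size == 0:
        raise ValueError("empty ensemble")
    miss = np.isnan(days)
    p_miss = float(miss.mean())
    valid = days[~miss]
    if valid.size == 0:
        return ProjectionSummary(
            ensemble.species, float("nan"), 1.0, {q: float("nan") for q in quantiles},
            days.shape[0], days.shape[1], True,
        )
    qs = {float(q): float(np.quantile(valid, q)) for q in quantiles}
    return ProjectionSummary(
        ensemble.species,
        float(np.median(valid)),
        p_miss,
        qs,
        days.shape[0],
        days.shape[1],
        False,
    )
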