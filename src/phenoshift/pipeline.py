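"""End-to-end orchestration: simulate -> scan/psr/fit -> compare -> mcmc -> project.

Every stage is a pure function of (inputs, config, seed); per-stage artifacts
are plain JSON/CSV files in the run directory and a manifest records the
config, derived sub-seeds and a hash per artifact, so identical configs give
identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .calendar import (
    DailyTemperatureSeries,
    read_deltas_csv,
    read_phenology_csv,
    read_temperature_csv,
    write_deltas_csv,
    write_phenology_csv,
    write_temperature_csv,
)
from .fit import fit_mechanistic
from .mcmc import McmcSchedule, run_mcmc
from .project import apply_deltas, pairwise_precedence, project_phenology, summarize
from .psr import fit_psr
from .simulate import (
    ClimateSpec,
    simulate_deltas,
    simulate_events_mechanistic,
    simulate_temperature,
)
from .thermal import UniForcParams
from .windows import akaike_weights, null_model_aic, scan_double_window, scan_single_window

__all__ = ["RunConfig", "run_pipeline", "default_config"]

MODEL_COLUMNS = [
    "null",
    "uniforc",
    "unichill_sep1",
    "unichill_nov1",
    "window",
    "double_window",
    "psr",
]


@dataclasses.dataclass
class RunConfig:
    """Configuration of a full pipeline run; round-trips through YAML."""

    out_dir: str
    seed: int = 0
    simulate: bool = True
    temps_csv: str | None = None
    events_csv: str | None = None
    deltas_csv: str | None = None
    start_year: int = 1900
    n_years: int = 60
    species: dict | None = None          # name -> uniforc params for simulation
    models: tuple = ("uniforc",)
    n_starts: int = 20
    sa_iters: int = 100
    pso_iters: int = 80
    mcmc_burn: int = 500
    mcmc_iters: int = 1500
    mcmc_chains: int = 2
    n_retain: int = 200
    project: bool = True
    n_delta_samples: int = 200
    delta_means: tuple = (2.0,) * 12
    delta_sds: tuple = (0.8,) * 12
    baseline_years: int = 30
    horizon: int = 250

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def subseed(self, stage: str) -> int:
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31)


def default_config(out_dir: str, seed: int = 0) -> RunConfig:
    return RunConfig(
        out_dir=out_dir,
        seed=seed,
        species={
            "earlybirch": {"t1": 10.0, "b_f": -0.3, "c_f": 8.0, "F_star": 25.0},
            "lateoak": {"t1": 40.0, "b_f": -0.25, "c_f": 12.0, "F_star": 30.0},
        },
    )


def _sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> Path:
    """Run the full workflow; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed, "stages": {}}

    # --- stage: inputs -----------------------------------------------------
    if config.simulate:
        spec = ClimateSpec(seed=config.subseed("climate"))
        temps = simulate_temperature(spec, config.start_year - 1, config.n_years + 1)
        species_cfg = config.species or default_config(config.out_dir).species
        years = range(config.start_year + 1, config.start_year + config.n_years)
        events = {}
        for i, (name, pdict) in enumerate(sorted(species_cfg.items())):
            params = UniForcParams(**pdict)
            events[name] = simulate_events_mechanistic(
                temps, params, years, noise_sd=2.0,
                seed=config.subseed(f"events:{name}"), species=name,
                horizon=config.horizon,
            )
        deltas = simulate_deltas(
            config.n_delta_samples, np.array(config.delta_means),
            np.array(config.delta_sds), seed=config.subseed("deltas"),
        )
        write_temperature_csv(temps, out / "temperatures.csv")
        write_phenology_csv(events, out / "phenology.csv")
        write_deltas_csv(deltas, out / "deltas.csv")
    else:
        missing = [
            p for p in (config.temps_csv, config.events_csv) if p is None or not Path(p).exists()
        ]
        if missing or config.temps_csv is None:
            raise FileNotFoundError(
                "simulation disabled and input files missing: supply temps_csv "
                "and events_csv (and deltas_csv for projection)"
            )
        temps = read_temperature_csv(config.temps_csv)
        events = read_phenology_csv(config.events_csv)
        deltas = read_deltas_csv(config.deltas_csv) if config.deltas_csv else None
    manifest["stages"]["inputs"] = {
        f.name: _sha(f) for f in sorted(out.glob("*.csv"))
    }

    # --- stage: per-species model fits ------------------------------------
    comparison: dict[str, dict[str, float]] = {}
    posteriors = {}
    for name, ev in sorted(events.items()):
        fits: dict[str, float] = {"null": null_model_aic(ev)}
        single = scan_single_window(temps, ev)
        fits["window"] = single.aic
        double = scan_double_window(temps, ev, single.windows[0])
        fits["double_window"] = double.aic
        psr = fit_psr(temps, ev)
        fits["psr"] = psr.aic
        best_mech = None
        for tag in config.models:
            fr = fit_mechanistic(
                tag, temps, ev, n_starts=config.n_starts,
                seed=config.subseed(f"fit:{tag}:{name}"),
                sa_iters=config.sa_iters, pso_iters=config.pso_iters,
                horizon=config.horizon,
            )
            fits[tag] = fr.aic
            if best_mech is None or fr.aic < best_mech.aic:
                best_mech = fr
        aics = np.array(list(fits.values()))
        delta_aic = aics - aics.min()
        comparison[name] = {
            **{f"dAIC_{k}": float(d) for k, d in zip(fits, delta_aic)},
            **{f"w_{k}": float(w) for k, w in zip(fits, akaike_weights(aics))},
        }

        # --- stage: posterior + projection per species --------------------
        if config.project and deltas is not None and best_mech is not None:
            sched = McmcSchedule(config.mcmc_burn, config.mcmc_iters, config.mcmc_chains)
            post = run_mcmc(
                best_mech.model_tag, temps, ev, best_mech, schedule=sched,
                seed=config.subseed(f"mcmc:{name}"), n_retain=config.n_retain,
                horizon=config.horizon, max_extensions=0,
            )
            posteriors[name] = post
            post.draws.to_csv(out / f"posterior_{name}.csv", index=False)

    with open(out / "comparison.json", "w") as fh:
        json.dump(comparison, fh, indent=1, sort_keys=True)
    manifest["stages"]["comparison"] = {"comparison.json": _sha(out / "comparison.json")}

    if config.project and deltas is not None and posteriors:
        base_start = config.start_year + config.n_years - config.baseline_years
        baseline = DailyTemperatureSeries(
            temps.data.loc[f"{base_start - 1}-06-01":]
        )
        idx = np.random.default_rng(config.subseed("deltapick")).choice(
            len(deltas), size=config.n_retain, replace=len(deltas) < config.n_retain
        )
        projected = apply_deltas(baseline, deltas[idx])
        ensembles = {}
        summaries = {}
        for name, post in sorted(posteriors.items()):
            ens = project_phenology(
                post.param_objects(), projected, species=name,
                horizon=config.horizon, seed=config.subseed(f"pair:{name}"),
            )
            ensembles[name] = ens
            s = summarize(ens)
            summaries[name] = {
                "median_day": s.median_day,
                "no_event_proportion": s.no_event_proportion,
            }
        prec = {}
        names = sorted(ensembles)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                prec[f"{a}<{b}"] = pairwise_precedence(ensembles[a], ensembles[b])[
                    "a_first"
                ]
        with open(out / "projection_summary.json", "w") as fh:
            json.dump(
                {"summaries": summaries, "precedence": prec}, fh, indent=1,
                sort_keys=True, allow_nan=True,
            )
        manifest["stages"]["projection"] = {
            "projection_summary.json": _sha(out / "projection_summary.json")
        }

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return out
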