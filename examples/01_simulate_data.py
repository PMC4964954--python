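"""Generate the three synthetic inputs every other example builds on.

A daily temperature series (seasonal cycle + AR(1) noise), an annual
first-leafing series driven by a forcing-only thermal-time model, and a
monthly temperature-change delta ensemble.
"""

import numpy as np

import phenoshift as ps

spec = ps.ClimateSpec(seed=1)  # ~9.5 degC mean, 6.5 degC seasonal amplitude
temps = ps.simulate_temperature(spec, start_year=1850, n_years=80)
print(f"temperature series: {temps.start}..{temps.end}, "
      f"mean {temps.data.mean():.2f} degC")

truth = ps.UniForcParams(t1=20, b_f=-0.3, c_f=10.0, F_star=30.0)
events = ps.simulate_events_mechanistic(
    temps, truth, range(1851, 1930), noise_sd=2.0, seed=2, species="birch"
)
print(f"phenology series: {len(events)} years, mean event day "
      f"{events.days.mean():.1f} (about mid-{'April' if 90 < events.days.mean() < 140 else '?'})")

deltas = ps.simulate_deltas(
    1000, monthly_means=np.full(12, 2.0), monthly_sds=np.full(12, 0.8), seed=3
)
print(f"delta ensemble: {deltas.shape[0]} samples x {deltas.shape[1]} months, "
      f"mean change {deltas.mean():+.2f} degC")

# The printed mean event day is the average ordinal date (Jan 1 = 1) at which
# the simulated species first leafs; the delta ensemble feeds the projection
# examples.
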