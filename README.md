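# phenoshift

Thermal sensitivity of plant phenology, and how climate change reshuffles the
order of spring.

Long phenological records — annual first-leafing and first-flowering dates —
carry a signal of how each species responds to daily temperatures: warm
springs force development and advance events, while for some species warm
autumns and winters slow the accumulation of *chilling* and delay them.
`phenoshift` infers these sensitivities from a daily temperature series and
an annual event series, compares regression-based and mechanistic process
models on a single footing, and propagates parameter and climate uncertainty
into projected future event-date distributions and pairwise species
orderings.

## Models

**Sliding time-window regression.** An exhaustive search over every window of
consecutive days (starts from 1 June of the preceding year, durations 2–120
days) for the window whose mean temperature best predicts the event day by
OLS, ranked on R²; a double-window variant adds an earlier (chilling-type)
window (durations 10–120 days) in a multiple regression.

**P-spline signal regression (PSR).** The event day is regressed on the whole
daily-temperature vector; the coefficient-per-day curve α(d) is expanded in a
cubic B-spline basis with a second-order difference penalty on the basis
coefficients, λ chosen by GCV, complexity reported as effective degrees of
freedom, with pointwise ~95 % confidence bands.

**UniForc.** Daily forcing units R_f(x_t) = 1 / (1 + exp(b_f (x_t − c_f))),
b_f < 0, accumulate from day t₁; the event occurs on the first day the sum
reaches F\*.  Four free parameters (t₁, b_f, c_f, F\*).

**UniChill.** A sequential chilling phase precedes forcing: from a fixed
start t₀ (1 Sep or 1 Nov of the preceding year) chilling units
R_c(x_t) = 1 / (1 + exp(a_c (x_t − c_c)² + b_c (x_t − c_c))) accumulate until
they reach C\*; forcing begins the following day.  Seven free parameters.

Mechanistic models are fitted by minimising the RMSE between predicted and
observed event days (threshold crossings made continuous by linear
interpolation) with multi-start simulated annealing followed by
particle-swarm refinement.  All families are compared with one Gaussian-ML
AIC convention, AIC = n ln(RSS/n) + 2(k+1), in which searched window starts
and durations count as parameters.  A Bayesian layer (adaptive Metropolis,
c_f fixed at the MLE; for UniChill c_c fixed and b_c > 0) yields 1000
posterior draws with Geweke, Heidelberger–Welch and Gelman–Rubin
diagnostics; each draw is paired with one sample of a monthly
temperature-change ensemble added to a 30-year baseline, giving an ensemble
of projected event days summarised by medians, no-event-by-day-250
proportions, and pairwise precedence tables.

A synthetic-data module generates all three inputs (seasonal + AR(1) daily
temperatures, events from known window-linear or thermal-time parameters,
Gaussian monthly deltas), so the full pipeline is testable end to end with
known ground truth.

## Worked example

```python
import phenoshift as ps

temps = ps.simulate_temperature(ps.ClimateSpec(seed=1), 1800, 130)
events = ps.simulate_events_linear(
    temps, range(1801, 1930), windows=[(-50, 10)], slopes=[-6.0],
    intercept=120.0, noise_sd=1.0, seed=2,
)
fit = ps.scan_single_window(temps, events)
w = fit.windows[0]
print(f"best window: offsets {w.start}..{w.end} ({w.duration} days)")
print(f"slope {fit.slopes[0]:+.2f} days/degC, R2 {fit.r2:.3f}")
```

prints

```
best window: offsets -50..-41 (10 days)
slope -6.01 days/degC, R2 0.982
```

i.e. the scan recovers the generating 10-day window exactly (offsets count
from Jan 1 of the event year, so −50..−41 is mid November of the preceding
year) and the fitted sensitivity of −6.01 days/°C means a winter 1 °C warmer
in that window shifts the event six days earlier.  The scripts in
`examples/` walk through each capability the same way: data simulation,
window scans, signal regression, mechanistic fitting and model comparison,
posterior sampling, and projection.

There is also a thin CLI mirroring the stages:

```bash
phenoshift simulate --out data/ --seed 1
phenoshift scan --mode single --temps data/temperatures.csv \
    --events data/phenology.csv --out fit.json
phenoshift run --config config.yaml   # full pipeline
```

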