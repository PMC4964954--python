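# Methods

This note records the models implemented in `phenoshift`, the numerical
choices behind them, what the synthetic-data generators do and do not
emulate, and the known limitations a user should weigh before trusting a
result.

## Day-index convention

All modules share one calendar convention: a signed integer offset relative
to 1 January of the *event year*, with Jan 1 = 1, Dec 31 of the preceding
year = 0, and e.g. 1 June / 1 September / 1 November of the preceding year
= −213 / −121 / −60.  Offsets are computed by true calendar arithmetic;
because Feb 29 can only fall *after* Jan 1 of the event year, the
preceding-year anchors are the same in every year, while offsets of dates
after February of a leap event year shift by one.  Missing temperature days
are kept in the index as explicit gaps and any operation whose window
touches one fails loudly; silent imputation would bias the window scans and
the accumulation models in ways that are hard to detect downstream.

## Sliding time-window regression

The single-window scan evaluates OLS of event day on mean temperature for
every window with start ≥ −213 and duration 2–120 days, ending no later than
the species' latest observed event day (windows include both endpoints), and
returns the maximum-R² fit.  The double-window model keeps that window and
adds a second one searched over strictly earlier starts with durations
10–120 days; overlap with the first window is allowed but flagged, since
"earlier" constrains only the start.  Exact R² ties are broken toward the
shorter duration, then the later start (parsimony; ties are measure-zero on
continuous data but matter for degenerate tests).  The scan is vectorised
over starts via per-year cumulative sums, which makes exhaustive enumeration
(~4·10⁴ candidates) essentially instantaneous; unit tests verify equality
with a naive double loop.

## AIC convention

Every family is compared with the same Gaussian maximum-likelihood AIC,

    AIC = n ln(RSS/n) + 2 (k + 1),

the +1 being the residual variance.  k counts searched window starts and
durations as parameters: k = 4 for the single-window model, 7 for the
double, 1 for the intercept-only null, 4 for UniForc, 7 for UniChill (the
fixed chilling start t₀ is not counted), and the effective degrees of
freedom replace k for PSR.  One deliberate caveat: charging the window
start/duration as 3 parameters only partially compensates the selection
bias of an exhaustive max-R² search, so on pure-noise responses the
selected window typically edges out the null by ~2–5 AIC units.  The tests
assert this bounded behaviour rather than a sign that does not hold; users
should treat small ΔAIC advantages of scanned-window models with suspicion.

## P-spline signal regression

The coefficient curve α(d) over the covariate span (offset −213 up to the
species' latest event day) is expanded as α = Bθ in a cubic B-spline basis
with interior knots every 4 days, and θ is estimated by penalised least
squares with a second-order difference penalty λ‖D₂θ‖²; the intercept is
unpenalised.  λ is selected by GCV over a log-spaced grid (10⁻²–10⁸, 41
points); effective degrees of freedom are tr of the hat matrix, and
pointwise ~95 % bands come from the Bayesian posterior covariance of the
penalised fit, σ²(UᵀU + λP)⁻¹.  Basis dimension, penalty order and the GCV
flavour are configurable and recorded in the fit object.  At λ → ∞ the
curve collapses to the penalty null space — a line through the Greville
abscissae, hence exactly straight in the interior with tiny boundary
deviations — and edf → 3 (intercept + 2-dimensional null space); both are
asserted in tests.

## Thermal-time models

Forcing units per day follow the logistic R_f(x) = 1/(1+exp(b_f(x−c_f))),
b_f < 0, c_f > 0; chilling units follow the logistic-of-quadratic
R_c(x) = 1/(1+exp(a_c(x−c_c)² + b_c(x−c_c))), which is bell-shaped for
a_c > 0 (only a band of cool temperatures chills effectively) and reduces to
a plain logistic at a_c = 0.  UniForc accumulates forcing from t₁ and
predicts the event when the sum reaches F\*; UniChill first accumulates
chilling from a fixed t₀ ∈ {1 Sep, 1 Nov} until C\* and starts forcing *the
following day* (whether forcing starts on the completion day or the next is
ambiguous in the sequential formulation; we chose the next day and test that
choice).

Two continuity devices keep the RMSE objective tractable for heuristic
search: threshold crossings are linearly interpolated within the crossing
day, day = d − 1 + (threshold − S_{d−1})/R_d, which always lies in
(d−1, d]; and t₁ is treated as continuous via fractional weighting of the
first active day (day d contributes weight clip(d − t₁ + 1, 0, 1)).  The
chilling crossing is interpolated the same way for internal consistency.
Predictions past the horizon (default ordinal day 250, the reporting
cut-off used throughout) are NO_EVENT; during fitting such years contribute
a residual of (horizon − observed) + 30 days, finite and decreasing as
parameters move toward producing an event.  The 30-day penalty is a design
constant: large enough that no-event draws are always worse than any
plausible event prediction, small enough to preserve gradient information.

## Heuristic fitting

The objective is piecewise smooth with many local minima and a degree of
parameter redundancy (b_f, c_f and F\* trade off against each other), so
fitting uses two phases: Latin-hypercube multi-start (default 200 starts)
screened by objective value, compact simulated-annealing chains from the
best tenth, then global-best particle-swarm refinement of a swarm seeded
from the SA solutions.  The returned optimum never loses to its own seeds
(asserted).  Default parameter boxes are b_f ∈ [−3, −0.01], c_f ∈ (0, 25],
F\* ∈ (0, 200], t₁ ∈ [−60, 120], a_c ∈ [−1, 1], b_c ∈ [−2, 2],
c_c ∈ [−5, 20], C\* ∈ (0, 150] — wide enough for sigmoid forcing functions
with midpoints anywhere plausible and for bell- or trough-shaped chilling.
UniChill fits accept a warm start assembled from UniForc estimates.  SA/PSO
hyper-parameters (cooling schedule, swarm size 30, inertia 0.72, cognitive
and social weights 1.49) are package defaults recorded in the fit metadata.
Tests and the acceptance script run with 20 starts, which recovers
noiseless generators to within rounding (RMSE < 0.5 day) on century-scale
series.

## Bayesian layer

The likelihood treats each observed day as Normal(continuous predicted day,
σ²).  Following the simplifications that tame parameter redundancy, c_f is
fixed at its MLE (and c_c for UniChill, with b_c constrained positive), so
the free parameters are (t₁, b_f, F\*, σ) or (a_c, b_c, C\*, b_f, F\*, σ).
Positivity/negativity constraints are enforced by sampling log-transformed
coordinates with the Jacobian included.  Priors are weakly informative
normals centred on the MLE with sd = 10(|MLE| + 0.1), truncated by the
transforms, and Half-Normal(10) on σ; they are declared stand-ins, recorded
in the output, and the calibration tests (below) are the evidence that they
are weak enough.

The sampler is component-wise adaptive random-walk Metropolis with an
additional adapted joint proposal: during burn-in the per-component scales
adapt toward ~40 % acceptance, and the empirical covariance of the burn-in
history drives a Haario-style joint move (scale 2.38/√d) that mixes through
the strong b_f–F\* correlation far faster than the sweeps alone.  Chains are
independent given the seed; draws are thinned per chain and pooled to
exactly 1000 retained draws.  Default schedules are 10 000 + 50 000
iterations (forcing-only) and 50 000 + 200 000 (chilling+forcing); when the
diagnostics fail the schedule doubles and the chains rerun, up to a
configurable number of extensions.

Diagnostics: Geweke z (first 10 % vs last 50 %), Heidelberger–Welch
(Cramér–von-Mises stationarity on the standardised Brownian-bridge of the
cumulative sums, 5 % critical value 0.461, discarding 10 %-steps up to half
the chain; then the half-width test) and split-R̂ across chains.  The
long-run variance these need is estimated with a Bartlett lag window
(bandwidth ~1.5 n^⅓) rather than an AR fit: an AR estimate diverges on
strongly trending chains, which would mask exactly the non-stationarity the
diagnostics exist to flag.  Calibration is tested by simulation: over 20
synthetic replicates at reduced chain lengths (2 chains × 400 + 1200
iterations, 150 years each — sizes chosen so the whole experiment is a
few minutes), the 95 % credible intervals cover the generating t₁, b_f and
F\* in ≥ 17/20 replicates.

## Projection

Monthly temperature-change samples (n × 12) are added month-wise to a
baseline daily series, one projected series per sample.  Each posterior
draw is paired with a different projected series — index-aligned after
independent seeded shuffles, since nothing ties a particular draw to a
particular climate sample — and the thermal-time model runs forward over
every projected year.  The first year of the baseline is dropped because
its covariates (from the preceding June) predate the series, so a 30-year
baseline yields 29 projected years per member.  Summaries are the median
event day excluding no-event cells, the proportion of cells with no event
by day 250, and quantiles.  Pairwise species order is tallied cellwise
(same member, same year, so climate variability is shared within each
comparison): precedence + reverse + exact ties + any-no-event = 1 exactly.

## Synthetic data

`simulate_temperature` produces T(d) = μ + A·cos(2π(d−φ)/365.25) + ε(d)
with AR(1) ε; defaults μ = 9.5 °C, A = 6.5 °C, φ = day 196, σ = 2 °C,
ρ = 0.7 loosely resemble a maritime temperate climate.  AR(1) rather than
white noise matters: window scans and chilling sums are sensitive to
temporal autocorrelation, and residual first-order autocorrelation is a
known feature of real phenology series.  Event generators invert the two
model classes (window-linear and thermal-time) and add Gaussian observation
noise, reporting integer days because first-observation records are integer
dated; delta generators draw independent Gaussians per month.

What the generators do *not* emulate: weather persistence beyond lag one,
the annual cycle of temperature variance, observation biases of historical
recorders (recorder changes, rounding to named days), cross-month
correlation in climate-change deltas, and any daily structure of a weather
generator.  Passing tests therefore demonstrate correctness of the
inference machinery under the stated generating processes, not robustness
to every pathology of real records.

## Numerical details and degenerate inputs

Logistic exponents are clipped at ±700 before exponentiation; window scans
skip zero-variance candidate windows and fail only when *no* candidate has
variance; `regression_aic` rejects RSS ≤ 0; PSR at λ = 0 with more basis
functions than years raises rather than silently pseudo-inverting; the
precedence tally counts exact ties separately (probability ~0 for
continuous predictions, but meaningful for degenerate test inputs); MCMC
diagnostics on chains shorter than 50 samples are reported as undetermined
rather than computed from meaningless spectral estimates.

## Known limitations

Sequential chilling→forcing is the only arrangement implemented (no
parallel accumulation, no photoperiod term).  The heuristic optimiser
carries no global-optimality guarantee; the multi-start envelope and
generative-recovery tests are the practical evidence.  Parameter
redundancy means individual mechanistic parameters are less well identified
than their joint predictions — recovery tolerances (median |ΔF\*| < 15 %,
|Δt₁| < 5 days across noisy replicates) reflect that, and posterior
predictive checks are the more trustworthy summary.  The AIC convention's
incomplete charge for exhaustive window search is documented above.
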