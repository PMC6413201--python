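# Methods

`meatrisk` implements two linked Monte Carlo microsimulation models that
quantify the trade-off at the heart of a food-risk communication campaign:
the health benefit of reduced processed-meat consumption (fewer colorectal
cancer cases) against the health cost of the demand shock it may cause in
the processed-meat industry (excess mortality among displaced workers).

## 1. Consumption-shift model (colorectal cancer)

### Data model

The model is parameterized by a cohort follow-up table stratified by daily
processed-meat intake: five contiguous strata (<10, 10–20, 20–40, 40–80,
≥80 g/day), each with accumulated person-years and incident colorectal
cancer (CRC) cases. The bundled table carries the published stratum case
counts (232, 256, 402, 318, 121; 1,329 in total) and the published cohort
total of 2,279,075 person-years. **The per-stratum person-year split was
never published**; the bundled file allocates the total by an assumed
vector and says so in the file. Every quantitative claim made by the tests
therefore rests either on synthetic tables with known truth or on
allocation-free quantities (the pooled rate 1,329 / 2,279,075 ≈ 5.83 per
10,000 person-years).

### Rates and risks

Per-stratum incidence rates are maximum-likelihood rates for a Poisson
process over exposure:

    rate_s = cases_s / person_years_s          [cases per person-year]

and the per-person annual risk used for binomial sampling is

    risk_s = 1 − exp(−rate_s)

which keeps risks valid probabilities; at cohort magnitudes (~6×10⁻⁴) the
difference from the raw rate is below 0.03%. Because rates are per
person-year, projecting a single calendar year onto N people needs no
further time scaling.

### Scenarios and projection

A shift scenario moves a fraction r of the consumers in the source strata
(by default every stratum with lower bound ≥ 40 g/day, reflecting the
assumption that only high-level consumers change behaviour) into a single
destination stratum (default: the adjacent 20–40 g/day stratum — the most
conservative behavioural move; both are configurable because no published
value exists). The operation is mass-conserving: source fractions scale by
(1 − r), the removed mass lands in the destination, the population total is
unchanged.

Expected yearly cases in a population are Σ_s N·f_s·risk_s; the expected
scenario benefit is the baseline-minus-shifted difference, which is exactly
linear in r.

### Simulation

Per Monte Carlo draw, baseline cases are a sum of independent per-stratum
binomials Binom(N_s, risk_s) on the baseline population, scenario cases the
same on the shifted population, and the draw is their difference. Stratum
counts are made integral by largest-remainder rounding so totals are
preserved and a null scenario cancels exactly under paired draws. Draws are
independent between baseline and scenario by default (`paired_draws=False`):
with common random numbers a small scenario could never produce an interval
spanning zero, whereas the observed behaviour of this class of analysis
(weak scenarios non-significant, strong ones significant) requires it.
Paired draws remain available for variance-reduction experiments.

### What is deliberately not reproduced

The published absolute results of this model (a baseline of ~289,000 yearly
cases and reductions of 406–2,087 cases) depend on three inputs that were
never released: the per-stratum person-years, the 2010 population's stratum
distribution, and the destination of shifted consumers. The published
reductions are also strongly sub-linear in scenario size while the stated
model is linear; no mechanism for that is given, and none is guessed here.
The model is therefore validated structurally: mass conservation, identity
at zero shift, closed-form/simulation agreement, exact small-instance
enumeration, and monotonicity in scenario size, all on synthetic inputs.

## 2. Job-displacement model (excess mortality)

### Displacement counts

Displaced workers under an employment-loss scenario ℓ:

    n(ℓ) = sector_total × processed_share × ℓ

with the published workforce (1,000,000 employees, 54.2% in processed
meat), giving 542–5,420 workers across the scenario grid ℓ ∈ {0.1%, 0.3%,
0.6%, 1%}.

### Calibration

The published grid reports, for five causes of death (all-cause, malignant
neoplasm, circulatory, suicide, alcohol-related), the expected number of
deaths in the 4 years after job loss with 95% intervals, at each scenario.
Each cell's mean and endpoints divided by n(ℓ) give a per-worker excess
probability with uncertainty quantiles:

    p_mean = mean/n,  p_q025 = lo/n,  p_q975 = hi/n

Lower quantiles may be negative: the excess is a difference against a
counterfactual. Calibration uses the −1% column (largest magnitudes, least
relative rounding); the published grid is exactly linear in n across
columns, so any column yields the same probabilities up to its own printed
rounding (cross-checked to 0.23% relative). Note that up-projecting from a
small column magnifies that rounding by the scenario ratio — reproduction
to ±0.02 of the printed cells holds when calibrating from the −1% column,
which is how the package does it.

### Projection and simulation

The deterministic projection is linear: mean and endpoints are n × the
calibrated probabilities. This matches the published grid's exact linear
scaling, which also implies the published intervals carry parameter
uncertainty only (a per-worker binomial component would grow as √n and
break linearity).

The Monte Carlo projection is second-order. Per draw an excess probability
e is sampled from Normal(p_mean, σ) with σ = (p_q975 − p_q025)/(2 × 1.959964)
— a normal uncertainty distribution is consistent with the symmetric,
linearly scaling, sign-crossing published intervals. Two sampling levels
are exposed:

- `worker_level=True` (default): the draw simulates the cohorts,
  Binom(n, clamp(baseline_p + e, 0, 1)) − Binom(n, baseline_p), a
  treated-minus-counterfactual difference whose draws and intervals can be
  negative. `baseline_p` (default 0.03 over 4 years, configurable, an
  assumption — the counterfactual level is not published) only feeds this
  second-order noise term; it does not move means or deterministic
  intervals.
- `worker_level=False`: the draw is n·e, parameter uncertainty only. Its
  percentile interval converges to the deterministic projection (observed
  within ~0.5% at n = 5,420 and 10,000 draws).

At n = 5,420 the worker-level binomial noise (sd ≈ 24 deaths for the
all-cause spec) is not negligible against the parameter sd (≈ 54 deaths):
it widens the 95% interval by roughly 9%. Consistency with the published
intervals is therefore a statement about the parameter-level component;
the worker-level interval is checked to be at least as wide. A second
caveat: the published suicide and alcohol intervals are asymmetric around
their means (e.g. suicide −1%: mean − lo = 113.2, hi − mean = 99.3), which
a symmetric parameter distribution reproduces in width and centre but not
endpoint-by-endpoint.

The 4-year horizon is a labeled constant; no per-year decomposition is
attempted.

## 3. Monte Carlo engine

`run_mc` draws through one `numpy` `SeedSequence` spawned into an
independent substream per draw index: results are bit-reproducible under a
fixed seed and the first k draws are unchanged when more draws are
requested. Credibility intervals are equal-tailed empirical percentile
intervals with the "linear" sample-quantile convention (linear
interpolation between order statistics; the convention is stated because
quantile conventions differ across tools). Agreement with an independently
coded sort-and-interpolate oracle is exact up to floating-point rounding
(~1 ULP; `numpy`'s internal lerp reorders the arithmetic). Reported
defaults: 10,000 draws, 95% level. The Monte Carlo standard error sd/√n is
available for diagnostics.

Interval calibration is checked as estimation coverage: a replicate
observes one Binomial(n, p) count, propagates the estimate's sampling
uncertainty through normal parameter draws, and takes the percentile
interval of the implied mean; across replicates the true mean must be
covered at the nominal 95% rate (Wald-type behaviour, ≈95% at n = 500,
p = 0.3).

## 4. Synthetic data and recovery

The generator emulates the structure the analyses assume, with defaults
fixed at study-like magnitudes: five intake strata, person-year allocation
(0.25, 0.22, 0.28, 0.17, 0.08), true rates (4.1, 5.1, 6.3, 8.2, 6.6) ×10⁻⁴
per person-year — a rising dose-response with a pooled rate matching the
published 5.8×10⁻⁴ — and workforce risks at the calibrated magnitudes
(baseline 0.03, all-cause excess 0.0502, down to 0.0028 for
alcohol-related). Cohort cases are Poisson against allocated person-years
(exposure-based, standard for rare events; indistinguishable from binomial
at these rates). Workforce outcomes are treated/counterfactual binomial
pairs, independent across causes — a simplification (real causes are
mutually exclusive) consistent with the row-wise structure of the published
grid.

What the generator does not emulate: age/sex/country structure,
longitudinal consumption trajectories, competing risks, re-employment
dynamics. Passing recovery tests therefore demonstrate internal consistency
of estimator and generator at realistic magnitudes, not validity of the
published analysis on real populations.

Recovery behaviour at the defaults: a 10⁷-person-year cohort gives the
sparsest stratum ~500 expected cases, so a single cohort's rate error has
sd ≈ 4.4%; the recovery claim (< 5% relative) is about the expected error
and is evaluated over replicate cohorts (mean error ~3.5%). The per-worker
excess probability from 10⁵ displaced workers is covered by its nominal 95%
Wald interval at ≈95% across replicates.

## 5. Numerical and design choices

- Quantile convention: linear interpolation (above); ties need no special
  handling.
- Counts validate as non-negative integers at read time; probabilities as
  reals; every domain type validates eagerly and names the offending field.
- Configs are YAML blocks (`strata`, `population`, `workforce`, `risks`,
  `rr`, `scenarios`, `mc`); unknown keys warn, missing required blocks
  error by name; risks may be given as per-worker probabilities or as
  published reference cells calibrated at read time.
- Degenerate inputs: a zero-spread risk spec collapses the simulation to a
  single binomial; zero workers/persons give exact zeros; a zero-reduction
  scenario is the identity and has zero variance under paired draws.
- Problem sizes used by the test-suite and the reproduction script: 10,000
  draws per simulation (the analysis default), 500 replicates for engine
  coverage (400 draws each), 10 replicate cohorts of 10⁷ person-years, 200
  replicate workforces of 10⁵ workers.
- The relative-risk engine (risk × RR^(Δg/50), clamped to [0, 1], RR = 1.18,
  95% CI 1.10–1.28 per 50 g/day) is an alternative scenario engine for
  settings without stratified rates; it is not used by the calibrated
  models.

## 6. Known limitations

- The consumption-shift model's absolute outputs are only as good as the
  supplied population and exposure split; with the published inputs missing
  these must be user-supplied or synthetic, and the bundled defaults are
  labeled assumptions.
- The normal parameter distribution for excess mortality is one of several
  consistent with the published intervals; it cannot reproduce their slight
  asymmetry.
- Cause-specific projections ignore competing risks and sum to more than an
  all-cause projection would under exclusivity; the published grid has the
  same property.
- `baseline_p` is an assumption affecting only worker-level interval width.
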