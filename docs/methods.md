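# Methods

## The conformity criterion

The package decides whether a room's annual average radon concentration
C_AA is below a reference level C_RL from a measurement C(t) of duration
t ∈ [2 days, 1 year] via

    C(t) · [1 + √(U_V(t)² + U_D²)] < C_RL,       strict inequality.

The bracket inflates the measurement to a ~95%-confidence upper bound on
the annual average. Temporal variability and instrumental error are
physically independent, so their relative expanded uncertainties combine in
quadrature. Ties (upper bound exactly at C_RL) report *not demonstrated*;
the rule is one-sided and its negation is never read as proven exceedance.
Decision accuracy is ultimately bounded by year-to-year variations of
indoor radon (typically 15–20%); decisions carry that note verbatim rather
than any numeric inflation.

## Temporal uncertainty U_V(t)

**Model.** A year-long continuous measurement (YLCM) at registration step h
gives M = round(365·24/h) samples (8760 at 1 h, 2920 at 3 h). Window i of
duration t = w·h is the mean of w consecutive samples starting at sample i,
indices wrapped circularly past the year end. Circular wrapping is a
deliberate convention: it is the only windowing that keeps all M windows per
interval and conserves the annual mean exactly, and both properties anchor
the deviation statistics (every transformed array has mean C_AA, so
deviations are centred by construction). The deviation of window i in room
j is D_ij(t) = C_j^AA / C_ij(t) − 1, and

    U_V(t) = 95th percentile of {D_ij(t)}, pooled over all rooms.

Pooling across rooms (rather than per-room curves enveloped afterwards)
follows the definition of the percentile over *all* deviations in a
representative sample; the estimator is a pure function of the pooled
multiset.

**Percentile convention.** The percentile is the nearest-rank order
statistic, sorted_D[ceil(0.95·n)] (1-based), with no interpolation. This
makes the in-sample exceedance guarantee exact: at most 5% of pooled
deviations lie strictly above U_V, hence the false-negative rate of the
criterion at C_RL = C_AA with a perfect device is ≤ 5% by construction, not
asymptotically. The estimate is clipped below at 0 (degenerate pools can
have a negative 95th percentile; U_V enters the criterion as a magnitude).
The percentile runs over the full signed distribution — negative deviations
simply never reach the upper tail.

**Numerical conventions.** Windowed concentrations ≤ 0 are floored at
0.1 Bq/m³ (configurable) before forming ratios. Pools smaller than 20
values per interval are flagged low-confidence in the log but still
evaluated. Records with ≤ 5% missing samples are accepted after linear
interpolation over the gaps (circular across the year boundary); more is
rejected as an incomplete YLCM.

**Conservative defaults.** Without an ensemble, built-in values
U_V(2 d) = 1.0 and U_V(7 d) = 0.7 apply, interpolated linearly in log t
between knots and extrapolated as a constant beyond the last knot.
Log-linear interpolation matches the concave decay of temporal uncertainty
on a log-duration axis and overestimates between sparse knots — the
conservative direction. Durations below 2 days are rejected as spot
measurements (temporal uncertainty above 200% and uncontrolled). Richer
tables transcribed from monitoring studies can be supplied as CSV
(`duration_hours,uv`); only the two text-anchored knots ship as built-ins.

**Eligibility screen.** Rooms feeding a U_V study must show an elevated
annual average (default threshold 50 Bq/m³, the inclusive lower end of the
recommended 50–70 range; configurable), exceed the outdoor concentration at
least five-fold, be occupied ≥ 6 h/day, and have operated in a regular mode
all year. Missing metadata produces a warning and a permissive default
rather than a rejection; mode regularity is metadata-declared, never
inferred from the data.

## Instrumental uncertainty U_D

For counting devices (continuous monitors, charcoal, electret),
C = (r_g − r₀)/ε with r_g = n_g/t, r₀ = n₀/t₀, and the GUM-style
propagation with Poisson rate uncertainties u(r) = √n/t = √(r/t) gives

    U_D = k·√[ (r_g/t + r₀/t₀)/(r_g − r₀)² + u_rel²(ε) ],   k = 2.

The first term is the random (counting) component, vanishing with duration;
u_rel(ε) is a single catch-all systematic (calibration, humidity, dust,
ageing, fading) that is not decomposed further. For track-etch devices
(SSNTD, retrospective CD/DVD) the observable is total etched tracks:
C = (n_g − n₀)/(ε·t) and

    U_D = k·√[ (n_g + n₀)/(n_g − n₀)² + u_rel²(ε) + u_rel²(t) ],

where u_rel(t) is the exposure-duration uncertainty — zero for a deployed
detector with a logged exposure, a free input for discs of imprecisely
known age. The k = 2 ≈ 95% reading rests on the normal approximation of
large-count Poisson statistics; the Monte-Carlo coverage experiment in the
test suite verifies ≈95% empirically.

Counts with times are the canonical input (the Poisson terms need them);
rates with explicit standard uncertainties are accepted alternatively. A
net signal ≤ 0 yields C = 0 with a below-background flag and an undefined
(infinite) relative uncertainty. No detection-threshold or decision-limit
machinery is implemented: under this criterion a low concentration never
needs accurate measurement, so those device characteristics are moot.

## Duration planning

`plan_duration` projects the criterion forward: for each candidate duration
it evaluates U_V from the same curve used for assessment and U_D from the
device's *expected* counts at the projected concentration (expected gross
rate ε·C + r₀; no sampling), and returns the smallest candidate whose
projected upper bound clears C_RL. Projections use exactly the assessment
rule, so a plan is internally consistent with the decision that follows it.
A projected concentration too close to (or above) the reference level is
reported not-resolvable rather than assigned a duration.

## The synthetic-data generator

No public YLCM repository exists, so every statistic is validated
closed-loop on simulated rooms:

    C(τ) = C_AA · seasonal(τ) · diurnal(τ) · exp(z_τ),

with seasonal(τ) = 1 + a_s·cos(2π(τ − τ_winter)/8760) peaking mid-January,
diurnal(τ) = 1 + a_d·cos(2π(τ − 3 h)/24) peaking at night, and z an AR(1)
process on the log scale with stationary standard deviation σ. Defaults —
a_s = 0.5, a_d = 0.3, σ = 0.4, AR coefficient 0.8 per 3-h step (an
autocorrelation e-folding of ≈13 h), annual means 50–1000 Bq/m³ — describe
a typical naturally ventilated room in a "normal" operation mode. The
"closed" preset (windows and doors kept shut) uses a_s = 0.8, a_d = 0.5,
σ = 0.5: amplitudes are raised as far as the multiplicative profile allows
while staying strictly positive (literally doubling the seasonal amplitude
would zero the profile). The series is rescaled at the end so the realized
annual mean equals the target exactly; all outputs are pure functions of
(config, seed).

The generator reproduces the features the statistics depend on — positive,
right-skewed concentrations, a dominant seasonal cycle, a diurnal cycle
that vanishes under daily averaging, short-range autocorrelation — and the
estimated U_V(t) on simulated ensembles decays steeply below 2 days and
flattens beyond 14 days, as observed curves do. It does not emulate
weather-driven episodes, occupancy schedules, mechanical ventilation or
inter-room correlation, so passing closed-loop tests demonstrates the
correctness of the estimators and the exactness of the ≤ 5% false-negative
construction, not the real-world magnitude of U_V; real curves must come
from monitoring campaigns.

The counting simulator draws n_g ~ Poisson((ε·C + r₀)·t),
n₀ ~ Poisson(r₀·t₀) per replicate, which makes the k = 2 coverage of the
expanded uncertainty directly measurable.

## Problem sizes and determinism

The shipped experiments use desk-scale sizes chosen to make the statistics
sharp while keeping a full run comfortably interactive: 10–12 rooms at a
3-h step (M = 2920) for ensemble statistics and 10⁴ replicates at expected
gross counts around 10⁴–10⁵ for coverage (Monte-Carlo standard error on a
95% coverage estimate ≈ 0.2 pp). All randomness flows through explicit
integer seeds; there is no global random state, and identical inputs give
bit-identical outputs, including CSV files written by the CLI.

## Known limitations

* U_V is treated as a universal function of duration; covariate modelling
  (climate, geology, building type) needs far larger YLCM samples and is
  out of scope.
* Whole-building roll-up from multiple rooms is not attempted; the unit of
  assessment is the room.
* Detector physics (charcoal adsorption kinetics, electret discharge) is
  abstracted into the (ε, background, u_rel(ε)) scheme.
* Durations use a 365-day year and 30-day months; calendar effects (leap
  years, DST) are ignored by design.
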