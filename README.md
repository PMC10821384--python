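# radonmetry

Conformity assessment of indoor radon against a reference level, with
explicit propagation of the two uncertainties that dominate any radon test:
the **temporal uncertainty** of indoor radon itself and the **instrumental
uncertainty** of the measuring device.

## Who this is for

Radon testing decides whether a room's *annual average* radon concentration
C_AA lies below a normative reference level C_RL (typically 100–300 Bq/m³;
the US regulates via an Action Level of 4 pCi/L = 148 Bq/m³). But tests run
for days to months, not a year, and indoor radon varies strongly over time —
so a short measurement C(t) is an uncertain proxy for C_AA. This package is
for measurement practitioners, device manufacturers and survey designers who
want a quantitative, auditable decision rule instead of a bare comparison of
C(t) with the reference level.

## The decision rule

A room is judged compliant when

```
C(t) · [ 1 + √( U_V(t)² + U_D² ) ]  <  C_RL        (strict)
```

* **C(t)** — concentration measured over the test duration t (t ≥ 2 days;
  shorter "spot" measurements have uncontrolled temporal uncertainty above
  200% and are rejected outright).
* **U_V(t)** — temporal uncertainty: the 95th percentile (nearest-rank order
  statistic) of the deviations D_ij(t) = C_j^AA / C_ij(t) − 1 between
  windowed measurements of duration t and the annual average, pooled over a
  representative sample of rooms with year-long continuous measurements
  (YLCMs, M = 8760 samples at a 1-h step or 2920 at 3 h). Each YLCM is
  re-read as M overlapping circular windows per integration interval, so I
  intervals yield L = M·I deviations per room. When no sample is available,
  conservative defaults U_V(2 d) = 1.0 and U_V(7 d) = 0.7 apply.
* **U_D** — expanded relative instrumental uncertainty at coverage factor
  k = 2, combining Poisson counting statistics and a systematic calibration
  component: for counting devices
  U_D = k·√[(r_g/t + r₀/t₀)/(r_g − r₀)² + u_rel²(ε)], and for track-etch
  devices U_D = k·√[(n_g + n₀)/(n_g − n₀)² + u_rel²(ε) + u_rel²(t)].

With U_V the nearest-rank 95th percentile, the false-negative rate — a room
judged compliant whose true annual average sits at the reference level — is
at most 5% by construction. The negation is reported as *compliance not
demonstrated*, never as proven exceedance: a failed short test calls for a
longer test (`plan_duration` finds the shortest promising one), not a
verdict.

Because the two components add in quadrature, a cheap device barely hurts a
short test: √(0.7² + 0.4²) ≈ 0.8, so a 40% device inflates the 70% temporal
band of a 7-day test by only a tenth.

## Worked example

A continuous monitor counted n_g = 1000 gross pulses in 10⁴ s against a
background of n_0 = 100 pulses in 10⁴ s, with sensitivity
ε = 9·10⁻⁴ s⁻¹/(Bq·m⁻³) known to 5%:

```sh
$ radonmetry ud --device device.yaml
{
  "U_D": 0.12422599874998833,
  "concentration_bqm3": 100.00000000000001,
  "u_rel_random": 0.03685138655950444,
  "u_rel_systematic": 0.05,
  ...
}
```

The device reports C = (0.1 − 0.01)/9·10⁻⁴ = 100 Bq/m³ with U_D ≈ 12.4%,
split into a 3.7% random (counting) part and the 5% calibration part.
Assessing a 2-day test of 100 Bq/m³ against a 300 Bq/m³ reference level with
the conservative U_V and a deliberately pessimistic U_D = 0.4:

```sh
$ radonmetry assess -c 100 -t 2d --rl 300 --uv-source conservative --ud 0.4
{
  "status": "compliant",
  "U_V": 1.0,
  "U_D": 0.4,
  "combined_expansion": 1.0770329614269007,
  "upper_bound_bqm3": 207.70329614269008,
  "margin_bqm3": 92.29670385730992,
  ...
}
```

The 95%-confidence upper bound on the annual average, 100 × 2.077 ≈ 208
Bq/m³, sits 92 Bq/m³ below the reference level: compliance is demonstrated
after two days even with a 40% device. The same library surface is available
in Python (`radonmetry.assess`, `radonmetry.measure_counting`,
`radonmetry.TemporalUncertaintyEstimator`, ...); the transformer and the
U_V estimator follow scikit-learn fit/transform/predict conventions.

Other subcommands: `simulate` (synthetic YLCM series with seasonal, diurnal
and autocorrelated lognormal structure), `uv` (estimate the U_V(t) curve
from YLCM CSV files), `plan` (smallest test duration expected to yield a
decision).

## Documentation

See `docs/methods.md` for the statistical model, the simulator, numerical
conventions and known limitations.
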