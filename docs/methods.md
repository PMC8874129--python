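# Methods

## The rate–temperature model

At a constant forcing temperature *T* in the sub-optimal range, the
development rate of a floral bud population toward bud break is modelled
as linear in temperature:

    D(T) = (T − T_b) / θ,

where D is the reciprocal of the hours needed to reach a 0.5 bud-break
fraction, T_b is the base temperature (°C) at which development
extrapolates to zero, and θ is the thermal-time requirement (°C·h). A
simple OLS regression D = mT + b over the forcing temperatures inverts the
model exactly: T_b = −b/m and θ = 1/m. The model assumes (a) linearity of
rate in temperature over the forcing range used, and (b) that the 0.5
bud-break quantile is a representative developmental milestone. T_b is
reported as *apparent* because every fit extrapolates below the lowest
forcing temperature; linearity down to T_b is an assumption, not an
observation.

Forcing temperatures default to the five measured chamber means 11.8,
13.6, 15.9, 17.8 and 20.1 °C; measured means, not set points, are the
regressors wherever both exist.

### Hours to 0.5 bud break

The bud-break fraction is cumulative opened buds over the initial bud
count; it is non-decreasing by construction because opened buds are
removed at each observation in the protocol this package targets. The
crossing time is linearly interpolated between the first pair of
observations bracketing 0.5 (first-crossing rule, robust to malformed
input even though crossings are unique for valid data); an observation
exactly at 0.5 returns its own time; if the first observation already
exceeds 0.5 the origin (0 h, fraction 0) is the lower bracket. A
combination that never reaches 0.5 yields no rate point and is excluded —
a valid experimental outcome, not an error.

### Fit requirements and diagnostics

- A fit needs at least **3** included temperatures (up to 5 are used).
  Three is the smallest count leaving a residual degree of freedom for R²
  and interval estimates; accessions with fewer completing treatments are
  excluded with a machine-readable reason.
- A non-positive slope has no positive thermal time; such fits are marked
  `invalid_slope` rather than raising, so cohort runs complete.
- 95% CIs for T_b = −b/m and θ = 1/m are computed by **parametric
  residual bootstrap** (default 1000 seeded resamples, percentile
  intervals, vectorized) because both quantities are nonlinear in (m, b).
  Bootstrap resamples with non-positive slope are discarded; if almost all
  resamples are degenerate the interval is reported as NaN. A first-order
  delta-method variant (`delta_method_cis`) is provided as a cross-check;
  with 3 residual degrees of freedom its t-based intervals are wider than
  the effectively normal bootstrap percentiles by roughly
  t₀.₉₇₅,₃/z₀.₉₇₅ ≈ 1.6, which the tests assert as a consistency band.

### The cross-accession curve

Apparent T_b and θ are negatively related across accessions; the package
fits T_b = a + c·ln θ by OLS of T_b on ln θ. The regression direction was
an open choice; this orientation reproduces the five canonical trait
combinations (7.3 °C, 3000 °C·h), (4.2, 5000), (2.2, 7000), (0.6, 9000),
(−0.6, 11000) to within 0.05 °C at θ = 7000, so it is the default; users
whose data favor the inverse regression can fit it themselves from the
fits table. The curve is used to place hypothetical trait combinations
"on the line" for simulation scenarios (`build_scenarios`).

## The chill-then-heat simulator

The phenology engine is strictly sequential, with no chill/heat overlap:

1. **Chill hours** accumulate from the 01 October season start as whole
   hours with temperature strictly below 7.2 °C (the classic chill-hour
   model). Strict inequality is a deliberate tie-break: the boundary is
   measure-zero in real data.
2. At the first hour where the running total reaches a threshold (500,
   750 or 1000 h), **GDH accumulation** begins: each hour contributes
   max(T − T_b, 0) °C·h. By default heat starts at the exact
   threshold-crossing hour; a `midnight` dialect instead starts at 00:00
   of the crossing day (a shift of < 1 day, exposed as
   `--gdh-start {hour|midnight}` because day-level definitions are common
   in the field).
3. **Bud break** is the first hour at which accumulated GDH reaches θ.
   Seasons end 30 June; non-completion is reported as absent, never
   extrapolated. Seasons whose chilling threshold is never met are
   omitted from comparisons, with a log notice.

Hourly values are credited at the end of their hour, so at constant
temperature the predicted interval is ceil(θ/(T − T_b)) hours — within one
hour of the continuous closed form, which the tests assert.

Delays are signed fractional days at hourly resolution,
(scenario bud break − reference bud break)/24 h. Per station × threshold ×
scenario cell the summary reports median/min/max delay over completing
seasons and a two-sided Wilcoxon signed-rank p-value of the paired
per-season delays against zero. The signed-rank test is an assumption
(paired, symmetric-under-null shifts); it is reported as a convenience,
not a core model output.

## Weather handling

Raw hourly tables (`simple_csv` or NOAA ISD-Lite dialect; ISD-Lite
temperatures are tenths of °C with −9999 as missing) are sorted,
sentinel-cleaned, then regularized: readings in clock hour [h:00, h+1:00)
are averaged into hour h; within each dormancy season (01 Oct–30 Jun) the
grid runs from the first to the last observed hour; missing runs of at
most `max_gap_h` hours (default 6) are linearly interpolated in time and
flagged imputed. A season with any longer gap, or more than 5% imputed
hours, is flagged invalid and refused by the simulator — mirroring
station selection by record completeness. Off-season (July–September)
hours are dropped. All timestamps are local standard time with no
daylight-saving shifts: accumulations are sums, so a fixed offset is
immaterial, but mixed conventions would corrupt season boundaries.
Regularization is idempotent, and previously assigned imputation flags
and invalid seasons are preserved.

## Synthetic data: what it emulates and what it does not

**Forcing generator.** Bud *i* at temperature *T* opens when elapsed heat
(T − T_b)·t reaches a personal threshold θᵢ drawn log-normal with median θ
and coefficient of variation `theta_cv` (default 0.15). Any smooth
positive threshold distribution yields the sigmoidal cumulative curves
seen in forcing experiments; log-normal keeps thresholds positive. Counts
are read off an observation grid starting 24 h after setup with a default
48-h spacing (a `(48, 48, 72)` pattern reproduces strict Mon/Wed/Fri
visits), continuing three intervals past the last opening to emulate the
no-change-for-three-visits stopping rule. Defaults — 125 buds (within the
100–150 per combination typical of such experiments), five temperatures,
48-h visits — are the study conditions the estimator is validated under:
with 200 seeded replicates the median |T_b error| is well under 1 °C and
the median relative θ error under 10%.

**Weather generator.** T(t) = annual sinusoid (minimum 15 January) +
diurnal sinusoid (minimum 05:00) + stationary AR(1) noise with marginal
SD `noise_sd_c`, emitted per season. Defaults (mean 15.5 °C, annual
amplitude 9 °C, diurnal amplitude 5 °C, φ = 0.8, SD 3 °C) approximate a
southeastern US piedmont winter and give ~1400–1500 chill hours per
season, so all three chilling thresholds are regularly met.

Neither generator models synoptic warm spells, frost events, bud death
under prolonged forcing, or chill negation; passing tests therefore
demonstrate correctness of the estimation and accumulation machinery
under the stated generative model, not fidelity of any particular real
station-winter or orchard. The chill-hour model itself ignores negation
by warm temperatures and is known to be coarse in warm climates; Utah and
Dynamic models are out of scope here.

## Numerical choices and degenerate inputs

- OLS is computed by the closed-form centered normal equations; tests pin
  it to an independent matrix-solve oracle at 1e-10 relative.
- Exact observation at a 0.5 fraction short-circuits interpolation,
  avoiding 0/0 when consecutive fractions are equal at 0.5.
- Zero-variance inputs to correlation or the bloom-trend regression raise
  rather than return NaN.
- All randomness (bootstrap, generators, cohort runs) flows from explicit
  integer seeds; per-accession bootstrap seeds are spawned from the
  top-level seed, so cohort outputs are byte-reproducible.

## Problem sizes used in validation

The default validation suite uses 200 estimation replicates of 5 × 125
buds, 10–30 synthetic seasons (each ≈ 6550 hours) for simulation checks,
and 1000 bootstrap resamples per fit; the acceptance script uses a
40-accession cohort and 30 seasons. These sizes give stable medians while
keeping a full run in seconds.

## Known limitations

- Apparent T_b is an extrapolation; curvature below the lowest forcing
  temperature would bias both T_b and θ, and θ for very low T_b
  accessions should be read as a minimum.
- The logarithmic T_b–θ curve is descriptive, not mechanistic, and is
  fitted in one direction only.
- The simulator's sequential chill/heat switch ignores partial overlap of
  the two processes and any photoperiod effect.
- External station reproduction requires pre-downloaded ISD-Lite files;
  no network retrieval is included, and gap-handling details of any
  particular historical analysis can shift external results by around a
  day.
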