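# budforce

Thermal-time analysis of floral bud break in temperate fruit trees
(developed around peach, *Prunus persica*), for phenology modellers and
breeders interested in heat-requirement traits.

Bud break in spring is gated by two sequential temperature requirements: a
**chilling requirement** (CR, here counted as hours below 7.2 °C) that
releases dormancy, and a **heat requirement** (HR) — the thermal time that
must then accumulate as warmth before buds open. The HR has two trait
dimensions: the **base temperature** T_b at which development stalls, and
the **thermal time** θ (in °C·h) needed above it. `budforce` provides both
halves of the analysis:

1. **Estimation.** At a constant forcing temperature *T*, the development
   rate (reciprocal hours to a 0.5 bud-break fraction) follows

   D = (T − T_b) / θ

   so an OLS regression of rate on temperature, D = mT + b, gives the
   *apparent* base temperature as the x-intercept, T_b = −b/m, and the
   thermal time as the reciprocal slope, θ = 1/m. ("Apparent" because T_b
   lies below the lowest forcing temperature and is reached only by
   extrapolation.) Per-accession fits come with R², seeded bootstrap 95%
   CIs, and exclusion reporting for accessions that never reached a 0.5
   bud-break fraction. The cross-accession trend is summarized by the
   logarithmic curve T_b = a + c·ln θ.

2. **Simulation.** Given hourly station weather (or the built-in synthetic
   weather generator), the simulator accumulates chill hours (T < 7.2 °C)
   from 01 October, then growing degree hours GDH = Σ max(T − T_b, 0) from
   the hour a chilling threshold (500/750/1000 h) is met, and reports the
   bud-break date shift of alternative (T_b, θ) trait combinations against
   a reference, per season and threshold.

Seeded generators for forcing experiments (per-bud log-normal thresholds
producing the familiar sigmoidal bud-break curves) and for winter weather
(annual + diurnal sinusoids with AR(1) noise) make every stage testable
without external data.

## Worked example

Generate a synthetic forcing experiment with known traits
(T_b = 4 °C, θ = 5000 °C·h), then estimate them back:

```bash
budforce generate forcing --tb 4 --theta 5000 --cv 0.15 --seed 11 --out forcing.csv
budforce estimate --forcing forcing.csv --out-fits fits.csv
```

```
accession  n_points      m       b  tb_c  theta_ch     r2  tb_lo  tb_hi  theta_lo  theta_hi status
   SYN001         5 0.0002 -0.0007 3.813 5124.5454 0.9988 3.2901 4.2549 4941.5202 5340.3448     ok
```

The fit recovers the truth to 0.19 °C and 2.5% from 125 buds observed
every 48 h at five forcing temperatures; `tb_lo … theta_hi` are bootstrap
95% CIs and both cover the true values.

Simulate trait scenarios over ten synthetic winters against the reference
combination (2.2 °C, 7000 °C·h):

```bash
budforce generate weather --seasons 10 --seed 3 --out weather.csv
printf 'tb_c,theta_ch\n-0.6,11000\n2.2,7000\n7.3,3000\n' > scen.csv
budforce simulate --weather weather.csv --scenarios scen.csv \
    --reference 2.2,7000 --out sim.csv --summary summary.csv
```

```
station_id  chill_threshold_h  tb_c  theta_ch  n_seasons  median_delay_days  min_delay_days  max_delay_days  wilcoxon_p
   weather                500  -0.6   11000.0         10              2.583           2.125           3.375       0.002
   weather                500   2.2    7000.0         10              0.000           0.000           0.000         NaN
   weather                500   7.3    3000.0         10              8.812           7.667          11.625       0.002
   weather                750  -0.6   11000.0         10              3.229           2.417           3.917       0.002
   weather                750   2.2    7000.0         10              0.000           0.000           0.000         NaN
   weather                750   7.3    3000.0         10              4.042           2.625           5.917       0.002
   weather               1000  -0.6   11000.0         10              4.312           3.500           4.875       0.002
   weather               1000   2.2    7000.0         10              0.000           0.000           0.000         NaN
   weather               1000   7.3    3000.0         10              0.312          -0.792           1.417       0.195
```

`median_delay_days` is the median bud-break shift in days relative to the
reference (positive = later): the low-T_b/high-θ combination delays bud
break by ~2.5–4.5 days across chilling thresholds, while the
high-T_b/low-θ combination is far more variable season to season. The
reference row is the identity check (all zeros); `wilcoxon_p` is a paired
signed-rank test of the per-season delays against zero.

Real station data in the NOAA ISD-Lite format is read with
`--dialect isd_lite`; records are regularized to one value per clock hour
with short gaps interpolated and gappy seasons excluded.

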