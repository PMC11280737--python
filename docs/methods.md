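# Methods

## Scope and model

`ptewater` assesses trace-element pollution and drinking-water health
risk for a sample-by-element concentration table (μg/L). Two models are
chained:

1. **Pollution indices.** Single-factor index `I_i = M_i / S_i` against
   the Chinese Class III groundwater thresholds (GB/T 14848—2017), and
   the per-sample Nemerow composite `NI = sqrt((I_max² + I_mean²)/2)`,
   which up-weights the worst element so that one badly polluted
   element cannot be averaged away. `NI` always lies between `I_mean`
   and `I_max`. Classification uses the conventional five classes with
   lower-exclusive/upper-inclusive boundaries (a value of exactly 0.7
   is "no pollution").
2. **EPA-style exposure/risk.** Chronic daily intake by ingestion and
   dermal contact, hazard quotients/index for non-carcinogenic effects,
   slope-factor risks for the two carcinogens (As, Cd). The model
   assumes lifetime-averaged, steady exposure through drinking water
   only: no inhalation pathway, no age-interpolated slope factors, no
   RfD uncertainty factors. CR is oral-route only because no dermal
   slope factors exist for As or Cd.

## Units and the single conversion point

All concentrations are μg/L throughout the package; thresholds are
stored in μg/L. The only μg→mg conversion (×10⁻³) happens inside the
two CDI functions. Reference doses are mg/kg/d, slope factors
(mg/kg/d)⁻¹. EF (d/yr) × ED (yr) yields days, consistent with AT in
days — no ×365 appears anywhere.

## Default parameters

| parameter | adult | child | units | role |
|---|---|---|---|---|
| IR | 1.8 | 0.70 | L/d | ingestion rate |
| EF | 350 (180–365, mode 350) | same | d/yr | exposure frequency; triangular in MC |
| ED | 24 | 6 | yr | exposure duration |
| BW | 70.0 | 21.2 | kg | body weight |
| AT (non-carc.) | 8760 | 2190 | d | ED × 365 |
| AT (carc.) | 25550 | 25550 | d | 70-yr lifetime |
| SA | 16600 | 8000 | cm² | skin surface |
| PC | 10⁻³ (Zn 6×10⁻⁴) | same | cm/h | dermal permeability |
| ET | 0.20 (0.13–0.33, mode 0.20) | same | h/event | bathing event time; triangular in MC |
| CF | 0.001 | same | L/cm³ | volume conversion |

A consequence worth knowing: EF·ED/AT(non-carc.) = 0.9589 for both
cohorts, so the child/adult oral HQ ratio is the constant
(0.7/21.2)/(1.8/70) = 1.28407 for every element and concentration.
Deterministic mode uses the EF/ET point values; the triangular ranges
belong to the Monte Carlo layer.

Class III thresholds (μg/L): Al 200, As 10, Cd 5, Cu 1000, Mn 100,
Pb 10, Se 10, Zn 1000. Reference doses and slope factors are the
standard oral/dermal RfD table with SF_oral 1.5 (As) and 6.1 (Cd).

## Synthetic-data generator

The generator emulates a 53-sample arid-basin survey whose per-element
summary statistics (mean, CV, min, max) are shipped as the built-in
preset. Marginals are lognormal, moment-matched in natural space
(`sd_log = sqrt(ln(1+CV²))`, `mean_log = ln(mean) − sd_log²/2`), then
optionally contaminated by multiplicative hotspots (a random subset of
samples multiplied by a constant — a point-source pattern; off by
default), then clipped to the published range. The lognormal family is
a modelling choice: every preset CV exceeds 1 with strong positive
skewness/kurtosis, which a lognormal reproduces, but the true field
distribution is unknown. What the generator does **not** emulate: any
spatial autocorrelation (coordinates are uniform noise), inter-element
correlation (elements are drawn independently, though real sources
correlate them), non-detect censoring mechanics, or measurement error.
Passing tests therefore validate the computational chain under
realistic marginal structure — not distributional claims about any real
aquifer.

Clipping to the observed range biases the moments slightly low; the
moment-recovery tests disable clipping. Because the preset's marginals
are heavy-tailed, the raw sample CV of 10⁵ draws still carries a
sampling SE of several percent (its variance is driven by an excess
kurtosis of order 10²–10³), so recovery of the distribution's mean and
CV is verified through the efficient log-moment estimator (the
lognormal MLE), whose SE at that size is a few tenths of a percent; the
log-moments themselves are checked against the closed forms at 3
standard errors.

## Monte Carlo layer

Stochastic inputs: one concentration per element, EF and ET. The
per-element concentration spec defaults to a lognormal refit (same
moment matching) to the supplied sample table, truncated to the
observed [min, max] via inverse-CDF sampling; zeros (non-detects) are
replaced by half the element's detection limit before fitting
(Se's limit 0.41 μg/L → substitution 0.205). An `empirical` mode
resamples the observed values instead, as a robustness check. BW, IR,
ED, SA, PC, CF are fixed at their point values (no published ranges).

Seeding: one master seed spawns an independent substream per input,
keyed by the input's name (CRC32 into a `SeedSequence`), so adding or
removing an element never perturbs other inputs' draws; the same scheme
seeds the generator's elements. Cohorts share the draws within an
iteration, so cohort comparisons are paired; with all specs degenerate
(point masses) the MC layer reproduces the deterministic engine to full
floating precision, which the tests assert. Default 10,000 iterations
(1,000 samples/10,000 iterations run in roughly a second; the full
pipeline stays well under a minute on one CPU).

## Sensitivity analysis

Contribution of input *i* to an endpoint = `100·|ρ_i|/Σ_j|ρ_j|` with
ρ the Spearman rank correlation against the endpoint draws; the sign is
reported separately, and a squared-ρ (contribution-to-variance) variant
is available. Rank correlation makes the ranking invariant to monotone
rescaling of inputs. Constant inputs get contribution 0 with a warning;
a constant endpoint is an error. At least 100 iterations are required.

Under the built-in preset, the As concentration carries the largest
contribution to both HI and TCR. For TCR the margin is wide (As
dominates Cd by orders of magnitude); for HI it is narrow by
construction — the preset's mean HQ of As (21/0.003) and Se (7/0.001)
are equal, so As leads Se by only a few points of contribution and the
ordering of the two can flip in some random realizations of a 53-sample
survey. Real surveys with genuinely elevated As separate the two far
more sharply.

## Numerical and design choices

- Exceedance against a threshold is strict (`>`); a value exactly at
  the threshold does not exceed.
- Descriptive statistics: SD with n−1 denominator; skewness and excess
  kurtosis as bias-corrected sample statistics; a constant column
  reports sd = cv = 0 and NaN shape statistics.
- The carcinogenic-risk scale is inclusive on the left at each printed
  edge (10⁻⁶, 10⁻⁴, 10⁻³) and exclusive above 0.1: exactly 0.1 is
  "high".
- Samples with a missing element value are excluded from that
  element's summary; their Nemerow index uses the remaining elements
  (logged warning).
- Truncated sampling uses inverse-CDF mapping between the CDF values
  of the bounds — exact, no rejection loops.
- CSV outputs format floats at 6 significant digits; in-memory results
  keep full precision, and the samples-CSV round-trip is exact.

## Known limitations

- Independence of elements in both the generator and the MC layer
  overstates the diversification of HI; correlated sources would widen
  its distribution.
- The lognormal refit inherits the small-sample noise of the input
  table; with 53 samples the fitted CV of a heavy-tailed element is
  itself uncertain by tens of percent.
- No spatial modelling of any kind (no kriging, no index surfaces).
- The deterministic engine assesses mean concentrations; site-by-site
  deterministic risk tables are available by passing single-sample
  contents, but no percentile-of-samples convention is built in.
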