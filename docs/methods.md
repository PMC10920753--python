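# Methods

## Scope and data model

The unit of analysis is a reported mortality record: country, reporting
unit (production site or county), period start date, temporal resolution
(`submonthly` / `monthly` / `yearly`), and a non-negative integer count of
fish lost.  Reporting conventions differ by country and the package keeps
them explicit rather than harmonising them away: sub-monthly records are
binned into their containing month, monthly records are anchored to the
first of the month, yearly records to January 1.  A yearly-native record
can never be aggregated to monthly grain (that would invent precision);
the attempt raises an error.

Aggregation to a regular series treats absence asymmetrically by design:
a period with no extreme events has a **count of zero** (that is genuine
information about frequency), but its **maximum is undefined** and is
emitted as missing — a zero maximum would fabricate a data point.
Frequency trend tests therefore run on count series including zeros;
magnitude trend tests run only on periods with at least one event.

Duplicate records — identical (country, unit, period, fish lost) — are
rejected by default because public collations often double-report events;
an `allow_duplicates` schema flag overrides this for sources where exact
repeats are legitimate.

Per-country analysis windows restrict each country to the years its
collation can be trusted to be comprehensive.  The defaults are
Norway 2012–2021, Canada 2013–2020, UK 2015–2021, and 2013–2021 for
Chile, Australia and New Zealand; all are configurable.

## Top-fraction selection

Jurisdictions define "mass mortality" differently (absolute kg/day,
percentage of stock, annual thresholds), so cross-country comparison uses
an ordinal device instead: within each country the k = ⌈fraction·N⌉
largest events by fish lost, with fraction 0.10 for monthly-or-finer
reporters and 0.50 for yearly reporters (whose ~10 records would not
support a top-10% rule).  Ties at the cutoff are broken deterministically
by earlier period start, then lexicographic unit id, so selection is
reproducible.

## Trend testing

The Mann–Kendall statistic is computed from its pairwise definition with
the classical tie correction in Var(S), the ±1 continuity correction in
the normal deviate Z, and Kendall's τ_b (value ties corrected; the time
index is assumed untied).  All tests are two-tailed at α = 0.05.  A
constant series degenerates to τ = 0, p = 1 rather than an error.  A
deliberately non-seasonal test is used even where seasonality may exist:
unmodelled seasonal variation inflates the denominator and makes the test
conservative, which is the safer direction for claiming trends.

Mann–Kendall assumes serial independence, so every series is screened
first: sample autocorrelations at lags 1..12 (monthly default; capped at
n − 3) are compared against the large-sample two-sided band
±z_{1−α/2}/√n.  The averaging window is 1 plus the longest run of
significant lags starting at lag 1.  If the window exceeds 1 the series
is replaced by means of non-overlapping blocks of that length (trailing
partial block averaged over its actual length), re-screened, and the
procedure iterates up to 5 rounds.  The full averaging trail (windows
applied, original and final n) is recorded on every result so averaged
and unaveraged variants can be audited.  Under an iid Gaussian null the
screened pipeline's empirical type-I error at n = 60 is close to the
nominal 5% (the acceptance suite checks 4–6% over 10,000 replicates).

Lowess (locally weighted linear regression, tricube weights) with default
span 2/3 is provided for plotting trends at monthly and yearly grain; it
never feeds inference.

## Extreme-value estimation

Peaks-over-threshold with a generalized Pareto tail:

- **Threshold.** u is the empirical (1 − top-fraction) quantile under the
  order-statistic (linear-interpolation, "type 7") convention;
  exceedances are strictly above u.  Fewer than 5 exceedances refuse to
  fit, and samples under 10 observations refuse to select a threshold.
- **Fit.** Maximum likelihood in (ξ, log σ) with L-BFGS-B from five
  starts (probability-weighted-moments estimate, perturbations, and an
  exponential start), ξ constrained to [−0.9, 0.95]; a solution on the
  box edge sets a boundary flag.  The ξ → 0 exponential limit of the
  likelihood is handled analytically, and for ξ < 0 the support
  constraint is enforced through a finite penalty so gradients stay
  usable.
- **Risk measures.** VaR_q = u + (σ/ξ)[((n/n_u)(1−q))^(−ξ) − 1] and
  ES_q = VaR_q/(1−ξ) + (σ − ξu)/(1−ξ), evaluated through `expm1`/`log1p`
  so the ξ → 0 limit is exact to machine precision.  q below the
  empirical coverage of u is a domain error (VaR would fall below the
  threshold); ξ ≥ 1 makes ES infinite and is reported as an error, never
  clipped.  Defaults: point estimate ES at q = 0.999, bounds VaR at
  q = 0.999 and q = 0.9999 — the 1/1,000- and 1/10,000-event return
  levels.
- **Basis.** Monthly-or-finer reporters are analysed per event
  (`per_event`); yearly reporters per (unit, year) aggregate loss
  (`per_year`).  Aggregating yearly countries to country-year totals
  instead would leave fewer than ten points and no usable tail, so the
  unit-year basis is the default; it is an explicit configuration choice,
  not an inference.
- **Comparison.** Each estimate carries the arithmetic mean of the
  country's company/county MME thresholds and the ratio ES/threshold.
- An optional nonparametric bootstrap over exceedances (off by default)
  supplies percentile intervals for ξ, σ and ES.

## Synthetic data generator

The generator emulates the statistical skeleton of an MME collation, not
fish biology: per-period event counts are Poisson with latent rate
λ_t = max(λ₀ + β_λ t, 0) · exp(A sin(2πt/12) + ε_t), where ε_t is a
stationary AR(1) process with lag-1 correlation φ and marginal standard
deviation `log_rate_sd`.  Noise lives on the log-rate so counts stay
integer and non-negative; with `log_rate_sd = 0` (the default) counts are
exactly Poisson, which the test suite verifies through the index of
dispersion.  `log_rate_sd` is a separate knob from φ so that φ controls
*correlation* and `log_rate_sd` controls *amplitude*; an AR(1) flag alone
cannot do both.

Magnitudes come from one of two families — the data give no reason to
assert one as true:

- `LognormalMagnitude(mu, sigma)`: a generic heavy-ish tailed body.
- `GpdTailMagnitude(body_scale, tail_shape, tail_scale, tail_fraction)`:
  Uniform(0, body_scale) below the threshold, exactly
  GPD(tail_shape, tail_scale) above it.  Because the exceedance law is
  exact, the mixture's VaR and ES have closed forms (`true_var`,
  `true_es`), giving the end-to-end pipeline an analytic target.

An optional multiplicative trend exp(β_m t) scales magnitudes over time.
Magnitudes are rounded to integer fish (minimum 1); at the fish-count
scales used (10⁴–10⁶) rounding is negligible.  One seed drives two
independent sub-streams (counts, magnitudes), so changing the magnitude
model leaves event times untouched, and a fixed seed reproduces the
table byte for byte.

What the generator does **not** emulate: spatial structure, shared
disease shocks across sites, reporting lags and censoring, changes in
reporting practice over time, and magnitude–frequency dependence.
Passing tests on synthetic data therefore demonstrate the statistical
machinery is correct under its stated assumptions, not that real
collations satisfy those assumptions.

## Problem sizes and tolerances

The test and acceptance workloads were sized to characterise each
property well while staying quick: 10,000 random series for the
Mann–Kendall oracle comparison (exact agreement required), 10,000 null
replicates at n = 60 for the type-I error (4–6% band), 10,000 draws for
GPD parameter recovery (ξ̂ within ±0.05, σ̂ within ±5%), 10⁶ draws for the
Monte-Carlo VaR/ES oracles (2–3% relative tolerance, matched to the
sampling error of a 99th-percentile tail mean), and a 120-month synthetic
country at 45 events/month (≥ 500 tail exceedances) for end-to-end ES
recovery within 15%.  ES at q = 0.999 from ~500 exceedances is inherently
variable — across seeds the relative error ranges from a few percent to
around 20% — which is exactly the uncertainty a practitioner should
expect from a decade of data at this reporting rate.

## Known limitations

- The autocorrelation band is the large-sample white-noise approximation;
  for very short yearly series (n ≈ 9) its power is low and the screen
  will rarely trigger.
- Block averaging before Mann–Kendall shortens the series and costs
  power; the recorded adjustment trail makes the trade-off visible but
  the package does not attempt variance-correction alternatives.
- GPD threshold choice is fixed by the top-fraction rule rather than
  diagnosed (no mean-residual-life or stability plots); this mirrors the
  design being implemented and keeps selection deterministic.
- No parameter uncertainty is propagated into the headline ES unless the
  optional bootstrap is switched on.
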