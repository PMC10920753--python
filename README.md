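# mmerisk

Trend and extreme-value analysis of **mass mortality events (MMEs)** in
salmon aquaculture.

Salmon-farming nations report large die-offs at very different grains —
per production site per month or finer (Canada, the UK), per county per
month (Norway), or only as yearly facility totals (Chile, Australia, New
Zealand).  Two questions matter to regulators, insurers and farm
epidemiologists working with such collations:

1. **Are extreme loss events becoming more frequent and larger?**
2. **How big can a single event plausibly get**, and how does that compare
   with the loss levels companies and counties themselves define as an MME?

`mmerisk` answers both with a reproducible pipeline: event ingestion and
aggregation, top-fraction event selection, autocorrelation-screened
Mann–Kendall trend tests, and peaks-over-threshold extreme-value
estimation — plus a synthetic-data generator so the whole stack is
testable against known truth.

## Methods at a glance

**Trend detection.**  Within each country the top 10% of events by fish
lost (top 50% for yearly reporters, which have too few records) are
selected — a device that stays agnostic to each jurisdiction's MME
definition.  Monotonic trends in the per-period count of these events, and
in the per-period maximum loss, are tested with the Mann–Kendall statistic

S = Σ_{i<j} sgn(x_j − x_i),  Var(S) = [n(n−1)(2n+5) − Σ_g t_g(t_g−1)(2t_g+5)]/18,

with tie-corrected variance, Kendall's τ_b, and a continuity-corrected
normal deviate (two-tailed, α = 0.05).  Because the test assumes
independence, each series is first screened for autocorrelation
(large-sample ±z_{1−α/2}/√n band); where lag-1 dependence is significant
the series is averaged over non-overlapping blocks until the dependence
disappears, and the test runs on the averaged series.  Lowess smoothing is
available for visualisation only.

**Maximum potential loss.**  Event magnitudes above the empirical
(1 − top-fraction) quantile u are fitted to the generalized Pareto
distribution GPD(ξ, σ) by maximum likelihood.  The fitted tail gives the
Value-at-Risk (return level) and Expected Shortfall

VaR_q = u + (σ/ξ)[((n/n_u)(1−q))^(−ξ) − 1],
ES_q  = VaR_q/(1−ξ) + (σ − ξu)/(1−ξ),

reported at q = 0.999 (the "expected loss of the worst 0.1% of cases")
with VaR at the 1/1,000 and 1/10,000 events as lower/upper bounds, and
compared against the mean company/county MME threshold.

## Worked example

```python
from mmerisk import (GeneratorConfig, GpdTailMagnitude, generate_events,
                     aggregate, select_top_fraction, trend_test_pipeline,
                     country_risk_summary)

# a synthetic country: rising event rate, heavy GPD(0.2, 50k) tail above 100k fish
magnitude = GpdTailMagnitude(body_scale=100_000, tail_shape=0.2,
                             tail_scale=50_000, tail_fraction=0.10)
config = GeneratorConfig(country="Synthia", start="2012-01", end="2021-12",
                         base_rate=8.0, rate_trend=0.05,
                         magnitude=magnitude, seed=11)
events = generate_events(config)

top = select_top_fraction(events, 0.10)
counts = aggregate(top, "monthly", "count", span=("2012-01", "2021-12"))
trend = trend_test_pipeline(counts)

risk = country_risk_summary(events, basis="per_event", top_fraction=0.10)
```

prints, via the obvious f-strings:

```
1339 events, 78,966,839 fish lost
frequency trend: tau = 0.166, p = 1.65e-02, n = 120 (windows [])
GPD fit: u = 98,497, xi = 0.487, sigma = 27,926, n_exceed = 134
ES_0.999 = 1.09 M fish (VaR_0.999 = 0.58 M, VaR_0.9999 = 1.70 M)
```

The frequency of this country's top-10% events rises significantly
(τ = 0.166, p ≈ 0.017 over 120 months; no autocorrelation averaging was
needed), and the fitted tail puts the expected loss of the worst 0.1% of
events at about 1.1 million fish — an order of magnitude above the
100k-fish threshold built into the generator.

### Command line

```bash
mmerisk simulate --config run.yml --out events.csv      # synthetic data
mmerisk analyze  --config run.yml --out reports/        # trend + EVT tables
mmerisk report   --config run.yml --out reports/        # + plots
```

A single YAML config drives everything (inputs or generators, per-country
resolution/basis/top-fraction/year-window, seed); every run writes a
manifest with the seed and a config hash, and identical configs produce
identical numeric outputs.  Exit codes: 0 ok, 2 config error, 3 data
error, 4 analysis error.

Real event CSVs are ingested with a user-editable column mapping (see
`mmerisk.events.read_events`), so arbitrary column headers and date
formats can be adapted without code changes; rejected rows are reported
with row numbers, never silently dropped.

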