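"""Trend analysis of MME frequency and magnitude series.

The question is whether extreme loss events are becoming more frequent and
larger.  Frequency is tracked by counting, per period, the country's
top-fraction largest events (top 10% for monthly reporters, top 50% for
yearly reporters, which keeps the analysis agnostic to each jurisdiction's
MME definition); magnitude by the per-period maximum loss.  Monotonic
trends are tested with the nonparametric Mann–Kendall test (tie-corrected
variance, tau-b, continuity-corrected normal deviate).  Because the test
assumes independence, series are first screened for autocorrelation; where
the lag-1 structure is significant the series is averaged over
non-overlapping blocks until the dependence disappears, and the test runs
on the averaged series.  Lowess smoothing is provided for visualisation
only and never feeds inference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess
from statsmodels.tsa.stattools import acf as _sm_acf

from .events import EventSeries, EventTable, ValidationError


class InsufficientDataError(ValueError):
    """Fewer than 3 usable observations."""


class ConstantSeriesError(ValueError):
    """Autocorrelation is undefined for a constant series."""


@dataclass
class AdjustmentRecord:
    """Trail of autocorrelation averaging applied before the trend test."""

    windows: list[int] = field(default_factory=list)
    n_original: int = 0
    n_final: int = 0

    @property
    def total_window(self) -> int:
        out = 1
        for w in self.windows:
            out *= w
        return out


@dataclass
class TrendResult:
    """Mann–Kendall statistic bundle."""

    S: int
    var_S: float
    Z: float
    tau: float
    p: float
    n: int
    adjustment: AdjustmentRecord = field(default_factory=AdjustmentRecord)

    def to_row(self) -> dict:
        return {
            "n": self.n,
            "S": self.S,
            "var_S": self.var_S,
            "Z": self.Z,
            "tau": self.tau,
            "p": self.p,
            "adjustment_window": self.adjustment.total_window,
        }


@dataclass
class AutocorrResult:
    """Sample autocorrelations with per-lag significance at level alpha."""

    lags: np.ndarray
    correlations: np.ndarray
    significant: np.ndarray
    alpha: float
    window: int


# ---------------------------------------------------------------------------
# Top-fraction selection
# ---------------------------------------------------------------------------

def select_top_fraction(events: EventTable, fraction: float) -> EventTable:
    """The k largest events of one country, k = ceil(fraction * N).

    Ties at the cutoff are resolved deterministically: earlier
    ``period_start`` first, then lexicographic ``unit_id``.
    """
    if not 0 < fraction <= 1:
        raise ValidationError(f"fraction must lie in (0, 1], got {fraction}")
    if len(events) == 0:
        raise ValidationError("cannot select from an empty event table")
    countries = events.countries()
    if len(countries) > 1:
        raise ValidationError(f"top-fraction selection is within-country only, got {countries}")
    k = math.ceil(fraction * len(events))
    ranked = sorted(
        events, key=lambda ev: (-ev.fish_lost, ev.period_start, ev.unit_id)
    )
    chosen = sorted(ranked[:k], key=lambda ev: (ev.period_start, ev.unit_id))
    return EventTable(chosen, source=f"{events.source}[top {fraction:g}]")


# ---------------------------------------------------------------------------
# Mann–Kendall
# ---------------------------------------------------------------------------

def _as_values(series) -> np.ndarray:
    if isinstance(series, EventSeries):
        if series.statistic == "count":
            return series.values.copy()
        return series.dropna()
    x = np.asarray(series, dtype=float)
    return x[~np.isnan(x)]


def mann_kendall(series) -> TrendResult:
    """Two-tailed Mann–Kendall trend test.

    S is the sum of signs over all ordered pairs; its variance carries the
    tie correction sum over groups of equal values; Z applies the +/-1
    continuity correction; tau is tau-b (value ties corrected, the time
    index assumed untied).  A constant series degenerates to tau = 0,
    p = 1 rather than an error.
    """
    x = _as_values(series)
    n = len(x)
    if n < 3:
        raise InsufficientDataError(f"Mann–Kendall needs n >= 3, got {n}")

    sgn = np.sign(x[np.newaxis, :] - x[:, np.newaxis])
    s = int(np.triu(sgn, k=1).sum())

    _, tie_counts = np.unique(x, return_counts=True)
    ties = tie_counts[tie_counts > 1].astype(float)
    var_s = (
        n * (n - 1) * (2 * n + 5) - np.sum(ties * (ties - 1) * (2 * ties + 5))
    ) / 18.0

    n0 = n * (n - 1) / 2.0
    n_tied = float(np.sum(ties * (ties - 1) / 2.0))
    denom = math.sqrt((n0 - n_tied) * n0)
    tau = s / denom if denom > 0 else 0.0

    if var_s <= 0 or s == 0:
        z = 0.0
    elif s > 0:
        z = (s - 1) / math.sqrt(var_s)
    else:
        z = (s + 1) / math.sqrt(var_s)
    p = 2.0 * stats.norm.sf(abs(z)) if var_s > 0 else 1.0

    return TrendResult(
        S=s, var_S=float(var_s), Z=float(z), tau=float(tau), p=float(p), n=n,
        adjustment=AdjustmentRecord(n_original=n, n_final=n),
    )


# ---------------------------------------------------------------------------
# Autocorrelation handling
# ---------------------------------------------------------------------------

def autocorrelation_diagnose(
    series, max_lag: int = 12, alpha: float = 0.05
) -> AutocorrResult:
    """Sample autocorrelation at lags 1..max_lag with significance flags.

    A lag is significant when |r_k| exceeds the large-sample two-sided
    bound z_{1-alpha/2} / sqrt(n).  The recommended averaging window is
    1 + the longest run of significant lags starting at lag 1 (window 1
    when lag 1 itself is not significant).
    """
    x = _as_values(series)
    n = len(x)
    if n < 4:
        raise InsufficientDataError(f"autocorrelation diagnosis needs n >= 4, got {n}")
    if np.ptp(x) == 0:
        raise ConstantSeriesError("autocorrelation undefined for a constant series")
    max_lag = max(1, min(max_lag, n - 3))

    r = _sm_acf(x, nlags=max_lag, fft=False)[1:]
    bound = stats.norm.ppf(1 - alpha / 2) / math.sqrt(n)
    significant = np.abs(r) > bound

    window = 1
    for flag in significant:
        if not flag:
            break
        window += 1

    return AutocorrResult(
        lags=np.arange(1, max_lag + 1),
        correlations=r,
        significant=significant,
        alpha=alpha,
        window=window,
    )


def average_adjust(series, window: int) -> np.ndarray:
    """Replace non-overlapping consecutive blocks by their means.

    The trailing partial block is averaged over its actual length; output
    length is ceil(n / window).
    """
    if window < 1:
        raise ValidationError(f"window must be >= 1, got {window}")
    x = _as_values(series)
    if window == 1:
        return x.copy()
    return np.array(
        [x[i : i + window].mean() for i in range(0, len(x), window)], dtype=float
    )


def trend_test_pipeline(
    series,
    max_lag: int = 12,
    alpha: float = 0.05,
    max_rounds: int = 5,
) -> TrendResult:
    """Autocorrelation-screened Mann–Kendall test.

    Diagnoses autocorrelation; while the recommended window exceeds 1 (and
    up to ``max_rounds`` rounds) averages the series over that window and
    re-diagnoses, then runs the Mann–Kendall test on the (possibly
    averaged) series.  The averaging trail is recorded on the result.
    """
    x = _as_values(series)
    n_original = len(x)
    if n_original < 3:
        raise InsufficientDataError(f"trend test needs n >= 3, got {n_original}")

    trail: list[int] = []
    for _ in range(max_rounds):
        if len(x) < 4 or np.ptp(x) == 0:
            break
        diag = autocorrelation_diagnose(x, max_lag=max_lag, alpha=alpha)
        if diag.window <= 1:
            break
        x = average_adjust(x, diag.window)
        trail.append(diag.window)
        if len(x) < 3:
            raise InsufficientDataError(
                f"averaging (windows {trail}) left n = {len(x)} < 3"
            )

    result = mann_kendall(x)
    result.adjustment = AdjustmentRecord(
        windows=trail, n_original=n_original, n_final=len(x)
    )
    return result


# ---------------------------------------------------------------------------
# Lowess (visualisation only)
# ---------------------------------------------------------------------------

def lowess_smooth(x: Sequence[float], y: Sequence[float], frac: float = 2.0 / 3.0) -> np.ndarray:
    """Locally weighted linear fit (tricube weights) evaluated at each x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValidationError(f"x and y lengths differ: {len(x)} vs {len(y)}")
    if len(x) < 3:
        raise InsufficientDataError("lowess needs n >= 3")
    if not 0 < frac <= 1:
        raise ValidationError(f"frac must lie in (0, 1], got {frac}")
    return _sm_lowess(y, x, frac=frac, return_sorted=False)
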