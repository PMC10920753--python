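import datetime as dt
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mmerisk import (
    EventTable,
    MortalityEvent,
    autocorrelation_diagnose,
    average_adjust,
    lowess_smooth,
    mann_kendall,
    select_top_fraction,
    trend_test_pipeline,
)
from mmerisk.events import ValidationError
from mmerisk.trends import ConstantSeriesError, InsufficientDataError


# ---------------------------------------------------------------------------
# Brute-force oracle: literal pairwise definitions
# ---------------------------------------------------------------------------

def brute_force_mk(x):
    """S, var_S and tau-b from their literal definitions, pair by pair."""
    n = len(x)
    s = 0
    for i in range(n):
        for j in range(i + 1, n):
            s += (x[j] > x[i]) - (x[j] < x[i])
    groups = {}
    for v in x:
        groups[v] = groups.get(v, 0) + 1
    tie_term = sum(t * (t - 1) * (2 * t + 5) for t in groups.values() if t > 1)
    var_s = (n * (n - 1) * (2 * n + 5) - tie_term) / 18
    n0 = n * (n - 1) / 2
    n_tied = sum(t * (t - 1) / 2 for t in groups.values() if t > 1)
    denom = math.sqrt((n0 - n_tied) * n0)
    tau = s / denom if denom > 0 else 0.0
    return s, var_s, tau


small_series = st.lists(
    st.integers(min_value=-5, max_value=5), min_size=3, max_size=12
)


class TestMannKendall:
    @pytest.mark.parametrize(
        "x, s, tau",
        [
            ([3, 1, 2, 4], 2, 2 / 6),
            (list(range(1, 11)), 45, 1.0),
            ([1, 2, 2, 3], 5, 5 / math.sqrt(30)),
        ],
    )
    def test_hand_worked_examples(self, x, s, tau):
        r = mann_kendall(x)
        assert r.S == s
        assert r.tau == pytest.approx(tau)

    def test_tie_corrected_variance(self):
        # one tie group of 2: [4*3*13 - 2*1*9] / 18
        r = mann_kendall([1, 2, 2, 3])
        assert r.var_S == pytest.approx(138 / 18)

    def test_no_tie_variance_closed_form(self):
        rng = np.random.default_rng(0)
        for n in (5, 20, 60):
            x = rng.normal(size=n)
            assert mann_kendall(x).var_S == pytest.approx(n * (n - 1) * (2 * n + 5) / 18)

    def test_constant_series_degenerates(self):
        r = mann_kendall([4.0] * 10)
        assert (r.S, r.tau, r.p) == (0, 0.0, 1.0)

    def test_too_short(self):
        with pytest.raises(InsufficientDataError):
            mann_kendall([1, 2])

    @given(small_series)
    @settings(derandomize=True, max_examples=300, deadline=None)
    def test_matches_bruteforce_oracle(self, x):
        s, var_s, tau = brute_force_mk(x)
        r = mann_kendall(x)
        assert r.S == s
        assert r.var_S == pytest.approx(var_s)
        assert r.tau == pytest.approx(tau)

    @given(small_series)
    @settings(derandomize=True, max_examples=300, deadline=None)
    def test_reversal_negates_s_and_tau_keeps_p(self, x):
        fwd, rev = mann_kendall(x), mann_kendall(x[::-1])
        assert rev.S == -fwd.S
        assert rev.tau == pytest.approx(-fwd.tau)
        assert rev.p == pytest.approx(fwd.p)

    def test_sign_of_z_matches_sign_of_s(self):
        up = mann_kendall([1, 3, 2, 5, 4, 6])
        down = mann_kendall([6, 4, 5, 2, 3, 1])
        assert up.S > 0 and up.Z > 0
        assert down.S < 0 and down.Z < 0


class TestTopFraction:
    @staticmethod
    def _table(mags, dates=None):
        dates = dates or [dt.date(2015, 1, 1)] * len(mags)
        return EventTable(
            [
                MortalityEvent("A", f"u{i}", d, "monthly", m)
                for i, (m, d) in enumerate(zip(mags, dates))
            ]
        )

    def test_top_ten_percent_of_twenty(self):
        table = self._table(list(range(1, 21)))
        top = select_top_fraction(table, 0.10)
        assert sorted(e.fish_lost for e in top) == [19, 20]

    def test_fraction_one_is_identity(self):
        table = self._table([7, 3, 9])
        top = select_top_fraction(table, 1.0)
        assert sorted(e.fish_lost for e in top) == [3, 7, 9]

    def test_cutoff_ties_broken_by_earliest_period(self):
        dates = [dt.date(2015, 3, 1), dt.date(2015, 1, 1), dt.date(2015, 2, 1),
                 dt.date(2015, 1, 1)]
        table = self._table([5, 5, 5, 1], dates)
        top = select_top_fraction(table, 0.5)  # k = 2
        assert [e.period_start.month for e in top] == [1, 2]
        assert all(e.fish_lost == 5 for e in top)

    def test_empty_and_multicountry_rejected(self):
        with pytest.raises(ValidationError):
            select_top_fraction(EventTable([]), 0.1)
        mixed = EventTable(
            [
                MortalityEvent("A", "u", dt.date(2015, 1, 1), "monthly", 1),
                MortalityEvent("B", "u", dt.date(2015, 1, 1), "monthly", 2),
            ]
        )
        with pytest.raises(ValidationError):
            select_top_fraction(mixed, 0.5)


class TestAutocorrelation:
    def test_alternating_series_flags_lag_one(self):
        x = np.tile([1.0, -1.0], 25)
        diag = autocorrelation_diagnose(x)
        assert diag.correlations[0] < -0.9
        assert diag.significant[0]
        assert diag.window >= 2

    def test_iid_null_rarely_triggers_averaging(self):
        rng = np.random.default_rng(7)
        windows = [
            autocorrelation_diagnose(rng.normal(size=200)).window
            for _ in range(1000)
        ]
        assert np.mean(np.asarray(windows) == 1) >= 0.90

    def test_ar1_dependence_detected(self):
        rng = np.random.default_rng(3)
        x = np.empty(200)
        x[0] = rng.normal()
        for i in range(1, 200):
            x[i] = 0.8 * x[i - 1] + rng.normal()
        diag = autocorrelation_diagnose(x)
        assert diag.significant[0] and diag.window >= 2

    def test_constant_series_rejected(self):
        with pytest.raises(ConstantSeriesError):
            autocorrelation_diagnose([1.0] * 20)


class TestAverageAdjust:
    def test_block_means(self):
        x = np.arange(12, dtype=float)
        out = average_adjust(x, 3)
        assert list(out) == [1.0, 4.0, 7.0, 10.0]

    def test_partial_trailing_block(self):
        assert list(average_adjust([2, 4, 6, 8, 10], 2)) == [3.0, 7.0, 10.0]

    def test_window_one_identity(self):
        x = [5.0, 1.0, 3.0]
        assert list(average_adjust(x, 1)) == x

    @given(
        st.lists(st.floats(-100, 100), min_size=4, max_size=40),
        st.integers(min_value=1, max_value=4),
    )
    @settings(derandomize=True, deadline=None)
    def test_mean_preserved_when_length_divisible(self, x, window):
        n = (len(x) // window) * window
        x = np.asarray(x[:n])
        out = average_adjust(x, window)
        assert len(out) == math.ceil(len(x) / window)
        assert out.mean() == pytest.approx(x.mean(), abs=1e-9)

    def test_bad_window(self):
        with pytest.raises(ValidationError):
            average_adjust([1, 2, 3], 0)


class TestTrendPipeline:
    def test_iid_series_identical_to_plain_test(self):
        rng = np.random.default_rng(42)
        # pick a draw the screen leaves untouched
        for _ in range(10):
            x = rng.normal(size=80)
            if autocorrelation_diagnose(x).window == 1:
                break
        piped = trend_test_pipeline(x)
        plain = mann_kendall(x)
        assert piped.adjustment.windows == []
        assert (piped.S, piped.var_S, piped.tau, piped.p) == (
            plain.S, plain.var_S, plain.tau, plain.p,
        )

    def test_ar1_with_trend_adjusts_and_still_detects(self):
        hits, adjusted = 0, 0
        n_rep = 100
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            eps = np.empty(120)
            eps[0] = rng.normal()
            for i in range(1, 120):
                eps[i] = 0.8 * eps[i - 1] + rng.normal()
            x = 0.08 * np.arange(120) + eps
            r = trend_test_pipeline(x)
            adjusted += bool(r.adjustment.windows)
            hits += r.p < 0.05 and r.S > 0
        assert adjusted / n_rep > 0.8
        assert hits / n_rep > 0.8

    def test_adjustment_trail_recorded(self):
        x = np.tile([1.0, -1.0], 30) + 0.01 * np.arange(60)
        r = trend_test_pipeline(x)
        assert r.adjustment.windows and r.adjustment.windows[0] >= 2
        assert r.adjustment.n_original == 60
        assert r.n == r.adjustment.n_final < 60

    def test_too_short(self):
        with pytest.raises(InsufficientDataError):
            trend_test_pipeline([1.0, 2.0])


class TestLowess:
    def test_reproduces_a_line(self):
        x = np.arange(20, dtype=float)
        y = 2.0 * x
        assert np.allclose(lowess_smooth(x, y), y, atol=1e-8)

    def test_constant_fit(self):
        x = np.arange(10, dtype=float)
        assert np.allclose(lowess_smooth(x, np.full(10, 3.0)), 3.0)

    def test_recovers_noisy_sine(self):
        rng = np.random.default_rng(5)
        x = np.linspace(0, 4 * np.pi, 200)
        truth = np.sin(x)
        noise_sd = 0.5
        y = truth + rng.normal(0, noise_sd, size=200)
        fit = lowess_smooth(x, y, frac=0.3)
        rmse = np.sqrt(np.mean((fit - truth) ** 2))
        assert rmse < noise_sd

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            lowess_smooth([1, 2, 3], [1, 2])
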