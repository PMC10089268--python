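"""Trend extraction, exact piecewise fitting, slope classification and the
composed risk detector."""

import datetime as dt
import itertools

import numpy as np
import pytest

import habitcoach as hc
from habitcoach.risk import (
    InsufficientDataError,
    SlopeClass,
    Verdict,
    _fit_fixed_k,
    _segment_costs,
    piecewise_sse,
)
from tests.conftest import START, daily_series

STEPS_CFG = hc.DetectorConfig(
    min_slope=100, max_slope=2000, harm_direction="descending_is_harmful"
)


def brute_force_sse(y: np.ndarray, k: int, min_len: int = 2) -> float:
    """Exhaustive minimum piecewise-OLS SSE over all breakpoint placements."""
    n = len(y)
    cost = _segment_costs(y)
    best = np.inf
    for cuts in itertools.combinations(range(1, n), k - 1):
        bounds = [0, *cuts, n]
        spans = list(zip(bounds[:-1], bounds[1:]))
        if any(b - a < min_len for a, b in spans):
            continue
        best = min(best, sum(cost[a, b - 1] for a, b in spans))
    return float(best)


# --- decomposition -----------------------------------------------------

def test_trend_of_constant_series_is_constant():
    trend = hc.extract_trend(daily_series([250.0] * 28), period=7)
    assert np.allclose(trend.trend, 250.0, atol=1e-9)
    assert len(trend) == 28


def test_trend_preserves_a_pure_line():
    t = np.arange(35.0)
    trend = hc.extract_trend(daily_series(100 + 3 * t), period=7)
    assert np.allclose(trend.trend, 100 + 3 * t, atol=1e-6)


def test_trend_removes_weekly_seasonality_from_a_line():
    t = np.arange(56.0)
    values = 500 + 4 * t + 80 * np.sin(2 * np.pi * t / 7)
    trend = hc.extract_trend(daily_series(values), period=7)
    assert np.max(np.abs(trend.trend - (500 + 4 * t))) < 5.0
    assert abs(np.nanmean(trend.resid)) < 1.0


def test_trend_requires_two_full_periods():
    with pytest.raises(InsufficientDataError):
        hc.extract_trend(daily_series([100.0] * 10), period=7)


# --- piecewise fit -----------------------------------------------------

def test_single_segment_recovers_line_slope():
    t = np.arange(30.0)
    segs = hc.fit_piecewise_segments(7.0 - 2.5 * t, max_segments=1)
    assert len(segs) == 1
    assert segs[0].slope == pytest.approx(-2.5, abs=1e-9)
    assert (segs[0].start_index, segs[0].end_index) == (0, 29)


def test_constant_series_has_zero_slope():
    segs = hc.fit_piecewise_segments(np.full(20, 3.0), max_segments=3)
    assert all(s.slope == pytest.approx(0.0, abs=1e-9) for s in segs)


def test_vee_breakpoint_found_within_one_day():
    t = np.arange(60.0)
    y = 10 * np.minimum(t, 30) - 10 * np.clip(t - 30, 0, None)
    segs = hc.fit_piecewise_segments(y, max_segments=2, n_segments=2)
    assert len(segs) == 2
    assert abs(segs[1].start_index - 30) <= 1
    assert segs[0].slope == pytest.approx(10, rel=0.05)
    assert segs[1].slope == pytest.approx(-10, rel=0.05)


def test_segments_are_contiguous_and_cover_the_series(rng):
    y = rng.normal(size=40)
    segs = hc.fit_piecewise_segments(y, max_segments=3, n_segments=3)
    assert segs[0].start_index == 0 and segs[-1].end_index == 39
    for a, b in zip(segs, segs[1:]):
        assert b.start_index == a.end_index + 1


@pytest.mark.parametrize("n,k", [(12, 2), (20, 3), (31, 2)])
def test_dp_equals_bruteforce_on_random_series(rng, n, k):
    for _ in range(5):
        y = rng.normal(size=n).cumsum()
        assert piecewise_sse(y, k) == pytest.approx(brute_force_sse(y, k), rel=1e-9, abs=1e-9)


def test_fit_rejects_bad_segment_count():
    with pytest.raises(ValueError):
        hc.fit_piecewise_segments(np.arange(20.0), max_segments=0)
    with pytest.raises(InsufficientDataError):
        hc.fit_piecewise_segments(np.arange(4.0), max_segments=3)


def test_shift_and_scale_equivariance(rng):
    """Adding a constant leaves slopes unchanged; scaling scales them."""
    y = rng.normal(size=36).cumsum()
    base = hc.fit_piecewise_segments(y, max_segments=2, n_segments=2)
    shifted = hc.fit_piecewise_segments(y + 1234.5, max_segments=2, n_segments=2)
    scaled = hc.fit_piecewise_segments(y * 3.5, max_segments=2, n_segments=2)
    for b, s in zip(base, shifted):
        assert s.slope == pytest.approx(b.slope, abs=1e-9)
    for b, s in zip(base, scaled):
        assert s.slope == pytest.approx(3.5 * b.slope, rel=1e-9)


# --- slope classification ---------------------------------------------

@pytest.mark.parametrize(
    "slope,expected",
    [
        (0.0, SlopeClass.no_risk),
        (-50.0, SlopeClass.no_risk),  # below min_slope
        (-300.0, SlopeClass.descending_unhealthy),
        (300.0, SlopeClass.no_risk),  # ascending is harmless for steps
        (-5000.0, SlopeClass.ignored_too_steep),
        (5000.0, SlopeClass.ignored_too_steep),
    ],
)
def test_slope_classes_for_steps(slope, expected):
    seg = hc.TrendSegment(0, 10, slope, 0.0)
    assert hc.classify_slope(seg, STEPS_CFG) is expected


def test_ascending_harmful_direction():
    cfg = hc.DetectorConfig(min_slope=1, max_slope=100, harm_direction="ascending_is_harmful")
    assert hc.classify_slope(hc.TrendSegment(0, 5, 10.0, 0), cfg) is SlopeClass.ascending_unhealthy
    assert hc.classify_slope(hc.TrendSegment(0, 5, -10.0, 0), cfg) is SlopeClass.no_risk


# --- reference point and forecast --------------------------------------

def test_reference_point_absent_when_all_harmless():
    segs = [hc.TrendSegment(0, 10, 0, 0), hc.TrendSegment(11, 20, 0, 0)]
    classes = [SlopeClass.no_risk, SlopeClass.no_risk]
    assert hc.find_reference_point(segs, classes, START) is None


def test_reference_point_is_latest_unhealthy_start():
    segs = [hc.TrendSegment(0, 10, -300, 0), hc.TrendSegment(11, 20, 0, 0),
            hc.TrendSegment(21, 30, -300, 0)]
    classes = [SlopeClass.descending_unhealthy, SlopeClass.no_risk,
               SlopeClass.descending_unhealthy]
    assert hc.find_reference_point(segs, classes, START) == START + dt.timedelta(days=21)
    # single unhealthy segment: its own start
    assert (
        hc.find_reference_point(segs[:2], classes[:2], START) == START
    )


def test_forecast_continues_a_linear_trend_exactly():
    t = np.arange(28.0)
    trend = hc.extract_trend(daily_series(40 + 2 * t), period=7)
    out = hc.forecast_values(trend, START, horizon=5)
    assert out == pytest.approx([40 + 2 * t for t in range(28, 33)], abs=1e-6)


def test_forecast_of_constant_trend_is_constant():
    trend = hc.extract_trend(daily_series([70.0] * 28), period=7)
    assert hc.forecast_values(trend, START, horizon=3) == pytest.approx([70.0] * 3, abs=1e-9)


def test_forecast_extrapolates_final_segment_only():
    # two-piece trend: flat then decline; forecasting from the kink must
    # follow the final declining line, not the overall fit
    t = np.arange(60.0)
    values = 5000 - 100 * np.clip(t - 30, 0, None)
    trend = hc.extract_trend(daily_series(values), period=7)
    out = hc.forecast_values(trend, START + dt.timedelta(days=40), horizon=4)
    slope, intercept = np.polyfit(np.arange(40, 60), trend.trend[40:], 1)
    expected = [intercept + slope * t for t in range(60, 64)]
    assert out == pytest.approx(expected, abs=1e-6)


def test_forecast_rejects_date_outside_series():
    trend = hc.extract_trend(daily_series([70.0] * 28), period=7)
    with pytest.raises(ValueError):
        hc.forecast_values(trend, START - dt.timedelta(days=1), horizon=3)


# --- the composed detector ---------------------------------------------

def test_flat_healthy_series_yields_no_risk():
    res = hc.detect_risk(daily_series([8000.0] * 30), STEPS_CFG)
    assert res.verdict is Verdict.no_risk
    assert res.reference_point is None and res.forecast is None


def test_single_day_dropout_is_an_ignored_artifact():
    values = np.full(30, 8000.0)
    values[15] = 0.0
    res = hc.detect_risk(daily_series(values), STEPS_CFG)
    assert res.verdict is Verdict.no_risk
    assert SlopeClass.ignored_too_steep in res.all_classes
    assert len(res.artifacts) == 1 and res.artifacts[0].start_index == 15


def test_noiseless_decline_is_confirmed_with_exact_reference():
    t = np.arange(84.0)
    values = np.clip(10000 - 200 * np.clip(t - 30, 0, None), 0, None)
    res = hc.detect_risk(daily_series(values), STEPS_CFG)
    assert res.verdict is Verdict.unhealthy_trend_confirmed_by_forecast
    assert abs((res.reference_point - START).days - 30) <= 2
    assert len(res.forecast) == STEPS_CFG.horizon
    # forecast keeps declining
    assert res.forecast[-1] < res.forecast[0]


def test_recovered_decline_is_not_confirmed():
    # decline then recovery: trend was unhealthy but the forecast is not
    t = np.arange(84.0)
    values = 9000 - 150 * np.clip(t - 20, 0, None) + 300 * np.clip(t - 55, 0, None)
    res = hc.detect_risk(daily_series(values), STEPS_CFG)
    assert res.verdict is Verdict.unhealthy_trend_not_confirmed
    assert res.reference_point is not None


def test_detector_is_deterministic(rng):
    values = np.clip(rng.normal(8000, 800, 60), 0, None)
    ts = daily_series(values)
    r1 = hc.detect_risk(ts, STEPS_CFG)
    r2 = hc.detect_risk(ts, STEPS_CFG)
    assert r1.verdict == r2.verdict
    assert r1.reference_point == r2.reference_point
    assert [(s.start_index, s.end_index, s.slope) for s in r1.segments] == [
        (s.start_index, s.end_index, s.slope) for s in r2.segments
    ]


def test_detector_handles_short_missing_gaps():
    values = np.full(35, 8000.0)
    values[10:12] = np.nan  # 2-day gap: interpolated
    res = hc.detect_risk(daily_series(values), STEPS_CFG)
    assert res.verdict is Verdict.no_risk


def test_detector_uses_most_recent_run_after_long_gap():
    values = np.concatenate([np.full(20, 8000.0), np.full(6, np.nan), np.full(30, 8000.0)])
    res = hc.detect_risk(daily_series(values), STEPS_CFG)
    assert res.verdict is Verdict.no_risk
    # analysed segments live in the most recent run (global indices >= 26)
    assert all(s.start_index >= 26 for s in res.segments)
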