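"""Hourly and daily behavioral measures."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from phenosense import (
    daily_nighttime,
    hourly_features,
    normalized_app_entropy,
    segment_apps,
    sessionize,
    typing_intervals,
)
from phenosense.features import hourly_session_median, hourly_typing_median

from conftest import make_events


@pytest.mark.parametrize(
    "shares, expected",
    [
        ((0.5, 0.5), 1.0),
        ((1.0,), 0.0),
        ((0.75, 0.25), 0.8113),
        ((0.5, 0.25, 0.25), 0.9464),
    ],
)
def test_entropy_reference_values(shares, expected):
    assert normalized_app_entropy(shares) == pytest.approx(expected, abs=5e-5)


def test_entropy_empty_allocation_is_missing():
    assert math.isnan(normalized_app_entropy([]))


@given(st.lists(st.floats(0.01, 10.0), min_size=1, max_size=8), st.integers(0, 10**6))
def test_entropy_bounds_and_merge_concavity(weights, salt):
    """Entropy lies in [0,1]; pooling two apps never raises the numerator."""
    p = np.asarray(weights) / np.sum(weights)
    h = normalized_app_entropy(p)
    assert 0.0 <= h <= 1.0
    if len(p) >= 2:
        i, j = salt % len(p), (salt // 7) % len(p)
        if i != j:
            merged = np.delete(p, [i, j])
            merged = np.append(merged, p[i] + p[j])
            num = lambda q: -(q * np.log(q)).sum()
            assert num(merged) <= num(p) + 1e-12


def test_entropy_uniform_is_exact_max():
    for n in range(2, 9):
        assert normalized_app_entropy(np.full(n, 1.0 / n)) == 1.0


@pytest.fixture
def app_hour_stream():
    """One session crossing an hour boundary plus a same-hour A/B/A pattern."""
    return make_events(
        [
            ("p1", "0 10:10:00.000", "screen_on"),
            ("p1", "0 10:10:00.000", "app_foreground", "A"),
            ("p1", "0 10:20:00.000", "app_foreground", "B"),
            ("p1", "0 10:30:00.000", "app_foreground", "A"),
            ("p1", "0 10:40:00.000", "screen_off"),
            ("p1", "0 10:58:00.000", "screen_on"),
            ("p1", "0 10:58:00.000", "app_foreground", "C"),
            ("p1", "0 11:04:00.000", "screen_off"),
        ]
    )


def test_hourly_app_count_rules(app_hour_stream):
    sessions, _ = sessionize(app_hour_stream)
    segs = segment_apps(app_hour_stream, sessions)
    hf = hourly_features(sessions, segs, app_hour_stream).set_index("hour")
    # hour 10: apps A, B, C -> 3 unique; boundary-spanning C also counts in hour 11
    assert hf.loc[10, "app_count"] == 3
    assert hf.loc[11, "app_count"] == 1
    assert hf.loc[11, "app_entropy"] == 0.0  # single app


def test_hourly_entropy_matches_time_shares(app_hour_stream):
    sessions, _ = sessionize(app_hour_stream)
    segs = segment_apps(app_hour_stream, sessions)
    hf = hourly_features(sessions, segs, app_hour_stream).set_index("hour")
    # hour 10: A 20 min, B 10 min, C 2 min
    expected = normalized_app_entropy(np.array([20, 10, 2]) / 32)
    assert hf.loc[10, "app_entropy"] == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize(
    "durations, expected",
    [([1, 3, 10], 3.0), ([2, 4], 3.0)],
)
def test_session_median_by_start_hour(durations, expected):
    rows = []
    t0 = pd.Timestamp("2023-01-02 10:00:00")
    for k, d in enumerate(durations):
        start = t0 + pd.Timedelta(minutes=2 * k)
        rows.append(("p1", start, start + pd.Timedelta(minutes=d), float(d)))
    sessions = pd.DataFrame(rows, columns=["person_id", "start", "end", "duration_min"])
    out = hourly_session_median(sessions)
    assert out["session_duration_min"].tolist() == [expected]


def test_session_spanning_hours_attributed_to_start_hour():
    start = pd.Timestamp("2023-01-02 10:59:00")
    sessions = pd.DataFrame(
        [("p1", start, start + pd.Timedelta(minutes=30), 30.0)],
        columns=["person_id", "start", "end", "duration_min"],
    )
    out = hourly_session_median(sessions)
    assert out["hour"].tolist() == [10]


def test_typing_intervals_cap_and_median():
    ev = make_events(
        [
            ("p1", "0 10:00:00.000", "screen_on"),
            ("p1", "0 10:00:00.000", "keystroke"),
            ("p1", "0 10:00:00.200", "keystroke"),
            ("p1", "0 10:00:07.000", "click"),
            ("p1", "0 10:00:30.000", "screen_off"),
        ]
    )
    sessions, _ = sessionize(ev)
    iv = typing_intervals(ev, sessions)
    assert sorted(iv["interval_s"]) == [pytest.approx(0.2), pytest.approx(5.0)]
    med = hourly_typing_median(iv)
    assert med["typing_interval_s"].iloc[0] == pytest.approx(2.6)


def test_keystroke_without_in_session_successor_contributes_nothing():
    ev = make_events(
        [
            ("p1", "0 10:00:00.000", "screen_on"),
            ("p1", "0 10:00:01.000", "keystroke"),  # next event: session's screen_off
            ("p1", "0 10:00:02.000", "screen_off"),
            ("p1", "0 10:30:00.000", "keystroke"),  # stray, outside any session
            ("p1", "0 11:00:00.000", "screen_on"),
            ("p1", "0 11:00:01.000", "screen_off"),
        ]
    )
    sessions, _ = sessionize(ev)
    iv = typing_intervals(ev, sessions)
    assert len(iv) == 1
    assert iv["interval_s"].iloc[0] == pytest.approx(1.0)


def _sessions(rows):
    return pd.DataFrame(
        [
            (
                p,
                pd.Timestamp(s),
                pd.Timestamp(e),
                (pd.Timestamp(e) - pd.Timestamp(s)).total_seconds() / 60,
            )
            for p, s, e in rows
        ],
        columns=["person_id", "start", "end", "duration_min"],
    )


@pytest.mark.parametrize(
    "start, end, date, expected_min",
    [
        ("2023-01-02 23:30", "2023-01-03 00:30", "2023-01-03", 30.0),
        ("2023-01-03 01:00", "2023-01-03 01:45", "2023-01-03", 45.0),
        ("2023-01-03 05:50", "2023-01-03 07:00", "2023-01-03", 10.0),
    ],
)
def test_nighttime_clipping(start, end, date, expected_min):
    out = daily_nighttime(_sessions([("p1", start, end)]))
    row = out[out["date"] == pd.Timestamp(date)]
    assert row["nighttime_min"].iloc[0] == pytest.approx(expected_min)


def test_nighttime_true_zero_on_silent_nights():
    out = daily_nighttime(
        _sessions([("p1", "2023-01-02 12:00", "2023-01-02 12:30")]),
        date_range=("2023-01-02", "2023-01-04"),
    )
    assert out["nighttime_min"].tolist() == [0.0, 0.0, 0.0]


def test_nighttime_conservation_under_clipping(rng):
    """Summed daily values equal total session time inside night windows."""
    starts = pd.Timestamp("2023-01-02") + pd.to_timedelta(
        np.sort(rng.uniform(0, 5 * 24 * 60, 60)), unit="m"
    )
    durs = rng.uniform(1, 200, 60)
    rows = []
    prev_end = None
    for s, d in zip(starts, durs):
        e = s + pd.Timedelta(minutes=float(d))
        if prev_end is not None and s <= prev_end:
            continue
        rows.append(("p1", s, e))
        prev_end = e
    sessions = _sessions([(p, str(s), str(e)) for p, s, e in rows])
    total = 0.0
    for _, s, e in rows:
        day = s.normalize()
        while day < e:
            lo, hi = max(s, day), min(e, day + pd.Timedelta(hours=6))
            total += max((hi - lo).value, 0) / 60e9  # ns, not truncated micros
            day += pd.Timedelta(days=1)
    out = daily_nighttime(sessions)
    assert out["nighttime_min"].sum() == pytest.approx(total, abs=1e-9)
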