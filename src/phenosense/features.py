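"""The five behavioral measures at their native timescales.

Four measures are hourly — app count, normalized app entropy, median session
duration, median typing interval — and one is daily: nighttime smartphone
use (active screen time between 00:00 and 06:00 local time). Hourly bins
are half-open calendar hours ``[h:00, h+1:00)`` in local clock time.

Hours in which no interaction was sensed yield *missing* hourly rows:
passive sensing records nothing when the phone is untouched, so absence of
events is non-observation for the intensity measures. Nighttime use, in
contrast, is a true zero on silent nights — not using the phone at night is
exactly the behavior being measured.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

HOUR_NS = 3_600_000_000_000
DAY_NS = 24 * HOUR_NS
NIGHT_END_NS = 6 * HOUR_NS  # night window is [00:00, 06:00)

#: cap on a single typing interval, seconds
TYPING_CAP_S = 5.0

HOURLY_COLUMNS = [
    "person_id",
    "date",
    "hour",
    "app_count",
    "app_entropy",
    "session_duration_min",
    "typing_interval_s",
]


def normalized_app_entropy(shares) -> float:
    """Normalized Shannon entropy of within-hour app time shares.

    H = -sum_i p_i ln p_i / ln N for N >= 2 apps, where p_i is the
    proportion of in-app time spent in app i during the hour. A single app
    (N = 1) returns 0 by convention (the normalizer ln 1 vanishes and usage
    is maximally concentrated); an empty allocation has no defined value and
    returns NaN. The ratio is invariant to the logarithm base.
    """
    p = np.asarray(shares, dtype=float)
    p = p[p > 0]
    if p.size == 0:
        return float("nan")
    if p.size == 1:
        return 0.0
    if not np.isclose(p.sum(), 1.0, atol=1e-9):
        raise ValueError("app time shares must sum to 1")
    if np.all(p == p[0]):
        return 1.0  # uniform allocation: exact maximum, no rounding residue
    return float(-(p * np.log(p)).sum() / np.log(p.size))


def _split_to_hours(df: pd.DataFrame) -> pd.DataFrame:
    """Explode [start, end) intervals into clipped per-clock-hour pieces."""
    if df.empty:
        return pd.DataFrame(
            columns=list(df.columns) + ["hour_start", "dur_min"]
        )
    s = df["start"].to_numpy().astype("datetime64[ns]").astype("int64")
    e = df["end"].to_numpy().astype("datetime64[ns]").astype("int64")
    first = s // HOUR_NS
    last = (e - 1) // HOUR_NS
    nb = (last - first + 1).astype("int64")
    total = int(nb.sum())
    idx = np.repeat(np.arange(len(df)), nb)
    offs = np.arange(total) - np.repeat(np.cumsum(nb) - nb, nb)
    hstart = (first[idx] + offs) * HOUR_NS
    lo = np.maximum(s[idx], hstart)
    hi = np.minimum(e[idx], hstart + HOUR_NS)
    out = df.iloc[idx].reset_index(drop=True)
    out["hour_start"] = hstart.astype("datetime64[ns]")
    out["dur_min"] = (hi - lo) / 60e9
    return out[out["dur_min"] > 0].reset_index(drop=True)


def _date_hour(ts: pd.Series) -> tuple[pd.Series, pd.Series]:
    t = pd.DatetimeIndex(ts)
    return pd.Series(t.normalize()), pd.Series(t.hour.astype("int64"))


def hourly_app_table(segments: pd.DataFrame) -> pd.DataFrame:
    """Per (person, date, hour): unique app count and normalized entropy.

    A segment spanning hour boundaries counts (and contributes clipped time)
    in every hour it touches.
    """
    ex = _split_to_hours(segments)
    if ex.empty:
        return pd.DataFrame(columns=["person_id", "date", "hour", "app_count", "app_entropy"])
    date, hour = _date_hour(ex["hour_start"])
    ex = ex.assign(date=date.to_numpy(), hour=hour.to_numpy())
    per_app = (
        ex.groupby(["person_id", "date", "hour", "app_id"], sort=True)["dur_min"]
        .sum()
        .reset_index()
    )
    g = per_app.groupby(["person_id", "date", "hour"], sort=True)
    tot = g["dur_min"].transform("sum")
    p = per_app["dur_min"] / tot
    plogp = -(p * np.log(p))
    agg = per_app.assign(plogp=plogp).groupby(["person_id", "date", "hour"], sort=True)
    n_apps = agg["app_id"].size()
    ent_num = agg["plogp"].sum()
    entropy = pd.Series(
        np.where(n_apps.to_numpy() > 1, ent_num.to_numpy() / np.log(np.maximum(n_apps.to_numpy(), 2)), 0.0),
        index=n_apps.index,
    )
    out = pd.DataFrame({"app_count": n_apps, "app_entropy": entropy}).reset_index()
    return out


def hourly_session_median(sessions: pd.DataFrame) -> pd.DataFrame:
    """Median session duration per hour; a session belongs to its start hour."""
    if sessions.empty:
        return pd.DataFrame(columns=["person_id", "date", "hour", "session_duration_min"])
    date, hour = _date_hour(sessions["start"])
    df = sessions.assign(date=date.to_numpy(), hour=hour.to_numpy())
    out = (
        df.groupby(["person_id", "date", "hour"], sort=True)["duration_min"]
        .median()
        .rename("session_duration_min")
        .reset_index()
    )
    return out


def typing_intervals(events: pd.DataFrame, sessions: pd.DataFrame) -> pd.DataFrame:
    """Per-keystroke intervals to the next event within the same session.

    Each keystroke followed by *any* subsequent event inside the same session
    contributes the time difference in seconds, clamped to ``[0, 5]`` (values
    above the cap are set to 5 s, not dropped). A keystroke that is the last
    event of its session contributes nothing.
    """
    cols = ["person_id", "t", "interval_s"]
    if events.empty or sessions.empty:
        return pd.DataFrame(columns=cols)
    out = []
    for pid, grp in events.groupby("person_id", sort=True):
        ses = sessions[sessions["person_id"] == pid]
        if ses.empty:
            continue
        starts = ses["start"].to_numpy()
        ends = ses["end"].to_numpy()
        ts = grp["t"].to_numpy()
        pos = np.searchsorted(starts, ts, side="right") - 1
        sid = np.where((pos >= 0) & (ts <= ends[np.clip(pos, 0, None)]), pos, -1)
        nxt_t = np.append(ts[1:], np.datetime64("NaT"))
        nxt_sid = np.append(sid[1:], -2)
        keys = (grp["kind"].to_numpy() == "keystroke") & (sid >= 0) & (sid == nxt_sid)
        if not keys.any():
            continue
        iv = (nxt_t[keys] - ts[keys]) / np.timedelta64(1, "s")
        out.append(
            pd.DataFrame(
                {"person_id": pid, "t": ts[keys], "interval_s": np.clip(iv, 0.0, TYPING_CAP_S)}
            )
        )
    if not out:
        return pd.DataFrame(columns=cols)
    return pd.concat(out, ignore_index=True)


def hourly_typing_median(intervals: pd.DataFrame) -> pd.DataFrame:
    """Median typing interval per hour of the keystroke."""
    if intervals.empty:
        return pd.DataFrame(columns=["person_id", "date", "hour", "typing_interval_s"])
    date, hour = _date_hour(intervals["t"])
    df = intervals.assign(date=date.to_numpy(), hour=hour.to_numpy())
    return (
        df.groupby(["person_id", "date", "hour"], sort=True)["interval_s"]
        .median()
        .rename("typing_interval_s")
        .reset_index()
    )


def hourly_features(
    sessions: pd.DataFrame, segments: pd.DataFrame, events: pd.DataFrame
) -> pd.DataFrame:
    """Join the four hourly measures on the union of active hours.

    A row exists for every (person, date, hour) touched by at least one app
    segment, session start, or typing interval. ``app_count`` is 0 in active
    hours without foreground-app segments; ``app_entropy`` is missing there.
    """
    apps = hourly_app_table(segments)
    med = hourly_session_median(sessions)
    typ = hourly_typing_median(typing_intervals(events, sessions))
    keys = ["person_id", "date", "hour"]
    out = apps.merge(med, on=keys, how="outer").merge(typ, on=keys, how="outer")
    if out.empty:
        return pd.DataFrame(columns=HOURLY_COLUMNS)
    out["app_count"] = out["app_count"].fillna(0).astype("int64")
    out = out.sort_values(keys).reset_index(drop=True)
    return out[HOURLY_COLUMNS]


def daily_nighttime(
    sessions: pd.DataFrame,
    date_range: tuple | None = None,
) -> pd.DataFrame:
    """Active screen minutes in [00:00, 06:00) per (person, date).

    A session spanning midnight contributes its post-midnight portion to the
    later date. Days with no overlap are true zeros; by default the output
    covers each person's observed date span, or an explicit ``(first, last)``
    date range (inclusive) applied to every person.
    """
    cols = ["person_id", "date", "nighttime_min"]
    if sessions.empty:
        return pd.DataFrame(columns=cols)
    s = sessions["start"].to_numpy().astype("datetime64[ns]").astype("int64")
    e = sessions["end"].to_numpy().astype("datetime64[ns]").astype("int64")
    pid = sessions["person_id"].to_numpy()
    first_day = s // DAY_NS
    last_day = e // DAY_NS  # sessions are capped at 24 h: at most 2 days
    nb = last_day - first_day + 1
    idx = np.repeat(np.arange(len(s)), nb)
    offs = np.arange(int(nb.sum())) - np.repeat(np.cumsum(nb) - nb, nb)
    day = (first_day[idx] + offs) * DAY_NS
    lo = np.maximum(s[idx], day)
    hi = np.minimum(e[idx], day + NIGHT_END_NS)
    mins = np.maximum(hi - lo, 0) / 60e9
    acc = (
        pd.DataFrame(
            {
                "person_id": pid[idx],
                "date": day.astype("datetime64[ns]"),
                "nighttime_min": mins,
            }
        )
        .groupby(["person_id", "date"], sort=True)["nighttime_min"]
        .sum()
    )
    pieces = []
    for person, grp in sessions.groupby("person_id", sort=True):
        if date_range is not None:
            d0, d1 = pd.Timestamp(date_range[0]), pd.Timestamp(date_range[1])
        else:
            d0 = pd.Timestamp(grp["start"].min()).normalize()
            d1 = pd.Timestamp(grp["end"].max()).normalize()
        days = pd.date_range(d0, d1, freq="D")
        vals = acc.reindex([(person, d) for d in days], fill_value=0.0).to_numpy()
        pieces.append(
            pd.DataFrame({"person_id": person, "date": days, "nighttime_min": vals})
        )
    return pd.concat(pieces, ignore_index=True)
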