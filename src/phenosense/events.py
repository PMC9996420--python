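"""Canonical event-log I/O, sessionization, and per-app usage segments.

The raw material of passive smartphone sensing is a stream of timestamped
interaction events: screen on/off, foreground-app changes, keystrokes,
clicks, scrolls, and view changes. This module reads and writes the
canonical delimited format, reconstructs screen-on -> screen-off *sessions*,
and tiles each session into per-app usage segments delimited by the
``app_foreground`` events inside it.

Timestamps are stored on disk as epoch milliseconds plus an IANA time-zone
name and converted to naive *local* clock time at ingest: hour-of-day
semantics (night windows, hourly bins) are local-time concepts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EVENT_KINDS = (
    "screen_on",
    "screen_off",
    "app_foreground",
    "keystroke",
    "click",
    "scroll",
    "view_change",
)

#: columns of the in-memory event frame (``t`` is naive local time)
EVENT_COLUMNS = ["person_id", "t", "kind", "app_id", "tz"]

# sort priority for events sharing a millisecond: a session must open before
# anything happens inside it and close after everything inside it
_KIND_PRIORITY = {k: 1 for k in EVENT_KINDS}
_KIND_PRIORITY["screen_on"] = 0
_KIND_PRIORITY["screen_off"] = 2

#: sessions longer than this are treated as sensor artifacts and dropped
MAX_SESSION_HOURS = 24.0


@dataclass
class QCLog:
    """Named counters for every row or interval discarded along the way."""

    duplicates: int = 0
    duplicate_on: int = 0
    orphan_off: int = 0
    dropped_open: int = 0
    dropped_zero_length: int = 0
    dropped_over_24h: int = 0
    foreground_outside_session: int = 0
    notes: list = field(default_factory=list)

    def counters(self) -> dict:
        return {
            f.name: getattr(self, f.name) for f in fields(self) if f.name != "notes"
        }

    def total_dropped(self) -> int:
        return sum(self.counters().values())

    def to_text(self) -> str:
        lines = ["QC log"] + [f"  {k}: {v}" for k, v in self.counters().items()]
        lines += [f"  note: {n}" for n in self.notes]
        return "\n".join(lines)


def _sort_events(events: pd.DataFrame) -> pd.DataFrame:
    prio = events["kind"].map(_KIND_PRIORITY)
    order = np.lexsort((prio.to_numpy(), events["t"].to_numpy(), events["person_id"].to_numpy()))
    return events.iloc[order].reset_index(drop=True)


def read_events(path, qc: QCLog | None = None) -> pd.DataFrame:
    """Read the canonical event log (CSV with epoch-ms timestamps).

    Required columns: ``person_id, timestamp_ms, kind, app_id``; an optional
    ``tz`` column (IANA zone per row, constant per person) defaults to UTC.
    Exact duplicate rows are dropped with a logged count; unparseable
    timestamps and unknown kinds raise ``ValueError`` naming the row.

    Returns a frame with columns ``person_id, t, kind, app_id, tz`` sorted by
    person and local time ``t``.
    """
    qc = qc if qc is not None else QCLog()
    raw = pd.read_csv(
        path, dtype={"person_id": str, "kind": str, "app_id": str, "tz": str}
    )
    missing = {"person_id", "timestamp_ms", "kind"} - set(raw.columns)
    if missing:
        raise ValueError(f"event log {path} lacks required columns {sorted(missing)}")
    if "app_id" not in raw.columns:
        raw["app_id"] = pd.NA
    if "tz" not in raw.columns:
        raw["tz"] = "UTC"
    raw["tz"] = raw["tz"].fillna("UTC")

    ts = pd.to_numeric(raw["timestamp_ms"], errors="coerce")
    bad = ts.isna() | (ts != np.floor(ts))
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"unparseable timestamp_ms {raw['timestamp_ms'].iloc[i]!r} at row {i}"
        )
    unknown = ~raw["kind"].isin(EVENT_KINDS)
    if unknown.any():
        i = int(np.flatnonzero(unknown.to_numpy())[0])
        raise ValueError(f"unknown event kind {raw['kind'].iloc[i]!r} at row {i}")
    fg = raw["kind"] == "app_foreground"
    no_app = fg & (raw["app_id"].isna() | (raw["app_id"].astype(str).str.len() == 0))
    if no_app.any():
        i = int(np.flatnonzero(no_app.to_numpy())[0])
        raise ValueError(f"app_foreground event without app_id at row {i}")

    n0 = len(raw)
    raw = raw.drop_duplicates(
        subset=["person_id", "timestamp_ms", "kind", "app_id"], keep="first"
    )
    ndup = n0 - len(raw)
    if ndup:
        qc.duplicates += ndup
        logger.warning("dropped %d exact duplicate event rows", ndup)

    utc = pd.to_datetime(ts.loc[raw.index].astype("int64"), unit="ms", utc=True)
    local = pd.Series(pd.NaT, index=raw.index, dtype="datetime64[ns]")
    for tz, idx in raw.groupby("tz").groups.items():
        local.loc[idx] = utc.loc[idx].dt.tz_convert(tz).dt.tz_localize(None)
    out = pd.DataFrame(
        {
            "person_id": raw["person_id"].to_numpy(),
            "t": local.to_numpy(),
            "kind": raw["kind"].to_numpy(),
            "app_id": raw["app_id"].to_numpy(),
            "tz": raw["tz"].to_numpy(),
        }
    )
    return _sort_events(out)


def write_events(events: pd.DataFrame, path) -> None:
    """Write events back to the canonical CSV (epoch-ms + zone name)."""
    ev = events.copy()
    if "tz" not in ev.columns:
        ev["tz"] = "UTC"
    ms = np.empty(len(ev), dtype="int64")
    for tz, idx in ev.groupby("tz").groups.items():
        loc = pd.DatetimeIndex(ev.loc[idx, "t"]).tz_localize(tz).tz_convert("UTC")
        ms[ev.index.get_indexer(idx)] = loc.asi8 // 1_000_000
    out = pd.DataFrame(
        {
            "person_id": ev["person_id"].to_numpy(),
            "timestamp_ms": ms,
            "tz": ev["tz"].to_numpy(),
            "kind": ev["kind"].to_numpy(),
            "app_id": ev["app_id"].to_numpy(),
        }
    )
    out.to_csv(path, index=False)


def sessionize(events: pd.DataFrame, qc: QCLog | None = None):
    """Pair screen_on/screen_off events into non-overlapping sessions.

    Rules for malformed streams: a second ``screen_on`` while a session is
    open is ignored (the original start is kept); a ``screen_off`` with no
    open session is ignored; a session still open at end-of-stream is
    dropped; sessions longer than 24 h are dropped as artifacts. Every drop
    increments a :class:`QCLog` counter.

    Returns ``(sessions, qc)`` where ``sessions`` has columns
    ``session_id, person_id, start, end, duration_min``.
    """
    qc = qc if qc is not None else QCLog()
    scr = events[events["kind"].isin(["screen_on", "screen_off"])]
    rows = []
    for pid, grp in scr.groupby("person_id", sort=True):
        open_t = None
        for t, kind in zip(grp["t"], grp["kind"]):
            if kind == "screen_on":
                if open_t is None:
                    open_t = t
                else:
                    qc.duplicate_on += 1
            else:
                if open_t is None:
                    qc.orphan_off += 1
                elif t <= open_t:
                    qc.dropped_zero_length += 1
                    open_t = None
                else:
                    dur_min = (t - open_t).total_seconds() / 60.0
                    if dur_min > MAX_SESSION_HOURS * 60.0:
                        qc.dropped_over_24h += 1
                    else:
                        rows.append((pid, open_t, t, dur_min))
                    open_t = None
        if open_t is not None:
            qc.dropped_open += 1
    sessions = pd.DataFrame(rows, columns=["person_id", "start", "end", "duration_min"])
    sessions.insert(0, "session_id", np.arange(len(sessions), dtype="int64"))
    return sessions, qc


def segment_apps(
    events: pd.DataFrame, sessions: pd.DataFrame, qc: QCLog | None = None
) -> pd.DataFrame:
    """Tile each session into app-usage segments from its foreground events.

    Within a session, each ``app_foreground`` event opens a segment that runs
    to the next foreground event or to session end; interaction time before
    the first foreground event is left unattributed. Foreground events
    falling outside every session are counted in the QC log and ignored.
    """
    qc = qc if qc is not None else QCLog()
    fg = events[events["kind"] == "app_foreground"]
    rows = []
    for pid, grp in fg.groupby("person_id", sort=True):
        ses = sessions[sessions["person_id"] == pid]
        if ses.empty:
            qc.foreground_outside_session += len(grp)
            continue
        starts = ses["start"].to_numpy()
        ends = ses["end"].to_numpy()
        sids = ses["session_id"].to_numpy()
        ts = grp["t"].to_numpy()
        pos = np.searchsorted(starts, ts, side="right") - 1
        inside = (pos >= 0) & (ts < ends[np.clip(pos, 0, None)])
        qc.foreground_outside_session += int((~inside).sum())
        g = grp[inside]
        pos = pos[inside]
        for k in np.unique(pos):
            sel = g[pos == k]
            t_fg = sel["t"].to_numpy()
            apps = sel["app_id"].to_numpy()
            bounds = np.append(t_fg, ends[k])
            for j in range(len(t_fg)):
                if bounds[j + 1] > bounds[j]:
                    rows.append((pid, int(sids[k]), apps[j], bounds[j], bounds[j + 1]))
    return pd.DataFrame(
        rows, columns=["person_id", "session_id", "app_id", "start", "end"]
    )
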