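"""14-day window alignment, data-sufficiency QC, aggregation, summaries.

Each biweekly symptom report (two depression items, 0-4) recalls the past
two weeks, so every survey is paired with the half-open date window
``[symptom_date - 14 d, symptom_date)`` of behavioral features — the survey
day itself is excluded. A window survives QC only if at least
``min_days`` days inside it each show at least ``min_hours`` unique active
hours (defaults 3 and 3); sparser windows cannot distinguish low phone use
from a sensor that stopped reporting.

Surviving windows are aggregated to one row per survey: the mean of each
hourly measure over its observed (non-missing) hours, and the mean of
nighttime minutes over all 14 days (silent nights count as zero). The three
right-skewed time measures — nighttime use, session duration, typing
interval — additionally get a ``ln(1 + x)`` transform applied to the window
mean, which accommodates their true zeros.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

WINDOW_DAYS = 14
MIN_QUALIFYING_DAYS = 3
MIN_UNIQUE_HOURS = 3

#: hourly measures averaged over observed hours within the window
_HOURLY_MEASURES = ["app_count", "app_entropy", "session_duration_min", "typing_interval_s"]

#: model-facing names of the five aggregated predictors
PREDICTOR_MAP = {
    "app_count": "app_count_mean",
    "app_entropy": "app_entropy_mean",
    "nighttime": "nighttime_log",
    "session_duration": "session_duration_log",
    "typing_interval": "typing_interval_log",
}

WINDOW_COLUMNS = [
    "person_id",
    "symptom_date",
    "loss_of_interest",
    "depressed_mood",
    "app_count_mean",
    "app_entropy_mean",
    "nighttime_mean",
    "session_duration_mean",
    "typing_interval_mean",
    "nighttime_log",
    "session_duration_log",
    "typing_interval_log",
    "n_qualifying_days",
    "n_active_hours",
    "qc_pass",
    "qc_reason",
]


def qc_filter(
    hours_per_day,
    min_days: int = MIN_QUALIFYING_DAYS,
    min_hours: int = MIN_UNIQUE_HOURS,
) -> tuple[bool, int, str]:
    """Decide the data-sufficiency rule for one window.

    ``hours_per_day`` maps each active day to its count of unique active
    hours. A day qualifies when it has at least ``min_hours`` unique hours;
    the window passes when at least ``min_days`` days qualify.
    Returns ``(passed, n_qualifying_days, reason)``.
    """
    if isinstance(hours_per_day, dict):
        hours_per_day = list(hours_per_day.values())
    counts = np.asarray(pd.Series(hours_per_day).to_numpy())
    n_qual = int((counts >= min_hours).sum()) if counts.size else 0
    if n_qual >= min_days:
        return True, n_qual, ""
    return False, n_qual, (
        f"only {n_qual} day(s) with >= {min_hours} unique active hours; need {min_days}"
    )


def log1p_transform(x):
    """The skew-reducing transform applied to window-mean time measures."""
    return np.log1p(x)


def align_windows(
    surveys: pd.DataFrame,
    hourly: pd.DataFrame,
    nighttime: pd.DataFrame,
    min_days: int = MIN_QUALIFYING_DAYS,
    min_hours: int = MIN_UNIQUE_HOURS,
    window_days: int = WINDOW_DAYS,
) -> pd.DataFrame:
    """Build one aggregated, QC-flagged row per survey.

    ``surveys`` needs columns ``person_id, symptom_date, loss_of_interest,
    depressed_mood``; ``hourly`` and ``nighttime`` are the outputs of the
    feature-extraction step. Windows failing QC are kept in the output with
    ``qc_pass = False`` and missing feature values, so the QC report can
    account for every survey.
    """
    hourly = hourly.copy()
    hourly["date"] = pd.DatetimeIndex(hourly["date"]).normalize()
    nighttime = nighttime.copy()
    nighttime["date"] = pd.DatetimeIndex(nighttime["date"]).normalize()
    h_by_p = dict(tuple(hourly.groupby("person_id", sort=False)))
    n_by_p = dict(tuple(nighttime.groupby("person_id", sort=False)))

    rows = []
    for rec in surveys.itertuples(index=False):
        sd = pd.Timestamp(rec.symptom_date).normalize()
        w0 = sd - pd.Timedelta(days=window_days)
        row = {
            "person_id": rec.person_id,
            "symptom_date": sd,
            "loss_of_interest": rec.loss_of_interest,
            "depressed_mood": rec.depressed_mood,
        }
        hp = h_by_p.get(rec.person_id)
        sub = (
            hp[(hp["date"] >= w0) & (hp["date"] < sd)]
            if hp is not None
            else hourly.iloc[0:0]
        )
        hours_per_day = sub.groupby("date")["hour"].nunique()
        passed, n_qual, reason = qc_filter(hours_per_day, min_days, min_hours)
        row.update(
            n_qualifying_days=n_qual,
            n_active_hours=int(len(sub)),
            qc_pass=passed,
            qc_reason=reason,
        )
        if passed:
            for m in _HOURLY_MEASURES:
                vals = sub[m].dropna()
                row[_mean_name(m)] = float(vals.mean()) if len(vals) else np.nan
            np_ = n_by_p.get(rec.person_id)
            if np_ is not None:
                night = (
                    np_[(np_["date"] >= w0) & (np_["date"] < sd)]
                    .set_index("date")["nighttime_min"]
                    .reindex(pd.date_range(w0, periods=window_days, freq="D"), fill_value=0.0)
                )
            else:
                night = pd.Series(0.0, index=pd.date_range(w0, periods=window_days, freq="D"))
            row["nighttime_mean"] = float(night.mean())
            for m in ("nighttime", "session_duration", "typing_interval"):
                row[f"{m}_log"] = log1p_transform(row[f"{m}_mean"])
        rows.append(row)
    out = pd.DataFrame(rows)
    for c in WINDOW_COLUMNS:
        if c not in out.columns:
            out[c] = np.nan
    return out[WINDOW_COLUMNS]


def _mean_name(measure: str) -> str:
    return {
        "app_count": "app_count_mean",
        "app_entropy": "app_entropy_mean",
        "session_duration_min": "session_duration_mean",
        "typing_interval_s": "typing_interval_mean",
    }[measure]


def qc_report(windows: pd.DataFrame) -> str:
    """Human-readable account of every excluded window."""
    lines = [
        f"windows: {len(windows)} total, {int(windows['qc_pass'].sum())} pass QC"
    ]
    for rec in windows[~windows["qc_pass"].astype(bool)].itertuples(index=False):
        lines.append(
            f"  EXCLUDED {rec.person_id} @ {pd.Timestamp(rec.symptom_date).date()}: {rec.qc_reason}"
        )
    return "\n".join(lines)


def moment_skewness(x) -> float:
    """Moment coefficient of skewness g1 = m3 / m2^(3/2) (population moments).

    Undefined (NaN) for constant input.
    """
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 2 or np.ptp(x) == 0:
        return float("nan")
    return float(stats.skew(x, bias=True))


def summarize_measures(windows: pd.DataFrame) -> pd.DataFrame:
    """Mean, SD, min, max, skewness per aggregated measure (raw & transformed).

    Uses QC-passing windows only; SD is the sample (n-1) standard deviation
    and skewness the population moment coefficient g1.
    """
    w = windows[windows["qc_pass"].astype(bool)]
    if len(w) < 2:
        raise ValueError("need at least 2 QC-passing windows to summarize")
    specs = [
        ("app_count", "app_count_mean", None),
        ("app_entropy", "app_entropy_mean", None),
        ("nighttime_min", "nighttime_mean", "nighttime_log"),
        ("session_duration_min", "session_duration_mean", "session_duration_log"),
        ("typing_interval_s", "typing_interval_mean", "typing_interval_log"),
        ("loss_of_interest", "loss_of_interest", None),
        ("depressed_mood", "depressed_mood", None),
    ]
    rows = []
    for name, raw_col, log_col in specs:
        for variant, col in (("raw", raw_col), ("log1p", log_col)):
            if col is None:
                continue
            v = w[col].astype(float).dropna()
            rows.append(
                {
                    "measure": name,
                    "variant": variant,
                    "mean": v.mean(),
                    "sd": v.std(ddof=1),
                    "min": v.min(),
                    "max": v.max(),
                    "skewness": moment_skewness(v),
                }
            )
    return pd.DataFrame(rows)
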