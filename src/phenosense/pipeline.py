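"""End-to-end convenience: events + surveys -> fitted models."""

from __future__ import annotations

import pandas as pd

from . import disaggregate, events, features, mlm, windows


def extract_features(event_frame: pd.DataFrame, qc: events.QCLog | None = None):
    """Events -> (hourly features, daily nighttime, QC log)."""
    qc = qc if qc is not None else events.QCLog()
    sessions, qc = events.sessionize(event_frame, qc)
    segments = events.segment_apps(event_frame, sessions, qc)
    hourly = features.hourly_features(sessions, segments, event_frame)
    nighttime = features.daily_nighttime(sessions)
    return hourly, nighttime, qc


def build_design(
    event_frame: pd.DataFrame,
    surveys: pd.DataFrame,
    min_days: int = windows.MIN_QUALIFYING_DAYS,
    min_hours: int = windows.MIN_UNIQUE_HOURS,
    center_between: bool = True,
):
    """Events + surveys -> (window table, disaggregated design, QC log)."""
    hourly, nighttime, qc = extract_features(event_frame)
    win = windows.align_windows(surveys, hourly, nighttime, min_days, min_hours)
    design = disaggregate.split_within_between(win, center_between=center_between)
    return win, design, qc


def fit_both_outcomes(design: pd.DataFrame, reml: bool = True):
    """Fit the loss-of-interest and depressed-mood models on one design."""
    fit_loss = mlm.fit_lmm(design, mlm.MLMSpec(outcome="loss_of_interest", reml=reml))
    fit_mood = mlm.fit_lmm(design, mlm.MLMSpec(outcome="depressed_mood", reml=reml))
    return fit_loss, fit_mood
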