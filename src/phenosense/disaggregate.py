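"""Within/between-person disaggregation of the window-level predictors.

Psychological processes are typically nonergodic: the association between a
behavior and a symptom *across people* need not resemble the association
*within a person over time*. Pooled ("raw") correlations conflate the two.
Each time-varying predictor X_it is therefore split as

    X_it = grand_mean + bp_i + wp_it

where ``bp_i`` is person i's mean (grand-mean centered, so the model
intercept describes a prototypical person) and ``wp_it`` the window-specific
deviation from that person's own mean. The two portions enter the multilevel
model as separate predictors.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .windows import PREDICTOR_MAP

PREDICTORS = tuple(PREDICTOR_MAP)  # app_count ... typing_interval
OUTCOMES = ("loss_of_interest", "depressed_mood")


def split_within_between(
    windows: pd.DataFrame,
    center_between: bool = True,
) -> pd.DataFrame:
    """Person-mean center the five predictors of QC-passing windows.

    For each predictor X: ``wp_X = X - person_mean(X)`` and ``bp_X =
    person_mean(X) - grand_mean``, where the grand mean is the mean of the
    person means (so each person counts once regardless of how many windows
    they contribute) and person means use that person's observed values
    only. A missing X propagates to a missing ``wp_X``; ``bp_X`` is still
    defined from the person's other windows. With ``center_between=False``
    the uncentered person mean is used as ``bp_X``.

    The grand means are stashed in ``result.attrs["grand_means"]`` so raw
    values can be reconstructed exactly as ``grand + bp + wp``.
    """
    w = windows[windows["qc_pass"].astype(bool)].reset_index(drop=True)
    out = w[["person_id", "symptom_date", *OUTCOMES]].copy()
    grand_means = {}
    for name, col in PREDICTOR_MAP.items():
        x = w[col].astype(float)
        person_mean = x.groupby(w["person_id"]).transform("mean")
        gm = float(person_mean.groupby(w["person_id"]).first().mean()) if center_between else 0.0
        grand_means[name] = gm
        out[f"wp_{name}"] = x - person_mean
        out[f"bp_{name}"] = person_mean - gm
    out.attrs["grand_means"] = grand_means
    return out


def reconstruct_raw(design: pd.DataFrame, predictor: str) -> pd.Series:
    """Invert the split: grand_mean + bp + wp."""
    gm = design.attrs.get("grand_means", {}).get(predictor, 0.0)
    return gm + design[f"bp_{predictor}"] + design[f"wp_{predictor}"]


def correlation_table(design: pd.DataFrame) -> pd.DataFrame:
    """Raw / within / between Pearson correlations with each outcome.

    One row per (predictor, outcome): the correlation of the outcome with
    the raw predictor, with its within-person portion, and with its
    between-person portion, each over all QC-passing windows. Zero-variance
    columns yield missing correlations.
    """
    rows = []
    for pred in PREDICTORS:
        raw = reconstruct_raw(design, pred)
        for outc in OUTCOMES:
            y = design[outc].astype(float)
            rows.append(
                {
                    "predictor": pred,
                    "outcome": outc,
                    "raw": y.corr(raw),
                    "within": y.corr(design[f"wp_{pred}"]),
                    "between": y.corr(design[f"bp_{pred}"]),
                }
            )
    return pd.DataFrame(rows)
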