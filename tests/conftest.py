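import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")

BASE = pd.Timestamp("2023-01-02")


def make_events(rows, tz="UTC"):
    """Build an event frame from (person, 'D HH:MM:SS.mmm', kind[, app]) rows.

    The day offset D and clock time are relative to a fixed Monday.
    """
    recs = []
    for row in rows:
        person, when, kind = row[:3]
        app = row[3] if len(row) > 3 else None
        day, clock = when.split(" ")
        t = BASE + pd.Timedelta(days=int(day)) + pd.Timedelta(clock)
        recs.append((person, t, kind, app, tz))
    df = pd.DataFrame(recs, columns=["person_id", "t", "kind", "app_id", "tz"])
    return df.sort_values(["person_id", "t"], kind="mergesort").reset_index(drop=True)


def make_hourly(rows):
    """Hourly feature rows from (person, day, hour, count, entropy, sess, typ)."""
    cols = [
        "person_id",
        "date",
        "hour",
        "app_count",
        "app_entropy",
        "session_duration_min",
        "typing_interval_s",
    ]
    recs = [
        (p, BASE + pd.Timedelta(days=d), h, c, e, s, ty)
        for p, d, h, c, e, s, ty in rows
    ]
    return pd.DataFrame(recs, columns=cols)


def make_surveys(rows):
    """Survey rows from (person, day_offset, loss, mood)."""
    return pd.DataFrame(
        [
            {
                "person_id": p,
                "symptom_date": BASE + pd.Timedelta(days=d),
                "loss_of_interest": lo,
                "depressed_mood": mo,
            }
            for p, d, lo, mo in rows
        ]
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230102)


@pytest.fixture(scope="session")
def small_design():
    """Window-level design from the generator, modest size, fixed seed."""
    from phenosense import WindowSimConfig, generate_window_level

    design, truth = generate_window_level(
        WindowSimConfig(n_persons=40, windows_per_person=5, seed=77)
    )
    return design, truth
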