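"""Synthetic study data with known ground truth, at two levels.

Real passive-sensing patient data cannot be shared, so everything the
pipeline consumes can be generated here with the statistical structure the
analysis assumes:

* **Window level** — draws between-person levels, within-person deviations,
  random effects, and outcomes directly from the two-level random-slope
  model, for estimator testing (parameter recovery, coverage).
* **Event level** — builds raw event streams with session/app/keystroke
  microstructure (Poisson session counts with a separate nighttime rate,
  lognormal durations, Dirichlet app-time shares, lognormal inter-key gaps)
  together with the exact hourly/daily feature values implied by
  construction. The ground truth is accumulated by an independent
  straightforward pass over the generated primitives — never by calling the
  pipeline — so round-trip tests are true oracle comparisons.
* **Linked scenario** — latent per-window symptom states drive both the
  survey items and the behavior rates (fewer apps in use and slower typing
  when symptoms are elevated), exercising the full pipeline end to end with
  programmed effect signs.

Default window-level population moments emulate the magnitudes typical of
biweekly smartphone-sensing panels (app counts near 7-8 per active hour,
normalized entropy near 0.5, log-minutes of nighttime use near 1.7, and so
on), split ~64%/36% between stable person differences and window-to-window
variation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .disaggregate import PREDICTORS
from .features import TYPING_CAP_S

MS = 1
SEC = 1000
MIN = 60 * SEC
HOUR = 60 * MIN
DAY = 24 * HOUR

#: first calendar day of every simulated stream (a Monday, local time)
BASE_DATE = pd.Timestamp("2023-01-02")


@dataclass(frozen=True)
class SimulationTruth:
    """Generating values of every fixed effect and variance component."""

    gamma00: float = 2.24
    gamma_wp: dict = field(
        default_factory=lambda: {
            "app_count": -0.14,
            "app_entropy": 0.0,
            "nighttime": 0.0,
            "session_duration": 0.0,
            "typing_interval": 0.88,
        }
    )
    gamma_bp: dict = field(
        default_factory=lambda: {
            "app_count": 0.0,
            "app_entropy": 0.0,
            "nighttime": 0.0,
            "session_duration": -0.37,
            "typing_interval": 0.0,
        }
    )
    var_intercept: float = 0.86
    var_slopes: dict = field(
        default_factory=lambda: {
            "app_count": 0.06,
            "app_entropy": 0.01,
            "nighttime": 0.01,
            "session_duration": 0.01,
            "typing_interval": 0.01,
        }
    )
    var_residual: float = 0.54

    def __post_init__(self):
        if self.var_intercept < 0 or self.var_residual < 0:
            raise ValueError("variances must be non-negative")
        if any(v < 0 for v in self.var_slopes.values()):
            raise ValueError("variances must be non-negative")

    def as_series(self) -> pd.Series:
        idx = (
            ["gamma00"]
            + [f"gamma_wp_{m}" for m in PREDICTORS]
            + [f"gamma_bp_{m}" for m in PREDICTORS]
            + ["var_intercept"]
            + [f"var_wp_{m}" for m in PREDICTORS]
            + ["var_residual"]
        )
        vals = (
            [self.gamma00]
            + [self.gamma_wp[m] for m in PREDICTORS]
            + [self.gamma_bp[m] for m in PREDICTORS]
            + [self.var_intercept]
            + [self.var_slopes[m] for m in PREDICTORS]
            + [self.var_residual]
        )
        return pd.Series(vals, index=idx)


# Table-like population moments for the five aggregated predictors:
# (mu, tau = between-person SD, omega = within-person SD)
_DEFAULT_MOMENTS = {
    "app_count": (7.53, 1.648, 1.236),
    "app_entropy": (0.48, 0.072, 0.054),
    "nighttime": (1.70, 1.088, 0.816),
    "session_duration": (1.35, 0.536, 0.402),
    "typing_interval": (0.43, 0.120, 0.090),
}


@dataclass(frozen=True)
class WindowSimConfig:
    """Window-level simulation: sizes, predictor moments, outcome truth."""

    n_persons: int = 150
    windows_per_person: int = 7
    moments: dict = field(default_factory=lambda: dict(_DEFAULT_MOMENTS))
    truth: SimulationTruth = field(default_factory=SimulationTruth)
    outcome: str = "loss_of_interest"
    likert_discretize: bool = False
    seed: int | None = None

    def __post_init__(self):
        if self.windows_per_person < 1 or self.n_persons < 1:
            raise ValueError("need at least one person and one window")
        if any(tau < 0 or om < 0 for _, tau, om in self.moments.values()):
            raise ValueError("SDs must be non-negative")


def generate_window_level(config: WindowSimConfig):
    """Draw a disaggregated design straight from the two-level model.

    Between-person levels bp_i ~ N(mu, tau^2) (emitted centered at mu, as a
    model-ready bp predictor), within-person deviations wp_it ~ N(0,
    omega^2), independent random effects u_ki ~ N(0, sigma^2_uk), and the
    outcome from the linear predictor plus N(0, sigma^2_e) noise. With
    ``likert_discretize`` the outcome is rounded and clipped to 0-4
    (attenuates variance-component recovery; off by default).

    Returns ``(design, truth)`` where ``design`` has ``person_id, wave,
    wp_*, bp_*`` and the outcome column.
    """
    rng = np.random.default_rng(config.seed)
    t = config.truth
    P, T = config.n_persons, config.windows_per_person
    person = np.repeat([f"p{i:04d}" for i in range(P)], T)
    df = pd.DataFrame({"person_id": person, "wave": np.tile(np.arange(T), P)})
    eta = np.full(P * T, t.gamma00, dtype=float)
    u0 = rng.normal(0.0, np.sqrt(t.var_intercept), P)
    eta += np.repeat(u0, T)
    for m in PREDICTORS:
        _, tau, omega = config.moments[m]
        bp = rng.normal(0.0, tau, P)
        wp = rng.normal(0.0, omega, P * T)
        uk = rng.normal(0.0, np.sqrt(t.var_slopes[m]), P)
        df[f"wp_{m}"] = wp
        df[f"bp_{m}"] = np.repeat(bp, T)
        eta += (t.gamma_wp[m] + np.repeat(uk, T)) * wp
        eta += t.gamma_bp[m] * np.repeat(bp, T)
    y = eta + rng.normal(0.0, np.sqrt(t.var_residual), P * T)
    if config.likert_discretize:
        y = np.clip(np.rint(y), 0, 4)
    df[config.outcome] = y
    return df, t


@dataclass(frozen=True)
class LinkageConfig:
    """How latent symptom states shift behavior in the linked scenario.

    ``app_count`` scales the apps-per-session rate by exp(coef * state);
    ``typing`` shifts the log inter-key gap by coef * state; ``session_rate``
    scales the daytime session rate by exp(coef * state).
    """

    app_count: float = -0.4
    typing: float = 0.25
    session_rate: float = 0.0


@dataclass(frozen=True)
class EventSimConfig:
    """Event-stream microstructure parameters (rates per person-day)."""

    n_persons: int = 30
    n_days: int = 28
    n_apps: int = 20  # person's app catalog size
    dirichlet_alpha: float = 0.8  # concentration of within-session app shares
    apps_per_session_rate: float = 2.0  # extra apps beyond the first, Poisson
    sessions_per_day: float = 10.0  # daytime sessions, Poisson
    night_sessions_per_day: float = 1.2  # sessions starting in [00:00, 06:00)
    session_lognorm: tuple = (0.9, 1.0)  # ln-minutes (mu, sigma)
    max_session_min: float = 180.0
    keystroke_burst_prob: float = 0.4  # probability a session contains typing
    keys_per_burst: float = 12.0  # Poisson mean
    interkey_lognorm: tuple = (-0.8, 0.9)  # ln-seconds (mu, sigma)
    extra_events_per_session: float = 3.0  # clicks/scrolls/view changes
    tz: str = "UTC"
    linkage: LinkageConfig = field(default_factory=LinkageConfig)
    seed: int | None = None

    def __post_init__(self):
        if min(self.sessions_per_day, self.night_sessions_per_day) < 0:
            raise ValueError("session rates must be non-negative")
        if self.dirichlet_alpha <= 0:
            raise ValueError("dirichlet_alpha must be positive")
        if self.n_apps < 1:
            raise ValueError("need at least one app in the catalog")


def _ms_to_ts(ms: int) -> pd.Timestamp:
    return BASE_DATE + pd.Timedelta(milliseconds=int(ms))


class _PersonStream:
    """Primitive sessions/segments/events for one simulated person."""

    def __init__(self, pid):
        self.pid = pid
        self.sessions = []  # (start_ms, end_ms)
        self.segments = []  # (app, start_ms, end_ms)
        self.events = []  # (t_ms, priority, kind, app)

    def add_event(self, t_ms, kind, app=None):
        prio = 0 if kind == "screen_on" else (2 if kind == "screen_off" else 1)
        self.events.append((int(t_ms), prio, kind, app))

    def finalize(self):
        self.events = sorted(set(self.events))
        self.sessions.sort()
        self.segments.sort(key=lambda s: s[1])


def _simulate_person_day(
    ps: _PersonStream,
    day: int,
    cfg: EventSimConfig,
    rng: np.random.Generator,
    app_weights: np.ndarray,
    day_rate: float,
    app_rate: float,
    interkey_mu: float,
):
    base = day * DAY
    n_day = rng.poisson(day_rate)
    n_night = rng.poisson(cfg.night_sessions_per_day)
    starts = np.concatenate(
        [
            base + rng.uniform(6.5 * HOUR, 23.8 * HOUR, n_day),
            base + rng.uniform(0, 6 * HOUR, n_night),
        ]
    )
    mu, sd = cfg.session_lognorm
    durs = np.clip(rng.lognormal(mu, sd, len(starts)), 0.05, cfg.max_session_min) * MIN
    order = np.argsort(starts)
    prev_end = ps.sessions[-1][1] if ps.sessions else -1
    for j in order:
        s = int(round(starts[j]))
        e = int(round(starts[j] + durs[j]))
        if s <= prev_end + SEC or e <= s:
            continue  # would overlap the previous session; skip
        prev_end = e
        ps.sessions.append((s, e))
        ps.add_event(s, "screen_on")
        ps.add_event(e, "screen_off")
        # apps tile the session from its first moment
        n_apps = 1 + min(int(rng.poisson(app_rate)), cfg.n_apps - 1)
        apps = rng.choice(cfg.n_apps, size=n_apps, replace=False, p=app_weights)
        shares = rng.dirichlet(np.full(n_apps, cfg.dirichlet_alpha))
        bounds = s + np.round(np.concatenate([[0.0], np.cumsum(shares)]) * (e - s)).astype(
            "int64"
        )
        bounds[-1] = e
        for k in range(n_apps):
            if bounds[k + 1] > bounds[k]:
                ps.segments.append((f"app{apps[k]:03d}", int(bounds[k]), int(bounds[k + 1])))
                ps.add_event(bounds[k], "app_foreground", f"app{apps[k]:03d}")
        # occasional typing burst somewhere inside the session
        if rng.uniform() < cfg.keystroke_burst_prob:
            n_keys = 2 + rng.poisson(cfg.keys_per_burst)
            t = rng.uniform(s, max(s + 1, e - 30 * SEC))
            for _ in range(n_keys):
                if t >= e - SEC:
                    break
                ps.add_event(int(round(t)), "keystroke")
                gap = np.clip(
                    rng.lognormal(interkey_mu, cfg.interkey_lognorm[1]), 0.03, 20.0
                )
                t += gap * SEC
        # other touchscreen interactions
        for _ in range(rng.poisson(cfg.extra_events_per_session)):
            kind = rng.choice(["click", "scroll", "view_change"])
            ps.add_event(int(rng.integers(s + 1, e)), kind)


def _truth_from_primitives(streams: list[_PersonStream]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Accumulate exact feature values from the generated primitives.

    Plain dictionary-and-loop arithmetic, independent of the pipeline's
    vectorized implementation, applying the same conventions: clock-hour
    clipping, session-start-hour attribution for the hourly median, typing
    interval to the next event of any kind within the session capped at 5 s,
    and night clipping to [00:00, 06:00).
    """
    hourly_rows = {}
    night_rows = {}

    def hour_cell(pid, hour_idx):
        key = (pid, hour_idx)
        if key not in hourly_rows:
            hourly_rows[key] = {"apps": {}, "sess": [], "typing": []}
        return hourly_rows[key]

    for ps in streams:
        pid = ps.pid
        for app, s, e in ps.segments:
            h = s // HOUR
            while h * HOUR < e:
                lo = max(s, h * HOUR)
                hi = min(e, (h + 1) * HOUR)
                if hi > lo:
                    cell = hour_cell(pid, h)
                    cell["apps"][app] = cell["apps"].get(app, 0) + (hi - lo)
                h += 1
        for s, e in ps.sessions:
            hour_cell(pid, s // HOUR)["sess"].append((e - s) / MIN)
            d = s // DAY
            while d * DAY < e:
                lo = max(s, d * DAY)
                hi = min(e, d * DAY + 6 * HOUR)
                night_rows[(pid, d)] = night_rows.get((pid, d), 0.0) + max(hi - lo, 0) / MIN
                d += 1
        # typing intervals: next event of any kind within the same session
        ev = ps.events
        si = 0
        sessions = ps.sessions
        for j, (t, _, kind, _a) in enumerate(ev):
            if kind != "keystroke":
                continue
            while si < len(sessions) and sessions[si][1] < t:
                si += 1
            if si >= len(sessions) or not (sessions[si][0] <= t <= sessions[si][1]):
                continue
            if j + 1 < len(ev) and ev[j + 1][0] <= sessions[si][1]:
                iv = min((ev[j + 1][0] - t) / SEC, TYPING_CAP_S)
                hour_cell(pid, t // HOUR)["typing"].append(iv)
        # nights with no use are true zeros across the observed span
        if ps.sessions:
            d0 = ps.sessions[0][0] // DAY
            d1 = ps.sessions[-1][1] // DAY
            for d in range(d0, d1 + 1):
                night_rows.setdefault((pid, d), 0.0)

    def median(v):
        v = sorted(v)
        n = len(v)
        return v[n // 2] if n % 2 else 0.5 * (v[n // 2 - 1] + v[n // 2])

    hrows = []
    for (pid, h), cell in sorted(hourly_rows.items()):
        durs = [d for d in cell["apps"].values() if d > 0]
        n_apps = len(durs)
        if n_apps == 0:
            ent = float("nan")
        elif n_apps == 1:
            ent = 0.0
        else:
            tot = sum(durs)
            ent = -sum((d / tot) * np.log(d / tot) for d in durs) / np.log(n_apps)
        hrows.append(
            {
                "person_id": pid,
                "date": _ms_to_ts((h * HOUR // DAY) * DAY),
                "hour": int(h % 24),
                "app_count": n_apps,
                "app_entropy": ent,
                "session_duration_min": median(cell["sess"]) if cell["sess"] else float("nan"),
                "typing_interval_s": median(cell["typing"]) if cell["typing"] else float("nan"),
            }
        )
    nrows = [
        {"person_id": pid, "date": _ms_to_ts(d * DAY), "nighttime_min": v}
        for (pid, d), v in sorted(night_rows.items())
    ]
    return pd.DataFrame(hrows), pd.DataFrame(nrows)


def _events_frame(streams: list[_PersonStream], tz: str) -> pd.DataFrame:
    pids, ts, kinds, apps = [], [], [], []
    for ps in streams:
        for t, _prio, kind, app in ps.events:
            pids.append(ps.pid)
            ts.append(t)
            kinds.append(kind)
            apps.append(app)
    t = BASE_DATE.to_datetime64() + np.asarray(ts, dtype="int64").astype("timedelta64[ms]")
    return pd.DataFrame(
        {
            "person_id": pids,
            "t": t.astype("datetime64[ns]"),
            "kind": kinds,
            "app_id": apps,
            "tz": tz,
        }
    )


def generate_event_streams(config: EventSimConfig):
    """Generate raw event streams plus their exact feature ground truth.

    Returns ``(events, truth_hourly, truth_nighttime)``. The event frame is
    a valid, well-formed pipeline input (paired on/off, no overlong
    sessions, every foreground event inside a session).
    """
    rng = np.random.default_rng(config.seed)
    streams = []
    for i in range(config.n_persons):
        ps = _PersonStream(f"p{i:04d}")
        w = rng.dirichlet(np.ones(config.n_apps) * 1.5)
        for day in range(config.n_days):
            _simulate_person_day(
                ps,
                day,
                config,
                rng,
                w,
                config.sessions_per_day,
                config.apps_per_session_rate,
                config.interkey_lognorm[0],
            )
        ps.finalize()
        streams.append(ps)
    truth_hourly, truth_night = _truth_from_primitives(streams)
    return _events_frame(streams, config.tz), truth_hourly, truth_night


def generate_linked_scenario(
    config: EventSimConfig,
    n_surveys: int | None = None,
    seed: int | None = None,
):
    """Full study bundle: events plus biweekly surveys linked through latent states.

    Each person has a stable trait and, for each 14-day reporting window, a
    latent state; both feed the two survey items (rounded/clipped to 0-4)
    and, through :class:`LinkageConfig`, the behavior generated during that
    window. Loss of interest is tied to the app-diversity channel
    (``linkage.app_count``, negative by default: elevated symptoms -> fewer
    apps in use) and depressed mood to the typing channel (positive:
    elevated mood symptoms -> slower typing).

    Returns a dict with ``events``, ``surveys``, ``latent`` (the per-window
    states), and ``config``.
    """
    seed = seed if seed is not None else config.seed
    rng = np.random.default_rng(seed)
    n_surveys = n_surveys if n_surveys is not None else config.n_days // 14
    if n_surveys < 1:
        raise ValueError("n_days too short for a single 14-day survey window")
    link = config.linkage
    streams = []
    survey_rows = []
    latent_rows = []
    for i in range(config.n_persons):
        pid = f"p{i:04d}"
        ps = _PersonStream(pid)
        w = rng.dirichlet(np.ones(config.n_apps) * 1.5)
        trait_loss = rng.normal()
        trait_mood = rng.normal()
        for k in range(n_surveys):
            z = rng.normal()  # loss-of-interest window state
            m = rng.normal()  # depressed-mood window state
            day_rate = config.sessions_per_day * np.exp(link.session_rate * z)
            app_rate = config.apps_per_session_rate * np.exp(link.app_count * z)
            interkey_mu = config.interkey_lognorm[0] + link.typing * m
            for day in range(14 * k, 14 * (k + 1)):
                _simulate_person_day(
                    ps, day, config, rng, w, day_rate, app_rate, interkey_mu
                )
            loss = int(np.clip(np.rint(2.2 + 0.9 * trait_loss + 0.9 * z + rng.normal(0, 0.4)), 0, 4))
            mood = int(np.clip(np.rint(2.0 + 0.9 * trait_mood + 0.9 * m + rng.normal(0, 0.4)), 0, 4))
            survey_rows.append(
                {
                    "person_id": pid,
                    "symptom_date": BASE_DATE + pd.Timedelta(days=14 * (k + 1)),
                    "loss_of_interest": loss,
                    "depressed_mood": mood,
                }
            )
            latent_rows.append(
                {"person_id": pid, "window": k, "state_loss": z, "state_mood": m}
            )
        ps.finalize()
        streams.append(ps)
    return {
        "events": _events_frame(streams, config.tz),
        "surveys": pd.DataFrame(survey_rows),
        "latent": pd.DataFrame(latent_rows),
        "config": config,
    }


def config_to_dict(config) -> dict:
    """YAML-friendly dump of any simulation config (for truth files)."""
    return asdict(config)
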