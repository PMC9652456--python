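"""Head-fixed operant self-administration schedule logic.

Implements the event-level rules of a head-fixed sucrose self-administration
task: an active-lever press (outside any timeout, below the session reward
cap) triggers a tone cue and a delayed sucrose delivery, then a refractory
timeout during which further presses are logged but have no effect. Phase
variants disable the cue and/or the reward (extinction, reinstatement).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "EventLog",
    "ScheduleConfig",
    "SessionSummary",
    "apply_schedule",
    "summarize_session",
    "extinction_met",
    "EVENT_TYPES",
]

EVENT_TYPES = ("press_active", "press_inactive", "cue_on", "sucrose_on", "timeout_start")


@dataclass
class ScheduleConfig:
    """Parameters of the reinforcement schedule.

    timeout_s: refractory period after each reinforced press (20 s).
    cue_dur_s: tone cue duration (1.6 s, 8 kHz in the task).
    sucrose_delay_s: press-to-delivery interval (3 s), also used downstream
        as the middle segment of the peri-event window.
    sucrose_dur_s: liquid delivery duration (2 s).
    reward_cap: max sucrose deliveries per session (10/20/40 across
        acquisition days), or None for uncapped sessions.
    deliver_sucrose / deliver_cue: phase switches. Extinction disables both;
        cue-induced reinstatement re-enables the cue only.
    """

    timeout_s: float = 20.0
    cue_dur_s: float = 1.6
    sucrose_delay_s: float = 3.0
    sucrose_dur_s: float = 2.0
    reward_cap: int | None = None
    deliver_sucrose: bool = True
    deliver_cue: bool = True

    def __post_init__(self) -> None:
        for name in ("timeout_s", "cue_dur_s", "sucrose_delay_s", "sucrose_dur_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.reward_cap is not None and self.reward_cap < 0:
            raise ValueError("reward_cap must be >= 0 or None")


@dataclass
class EventLog:
    """Ordered behavioral events of one session.

    ``events`` has columns (time_s, event_type, lever, reinforced); times are
    non-decreasing and lie within [0, duration_s]. Every reinforced press has
    exactly one cue event at its time whenever the phase delivers cues.
    """

    events: pd.DataFrame
    duration_s: float
    phase: str = "acquisition"

    def __post_init__(self) -> None:
        required = {"time_s", "event_type", "lever", "reinforced"}
        missing = required - set(self.events.columns)
        if missing:
            raise ValueError(f"EventLog missing columns: {sorted(missing)}")
        t = self.events["time_s"].to_numpy(dtype=float)
        if t.size and (np.any(np.diff(t) < 0) or t[0] < 0 or t[-1] > self.duration_s):
            raise ValueError("event times must be non-decreasing within [0, duration_s]")

    def press_times(self, lever: str = "active") -> np.ndarray:
        ev = self.events
        m = (ev["event_type"] == f"press_{lever}")
        return ev.loc[m, "time_s"].to_numpy(dtype=float)

    @property
    def active_press_times(self) -> np.ndarray:
        return self.press_times("active")

    def to_csv(self, path) -> None:
        df = self.events.copy()
        df.insert(0, "phase", self.phase)
        df["duration_s"] = self.duration_s
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "EventLog":
        df = pd.read_csv(path)
        phase = str(df["phase"].iloc[0]) if ("phase" in df and len(df)) else "acquisition"
        duration = float(df["duration_s"].iloc[0]) if ("duration_s" in df and len(df)) else np.inf
        events = df[["time_s", "event_type", "lever", "reinforced"]].copy()
        events["reinforced"] = events["reinforced"].astype(bool)
        return cls(events=events, duration_s=duration, phase=phase)


@dataclass
class SessionSummary:
    active_presses: int
    inactive_presses: int
    reinforced_presses: int
    rewards_delivered: int


def _as_times(x, duration_s: float, what: str) -> np.ndarray:
    t = np.asarray(x, dtype=float)
    if t.ndim != 1 and t.size:
        t = t.ravel()
    if np.any(t < 0):
        raise ValueError(f"{what} contains negative times")
    if np.any(t > duration_s):
        raise ValueError(f"{what} contains times beyond the session duration")
    if t.size and np.any(np.diff(t) < 0):
        warnings.warn(f"{what} unsorted; sorting internally", stacklevel=3)
        t = np.sort(t)
    return t


def apply_schedule(
    press_times_active,
    press_times_inactive,
    cfg: ScheduleConfig,
    duration_s: float,
    phase: str = "acquisition",
) -> EventLog:
    """Run raw press times through the reinforcement schedule.

    Active presses are processed in order. A press is reinforced iff no
    timeout is in effect and the reward cap has not been reached (the cap is
    only consumed when sucrose is actually delivered). A reinforced press
    emits a cue (if enabled), a sucrose delivery at ``press +
    sucrose_delay_s`` (if enabled), and starts a timeout. The timeout
    interval is half-open ``[t, t + timeout_s)``: a press landing exactly at
    the end is reinforced. Inactive presses are logged, never reinforced. In
    phases where neither cue nor sucrose is delivered (extinction), no press
    is reinforced and no timeout ever starts.
    """
    active = _as_times(press_times_active, duration_s, "active press times")
    inactive = _as_times(press_times_inactive, duration_s, "inactive press times")

    rows: list[tuple[float, str, str, bool]] = []
    timeout_until = -np.inf
    rewards = 0
    any_consequence = cfg.deliver_cue or cfg.deliver_sucrose

    for t in active:
        cap_ok = (not cfg.deliver_sucrose) or (cfg.reward_cap is None) or (rewards < cfg.reward_cap)
        # 1-ns slack so a press exactly at the timeout boundary is reinforced
        # regardless of how its timestamp rounds in binary
        reinforced = any_consequence and (t >= timeout_until - 1e-9) and cap_ok
        rows.append((t, "press_active", "active", reinforced))
        if reinforced:
            if cfg.deliver_cue:
                rows.append((t, "cue_on", "active", False))
            if cfg.deliver_sucrose:
                rows.append((t + cfg.sucrose_delay_s, "sucrose_on", "active", False))
                rewards += 1
            rows.append((t, "timeout_start", "active", False))
            timeout_until = t + cfg.timeout_s

    rows.extend((t, "press_inactive", "inactive", False) for t in inactive)

    df = pd.DataFrame(rows, columns=["time_s", "event_type", "lever", "reinforced"])
    # sucrose deliveries may land past the session end; clip them out
    df = df[df["time_s"] <= duration_s]
    df = df.sort_values("time_s", kind="stable").reset_index(drop=True)
    return EventLog(events=df, duration_s=duration_s, phase=phase)


def summarize_session(log: EventLog) -> SessionSummary:
    """Tally presses, reinforced presses and rewards from an event log."""
    ev = log.events
    is_active = ev["event_type"] == "press_active"
    return SessionSummary(
        active_presses=int(is_active.sum()),
        inactive_presses=int((ev["event_type"] == "press_inactive").sum()),
        reinforced_presses=int((is_active & ev["reinforced"]).sum()),
        rewards_delivered=int((ev["event_type"] == "sucrose_on").sum()),
    )


def extinction_met(
    extinction_daily_counts,
    acquisition_last2_counts,
    min_days: int = 10,
    frac: float = 0.20,
) -> tuple[bool, dict]:
    """Evaluate the a-priori extinction criterion.

    Met iff (1) at least ``min_days`` extinction sessions have run and
    (2) on at least 2 of the last 3 days the daily active-press count is at
    most ``frac`` (default 20%) of the mean of the last two acquisition days.
    Daily press count stands in for "pressing rate" since sessions are
    fixed-length. Returns (met, reasons-dict).
    """
    counts = list(extinction_daily_counts)
    acq = np.asarray(acquisition_last2_counts, dtype=float)
    baseline = float(acq.mean())
    if baseline <= 0:
        raise ValueError("acquisition baseline mean must be > 0 for the 20% criterion")
    threshold = frac * baseline
    enough_days = len(counts) >= min_days
    last3 = counts[-3:]
    n_below = sum(c <= threshold for c in last3)
    met = enough_days and n_below >= 2
    reasons = {
        "n_days": len(counts),
        "min_days": min_days,
        "threshold": threshold,
        "last3": last3,
        "n_below": n_below,
        "enough_days": enough_days,
    }
    return met, reasons
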