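"""Core domain types shared by all pipeline stages.

Conventions used throughout the package:

* times are seconds from session start (floats),
* sample indices are 0-based,
* event intervals are half-open ``[start, end)``,
* voltages are in microvolts,
* maze arms are labelled 1-based (arm 1 is adjacent to arm 8 on the
  eight-arm ring; positions 1..12 on the twelve-position ring).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

log = logging.getLogger("ripplecheck")

CHANNEL_ROLES = ("hippocampal", "cortical", "reference")
CONDITIONS = ("disruption", "stim_control", "no_stim")
TASKS = ("NMTS", "MTS", "SEQ")
ZONES = ("reward", "center", "arm")

#: speed below which the animal counts as immobile (cm/s)
IMMOBILITY_SPEED_CM_S = 5.0


class ValidationError(ValueError):
    """An input violates a domain-type invariant."""


class FormatError(ValueError):
    """A file is syntactically readable but missing required metadata."""


class IntegrityError(ValueError):
    """A file's payload is inconsistent with its metadata."""


# ---------------------------------------------------------------------------
# continuous signals
# ---------------------------------------------------------------------------


@dataclass
class ContinuousSignal:
    """Multichannel sampled voltage trace.

    Parameters
    ----------
    data:
        Array of shape ``(n_channels, n_samples)`` in microvolts.
    fs:
        Sampling rate in Hz (default 4000).
    t0:
        Time of the first sample in seconds.
    channel_roles:
        One role per channel, each from ``{"hippocampal", "cortical",
        "reference"}``.
    """

    data: np.ndarray
    fs: float = 4000.0
    t0: float = 0.0
    channel_roles: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if not self.channel_roles:
            self.channel_roles = ("hippocampal",) * self.data.shape[0]
        self.channel_roles = tuple(self.channel_roles)
        if self.fs <= 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        if len(self.channel_roles) != self.data.shape[0]:
            raise IntegrityError(
                f"{len(self.channel_roles)} roles for {self.data.shape[0]} channels"
            )
        for role in self.channel_roles:
            if role not in CHANNEL_ROLES:
                raise ValidationError(f"unknown channel role {role!r}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def t_end(self) -> float:
        return self.t0 + self.duration_s

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    def channels_with_role(self, role: str) -> list[int]:
        return [i for i, r in enumerate(self.channel_roles) if r == role]

    def require_role(self, role: str) -> list[int]:
        idx = self.channels_with_role(role)
        if not idx:
            raise ValidationError(f"signal has no {role} channel")
        return idx

    def time_to_index(self, t: float) -> int:
        return int(round((t - self.t0) * self.fs))

    def index_to_time(self, i: int) -> float:
        return self.t0 + i / self.fs

    def copy(self) -> "ContinuousSignal":
        return ContinuousSignal(
            self.data.copy(), fs=self.fs, t0=self.t0, channel_roles=self.channel_roles
        )


# ---------------------------------------------------------------------------
# ripple events
# ---------------------------------------------------------------------------

EVENT_COLUMNS = ("start_s", "end_s", "peak_time_s", "peak_amp_uv")

#: events detected offline must last at least this long (s)
MIN_EVENT_DURATION_S = 0.040


@dataclass
class EventList:
    """Sorted, non-overlapping ripple intervals with peak time/amplitude.

    ``source`` records whether the list came from the offline detector or
    from the synthetic generator's ground truth.
    """

    start_s: np.ndarray
    end_s: np.ndarray
    peak_time_s: np.ndarray
    peak_amp_uv: np.ndarray
    source: str = "offline"

    def __post_init__(self) -> None:
        self.start_s = np.asarray(self.start_s, dtype=float)
        self.end_s = np.asarray(self.end_s, dtype=float)
        self.peak_time_s = np.asarray(self.peak_time_s, dtype=float)
        self.peak_amp_uv = np.asarray(self.peak_amp_uv, dtype=float)
        n = len(self.start_s)
        if not (len(self.end_s) == len(self.peak_time_s) == len(self.peak_amp_uv) == n):
            raise IntegrityError("event columns have unequal lengths")
        if n and np.any(self.start_s >= self.end_s):
            raise ValidationError("every event must satisfy start_s < end_s")
        if n > 1:
            if np.any(np.diff(self.start_s) < 0):
                raise ValidationError("events must be sorted by start_s")
            if np.any(self.start_s[1:] < self.end_s[:-1]):
                raise ValidationError("events must be non-overlapping")
        if self.source == "offline" and n:
            dur = self.end_s - self.start_s
            # allow one sample of rounding slack
            if np.any(dur < MIN_EVENT_DURATION_S - 1e-9):
                raise ValidationError(
                    "offline-detected events must be at least 40 ms long"
                )

    @classmethod
    def empty(cls, source: str = "offline") -> "EventList":
        z = np.empty(0)
        return cls(z, z.copy(), z.copy(), z.copy(), source=source)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, source: str = "offline") -> "EventList":
        return cls(
            df["start_s"].to_numpy(),
            df["end_s"].to_numpy(),
            df["peak_time_s"].to_numpy(),
            df["peak_amp_uv"].to_numpy(),
            source=source,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "start_s": self.start_s,
                "end_s": self.end_s,
                "peak_time_s": self.peak_time_s,
                "peak_amp_uv": self.peak_amp_uv,
            }
        )

    @property
    def durations_s(self) -> np.ndarray:
        return self.end_s - self.start_s

    def __len__(self) -> int:
        return len(self.start_s)

    def __iter__(self):
        for i in range(len(self)):
            yield (
                self.start_s[i],
                self.end_s[i],
                self.peak_time_s[i],
                self.peak_amp_uv[i],
            )


# ---------------------------------------------------------------------------
# online detection log
# ---------------------------------------------------------------------------


@dataclass
class DetectionLog:
    """Outcome of a simulated real-time detection run.

    ``entries`` has one row per raw threshold crossing with columns
    ``t_detect_s`` (float), ``vetoed`` (bool, cortical artifact veto),
    ``t_stim_s`` (float or NaN) and ``discarded_by_lockout`` (bool).
    """

    entries: pd.DataFrame
    condition: str
    f: float

    LOCKOUT_S = 0.150

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValidationError(f"unknown condition {self.condition!r}")
        if not 5.0 <= self.f <= 13.0:
            raise ValidationError(f"threshold multiplier f={self.f} outside [5, 13]")
        required = {"t_detect_s", "vetoed", "t_stim_s", "discarded_by_lockout"}
        missing = required - set(self.entries.columns)
        if missing:
            raise IntegrityError(f"detection log missing columns {sorted(missing)}")
        stim = np.sort(self.stim_times())
        if len(stim) > 1 and np.any(np.diff(stim) < self.LOCKOUT_S - 1e-9):
            raise ValidationError("stimulations closer than the 150 ms lockout")
        if self.condition == "no_stim" and len(self.stim_times()):
            raise ValidationError("no_stim log contains stimulation times")

    def detection_times(self, include_discarded: bool = False) -> np.ndarray:
        df = self.entries
        if not include_discarded:
            df = df[~df["discarded_by_lockout"]]
        return df["t_detect_s"].to_numpy(dtype=float)

    def accepted_times(self) -> np.ndarray:
        """Detection times that were neither vetoed nor discarded."""
        df = self.entries
        keep = ~df["vetoed"] & ~df["discarded_by_lockout"]
        return df.loc[keep, "t_detect_s"].to_numpy(dtype=float)

    def stim_times(self) -> np.ndarray:
        t = self.entries["t_stim_s"].to_numpy(dtype=float)
        return t[np.isfinite(t)]

    def __len__(self) -> int:
        return len(self.entries)


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Visit:
    """A single arm entry within a trial."""

    arm: int
    phase: str
    correct: bool
    t_entry_s: float
    t_exit_s: float


VISIT_PHASES = ("instruction", "test", "free", "run1", "run2")


@dataclass
class VisitLog:
    """Ordered arm visits of one behavioral session.

    ``session_config`` carries task-specific structure: per-trial
    instructed arm sets for NMTS (``instructed_arms``), the baited 4-arm
    set for MTS (``baited_arms``), and for SEQ the 4 occupied positions
    of the 12-position ring (``arm_positions``) plus the correct cyclic
    order (``sequence``).
    """

    task: str
    session_id: str
    condition: str
    trials: list[list[Visit]]
    session_config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValidationError(f"unknown task {self.task!r}")
        if self.condition not in CONDITIONS:
            raise ValidationError(f"unknown condition {self.condition!r}")
        max_arm = 12 if self.task == "SEQ" else 8
        for ti, trial in enumerate(self.trials):
            t_prev = -np.inf
            for v in trial:
                if not 1 <= v.arm <= max_arm:
                    raise ValidationError(
                        f"trial {ti}: arm {v.arm} outside 1..{max_arm} for {self.task}"
                    )
                if v.phase not in VISIT_PHASES:
                    raise ValidationError(f"trial {ti}: unknown phase {v.phase!r}")
                if v.t_entry_s <= t_prev:
                    raise ValidationError(
                        f"trial {ti}: visits must be strictly time-ordered"
                    )
                if v.t_exit_s < v.t_entry_s:
                    raise ValidationError(f"trial {ti}: t_exit before t_entry")
                t_prev = v.t_entry_s
        if self.task == "NMTS":
            for ti, trial in enumerate(self.trials):
                n_instr = sum(1 for v in trial if v.phase == "instruction")
                if n_instr != 4:
                    raise ValidationError(
                        f"trial {ti}: NMTS instruction phase has {n_instr} visits, "
                        "expected exactly 4"
                    )
        if self.task == "SEQ":
            pos = self.session_config.get("arm_positions")
            if pos is not None and len(set(pos)) != 4:
                raise ValidationError("SEQ sessions must have exactly 4 arms present")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def visits(self, phase: str | None = None) -> list[Visit]:
        out = []
        for trial in self.trials:
            for v in trial:
                if phase is None or v.phase == phase:
                    out.append(v)
        return out


# ---------------------------------------------------------------------------
# position / zone trace
# ---------------------------------------------------------------------------


@dataclass
class ZoneTrace:
    """Per-sample maze zone and running speed, for immobility gating."""

    time_s: np.ndarray
    zone: np.ndarray
    speed_cm_s: np.ndarray

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.zone = np.asarray(self.zone, dtype=object)
        self.speed_cm_s = np.asarray(self.speed_cm_s, dtype=float)
        if not (len(self.time_s) == len(self.zone) == len(self.speed_cm_s)):
            raise IntegrityError("zone trace columns have unequal lengths")
        if np.any(self.speed_cm_s < 0):
            raise ValidationError("speed must be nonnegative")
        for z in set(self.zone.tolist()):
            if z not in ZONES:
                raise ValidationError(f"unknown zone {z!r}")

    @property
    def dt(self) -> float:
        if len(self.time_s) < 2:
            return 0.0
        return float(np.median(np.diff(self.time_s)))

    def immobile_mask(self, speed_threshold: float = IMMOBILITY_SPEED_CM_S) -> np.ndarray:
        return self.speed_cm_s < speed_threshold

    def zone_at(self, t: np.ndarray) -> np.ndarray:
        """Zone label at each query time (nearest sample)."""
        idx = np.clip(
            np.searchsorted(self.time_s, np.asarray(t, dtype=float)),
            0,
            len(self.time_s) - 1,
        )
        return self.zone[idx]

    def state_at(self, t: np.ndarray) -> np.ndarray:
        """Behavioral state label combining zone and immobility."""
        idx = np.clip(
            np.searchsorted(self.time_s, np.asarray(t, dtype=float)),
            0,
            len(self.time_s) - 1,
        )
        immobile = self.speed_cm_s[idx] < IMMOBILITY_SPEED_CM_S
        out = np.empty(len(idx), dtype=object)
        for k, (z, im) in enumerate(zip(self.zone[idx], immobile)):
            if z == "reward" and im:
                out[k] = "reward_immobile"
            elif z == "center":
                out[k] = "center"
            else:
                out[k] = "arm_run"
        return out


# ---------------------------------------------------------------------------
# per-session metrics
# ---------------------------------------------------------------------------


@dataclass
class SessionMetrics:
    """Named scalar metrics for one session, keyed for group statistics."""

    session_id: str
    condition: str
    metrics: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValidationError(f"unknown condition {self.condition!r}")

    def to_series(self) -> pd.Series:
        s = pd.Series(self.metrics, dtype=float)
        s["session_id"] = self.session_id
        s["condition"] = self.condition
        return s


def metrics_table(sessions: Sequence[SessionMetrics]) -> pd.DataFrame:
    """Stack per-session metrics into one DataFrame (sessions as rows)."""
    rows = []
    for s in sessions:
        row = {"session_id": s.session_id, "condition": s.condition}
        row.update(s.metrics)
        rows.append(row)
    return pd.DataFrame(rows)
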