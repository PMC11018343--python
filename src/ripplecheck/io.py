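"""Readers and writers for signals, event tables, visit logs and config.

Signals are stored as flat little-endian int16 binary with a JSON
sidecar (``<path>.json``) that carries the sampling rate, start time,
channel roles and the microvolt scale factor.  Event lists and visit
logs are plain TSV with a small ``#key<TAB>json`` comment header.
Configuration files are YAML.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import (
    ContinuousSignal,
    EventList,
    FormatError,
    IntegrityError,
    Visit,
    VisitLog,
)

log = logging.getLogger("ripplecheck")

_SIDECAR_REQUIRED = ("fs", "channel_roles", "scale_uv_per_bit")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_signal(signal: ContinuousSignal, path: str | Path) -> Path:
    """Write a signal as int16 flat binary plus JSON sidecar.

    The scale factor is chosen so the largest absolute sample maps to
    ~32000 counts; it is recorded in the sidecar for lossless-enough
    round trips (quantization error < scale/2 microvolts).
    """
    path = Path(path)
    peak = float(np.max(np.abs(signal.data))) if signal.data.size else 1.0
    scale = max(peak, 1e-12) / 32000.0
    quantized = np.round(signal.data / scale).astype("<i2")
    quantized.tofile(path)
    sidecar = {
        "fs": signal.fs,
        "t0": signal.t0,
        "channel_roles": list(signal.channel_roles),
        "scale_uv_per_bit": scale,
        "n_channels": signal.n_channels,
        "n_samples": signal.n_samples,
        "dtype": "<i2",
        "order": "channel_major",
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_signal(path: str | Path, format: str = "flat_binary_with_sidecar") -> ContinuousSignal:
    """Read a signal written by :func:`write_signal`.

    Only the flat-binary-with-sidecar format is supported; the vendor
    acquisition format is out of scope and NWB is not available in this
    build.
    """
    if format != "flat_binary_with_sidecar":
        raise FormatError(f"unsupported signal format {format!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sidecar_path = _sidecar_path(path)
    if not sidecar_path.exists():
        raise FormatError(f"missing sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    for key in _SIDECAR_REQUIRED:
        if key not in meta:
            raise FormatError(f"sidecar lacks required key {key!r}")
    raw = np.fromfile(path, dtype=meta.get("dtype", "<i2"))
    n_channels = int(meta.get("n_channels", len(meta["channel_roles"])))
    if n_channels <= 0 or raw.size % n_channels:
        raise IntegrityError(
            f"{raw.size} samples not divisible into {n_channels} equal channels"
        )
    data = raw.reshape(n_channels, -1).astype(float) * float(meta["scale_uv_per_bit"])
    return ContinuousSignal(
        data,
        fs=float(meta["fs"]),
        t0=float(meta.get("t0", 0.0)),
        channel_roles=tuple(meta["channel_roles"]),
    )


# ---------------------------------------------------------------------------
# event tables
# ---------------------------------------------------------------------------


def write_events(events: EventList, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"#source\t{json.dumps(events.source)}\n")
        events.to_dataframe().to_csv(fh, sep="\t", index=False)
    return path


def _read_header(path: Path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].rstrip("\n").partition("\t")
            meta[key] = json.loads(value) if value else None
    return meta


def read_events(path: str | Path) -> EventList:
    path = Path(path)
    meta = _read_header(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.empty:
        return EventList.empty(source=meta.get("source", "offline"))
    return EventList.from_dataframe(df, source=meta.get("source", "offline"))


# ---------------------------------------------------------------------------
# visit logs
# ---------------------------------------------------------------------------


def write_visits(visits: VisitLog, path: str | Path) -> Path:
    path = Path(path)
    rows = []
    for ti, trial in enumerate(visits.trials):
        for v in trial:
            rows.append(
                {
                    "trial": ti + 1,
                    "arm": v.arm,
                    "phase": v.phase,
                    "correct": int(v.correct),
                    "t_entry": v.t_entry_s,
                    "t_exit": v.t_exit_s,
                }
            )
    df = pd.DataFrame(rows, columns=["trial", "arm", "phase", "correct", "t_entry", "t_exit"])
    with open(path, "w") as fh:
        fh.write(f"#task\t{json.dumps(visits.task)}\n")
        fh.write(f"#session_id\t{json.dumps(visits.session_id)}\n")
        fh.write(f"#condition\t{json.dumps(visits.condition)}\n")
        fh.write(f"#session_config\t{json.dumps(visits.session_config)}\n")
        df.to_csv(fh, sep="\t", index=False)
    return path


def read_visits(path: str | Path) -> VisitLog:
    """Read a visit-log TSV (columns trial, arm, phase, correct, t_entry, t_exit).

    Raises :class:`ValidationError` for out-of-range arm ids or unsorted
    visit times — the :class:`VisitLog` constructor enforces both.
    """
    path = Path(path)
    meta = _read_header(path)
    for key in ("task", "session_id", "condition"):
        if key not in meta:
            raise FormatError(f"visit log lacks required header {key!r}")
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"trial", "arm", "phase", "correct", "t_entry", "t_exit"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"visit log missing columns {sorted(missing)}")
    trials: list[list[Visit]] = []
    for _, group in df.groupby("trial", sort=True):
        trials.append(
            [
                Visit(
                    arm=int(r.arm),
                    phase=str(r.phase),
                    correct=bool(r.correct),
                    t_entry_s=float(r.t_entry),
                    t_exit_s=float(r.t_exit),
                )
                for r in group.itertuples()
            ]
        )
    return VisitLog(
        task=meta["task"],
        session_id=meta["session_id"],
        condition=meta["condition"],
        trials=trials,
        session_config=meta.get("session_config") or {},
    )


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "synth": {
        "duration_s": 60.0,
        "fs": 4000.0,
        "noise_exponent": 1.0,
        "noise_rms_uv": 20.0,
        "ripple_rate_by_state": {"reward_immobile": 0.5, "center": 0.1, "arm_run": 0.02},
        "ripple_freq_range_hz": [150.0, 220.0],
        "ripple_duration_range_s": [0.04, 0.15],
        "long_fraction": 0.26,
        "ripple_amp_range_uv": [110.0, 210.0],
        "artifact_amp_uv": 1000.0,
    },
    "offline": {
        "band_hz": [140.0, 225.0],
        "smooth_s": 0.015,
        "detect_multiplier": 9.0,
        "boundary_multiplier": 0.4,
        "merge_gap_s": 0.020,
        "min_duration_s": 0.040,
    },
    "online": {
        "f": 7.0,
        "band_hz": [135.0, 255.0],
        "filter_order": 20,
        "stopband_db": 40.0,
        "rms_window_s": 0.008,
        "span_s": 7.0,
        "freeze_s": 0.050,
        "warmup_s": 2.0,
        "veto_window_s": [0.040, 0.0015],
        "lockout_s": 0.150,
        "disruption_latency_s": 0.001,
        "delay_range_s": [0.150, 0.250],
    },
    "evaluate": {
        "match_tolerance_s": 0.0,
        "power_pre_window_s": [-0.050, -0.020],
        "power_post_window_s": [0.020, 0.050],
        "long_ripple_threshold_s": 0.100,
    },
    "behavior": {
        "bandwidth_trials": 50,
        "alpha": 0.01,
        "chance": 0.5,
        "n_shuffles": 2000,
        "final_trials": 10,
        "final_visits": 100,
        "seq_min_run1_visits": 150,
        "seq_max_visits": 400,
        "sequence_window": 5,
        "moving_average_window": 50,
    },
    "stats": {"ci_level": 0.99, "n_boot": 10000},
}


def _deep_update(base: dict, update: dict) -> dict:
    out = dict(base)
    for key, value in update.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_update(out[key], value)
        else:
            out[key] = value
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Load a YAML config, overlaying user keys on the package defaults."""
    config = DEFAULT_CONFIG
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(user, dict):
            raise FormatError("config file must contain a YAML mapping")
        config = _deep_update(config, user)
    return config
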