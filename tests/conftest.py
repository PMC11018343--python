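"""Shared fixtures: synthetic recordings are generated once per session
and cached, so the detector tests and the acceptance suite reuse them."""

from __future__ import annotations

import numpy as np
import pytest

from ripplecheck.offline import detect_ripples_offline, ripple_envelope
from ripplecheck.online import detect_online
from ripplecheck.synth import LfpSynthParams, constant_zones, generate_lfp

#: the standard synthetic recording: 200 s of immobile reward consumption,
#: 0.5 Hz ripple rate, ~160 uV peak envelope over 20 uV RMS 1/f noise
STANDARD_DURATION_S = 200.0


def standard_params(seed: int) -> LfpSynthParams:
    return LfpSynthParams(duration_s=STANDARD_DURATION_S, seed=seed)


@pytest.fixture(scope="session")
def recording_cache():
    """Lazily computed (signal, truth, envelope, offline, online) per seed."""
    cache: dict[int, dict] = {}

    def get(seed: int, with_online: bool = False) -> dict:
        entry = cache.setdefault(seed, {})
        if "signal" not in entry:
            zones = constant_zones(STANDARD_DURATION_S)
            signal, truth = generate_lfp(standard_params(seed), zones)
            entry.update(signal=signal, truth=truth, zones=zones)
        if "offline" not in entry:
            env = ripple_envelope(entry["signal"])
            entry["env"] = env
            entry["offline"] = detect_ripples_offline(env)
        if with_online and "online" not in entry:
            entry["online"] = detect_online(
                entry["signal"], f=7.0, condition="no_stim", seed=seed
            )
        return entry

    return get


def match_truth_boundaries(truth, detected) -> tuple[int, np.ndarray]:
    """Recovered count and |boundary error| (ms) per recovered truth event.

    A truth event is recovered when an offline event overlaps it; the
    boundary error of a recovered event is the mean of its |start| and
    |end| discrepancies.
    """
    n_rec = 0
    errs = []
    for s, e, _, _ in truth:
        overlap = np.flatnonzero((detected.start_s < e) & (detected.end_s > s))
        if len(overlap) == 0:
            continue
        n_rec += 1
        i = overlap[0]
        errs.append(
            0.5 * (abs(detected.start_s[i] - s) + abs(detected.end_s[i] - e)) * 1e3
        )
    return n_rec, np.asarray(errs)
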