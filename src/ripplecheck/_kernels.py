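"""Numba kernels for the sample-by-sample online detector sweep."""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def ema_threshold_sweep(
    rp: np.ndarray,
    i0: int,
    i1: int,
    mu: float,
    mad: float,
    freeze_left: int,
    alpha: float,
    f: float,
    freeze_n: int,
    detect_from: int,
):
    """Causal sweep of the adaptive threshold ``RP - mu(t) > f * mad(t)``.

    ``mu`` and ``mad`` are exponential moving averages of the ripple
    power and of its absolute deviation.  Both are frozen (not updated)
    for ``freeze_n`` samples after each detection, and re-detection is
    suppressed for the same refractory window so one event yields one
    raw detection.  Detections are only emitted from ``detect_from``
    onward (warm-up).  Returns the detection sample indices and the
    final state so the sweep can be resumed mid-stream.
    """
    cap = 16
    out = np.empty(cap, dtype=np.int64)
    k = 0
    for i in range(i0, i1):
        x = rp[i]
        if freeze_left > 0:
            freeze_left -= 1
        else:
            mu += alpha * (x - mu)
            mad += alpha * (abs(x - mu) - mad)
            if i >= detect_from and mad > 0.0 and x - mu > f * mad:
                if k == cap:
                    cap *= 2
                    grown = np.empty(cap, dtype=np.int64)
                    grown[:k] = out[:k]
                    out = grown
                out[k] = i
                k += 1
                freeze_left = freeze_n
    return out[:k].copy(), mu, mad, freeze_left
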