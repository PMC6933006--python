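"""EMG movement-onset detection.

Onsets are the first samples at which the rectified, envelope-smoothed
EMG crosses an amplitude threshold (individually adjusted in practice,
30-110 microvolts depending on noise level), with a refractory lockout
between detections since elevations are self-paced roughly 5 s apart.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

__all__ = ["detect_onsets", "emg_envelope", "THRESHOLD_RANGE_UV"]

THRESHOLD_RANGE_UV = (30.0, 110.0)


def emg_envelope(emg: np.ndarray, rate_hz: float,
                 lowpass_hz: float = 5.0) -> np.ndarray:
    """Rectified, low-pass smoothed EMG amplitude envelope."""
    sos = signal.butter(2, lowpass_hz, btype="lowpass", fs=rate_hz, output="sos")
    return signal.sosfiltfilt(sos, np.abs(np.asarray(emg, float)))


def detect_onsets(emg: np.ndarray, rate_hz: float,
                  threshold_uv: float = 50.0,
                  refractory_s: float = 3.0) -> np.ndarray:
    """Detect movement onsets in a single EMG channel.

    Returns sample indices of threshold crossings (rising edges of the
    smoothed envelope), enforcing the refractory lockout.
    """
    lo, hi = THRESHOLD_RANGE_UV
    if not lo <= threshold_uv <= hi:
        raise ValueError(f"threshold {threshold_uv} outside the configured "
                         f"range {lo}-{hi} uV")
    if refractory_s <= 0:
        raise ValueError("refractory period must be positive")
    env = emg_envelope(emg, rate_hz)
    above = env >= threshold_uv
    rising = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if above[0]:
        rising = np.concatenate([[0], rising])
    lockout = int(round(refractory_s * rate_hz))
    low = 0.2 * threshold_uv  # back-track to where the burst really starts
    onsets: list[int] = []
    last = -lockout - 1
    for idx in rising:
        if idx - last <= lockout:
            continue
        start = int(idx)
        while start > 0 and env[start - 1] > low:
            start -= 1
        if onsets and start - onsets[-1] <= lockout:
            continue
        onsets.append(start)
        last = idx
    return np.asarray(onsets, dtype=int)
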