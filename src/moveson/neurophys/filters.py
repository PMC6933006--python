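"""The preprocessing filter chain for EEG/EMG recordings.

Applied in order: linear detrend; 2-80 Hz band-pass; 1-80 Hz 3rd-order
Butterworth band-pass (both zero-phase, forward-backward); 49-51 Hz
band-stop (line noise).  The two band-passes are applied sequentially,
in the order stated, rather than treating the first as superseded.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .recording import EphysRecording

__all__ = ["preprocess", "filter_chain"]


def _sos_chain(rate_hz: float):
    nyq = rate_hz / 2.0
    if nyq <= 80.0:
        raise ValueError(f"sampling rate {rate_hz} Hz too low for the 80 Hz "
                         "corner (Nyquist)")
    return [
        signal.butter(3, [2.0, 80.0], btype="bandpass", fs=rate_hz, output="sos"),
        signal.butter(3, [1.0, 80.0], btype="bandpass", fs=rate_hz, output="sos"),
        signal.butter(3, [49.0, 51.0], btype="bandstop", fs=rate_hz, output="sos"),
    ]


def filter_chain(data: np.ndarray, rate_hz: float) -> np.ndarray:
    """Detrend + zero-phase filter an array along its last axis."""
    out = signal.detrend(np.asarray(data, float), axis=-1, type="linear")
    for sos in _sos_chain(rate_hz):
        out = signal.sosfiltfilt(sos, out, axis=-1)
    return out


def preprocess(rec: EphysRecording) -> EphysRecording:
    """Return a new recording with the filter chain applied to all channels."""
    return EphysRecording(
        eeg=filter_chain(rec.eeg, rec.rate_hz),
        emg=filter_chain(rec.emg, rec.rate_hz),
        eeg_channels=list(rec.eeg_channels),
        emg_channels=list(rec.emg_channels),
        rate_hz=rec.rate_hz,
        events=rec.events.copy(),
        lesioned_hemisphere=rec.lesioned_hemisphere,
        trained_arm=rec.trained_arm,
        meta={**rec.meta, "preprocessed": True},
    )
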