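"""Event-locked epoching with automated artifact rejection.

Visual trial inspection is replaced by an automated criterion: trials
whose peak-to-peak EEG amplitude on any channel exceeds a configurable
limit are rejected, with the reason logged on the trial set.
"""

from __future__ import annotations

import numpy as np

from .recording import EphysRecording, TrialSet

__all__ = ["epoch"]


def epoch(rec: EphysRecording,
          events: np.ndarray | None = None,
          window_s: tuple[float, float] = (-1.0, 2.0),
          reject_ptp_uv: float | None = 150.0,
          channels: list[str] | None = None) -> TrialSet:
    """Slice a recording into event-locked trials.

    Parameters
    ----------
    events
        Onset sample indices; defaults to the recording's own markers.
    window_s
        Epoch window in seconds relative to each onset.
    reject_ptp_uv
        Peak-to-peak EEG rejection criterion (None disables rejection;
        EMG channels are exempt — bursts are high-amplitude by design).
    channels
        Channel subset (EEG and/or EMG names); default all.
    """
    if events is None:
        events = rec.events
    events = np.asarray(events, dtype=int)
    if channels is None:
        channels = list(rec.eeg_channels) + list(rec.emg_channels)
    data = np.vstack([rec.channel(c)[None, :] for c in channels])
    is_eeg = np.array([c in rec.eeg_channels for c in channels])

    lo = int(round(window_s[0] * rec.rate_hz))
    hi = int(round(window_s[1] * rec.rate_hz))
    if hi <= lo:
        raise ValueError("window must have positive length")
    n = rec.n_samples
    kept: list[np.ndarray] = []
    rejected: list[tuple[int, str]] = []
    for i, ev in enumerate(events):
        a, b = ev + lo, ev + hi
        if a < 0 or b > n:
            rejected.append((i, "outside recording"))
            continue
        ep = data[:, a:b]
        if reject_ptp_uv is not None and is_eeg.any():
            ptp = ep[is_eeg].max(axis=1) - ep[is_eeg].min(axis=1)
            if ptp.max() > reject_ptp_uv:
                ch = np.array(channels)[is_eeg][ptp.argmax()]
                rejected.append((i, f"peak-to-peak {ptp.max():.0f} uV on {ch}"))
                continue
        kept.append(ep)
    epochs = (np.stack(kept) if kept
              else np.empty((0, len(channels), hi - lo)))
    return TrialSet(epochs=epochs, channels=list(channels),
                    window_s=window_s, rate_hz=rec.rate_hz, rejected=rejected)
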