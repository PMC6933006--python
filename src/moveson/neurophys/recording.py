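"""Containers for multichannel EEG+EMG recordings and epoched trials."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["EphysRecording", "TrialSet"]


@dataclass
class EphysRecording:
    """A continuous EEG+EMG recording with event markers.

    ``eeg`` is (n_eeg_channels, n_samples) in microvolts, referenced to
    linked earlobes; ``emg`` is (n_emg_channels, n_samples).
    """

    eeg: np.ndarray
    emg: np.ndarray
    eeg_channels: list[str]
    emg_channels: list[str]
    rate_hz: float
    events: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    lesioned_hemisphere: str | None = None  # "left" | "right"
    trained_arm: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.eeg = np.atleast_2d(np.asarray(self.eeg, float))
        self.emg = np.atleast_2d(np.asarray(self.emg, float))
        self.events = np.asarray(self.events, dtype=int)
        if self.eeg.shape[0] != len(self.eeg_channels):
            raise ValueError("eeg channel count mismatch")
        if self.emg.shape[0] != len(self.emg_channels):
            raise ValueError("emg channel count mismatch")
        if self.eeg.shape[1] != self.emg.shape[1]:
            raise ValueError("eeg and emg must have equal length")
        if self.rate_hz <= 0:
            raise ValueError("rate must be positive")
        n = self.eeg.shape[1]
        if self.events.size and (self.events.min() < 0 or self.events.max() >= n):
            raise ValueError("event indices out of range")

    @property
    def n_samples(self) -> int:
        return self.eeg.shape[1]

    def channel(self, name: str) -> np.ndarray:
        if name in self.eeg_channels:
            return self.eeg[self.eeg_channels.index(name)]
        if name in self.emg_channels:
            return self.emg[self.emg_channels.index(name)]
        raise KeyError(name)


@dataclass
class TrialSet:
    """Epoched trials: (n_trials, n_channels, n_samples)."""

    epochs: np.ndarray
    channels: list[str]
    window_s: tuple[float, float]
    rate_hz: float
    rejected: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, float)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be trials x channels x samples")
        if self.epochs.shape[1] != len(self.channels):
            raise ValueError("channel count mismatch")

    @property
    def n_trials(self) -> int:
        return self.epochs.shape[0]

    def channel_index(self, name: str) -> int:
        return self.channels.index(name)
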