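"""Synthetic EEG+EMG with tunable beta-band cortico-muscular coupling.

Emulates the clinical recording setup: 20-channel 10-20 EEG referenced to
linked earlobes plus a deltoid EMG channel, sampled at 200 Hz, during
~100 self-paced arm elevations spaced about 5 s apart.

The coupling model: a band-limited Gaussian "beta" process (centred on
``beta_freq``) is injected into the chosen EEG channels and — delayed by
``lag`` seconds (cortico-spinal conduction) — into the EMG during each
movement burst.  ``coupling_strength`` in [0, 1] sets the fraction of
the EMG beta component shared with cortex (0 = independent, 1 = fully
shared).  Background EEG activity is 1/f noise scaled by ``noise_sd``;
EMG bursts are envelope-modulated broadband noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from ..neurophys.montage import MONTAGE_1020
from ..neurophys.recording import EphysRecording

__all__ = ["CouplingDesign", "gen_ephys"]

RATE_HZ = 200.0
EEG_BETA_AMP_UV = 4.0
EMG_BETA_AMP_UV = 20.0
EMG_BURST_GAIN = 8.0  # broadband burst SD = gain * noise_sd
BURST_DURATION_S = 2.0


@dataclass(frozen=True)
class CouplingDesign:
    """Design of a coupled EEG/EMG simulation."""

    coupling_strength: float = 0.8
    coupled_channels: tuple[str, ...] = ("C3",)
    beta_freq: float = 17.0  # Hz, centre of the low-beta band
    bandwidth: float = 6.0   # Hz, full width of the beta process
    lag: float = 0.015       # s, cortex -> muscle conduction delay
    n_trials: int = 100
    noise_sd: float = 10.0   # uV, EEG background scale
    trial_spacing_s: float = 5.0
    seed: int = 0
    lesioned_hemisphere: str = "left"
    trained_arm: str = "right"

    def __post_init__(self) -> None:
        if not 0.0 <= self.coupling_strength <= 1.0:
            raise ValueError("coupling_strength must be in [0, 1]")
        unknown = [c for c in self.coupled_channels if c not in MONTAGE_1020]
        if unknown:
            raise ValueError(f"coupled channels not in 10-20 montage: {unknown}")
        if self.lag <= 0:
            raise ValueError("lag must be > 0")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if not 14.0 <= self.beta_freq <= 20.0:
            raise ValueError("beta_freq must lie in the low-beta band (14-20 Hz)")


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-SD 1/f-amplitude noise via spectral shaping."""
    white = rng.normal(size=n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / RATE_HZ)
    scale = np.ones_like(f)
    nz = f > 0
    scale[nz] = 1.0 / np.sqrt(f[nz])
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _beta_process(rng: np.random.Generator, n: int, freq: float,
                  bandwidth: float) -> np.ndarray:
    lo = max(freq - bandwidth / 2.0, 0.5)
    hi = min(freq + bandwidth / 2.0, RATE_HZ / 2.0 - 1.0)
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=RATE_HZ, output="sos")
    x = signal.sosfiltfilt(sos, rng.normal(size=n))
    sd = x.std()
    return x / sd if sd > 0 else x


def gen_ephys(design: CouplingDesign) -> EphysRecording:
    """Generate a coupled EEG+EMG recording; deterministic given seed."""
    rng = np.random.default_rng(design.seed)
    spacing = design.trial_spacing_s
    duration = spacing * (design.n_trials + 1)
    n = int(round(duration * RATE_HZ))
    t = np.arange(n) / RATE_HZ

    # event markers (EMG burst onsets), jittered around the nominal spacing
    onsets_s = spacing * np.arange(1, design.n_trials + 1)
    onsets_s = onsets_s + rng.uniform(-0.3, 0.3, size=design.n_trials)
    events = np.round(onsets_s * RATE_HZ).astype(int)

    # movement envelope: smooth bursts after each onset
    env = np.zeros(n)
    ramp = int(0.15 * RATE_HZ)
    burst = int(BURST_DURATION_S * RATE_HZ)
    win = np.ones(burst)
    win[:ramp] = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
    win[-ramp:] = win[:ramp][::-1]
    for ev in events:
        hi = min(ev + burst, n)
        env[ev:hi] = np.maximum(env[ev:hi], win[: hi - ev])

    beta_shared = _beta_process(rng, n, design.beta_freq, design.bandwidth)
    lag_samples = int(round(design.lag * RATE_HZ))
    beta_lagged = np.roll(beta_shared, lag_samples)
    beta_indep = _beta_process(rng, n, design.beta_freq, design.bandwidth)

    channels = list(MONTAGE_1020)
    eeg = np.empty((len(channels), n))
    for i, ch in enumerate(channels):
        x = design.noise_sd * _pink_noise(rng, n)
        if ch in design.coupled_channels:
            x = x + EEG_BETA_AMP_UV * beta_shared
        eeg[i] = x

    cs = design.coupling_strength
    emg_beta = cs * beta_lagged + np.sqrt(max(1.0 - cs**2, 0.0)) * beta_indep
    broadband = rng.normal(size=n)
    emg = env * (EMG_BURST_GAIN * design.noise_sd * broadband
                 + EMG_BETA_AMP_UV * emg_beta)
    emg = emg + 0.05 * design.noise_sd * rng.normal(size=n)

    return EphysRecording(
        eeg=eeg, emg=emg[None, :], eeg_channels=channels,
        emg_channels=["DELT"], rate_hz=RATE_HZ, events=events,
        lesioned_hemisphere=design.lesioned_hemisphere,
        trained_arm=design.trained_arm,
        meta={"design": design.__dict__ | {"coupled_channels":
                                           list(design.coupled_channels)}},
    )
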