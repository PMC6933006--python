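"""Weighted Phase Lag Index between EEG channels and EMG.

WPLI measures the consistency of the sign of the imaginary part of the
EEG-EMG cross-spectrum across trials.  It ignores zero-lag (volume
conducted) contributions and ranges from 0 (no consistent lagged phase
relation) to 1 (perfectly consistent lag).  For a set of trials with
per-trial, per-frequency imaginary cross-spectra Im S_xy:

    WPLI = | sum_{trials, band bins} Im S_xy | / sum_{trials, band bins} |Im S_xy|

i.e. the band estimate pools trials and frequency bins into the same
sums ("band-pooled"), which keeps the small-sample null bias at
~1/sqrt(n_trials * n_bins).  A per-bin estimator averaged across the
band is available via ``band_average=True``.

Significance is assessed with a leave-one-trial-out jackknife on the
*signed* ratio u = sum(Im)/sum(|Im|) — u is symmetric around 0 under
the null (WPLI = |u| is not), so a two-sided z-test on u has correct
level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal

from .recording import TrialSet

__all__ = ["WPLIMap", "wpli", "band_imag_cross_spectra", "LOW_BETA_BAND"]

LOW_BETA_BAND = (14.0, 20.0)


@dataclass
class WPLIMap:
    """Per-EEG-channel band WPLI with jackknife uncertainty."""

    channels: list[str]
    wpli: np.ndarray           # in [0, 1]
    signed: np.ndarray         # signed ratio u, wpli == |u|
    jackknife_var: np.ndarray  # variance of u
    significant: np.ndarray    # two-sided 95% flag vs 0
    band: tuple[float, float]
    n_trials: int

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.channels, map(float, self.wpli)))


def band_imag_cross_spectra(trials: TrialSet, emg_channel: str = "DELT",
                            band: tuple[float, float] = LOW_BETA_BAND,
                            rectify_emg: bool = False,
                            taper: str = "boxcar"
                            ) -> tuple[np.ndarray, list[str]]:
    """Per-trial imaginary cross-spectra in a frequency band.

    One taper per epoch; the default rectangular taper keeps the DFT
    bins of broadband signals uncorrelated, which minimises the
    small-sample bias of the pooled WPLI ratio (a Hann taper is
    available for strongly line-like spectra).  Returns
    ``(imc, eeg_channels)`` with ``imc`` of shape
    (n_trials, n_eeg_channels, n_band_bins).
    """
    if trials.n_trials < 1:
        raise ValueError("no trials")
    emg_idx = trials.channel_index(emg_channel)
    eeg_names = [c for c in trials.channels if c != emg_channel]
    eeg_idx = [trials.channel_index(c) for c in eeg_names]

    x = trials.epochs  # (n, C, T)
    nsamp = x.shape[-1]
    if taper == "boxcar":
        taper_w = np.ones(nsamp)
    elif taper == "hann":
        taper_w = _signal.windows.hann(nsamp, sym=False)
    else:
        raise ValueError(f"unknown taper {taper!r}")
    freqs = np.fft.rfftfreq(nsamp, d=1.0 / trials.rate_hz)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    if not sel.any():
        raise ValueError(f"band {band} contains no frequency bins at "
                         f"resolution {freqs[1]:.3f} Hz")
    spec = np.fft.rfft(x * taper_w, axis=-1)[..., sel]
    emg_spec = spec[:, emg_idx, :]
    if rectify_emg:
        rect = np.abs(x[:, emg_idx, :])
        rect = rect - rect.mean(axis=-1, keepdims=True)
        emg_spec = np.fft.rfft(rect * taper_w, axis=-1)[..., sel]
    eeg_spec = spec[:, eeg_idx, :]
    cross = eeg_spec * np.conj(emg_spec)[:, None, :]
    imc = np.imag(cross)
    # zero-lag (purely real) cross-spectra leave only float rounding in
    # the imaginary part; zero it so the 0/0 convention applies
    imc[np.abs(imc) < 1e-9 * np.abs(cross)] = 0.0
    return imc, eeg_names


def _signed_ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    """sum(Im)/sum(|Im|) with the 0/0 (zero-lag) convention -> 0."""
    tiny = np.finfo(float).tiny
    return np.where(den > tiny, num / np.maximum(den, tiny), 0.0)


def wpli(trials: TrialSet, emg_channel: str = "DELT",
         band: tuple[float, float] = LOW_BETA_BAND,
         band_average: bool = False, min_trials: int = 10,
         rectify_emg: bool = False,
         passband: tuple[float, float] = (1.0, 80.0)) -> WPLIMap:
    """Band WPLI between every EEG channel and one EMG channel.

    Requires at least ``min_trials`` trials (jackknife variance needs a
    sensible sample).  ``band_average=True`` switches to the per-bin
    estimator averaged across band bins.
    """
    if trials.n_trials < min_trials:
        raise ValueError(f"need >= {min_trials} trials, got {trials.n_trials}")
    if not 0.0 < band[0] < band[1]:
        raise ValueError("band must be an increasing positive pair")
    if band[1] > min(passband[1], trials.rate_hz / 2.0) or band[0] < passband[0]:
        raise ValueError(f"band {band} outside the preprocessing passband "
                         f"{passband} / Nyquist {trials.rate_hz / 2:.0f} Hz")
    imc, names = band_imag_cross_spectra(trials, emg_channel, band,
                                         rectify_emg=rectify_emg)
    n = imc.shape[0]
    if band_average:
        num = np.abs(imc.sum(axis=0))            # (C, F)
        den = np.abs(imc).sum(axis=0)
        w = np.abs(_signed_ratio(num, den)).mean(axis=-1)
        # jackknife on the per-bin-averaged signed ratio
        s_loo = imc.sum(axis=0)[None] - imc       # (n, C, F)
        a_loo = np.abs(imc).sum(axis=0)[None] - np.abs(imc)
        u_loo = _signed_ratio(s_loo, a_loo).mean(axis=-1)  # (n, C)
        u = _signed_ratio(imc.sum(axis=(0, 2)), np.abs(imc).sum(axis=(0, 2)))
    else:
        s = imc.sum(axis=-1)                      # (n, C) band-pooled
        a = np.abs(imc).sum(axis=-1)
        u = _signed_ratio(s.sum(axis=0), a.sum(axis=0))
        w = np.abs(u)
        u_loo = _signed_ratio(s.sum(axis=0)[None] - s,
                              a.sum(axis=0)[None] - a)  # (n, C)
    var = (n - 1) / n * ((u_loo - u_loo.mean(axis=0)) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(var > 0, u / np.sqrt(var), 0.0)
    return WPLIMap(channels=names, wpli=np.asarray(w, float),
                   signed=np.asarray(u, float), jackknife_var=var,
                   significant=np.abs(z) > 1.959963984540054,
                   band=band, n_trials=n)
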