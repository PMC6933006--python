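"""WPLI estimator limits and the 10-20 montage adjacency."""

import numpy as np
import pytest

from moveson.neurophys import (MONTAGE_1020, epoch, neighbors_1020,
                               preprocess, wpli)
from moveson.neurophys.recording import TrialSet
from moveson.simulate import CouplingDesign, gen_ephys


def _trials_from_arrays(eeg_by_channel: dict, emg: np.ndarray,
                        rate=200.0) -> TrialSet:
    names = list(eeg_by_channel) + ["DELT"]
    arrs = list(eeg_by_channel.values()) + [emg]
    epochs = np.stack([np.stack([a[i] for a in arrs]) for i in
                       range(emg.shape[0])])
    return TrialSet(epochs=epochs, channels=names, window_s=(0.0, 3.0),
                    rate_hz=rate)


class TestWpliLimits:
    def test_noise_free_lagged_coupling_reaches_one(self):
        design = CouplingDesign(coupling_strength=1.0, noise_sd=0.0,
                                n_trials=30, seed=0)
        ts = epoch(preprocess(gen_ephys(design)), window_s=(0.2, 1.8),
                   reject_ptp_uv=None)
        m = wpli(ts)
        assert m.as_dict()["C3"] > 0.999
        assert bool(m.significant[m.channels.index("C3")])

    def test_zero_lag_identical_signals_give_zero_by_convention(self):
        rng = np.random.default_rng(1)
        sig = rng.normal(size=(20, 600))
        ts = _trials_from_arrays({"C3": sig}, sig)  # EMG == EEG, lag 0
        m = wpli(ts)
        assert m.as_dict()["C3"] == 0.0
        assert not m.significant[0]

    def test_independent_noise_wpli_small_and_rarely_flagged(self):
        total_flags = 0
        for seed in range(5):
            design = CouplingDesign(coupling_strength=0.0, n_trials=100,
                                    seed=300 + seed)
            ts = epoch(preprocess(gen_ephys(design)), reject_ptp_uv=None)
            m = wpli(ts)
            assert max(m.wpli) < 0.15
            total_flags += int(m.significant.sum())
        # nominal 5% two-sided test: expect ~5 of 100 channel decisions
        assert total_flags <= 10

    def test_wpli_monotone_in_coupling_strength(self):
        values = []
        for cs in (0.0, 0.25, 0.5, 0.75, 1.0):
            design = CouplingDesign(coupling_strength=cs, n_trials=100,
                                    seed=7)
            ts = epoch(preprocess(gen_ephys(design)), reject_ptp_uv=None)
            values.append(wpli(ts).as_dict()["C3"])
        assert all(b >= a for a, b in zip(values, values[1:]))

    def test_bounded_in_unit_interval(self, coupled_trials):
        m = wpli(coupled_trials)
        assert (m.wpli >= 0).all() and (m.wpli <= 1).all()


class TestWpliInvariances:
    def test_amplitude_rescaling_leaves_wpli_unchanged(self, coupled_trials):
        base = wpli(coupled_trials)
        scaled = TrialSet(epochs=coupled_trials.epochs * 7.3,
                          channels=coupled_trials.channels,
                          window_s=coupled_trials.window_s,
                          rate_hz=coupled_trials.rate_hz)
        assert np.allclose(wpli(scaled).wpli, base.wpli)

    def test_emg_polarity_flip_leaves_wpli_unchanged(self, coupled_trials):
        flipped_epochs = coupled_trials.epochs.copy()
        emg_idx = coupled_trials.channel_index("DELT")
        flipped_epochs[:, emg_idx, :] *= -1.0
        flipped = TrialSet(epochs=flipped_epochs,
                           channels=coupled_trials.channels,
                           window_s=coupled_trials.window_s,
                           rate_hz=coupled_trials.rate_hz)
        assert np.allclose(wpli(flipped).wpli, wpli(coupled_trials).wpli)


class TestWpliValidation:
    def test_too_few_trials_rejected(self, coupled_trials):
        small = TrialSet(epochs=coupled_trials.epochs[:5],
                         channels=coupled_trials.channels,
                         window_s=coupled_trials.window_s,
                         rate_hz=coupled_trials.rate_hz)
        with pytest.raises(ValueError, match="trials"):
            wpli(small)

    def test_band_outside_passband_rejected(self, coupled_trials):
        with pytest.raises(ValueError, match="passband"):
            wpli(coupled_trials, band=(85.0, 95.0))
        with pytest.raises(ValueError, match="passband"):
            wpli(coupled_trials, band=(0.2, 0.8))


class TestMontage:
    def test_c3_neighbourhood(self):
        adj = neighbors_1020()
        names = list(MONTAGE_1020)
        nbrs = {names[j] for j in np.flatnonzero(adj[names.index("C3")])}
        assert {"F3", "P3", "T3", "Cz"} <= nbrs

    def test_adjacency_symmetric_no_self(self):
        adj = neighbors_1020()
        assert np.array_equal(adj, adj.T)
        assert not adj.diagonal().any()

    def test_mean_neighbour_count_in_design_range(self):
        adj = neighbors_1020()
        mean_nbrs = adj.sum(axis=1).mean()
        assert 3.0 <= mean_nbrs <= 5.0

    def test_unknown_channel_rejected(self):
        with pytest.raises(KeyError):
            neighbors_1020(["C3", "XX"])
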