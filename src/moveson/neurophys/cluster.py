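"""Cluster-based permutation comparison of pre vs. post WPLI maps.

The test operates at the single-subject level with trials as the unit of
observation.  A per-trial coherence contribution is formed as the
leave-one-trial-out jackknife pseudovalue of the band WPLI,

    pseudo_i = n * WPLI_all - (n - 1) * WPLI_without_i ,

whose mean is (a bias-reduced estimate of) the condition's WPLI.  Each
channel is compared pre vs. post with a two-sample t statistic on the
pseudovalues; channels exceeding the cluster-forming threshold are kept
only if at least two of their spatial neighbours also exceed it (with
the same sign), connected components are summed into cluster statistics,
and the null distribution of the maximal |cluster statistic| is obtained
by permuting trial condition labels.  Positive clusters have
WPLI_post > WPLI_pre on their members; negative ones the reverse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .montage import neighbors_1020
from .recording import TrialSet
from .wpli import LOW_BETA_BAND, band_imag_cross_spectra

__all__ = ["Cluster", "ClusterResult", "cluster_permutation",
           "wpli_pseudovalues"]


@dataclass
class Cluster:
    channels: list[str]
    sign: str  # "positive" | "negative"
    statistic: float  # summed t over members
    p_value: float


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    channel_t: np.ndarray
    channels: list[str]
    n_permutations: int

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p_value < alpha]


def wpli_pseudovalues(trials: TrialSet, emg_channel: str = "DELT",
                      band: tuple[float, float] = LOW_BETA_BAND
                      ) -> tuple[np.ndarray, list[str]]:
    """Per-trial jackknife pseudovalues of the band-pooled WPLI.

    Returns ``(pseudo, channels)`` with ``pseudo`` (n_trials, n_channels).
    """
    imc, names = band_imag_cross_spectra(trials, emg_channel, band)
    s = imc.sum(axis=-1)
    a = np.abs(imc).sum(axis=-1)
    pseudo = _pseudovalues(s, a)
    return pseudo, names


def _pseudovalues(s: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Jackknife pseudovalues of |sum s|/sum a from per-trial sums."""
    n = s.shape[0]
    tiny = np.finfo(float).tiny
    S, A = s.sum(axis=0), a.sum(axis=0)
    w_all = np.abs(S) / np.maximum(A, tiny)
    w_loo = np.abs(S[None] - s) / np.maximum(A[None] - a, tiny)
    return n * w_all[None] - (n - 1) * w_loo


def _channel_t(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t per channel (columns), y minus x."""
    nx, ny = x.shape[0], y.shape[0]
    mx, my = x.mean(axis=0), y.mean(axis=0)
    vx = x.var(axis=0, ddof=1)
    vy = y.var(axis=0, ddof=1)
    sp = ((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2)
    se = np.sqrt(np.maximum(sp * (1.0 / nx + 1.0 / ny), np.finfo(float).tiny))
    return (my - mx) / se


def _clusters_from_t(t: np.ndarray, thresh: float, adjacency: np.ndarray
                     ) -> list[tuple[np.ndarray, float]]:
    """Same-sign suprathreshold components after the min-2-neighbour rule."""
    out: list[tuple[np.ndarray, float]] = []
    for sign in (1.0, -1.0):
        supra = (sign * t) > thresh
        if supra.sum() == 0:
            continue
        # a suprathreshold channel needs >= 2 suprathreshold neighbours
        nbr_counts = adjacency[:, supra].sum(axis=1)
        keep = supra & (nbr_counts >= 2)
        if keep.sum() == 0:
            continue
        # connected components among kept channels
        idx = np.flatnonzero(keep)
        unvisited = set(idx.tolist())
        while unvisited:
            stack = [unvisited.pop()]
            comp = [stack[0]]
            while stack:
                u = stack.pop()
                for v in np.flatnonzero(adjacency[u]):
                    if v in unvisited:
                        unvisited.remove(v)
                        stack.append(v)
                        comp.append(v)
            members = np.array(sorted(comp))
            out.append((members, float(t[members].sum())))
    return out


def cluster_permutation(pre: TrialSet, post: TrialSet,
                        emg_channel: str = "DELT",
                        adjacency: np.ndarray | None = None,
                        band: tuple[float, float] = LOW_BETA_BAND,
                        n_perm: int = 1000,
                        cluster_alpha: float = 0.05,
                        seed: int = 0) -> ClusterResult:
    """Cluster-based permutation test of post vs. pre coherence.

    ``cluster_alpha`` is the two-sided cluster-forming level applied to
    the per-channel t statistics; cluster p-values are computed against
    the permutation distribution of the maximal absolute cluster
    statistic.
    """
    if n_perm < 200:
        raise ValueError("n_perm must be >= 200")
    if pre.channels != post.channels:
        raise ValueError("pre and post trial sets have different channels")
    imc_pre, names = band_imag_cross_spectra(pre, emg_channel, band)
    imc_post, _ = band_imag_cross_spectra(post, emg_channel, band)
    if adjacency is None:
        adjacency = neighbors_1020(names)
    if adjacency.shape != (len(names), len(names)):
        raise ValueError("adjacency shape does not match channel count")

    s1, a1 = imc_pre.sum(axis=-1), np.abs(imc_pre).sum(axis=-1)
    s2, a2 = imc_post.sum(axis=-1), np.abs(imc_post).sum(axis=-1)
    n1, n2 = s1.shape[0], s2.shape[0]
    df = n1 + n2 - 2
    thresh = stats.t.ppf(1.0 - cluster_alpha / 2.0, df)

    t_obs = _channel_t(_pseudovalues(s1, a1), _pseudovalues(s2, a2))
    observed = _clusters_from_t(t_obs, thresh, adjacency)

    s_all = np.concatenate([s1, s2])
    a_all = np.concatenate([a1, a2])
    rng = np.random.default_rng(seed)
    null_max = np.zeros(n_perm)
    for p in range(n_perm):
        perm = rng.permutation(n1 + n2)
        g1, g2 = perm[:n1], perm[n1:]
        tp = _channel_t(_pseudovalues(s_all[g1], a_all[g1]),
                        _pseudovalues(s_all[g2], a_all[g2]))
        comps = _clusters_from_t(tp, thresh, adjacency)
        if comps:
            null_max[p] = max(abs(c[1]) for c in comps)

    clusters = []
    for members, stat in observed:
        pval = (1.0 + float((null_max >= abs(stat)).sum())) / (n_perm + 1.0)
        clusters.append(Cluster(
            channels=[names[i] for i in members],
            sign="positive" if stat > 0 else "negative",
            statistic=stat, p_value=pval))
    clusters.sort(key=lambda c: c.p_value)
    return ClusterResult(clusters=clusters, channel_t=t_obs,
                         channels=names, n_permutations=n_perm)
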