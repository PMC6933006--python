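"""20-channel International 10-20 montage: names, 2D layout, adjacency.

Coordinates are the conventional schematic top-view layout (nose up,
left ear at negative x) on a unit head circle — adequate for
sensor-level neighbourhood structure; no volume conduction modelling is
attempted.
"""

from __future__ import annotations

import numpy as np

__all__ = ["MONTAGE_1020", "channel_positions", "neighbors_1020"]

#: name -> (x, y) schematic position; 20 scalp channels of the 10-20 system.
MONTAGE_1020: dict[str, tuple[float, float]] = {
    "Fp1": (-0.25, 0.80), "Fp2": (0.25, 0.80),
    "F7": (-0.65, 0.45), "F3": (-0.35, 0.40), "Fz": (0.0, 0.40),
    "F4": (0.35, 0.40), "F8": (0.65, 0.45),
    "T3": (-0.80, 0.0), "C3": (-0.40, 0.0), "Cz": (0.0, 0.0),
    "C4": (0.40, 0.0), "T4": (0.80, 0.0),
    "T5": (-0.65, -0.45), "P3": (-0.35, -0.40), "Pz": (0.0, -0.40),
    "P4": (0.35, -0.40), "T6": (0.65, -0.45),
    "O1": (-0.25, -0.80), "Oz": (0.0, -0.80), "O2": (0.25, -0.80),
}

#: Distance threshold chosen so the mean neighbour count lies in [3, 5]
#: (C3's neighbours are exactly F3, P3, T3 and Cz).
DEFAULT_THRESHOLD = 0.50


def channel_positions(channels: list[str] | None = None) -> np.ndarray:
    channels = list(MONTAGE_1020) if channels is None else channels
    unknown = [c for c in channels if c not in MONTAGE_1020]
    if unknown:
        raise KeyError(f"channels not in the 10-20 montage: {unknown}")
    return np.array([MONTAGE_1020[c] for c in channels], dtype=float)


def neighbors_1020(channels: list[str] | None = None,
                   threshold: float = DEFAULT_THRESHOLD) -> np.ndarray:
    """Boolean adjacency matrix by Euclidean distance on the 2D layout.

    Symmetric with an all-False diagonal.
    """
    pos = channel_positions(channels)
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    adj = d <= threshold
    np.fill_diagonal(adj, False)
    return adj
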