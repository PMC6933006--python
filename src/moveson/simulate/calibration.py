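"""Corruption <-> smoothness calibration for the cohort generator.

The cohort generator specifies each patient-session's *latent* smoothness
(on the MedianLC scale) and realises it through the trajectory
generator's ``corruption`` knob.  The monotone map between the two is
built by simulation — many strokes of the standard scale task at a grid
of corruption levels, per motion-capture dialect — and shipped as a
versioned JSON fixture.  ``scripts/build_calibration.py`` rebuilds it.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = ["build_calibration", "load_calibration", "smoothness_to_corruption",
           "corruption_to_smoothness", "CALIBRATION_RESOURCE"]

CALIBRATION_RESOURCE = "corruption_calibration.json"

DEFAULT_GRID = (0.0, 0.1, 0.2, 0.35, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0)

_cache: dict | None = None


def build_calibration(grid=DEFAULT_GRID, n_traj_per_level: int = 10,
                      seed: int = 20260101, dialects=("inertial", "optical")) -> dict:
    """Simulate the mean stroke smoothness at each corruption level."""
    from ..kinematics import resample, segment_strokes, stroke_smoothness
    from ..sonification import TaskSpec
    from .trajectory import DIALECT_SMOOTH_WINDOW, gen_trajectory

    task = TaskSpec.scale()
    out: dict = {"version": 1, "task": "scale", "n_traj_per_level": n_traj_per_level,
                 "seed": seed, "dialects": {}}
    rng = np.random.default_rng(seed)
    for dialect in dialects:
        means = []
        n_strokes = 0
        for c in grid:
            vals = []
            for _ in range(n_traj_per_level):
                s = int(rng.integers(0, 2**31 - 1))
                tr = resample(gen_trajectory(task, float(c), dialect, seed=s),
                              smooth_window=DIALECT_SMOOTH_WINDOW[dialect])
                vals.extend(stroke_smoothness(st) for st in segment_strokes(tr))
            n_strokes += len(vals)
            means.append(float(np.mean(vals)))
        # enforce strict monotone decrease for a well-defined inverse
        means = np.minimum.accumulate(means).tolist()
        out["dialects"][dialect] = {"corruption": list(map(float, grid)),
                                    "smoothness": means,
                                    "n_strokes": n_strokes}
    return out


def load_calibration() -> dict:
    global _cache
    if _cache is None:
        path = resources.files("moveson.data").joinpath(CALIBRATION_RESOURCE)
        _cache = json.loads(path.read_text())
    return _cache


def corruption_to_smoothness(c, dialect: str = "inertial") -> np.ndarray:
    cal = load_calibration()["dialects"][dialect]
    return np.interp(np.asarray(c, float), cal["corruption"], cal["smoothness"])


def smoothness_to_corruption(s, dialect: str = "inertial") -> np.ndarray:
    """Inverse map: latent smoothness -> corruption (clipped to the
    calibrated range; smoothness decreases with corruption)."""
    cal = load_calibration()["dialects"][dialect]
    smooth = np.asarray(cal["smoothness"])[::-1]
    corr = np.asarray(cal["corruption"])[::-1]
    return np.interp(np.asarray(s, float), smooth, corr)


def write_calibration(path: str | Path, calibration: dict) -> None:
    Path(path).write_text(json.dumps(calibration, indent=1))
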