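"""Synthetic 3D hand trajectories for the sonification training tasks.

Movements are built from minimum-jerk point-to-point vertical strokes
between the target heights of a task's note sequence.  A ``corruption``
knob superimposes sub-movement perturbations (the kinematic signature of
impaired, non-smooth movement) without changing stroke endpoints:

* gross sub-movements: a Poisson(``corruption``) number of Gaussian-bell
  position bumps per stroke, amplitude proportional to ``corruption``;
* a low-amplitude ~4 Hz tremor in the horizontal plane, amplitude
  proportional to ``corruption``, so roughness grows smoothly with the
  knob rather than only in discrete jumps.

Two motion-capture "dialects" emulate the two kinds of sensor system
used in sonification training:

* ``inertial`` — uniform 60 Hz sampling with a very low positional noise
  floor (smooth, model-integrated positions);
* ``optical``  — jittered sample times, higher positional noise and
  occasional 1-3-sample dropouts (marked invalid, never silently
  deleted).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from ..sonification import FrameGeometry, TaskSpec, field_center, note_height

__all__ = ["Trajectory", "gen_trajectory", "min_jerk_profile"]

Dialect = Literal["inertial", "optical"]

#: Corruption model constants (design choices, documented in the methods
#: note): bump amplitude per unit corruption (cm), bump width (s), tremor
#: amplitude per unit corruption (cm) and tremor frequency (Hz).
BUMP_AMP_CM = 0.6
BUMP_WIDTH_S = 0.12
TREMOR_AMP_CM = 0.06
TREMOR_FREQ_HZ = 4.0

_DIALECTS = {
    # (noise_sd_cm, time_jitter_fraction, dropout_rate_per_s)
    "inertial": (0.002, 0.0, 0.0),
    "optical": (0.012, 0.25, 0.08),
}

#: Recommended resampling smooth window per dialect: optical marker noise
#: is white in position and must be smoothed before double differentiation;
#: inertial positions are already model-integrated and smooth.
DIALECT_SMOOTH_WINDOW = {"inertial": None, "optical": 9}


@dataclass
class Trajectory:
    """Timestamped 3D hand positions (cm) with sampling metadata."""

    t: np.ndarray  # seconds
    x: np.ndarray  # cm, left-right
    y: np.ndarray  # cm, vertical
    z: np.ndarray  # cm, proximal-distal
    valid: np.ndarray  # bool, False for sensor dropouts
    rate_hz: float  # nominal sampling rate
    source_id: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.t)
        for name in ("x", "y", "z", "valid"):
            if len(getattr(self, name)) != n:
                raise ValueError("trajectory arrays must have equal length")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def xyz(self) -> np.ndarray:
        return np.column_stack([self.x, self.y, self.z])

    def copy(self) -> "Trajectory":
        return replace(self, t=self.t.copy(), x=self.x.copy(), y=self.y.copy(),
                       z=self.z.copy(), valid=self.valid.copy(),
                       meta=dict(self.meta))


def min_jerk_profile(tau: np.ndarray) -> np.ndarray:
    """Normalised minimum-jerk position profile on tau in [0, 1].

    The quintic 10 tau^3 - 15 tau^4 + 6 tau^5 that minimises integrated
    squared jerk for a rest-to-rest point-to-point movement.
    """
    tau = np.asarray(tau, dtype=float)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def _monotone_runs(seq: tuple[int, ...]) -> list[list[int]]:
    """Split a note sequence into maximal monotone runs (the strokes)."""
    runs: list[list[int]] = []
    cur = [seq[0]]
    direction = 0
    for n in seq[1:]:
        d = int(np.sign(n - cur[-1]))
        if d == 0:
            continue
        if direction == 0 or d == direction:
            cur.append(n)
            direction = d
        else:
            runs.append(cur)
            cur = [cur[-1], n]
            direction = d
    runs.append(cur)
    return runs


def gen_trajectory(task: TaskSpec,
                   corruption: float = 0.0,
                   dialect: Dialect = "inertial",
                   seed: int = 0,
                   geometry: FrameGeometry = FrameGeometry(),
                   stroke_duration_s: float = 2.0,
                   rate_hz: float = 60.0) -> Trajectory:
    """Generate a synthetic hand trajectory for a training task.

    Parameters
    ----------
    task
        Note sequence and board field.
    corruption
        Non-negative roughness knob; 0 gives pure minimum-jerk strokes.
    dialect
        ``"inertial"`` or ``"optical"`` sensor noise model.
    seed
        Generator seed; the function is a pure function of its arguments.
    stroke_duration_s
        Duration of one full monotone run (a complete up- or down-stroke),
        shared equally by its note-to-note segments.
    """
    if corruption < 0:
        raise ValueError("corruption must be non-negative")
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    rng = np.random.default_rng(seed)
    noise_sd, jitter_frac, dropout_rate = _DIALECTS[dialect]

    # --- ideal continuous path: concatenated minimum-jerk strokes -------
    seq = tuple(task.note_sequence) * task.repetitions
    runs = _monotone_runs(seq)
    # breakpoints: (time, height) knots of the piecewise-quintic path
    seg_t: list[float] = [0.0]
    seg_y: list[float] = [note_height(runs[0][0], geometry)]
    run_spans: list[tuple[float, float]] = []
    t0 = 0.0
    for run in runs:
        nseg = len(run) - 1
        if nseg <= 0:
            continue
        seg_dur = stroke_duration_s / nseg
        for a, b in zip(run, run[1:]):
            seg_t.append(seg_t[-1] + seg_dur)
            seg_y.append(note_height(b, geometry))
        run_spans.append((t0, t0 + stroke_duration_s))
        t0 += stroke_duration_s

    total_dur = seg_t[-1]
    dt = 1.0 / rate_hz
    n = int(round(total_dur / dt)) + 1
    t = np.arange(n) * dt
    if jitter_frac > 0:
        jit = rng.uniform(-jitter_frac, jitter_frac, size=n) * dt
        jit[0] = jit[-1] = 0.0
        t = np.sort(t + jit)

    y = np.empty(n)
    idx = np.searchsorted(seg_t, t, side="right") - 1
    idx = np.clip(idx, 0, len(seg_t) - 2)
    for k in range(len(seg_t) - 1):
        m = idx == k
        if not np.any(m):
            continue
        dur = seg_t[k + 1] - seg_t[k]
        tau = (t[m] - seg_t[k]) / dur
        y[m] = seg_y[k] + (seg_y[k + 1] - seg_y[k]) * min_jerk_profile(np.clip(tau, 0, 1))

    cx, cz = field_center(task.position_field, geometry)
    x = np.full(n, cx)
    z = np.full(n, cz)

    # --- corruption: sub-movement bumps + proportional tremor -----------
    if corruption > 0:
        for (a, b) in run_spans:
            n_bumps = rng.poisson(corruption)
            for _ in range(n_bumps):
                center = rng.uniform(a + 0.1 * (b - a), b - 0.1 * (b - a))
                amp = BUMP_AMP_CM * corruption * rng.uniform(0.5, 1.0)
                width = BUMP_WIDTH_S * rng.uniform(0.7, 1.3)
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                bump = amp * np.exp(-0.5 * ((t - center) / width) ** 2)
                x += direction[0] * bump
                y += direction[1] * bump
                z += direction[2] * bump
        phase_x, phase_z = rng.uniform(0, 2 * np.pi, size=2)
        tre = TREMOR_AMP_CM * corruption
        x += tre * np.sin(2 * np.pi * TREMOR_FREQ_HZ * t + phase_x)
        z += tre * np.sin(2 * np.pi * TREMOR_FREQ_HZ * t + phase_z)

    # --- sensor noise and dropouts --------------------------------------
    if noise_sd > 0:
        x = x + rng.normal(0, noise_sd, n)
        y = y + rng.normal(0, noise_sd, n)
        z = z + rng.normal(0, noise_sd, n)
    valid = np.ones(n, dtype=bool)
    if dropout_rate > 0:
        n_drop = rng.poisson(dropout_rate * total_dur)
        for _ in range(n_drop):
            start = rng.integers(0, n)
            valid[start:start + rng.integers(1, 4)] = False

    return Trajectory(
        t=t, x=x, y=y, z=z, valid=valid, rate_hz=rate_hz,
        source_id=f"task-f{task.position_field}-c{corruption}-{dialect}-s{seed}",
        meta={"corruption": corruption, "dialect": dialect, "seed": seed,
              "stroke_duration_s": stroke_duration_s,
              "n_strokes": len(run_spans)},
    )
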