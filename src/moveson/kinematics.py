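"""Stroke segmentation and the curvature-based movement-smoothness metric.

Movement smoothness of a single up- or down-stroke is quantified from the
squared three-dimensional curvature of the hand path.  With velocity
v = (xdot, ydot, zdot) and acceleration a = (xddot, yddot, zddot), the
squared curvature at each sample is

    kappa^2 = (|v|^2 |a|^2 - (v . a)^2) / |v|^(2p)

With the default exponent p = 3 this is the standard geometric squared
curvature of a space curve, kappa^2 = |v x a|^2 / |v|^6 (units cm^-2;
a circle of radius r gives kappa^2 = 1/r^2, independent of traversal
speed).  The exponent is configurable: p = 1 reproduces a variant in
circulation whose denominator is |v|^2 — that form is dimensionally
inconsistent with curvature and is presumed a typesetting loss of the
cube, but it is kept available rather than silently corrected.

The per-stroke smoothness statistic (``MedianLC``) is the median of
-ln kappa^2 over the stroke: straighter, smoother paths have smaller
curvature and hence larger MedianLC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .simulate.trajectory import Trajectory

__all__ = [
    "Stroke",
    "CurvatureSeries",
    "resample",
    "segment_strokes",
    "curvature_sq",
    "stroke_smoothness",
    "build_records",
    "RECORD_COLUMNS",
]

#: Fixed column order of the smoothness-record table.
RECORD_COLUMNS = ["IDanon", "Group.c", "Session.c", "pre.z", "MoCap.c", "MedianLC"]

SPEED_FLOOR_CM_S = 0.5
KAPPA_SQ_FLOOR = 1e-12
MAX_GAP_S = 0.25  # dropout gaps longer than this are excluded from strokes


@dataclass
class Stroke:
    """One uniformly sampled up- or down-stroke."""

    t: np.ndarray
    xyz: np.ndarray  # (n, 3) cm
    direction: str  # "up" | "down"
    rate_hz: float
    patient: str | None = None
    session: int | None = None

    def __post_init__(self) -> None:
        if len(self.t) < 5:
            raise ValueError("stroke needs at least 5 samples")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("stroke timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class CurvatureSeries:
    kappa_sq: np.ndarray  # cm^-2, floored at KAPPA_SQ_FLOOR
    clamped_fraction: float  # share of samples hit by speed/curvature floors


def resample(traj: Trajectory, rate_hz: float = 60.0,
             max_gap_s: float = MAX_GAP_S,
             smooth_window: int | None = None) -> Trajectory:
    """Linearly interpolate a trajectory onto a uniform grid.

    Grid samples falling inside a dropout gap longer than ``max_gap_s``
    are marked invalid so segmentation never bridges them.  An optional
    Savitzky-Golay smoother (odd ``smooth_window``, cubic) is applied to
    the interpolated positions — appropriate for optical tracking data,
    whose white positional noise otherwise dominates the second
    derivatives.
    """
    valid = np.asarray(traj.valid, bool)
    if valid.sum() < 2:
        raise ValueError("trajectory has fewer than 2 valid samples")
    tv = np.asarray(traj.t, float)[valid]
    dt = 1.0 / rate_hz
    t_new = np.arange(tv[0], tv[-1] + 0.5 * dt, dt)
    cols = []
    for arr in (traj.x, traj.y, traj.z):
        col = np.interp(t_new, tv, np.asarray(arr, float)[valid])
        if smooth_window is not None and len(col) >= smooth_window:
            from scipy.signal import savgol_filter
            col = savgol_filter(col, smooth_window, 3)
        cols.append(col)
    new_valid = np.ones(len(t_new), dtype=bool)
    gaps = np.diff(tv)
    for i in np.flatnonzero(gaps > max_gap_s):
        new_valid[(t_new > tv[i]) & (t_new < tv[i + 1])] = False
    return Trajectory(t=t_new, x=cols[0], y=cols[1], z=cols[2],
                      valid=new_valid, rate_hz=rate_hz,
                      source_id=traj.source_id, meta=dict(traj.meta))


def _moving_average(x: np.ndarray, w: int) -> np.ndarray:
    if w <= 1:
        return x
    kernel = np.ones(w) / w
    pad = w // 2
    xp = np.pad(x, pad, mode="edge")
    out = np.convolve(xp, kernel, mode="same")[pad:pad + len(x)]
    return out


def segment_strokes(traj: Trajectory,
                    min_amplitude_fraction: float = 0.3,
                    min_duration_s: float = 0.3,
                    bar_height_cm: float = 51.0,
                    smooth_window: int = 5,
                    patient: str | None = None,
                    session: int | None = None) -> list[Stroke]:
    """Split a uniformly sampled trajectory into up/down strokes.

    Strokes are delimited by sign changes of the (moving-average
    smoothed) vertical velocity and kept only if their vertical excursion
    is at least ``min_amplitude_fraction * bar_height_cm`` and their
    duration at least ``min_duration_s``.
    """
    t = np.asarray(traj.t, float)
    y = np.asarray(traj.y, float)
    valid = np.asarray(traj.valid, bool)
    strokes: list[Stroke] = []
    # process each contiguous valid run independently
    runs = _bool_runs(valid)
    for lo, hi in runs:
        if hi - lo < 5:
            continue
        ts, ys = t[lo:hi], y[lo:hi]
        vy = np.gradient(_moving_average(ys, smooth_window), ts)
        sign = np.sign(vy)
        sign[sign == 0] = 1.0
        # candidate breakpoints where smoothed vertical velocity flips
        flips = np.flatnonzero(np.diff(sign) != 0) + 1
        bounds = np.concatenate([[0], flips, [len(ts)]])
        for a, b in zip(bounds[:-1], bounds[1:]):
            if b - a < 5:
                continue
            dur = ts[b - 1] - ts[a]
            excursion = ys[a:b].max() - ys[a:b].min()
            if dur < min_duration_s:
                continue
            if excursion < min_amplitude_fraction * bar_height_cm:
                continue
            net = ys[b - 1] - ys[a]
            direction = "up" if net >= 0 else "down"
            xyz = np.column_stack([traj.x[lo + a:lo + b],
                                   traj.y[lo + a:lo + b],
                                   traj.z[lo + a:lo + b]])
            strokes.append(Stroke(t=ts[a:b].copy(), xyz=xyz,
                                  direction=direction, rate_hz=traj.rate_hz,
                                  patient=patient, session=session))
    return strokes


def _bool_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """[lo, hi) index ranges of True runs."""
    out = []
    idx = np.flatnonzero(np.diff(np.concatenate([[0], mask.view(np.int8), [0]])))
    for lo, hi in zip(idx[::2], idx[1::2]):
        out.append((int(lo), int(hi)))
    return out


def curvature_sq(stroke: Stroke, exponent: int = 3,
                 speed_floor: float = SPEED_FLOOR_CM_S,
                 floor: float = KAPPA_SQ_FLOOR) -> CurvatureSeries:
    """Per-sample squared curvature of a stroke.

    Derivatives are central finite differences (one-sided at the stroke
    edges, via ``numpy.gradient``).  Samples slower than ``speed_floor``
    are clamped to the floor (curvature is numerically meaningless at
    near-zero speed), and kappa^2 is floored at ``floor`` before any
    logarithm; the fraction of floored samples is reported.
    """
    if len(stroke) < 5:
        raise ValueError("stroke too short for second differences")
    t = stroke.t
    v = np.gradient(stroke.xyz, t, axis=0)
    a = np.gradient(v, t, axis=0)
    v2 = np.einsum("ij,ij->i", v, v)
    a2 = np.einsum("ij,ij->i", a, a)
    va = np.einsum("ij,ij->i", v, a)
    num = np.clip(v2 * a2 - va**2, 0.0, None)  # = |v x a|^2 >= 0
    speed = np.sqrt(v2)
    slow = speed < speed_floor
    denom = np.where(slow, 1.0, v2 ** exponent)
    kappa_sq = np.where(slow, floor, num / denom)
    clamped = slow | (kappa_sq <= floor)
    kappa_sq = np.maximum(kappa_sq, floor)
    return CurvatureSeries(kappa_sq=kappa_sq,
                           clamped_fraction=float(clamped.mean()))


def stroke_smoothness(stroke: Stroke, exponent: int = 3) -> float:
    """MedianLC of one stroke: median of -ln kappa^2 (higher = smoother)."""
    series = curvature_sq(stroke, exponent=exponent)
    return float(np.median(-np.log(series.kappa_sq)))


def build_records(stroke_sets: Iterable[tuple[dict, Sequence[Stroke]]],
                  standardize_outcome: bool = True,
                  exponent: int = 3) -> pd.DataFrame:
    """Build the smoothness-record table used by the group models.

    Parameters
    ----------
    stroke_sets
        Iterable of ``(metadata, strokes)`` where metadata carries
        ``patient`` (id), ``group`` (0 control / 1 treatment), ``session``
        (int, 0 = pre-intervention measurement) and ``mocap``
        (0 inertial / 1 optical).
    standardize_outcome
        If True the returned table carries the z-scored outcome in
        ``MedianLC`` (zero mean and unit SD across all training-session
        records) with the raw value in ``MedianLC.raw``; otherwise
        ``MedianLC`` is raw.

    Notes
    -----
    ``pre.z`` is each patient's mean smoothness over the
    pre-intervention (session 0) strokes, standardised across the cohort.
    ``Group.c`` and ``MoCap.c`` are centred two-level codes (-0.5 / +0.5)
    and ``Session.c`` is the session index centred at the per-patient
    median session.  Session-0 records feed only ``pre.z`` and are not
    rows of the returned modelling table.
    """
    rows = []
    missing = []
    for meta, strokes in stroke_sets:
        need = {"patient", "group", "session", "mocap"}
        if not need.issubset(meta):
            missing.append(meta)
            continue
        for s in strokes:
            rows.append({
                "IDanon": str(meta["patient"]),
                "group": int(meta["group"]),
                "session": int(meta["session"]),
                "mocap": int(meta["mocap"]),
                "MedianLC.raw": stroke_smoothness(s, exponent=exponent),
                "direction": s.direction,
            })
    if missing:
        import logging
        logging.getLogger(__name__).warning(
            "dropped %d stroke sets with incomplete metadata", len(missing))
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("no complete records")

    pre = (df[df["session"] == 0].groupby("IDanon")["MedianLC.raw"]
           .mean().rename("pre_mean"))
    out = df[df["session"] > 0].copy()
    if out.empty:
        raise ValueError("no training-session records (all session 0)")
    out = out.join(pre, on="IDanon")
    if out["pre_mean"].isna().any():
        # patients without a pre measurement get the cohort mean (neutral)
        out["pre_mean"] = out["pre_mean"].fillna(pre.mean())
    pre_sd = out["pre_mean"].std(ddof=1)
    if not np.isfinite(pre_sd) or pre_sd == 0:
        out["pre.z"] = 0.0
    else:
        out["pre.z"] = (out["pre_mean"] - out["pre_mean"].mean()) / pre_sd

    out["Group.c"] = out["group"].map({0: -0.5, 1: 0.5})
    out["MoCap.c"] = out["mocap"].map({0: -0.5, 1: 0.5})
    med = out.groupby("IDanon")["session"].transform("median")
    out["Session.c"] = out["session"] - med

    raw = out["MedianLC.raw"].to_numpy()
    if standardize_outcome:
        sd = raw.std(ddof=1)
        if sd == 0:
            raise ValueError("degenerate outcome: zero variance")
        out["MedianLC"] = (raw - raw.mean()) / sd
    else:
        out["MedianLC"] = raw
    cols = RECORD_COLUMNS + ["MedianLC.raw", "session", "direction"]
    return out[cols].reset_index(drop=True)
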