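"""Synthetic patient cohorts with known smoothness effect structure.

Each patient belongs to a treatment (sonification) or control group and
contributes one pre-intervention measurement session (session 0) plus
``n_sessions`` training sessions of the standard four-scales task.  The
latent smoothness of patient *i* in training session *s* is

    latent_is = baseline + b_i + group_effect * Group.c_i
                + session_slope * (s - (n_sessions+1)/2)
                + mocap_effect * MoCap.c_i

with b_i ~ N(0, patient_sd^2) a patient random intercept shared with the
pre measurement, Group.c and MoCap.c centred -0.5/+0.5 codes.  The
pre-session latent is baseline + b_i + e_i, e_i ~ N(0, pre_smoothness_sd^2)
(no group term: it precedes randomised treatment).  Latents are realised
through the corruption knob via the simulation-calibrated inverse map,
so the ground truth of every generated record is known exactly.

All effect parameters are expressed on the MedianLC scale, whose total
record spread under the defaults is close to 1, so they read as
approximate SD units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..sonification import TaskSpec
from .calibration import smoothness_to_corruption
from .trajectory import Trajectory, gen_trajectory

__all__ = ["CohortDesign", "gen_cohort"]


@dataclass(frozen=True)
class CohortDesign:
    """Design parameters of a simulated two-arm cohort."""

    n_treatment: int = 14
    n_control: int = 14
    n_sessions: int = 15
    group_effect: float = 0.5     # MedianLC units (treatment - control)
    session_slope: float = 0.01   # MedianLC units per session
    patient_sd: float = 0.25      # between-patient intercept SD
    pre_smoothness_sd: float = 0.1  # extra pre-measurement-day SD
    mocap_effect: float = -0.3    # optical relative to inertial
    baseline: float = 5.0         # cohort mean latent MedianLC
    seed: int = 0
    split_mocap: bool = True      # half the patients per device (two sites)

    def __post_init__(self) -> None:
        if min(self.n_treatment, self.n_control, self.n_sessions) < 1:
            raise ValueError("counts must be >= 1")
        for name in ("patient_sd", "pre_smoothness_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def gen_cohort(design: CohortDesign,
               return_trajectories: bool = False,
               stroke_duration_s: float = 2.0
               ) -> tuple[pd.DataFrame, list[tuple[dict, Trajectory]]]:
    """Generate a cohort of per-session trajectories with known truth.

    Returns
    -------
    truth : DataFrame
        One row per patient x session (session 0 = pre) with columns
        ``patient, group, mocap, session, latent, corruption``.
    sessions : list of (metadata dict, Trajectory)
        The generated trajectories (empty unless ``return_trajectories``;
        metadata rows always returned in ``truth`` order and regenerable
        from the recorded per-session seeds).
    """
    rng = np.random.default_rng(design.seed)
    n = design.n_treatment + design.n_control
    groups = np.array([1] * design.n_treatment + [0] * design.n_control)
    if design.split_mocap:
        # alternate devices within each arm (two balanced sites)
        mocap = np.array([i % 2 for i in range(n)])
    else:
        mocap = np.zeros(n, dtype=int)
    b = rng.normal(0.0, design.patient_sd, size=n)
    e_pre = rng.normal(0.0, design.pre_smoothness_sd, size=n)

    task = TaskSpec.scale()
    rows = []
    sessions: list[tuple[dict, Trajectory]] = []
    mid = (design.n_sessions + 1) / 2.0
    for i in range(n):
        dialect = "optical" if mocap[i] else "inertial"
        gc = 0.5 if groups[i] else -0.5
        mc = 0.5 if mocap[i] else -0.5
        for s in range(design.n_sessions + 1):
            if s == 0:
                latent = design.baseline + b[i] + e_pre[i]
            else:
                latent = (design.baseline + b[i]
                          + design.group_effect * gc
                          + design.session_slope * (s - mid)
                          + design.mocap_effect * mc)
            corruption = float(smoothness_to_corruption(latent, dialect))
            sess_seed = int(rng.integers(0, 2**31 - 1))
            meta = {"patient": f"P{i:03d}", "group": int(groups[i]),
                    "mocap": int(mocap[i]), "session": s,
                    "dialect": dialect, "seed": sess_seed}
            rows.append({**{k: meta[k] for k in
                            ("patient", "group", "mocap", "session", "seed")},
                         "latent": latent, "corruption": corruption})
            if return_trajectories:
                traj = gen_trajectory(task, corruption, dialect, seed=sess_seed,
                                      stroke_duration_s=stroke_duration_s)
                sessions.append((meta, traj))
    return pd.DataFrame(rows), sessions


def cohort_records(design: CohortDesign, standardize_outcome: bool = True,
                   exponent: int = 3) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full generator -> kinematics pipeline for a cohort.

    Returns ``(records, truth)`` where ``records`` is the modelling table
    from :func:`moveson.kinematics.build_records` and ``truth`` the
    latent-value table.
    """
    from ..kinematics import build_records, resample, segment_strokes
    from .trajectory import DIALECT_SMOOTH_WINDOW

    truth, sessions = gen_cohort(design, return_trajectories=True)
    stroke_sets = []
    for meta, traj in sessions:
        win = DIALECT_SMOOTH_WINDOW[meta["dialect"]]
        strokes = segment_strokes(resample(traj, smooth_window=win))
        stroke_sets.append((meta, strokes))
    records = build_records(stroke_sets, standardize_outcome=standardize_outcome,
                            exponent=exponent)
    return records, truth
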