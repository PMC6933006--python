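"""Synthetic pre-intervention clinical score tables.

One row per patient with numeric columns for each motor-test and
stroke-impact scale of subacute rehabilitation (treated throughout as opaque
numeric outcomes), a group label, and optional injected group offsets
expressed in within-scale SD units.  Used to exercise the
pre-intervention group-difference regressions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["CLINICAL_SCALES", "gen_clinical_table"]

#: (name, population mean, population SD) — plausible subacute-stroke
#: cohort values; scales are opaque numbers to every downstream consumer.
CLINICAL_SCALES: tuple[tuple[str, float, float], ...] = (
    ("FM.A-D", 30.0, 12.0),
    ("FM.H", 8.0, 3.0),
    ("FM.I", 20.0, 3.5),
    ("FM.J", 20.0, 4.0),
    ("SIS.1", 60.0, 15.0),
    ("SIS.2", 75.0, 15.0),
    ("SIS.3", 70.0, 15.0),
    ("SIS.4", 80.0, 15.0),
    ("SIS.5", 55.0, 18.0),
    ("SIS.6", 60.0, 18.0),
    ("SIS.7", 40.0, 20.0),
    ("SIS.8", 55.0, 20.0),
    ("SIS.9", 50.0, 20.0),
    ("SIS.total", 545.0, 90.0),
    ("ARAT", 25.0, 15.0),
    ("BBT", 20.0, 12.0),
    ("invNHPT", 0.02, 0.012),
    ("TLT", 2.0, 1.5),
    ("BI", 55.0, 20.0),
    ("DSS", 30.0, 15.0),
)


def gen_clinical_table(n_per_group: int = 14,
                       offsets: dict[str, float] | None = None,
                       seed: int = 0) -> pd.DataFrame:
    """Generate a clinical score table with injected group offsets.

    Parameters
    ----------
    n_per_group
        Patients per arm (>= 2).
    offsets
        Mapping scale name -> offset in SD units added to the treatment
        group; unlisted scales get offset 0.
    """
    if n_per_group < 2:
        raise ValueError("need at least 2 patients per group")
    offsets = dict(offsets or {})
    unknown = set(offsets) - {name for name, *_ in CLINICAL_SCALES}
    if unknown:
        raise ValueError(f"unknown scales in offsets: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    treatment = np.array([1] * n_per_group + [0] * n_per_group)
    data: dict[str, np.ndarray] = {
        "IDanon": np.array([f"P{i:03d}" for i in range(n)]),
        "Treatment": treatment,
    }
    for name, mu, sd in CLINICAL_SCALES:
        vals = rng.normal(mu, sd, size=n)
        vals = vals + offsets.get(name, 0.0) * sd * treatment
        data[name] = vals
    return pd.DataFrame(data)
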