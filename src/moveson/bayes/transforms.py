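"""Standardisation helpers used across the regression stack."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ZTransform", "ztransform"]


@dataclass(frozen=True)
class ZTransform:
    """A stored z-transform reference, supporting exact round trips."""

    mean: float
    sd: float

    def apply(self, values) -> np.ndarray:
        return (np.asarray(values, float) - self.mean) / self.sd

    def invert(self, values) -> np.ndarray:
        return np.asarray(values, float) * self.sd + self.mean


def ztransform(values, reference_mean: float | None = None,
               reference_sd: float | None = None
               ) -> tuple[np.ndarray, ZTransform]:
    """Standardise values to zero mean / unit SD.

    Uses the supplied reference moments when given (e.g. to place new
    data on a stored scale).  A zero or non-finite SD raises rather than
    silently producing NaNs.
    """
    x = np.asarray(values, dtype=float)
    mean = float(x.mean()) if reference_mean is None else float(reference_mean)
    sd = float(x.std(ddof=1)) if reference_sd is None else float(reference_sd)
    if not np.isfinite(sd) or sd <= 0:
        raise ValueError("z-transform reference SD must be positive "
                         "(constant input?)")
    ref = ZTransform(mean=mean, sd=sd)
    return ref.apply(x), ref
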