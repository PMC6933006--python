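"""Prior specifications for the Bayesian regression stack.

Defaults: Student-t(df=3, 0, scale) slope
priors (scale 1 for the pre-intervention clinical regressions, scale 3
for the smoothness multilevel models), half-Student-t left-bounded at
zero for standard-deviation parameters, and LKJ(eta=2) on correlation
matrices of varying coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["PriorSpec", "student_t_logpdf", "half_t_logpdf_from_log",
           "lkj_partial_logprior", "partials_to_corr", "corr_param_layers"]


@dataclass(frozen=True)
class PriorSpec:
    slope_df: float = 3.0
    slope_scale: float = 3.0
    intercept_df: float = 3.0
    intercept_scale: float = 3.0
    sd_df: float = 3.0
    sd_scale: float = 3.0
    lkj_eta: float = 2.0

    def __post_init__(self) -> None:
        for f in ("slope_df", "slope_scale", "intercept_df", "intercept_scale",
                  "sd_df", "sd_scale", "lkj_eta"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be > 0")

    @classmethod
    def clinical(cls) -> "PriorSpec":
        """Priors of the pre-intervention clinical regressions (scale 1)."""
        return cls(slope_scale=1.0, intercept_scale=1.0, sd_scale=1.0)


def student_t_logpdf(x: np.ndarray, df: float, scale: float) -> np.ndarray:
    return stats.t.logpdf(x, df=df, loc=0.0, scale=scale)


def half_t_logpdf_from_log(log_x: np.ndarray, df: float, scale: float) -> np.ndarray:
    """log density of a half-t variable evaluated through its log.

    Includes the Jacobian of the log transform, so this is the log prior
    contribution when sampling ``log_x`` unconstrained.
    """
    x = np.exp(log_x)
    return np.log(2.0) + stats.t.logpdf(x, df=df, scale=scale) + log_x


def corr_param_layers(q: int) -> list[tuple[int, int, int]]:
    """(i, j, layer) index triples of the canonical partial correlations."""
    return [(i, j, j - i) for l in range(1, q) for i in range(q - l)
            for j in [i + l] if j - i == l]


def lkj_partial_logprior(x: np.ndarray, q: int, eta: float) -> float:
    """Log prior of unconstrained partial-correlation parameters.

    The LKJ(eta) distribution on a q x q correlation matrix factorises
    over its canonical partial correlations p_l: (p_l + 1)/2 is
    Beta(a_l, a_l) with a_l = eta + (q - 1 - l)/2 for layer l = j - i.
    Parameters are unconstrained via p = tanh(x); with the Jacobian the
    contribution per parameter is a_l * log(1 - p^2) (up to constants).
    """
    layers = corr_param_layers(q)
    if len(x) != len(layers):
        raise ValueError("wrong number of correlation parameters")
    total = 0.0
    for xv, (_i, _j, l) in zip(x, layers):
        a = eta + (q - 1 - l) / 2.0
        p = np.tanh(xv)
        total += a * np.log1p(-p * p)
    return float(total)


def partials_to_corr(x: np.ndarray, q: int) -> np.ndarray:
    """Build a correlation matrix from unconstrained partial correlations.

    Supports q <= 3 (the model ladder's varying-coefficient blocks are
    at most intercept + two slopes).
    """
    p = np.tanh(np.asarray(x, float))
    R = np.eye(q)
    if q == 1:
        return R
    if q == 2:
        R[0, 1] = R[1, 0] = p[0]
        return R
    if q == 3:
        p12, p23, p13_2 = p  # layer-1 pair, layer-1 pair, layer-2 partial
        r13 = p13_2 * np.sqrt((1 - p12**2) * (1 - p23**2)) + p12 * p23
        R[0, 1] = R[1, 0] = p12
        R[1, 2] = R[2, 1] = p23
        R[0, 2] = R[2, 0] = r13
        return R
    raise NotImplementedError("correlated varying blocks limited to q <= 3")
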