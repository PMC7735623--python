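"""Outcome utility (value) functions applied branch-wise before the transform.

Two families are supported:

* ``linear`` — u(o) = o
* ``cara``   — u(o) = (1 - exp(-r o)) / r, constant absolute risk aversion
  -u''/u' = r (units of 1/currency).  The r -> 0 limit is the linear family,
  and the implementation is continuous through r = 0.

Outcomes are unitless reals; an optional global ``outcome_scale`` is applied
before u so that figure-regime parameterizations (e.g. 100-euro stakes with
r of order one) stay in the non-saturated region of the CARA exponential.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["UtilitySpec", "utility"]

#: below this, the CARA coefficient is treated as exactly zero (linear limit)
_R_TINY = 1e-12


@dataclass(frozen=True)
class UtilitySpec:
    """Parameterization of the branch-wise value function.

    Parameters
    ----------
    family:
        ``"linear"`` or ``"cara"``.
    r:
        Absolute risk-aversion coefficient, >= 0.  Ignored for ``linear``.
    outcome_scale:
        Positive factor multiplying outcomes before u is applied.
    custom:
        Optional callable replacing the built-in family.  Must satisfy
        u(0) = 0 and be non-decreasing; spot-checked at construction.
    """

    family: str = "linear"
    r: float = 0.0
    outcome_scale: float = 1.0
    custom: Callable[[np.ndarray], np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.family not in ("linear", "cara"):
            raise ValueError(f"unknown utility family {self.family!r}")
        if self.r < 0:
            raise ValueError("risk-aversion coefficient r must be >= 0")
        if not self.outcome_scale > 0:
            raise ValueError("outcome_scale must be positive")
        if self.custom is not None:
            z = float(np.asarray(self.custom(np.array(0.0))))
            if abs(z) > 1e-9:
                raise ValueError("custom utility must satisfy u(0) = 0")
            grid = np.linspace(-5.0, 5.0, 11)
            vals = np.asarray(self.custom(grid), dtype=float)
            if np.any(np.diff(vals) < -1e-12):
                raise ValueError("custom utility must be non-decreasing")


def utility(spec: UtilitySpec, o) -> np.ndarray | float:
    """Evaluate u(outcome_scale * o).  Vectorized; total on finite inputs.

    For the CARA family, ``-expm1(-r x) / r`` keeps the evaluation accurate
    down to r ~ 1e-300 and continuous with the linear family at r = 0.
    """
    x = np.asarray(o, dtype=float) * spec.outcome_scale
    if spec.custom is not None:
        out = np.asarray(spec.custom(x), dtype=float)
    elif spec.family == "linear" or spec.r < _R_TINY:
        out = x
    else:
        # cap the loss-side exponent so deeply saturated losses stay finite
        # (they are later exponentially suppressed in log space anyway)
        out = -np.expm1(np.minimum(-spec.r * x, 700.0)) / spec.r
    if out.ndim == 0:
        return float(out)
    return out
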