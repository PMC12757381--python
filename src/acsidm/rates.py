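"""Parametric transition hazards of the extended illness-death model.

The model uses three age-dependent hazards, parameterized by a
six-dimensional vector ``theta``:

* incidence of the chronic disease, hinge-linear in age:
  ``i(t) = theta2 * max(0, t - theta1)``;
* mortality of the non-diseased, Gompertz:
  ``m0(t) = exp(theta3 + theta4 * t)``;
* mortality of the diseased, Gompertz:
  ``m1(t) = exp(theta5 + theta6 * t)``.

Both families admit closed-form cumulative hazards and closed-form
inverses, which makes exact inverse-transform sampling of event times
possible (see :mod:`acsidm.microsim`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ParameterVector",
    "THETA_TRUE",
    "LOG_HAZARD_CAP",
    "incidence_rate",
    "gompertz_rate",
    "cumulative_hazard",
    "invert_cumulative_hazard",
]

#: Cap on the log-hazard argument before a range error is raised.
#: exp(50) ~ 5e21 / year is far beyond any meaningful mortality; values
#: above this indicate a runaway parameter, not a model evaluation.
LOG_HAZARD_CAP = 50.0


@dataclass(frozen=True)
class ParameterVector:
    """The six rate parameters of the extended illness-death model.

    Attributes
    ----------
    theta1 : onset age of the disease in years (incidence is 0 before it).
    theta2 : slope of the incidence rate, per year per year of age.
    theta3, theta4 : log-intercept and age slope (1/year) of the Gompertz
        mortality of the non-diseased, ``m0(t) = exp(theta3 + theta4 t)``.
    theta5, theta6 : same for the mortality of the diseased, ``m1``.
    """

    theta1: float
    theta2: float
    theta3: float
    theta4: float
    theta5: float
    theta6: float

    def __post_init__(self) -> None:
        values = self.as_array()
        if not np.all(np.isfinite(values)):
            raise ValueError("all six parameter components must be finite")
        if self.theta1 < 0:
            raise ValueError("theta1 (onset age) must be non-negative")
        if self.theta2 < 0:
            raise ValueError("theta2 (incidence slope) must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.theta1, self.theta2, self.theta3,
             self.theta4, self.theta5, self.theta6],
            dtype=float,
        )

    @classmethod
    def from_array(cls, values: Sequence[float]) -> "ParameterVector":
        values = np.asarray(values, dtype=float)
        if values.shape != (6,):
            raise ValueError("parameter vector must have exactly 6 components")
        return cls(*values.tolist())


#: Reference parameter vector of the diabetes-motivated feasibility
#: experiment: onset at age 30, incidence slope 1/2000, and Gompertz
#: mortalities exp(-10.7 + t/10) (non-diseased) and exp(-10 + t/10)
#: (diseased).
THETA_TRUE = ParameterVector(30.0, 1.0 / 2000.0, -10.7, 0.1, -10.0, 0.1)


def incidence_rate(theta: ParameterVector, t: float) -> float:
    """Hinge-linear incidence hazard ``theta2 * max(0, t - theta1)``."""
    return theta.theta2 * max(0.0, t - theta.theta1)


def gompertz_rate(log_intercept: float, slope: float, t: float) -> float:
    """Gompertz hazard ``exp(log_intercept + slope * t)``.

    Raises
    ------
    OverflowError
        If the log-hazard exceeds :data:`LOG_HAZARD_CAP`.
    """
    x = log_intercept + slope * t
    if x > LOG_HAZARD_CAP:
        raise OverflowError(
            f"log-hazard {x:.3g} exceeds the cap {LOG_HAZARD_CAP}; "
            "the hazard would overflow"
        )
    return math.exp(x)


def _incidence_params(params) -> tuple[float, float]:
    if isinstance(params, ParameterVector):
        return params.theta1, params.theta2
    theta1, theta2 = params
    return float(theta1), float(theta2)


def cumulative_hazard(kind: str, params, t0: float, t1: float) -> float:
    """Integrated hazard mass over the age interval ``[t0, t1]``.

    Parameters
    ----------
    kind : ``"incidence"`` or ``"gompertz"``.
    params : for ``"incidence"`` a :class:`ParameterVector` or pair
        ``(theta1, theta2)``; for ``"gompertz"`` a pair
        ``(log_intercept, slope)``.
    """
    if t0 > t1:
        raise ValueError(f"t0={t0} must not exceed t1={t1}")
    if kind == "gompertz":
        a, b = params
        if b == 0.0:
            return math.exp(a) * (t1 - t0)
        # expm1 form stays accurate (and finite) as b -> 0
        return math.exp(a + b * t0) * math.expm1(b * (t1 - t0)) / b
    if kind == "incidence":
        theta1, theta2 = _incidence_params(params)
        s1 = max(0.0, t1 - theta1)
        s0 = max(0.0, t0 - theta1)
        return 0.5 * theta2 * (s1 * s1 - s0 * s0)
    raise ValueError(f"unknown hazard kind {kind!r}")


def invert_cumulative_hazard(kind: str, params, t0: float, target: float) -> float:
    """Smallest ``t >= t0`` accruing hazard mass ``target`` from ``t0``.

    Returns ``math.inf`` when the total hazard mass remaining after ``t0``
    is smaller than ``target`` (a hazard that never accrues enough mass,
    e.g. a zero incidence slope or a negative Gompertz slope).
    """
    if target < 0:
        raise ValueError("target hazard mass must be non-negative")
    if target == 0.0:
        return float(t0)
    if kind == "gompertz":
        a, b = params
        if b == 0.0:
            return t0 + target * math.exp(-a)
        arg = b * target * math.exp(-a - b * t0)
        if arg <= -1.0:  # only possible for b < 0: finite total mass exhausted
            return math.inf
        return t0 + math.log1p(arg) / b
    if kind == "incidence":
        theta1, theta2 = _incidence_params(params)
        if theta2 == 0.0:
            return math.inf
        s0 = max(0.0, t0 - theta1)
        return theta1 + math.sqrt(s0 * s0 + 2.0 * target / theta2)
    raise ValueError(f"unknown hazard kind {kind!r}")
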