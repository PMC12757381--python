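"""Individual-level micro-simulation of life courses through the model.

Each subject starts non-diseased at age 0.  Competing risks of disease
onset (hazard ``i``) and death without disease (hazard ``m0``) are
realized through independent latent event times drawn by exact
inverse-transform sampling of the closed-form cumulative hazards; the
earlier latent time wins, which reproduces the cause-specific hazards.
After onset, the death time is drawn from the diseased mortality ``m1``
with hazard accruing from the onset age (left-truncated inversion).

Draw order per subject is fixed (U1 for onset, U2 for death without
disease, U3 for death after onset, drawn only when needed), so a seeded
generator reproduces populations bit-identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .rates import ParameterVector, invert_cumulative_hazard

__all__ = ["LifeCourse", "sample_life_course", "simulate_population", "state_at"]


@dataclass(frozen=True)
class LifeCourse:
    """One simulated subject: onset and death ages within the horizon.

    ``None`` means the event did not occur before the horizon.
    """

    subject_id: int
    illness_age: Optional[float]
    death_age: Optional[float]
    horizon: float

    def __post_init__(self) -> None:
        for name in ("illness_age", "death_age"):
            age = getattr(self, name)
            if age is not None and not 0.0 <= age <= self.horizon:
                raise ValueError(f"{name}={age} outside [0, {self.horizon}]")
        if (
            self.illness_age is not None
            and self.death_age is not None
            and self.illness_age > self.death_age
        ):
            raise ValueError("illness_age must not exceed death_age")

    @property
    def died_with_disease(self) -> bool:
        return self.death_age is not None and self.illness_age is not None


def _exp_draw(rng) -> float:
    # -log(1 - U) with U in [0, 1): finite, non-negative hazard target.
    return -math.log1p(-rng.random())


def sample_life_course(
    theta: ParameterVector,
    rng: np.random.Generator,
    horizon: float,
    subject_id: int = 1,
) -> LifeCourse:
    """Draw one life course by inverse-transform sampling.

    Ties between the latent onset and death times (a probability-zero
    event) are broken in favor of death.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    t_ill = invert_cumulative_hazard(
        "incidence", (theta.theta1, theta.theta2), 0.0, _exp_draw(rng)
    )
    t_d0 = invert_cumulative_hazard(
        "gompertz", (theta.theta3, theta.theta4), 0.0, _exp_draw(rng)
    )
    if t_d0 <= t_ill:
        death = t_d0 if t_d0 <= horizon else None
        return LifeCourse(subject_id, None, death, horizon)
    if t_ill > horizon:
        return LifeCourse(subject_id, None, None, horizon)
    t_d1 = invert_cumulative_hazard(
        "gompertz", (theta.theta5, theta.theta6), t_ill, _exp_draw(rng)
    )
    death = t_d1 if t_d1 <= horizon else None
    return LifeCourse(subject_id, t_ill, death, horizon)


def simulate_population(
    theta: ParameterVector,
    n: int,
    rng: Union[int, np.random.Generator],
    horizon: float = 100.0,
) -> list[LifeCourse]:
    """Simulate ``n`` independent life courses with ids ``1..n``."""
    if n < 1:
        raise ValueError("population size n must be at least 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return [
        sample_life_course(theta, rng, horizon, subject_id=i + 1)
        for i in range(n)
    ]


def state_at(course: LifeCourse, t: float) -> int:
    """Model state (1-4) occupied at age ``t``.

    State changes take effect at the event age itself (closed on the
    left): at ``t == illness_age`` the subject is already diseased.
    """
    if not 0.0 <= t <= course.horizon:
        raise ValueError(f"t={t} outside [0, {course.horizon}]")
    ill = course.illness_age is not None and course.illness_age <= t
    dead = course.death_age is not None and course.death_age <= t
    if dead:
        return 4 if course.illness_age is not None else 3
    return 2 if ill else 1
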