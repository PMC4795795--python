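"""Temporal interpolation and the two-stage desired-trajectory computation.

The internal kinematic model generates a desired hand trajectory in visual
(eye-centered) coordinates by interpolating between the initial hand position
and the reach target.  All positions are 1D eccentricities in degrees.  Task
time is dimensionless, with three unit-length epochs:

* pre-target:  -2 <= t < -1
* delay:       -1 <= t <= 0   (target visible, movement withheld)
* movement:     0 <  t <= 1

The interpolation function ``psi(t)`` equals 1 throughout the delay period
(back-extrapolated into the pre-target epoch) and falls linearly to 0 during
movement.  The model computes, in two stages,

    TH    = TE - HE             (displacement vector, eye coordinates)
    he(t) = TE - psi(t) * TH    (desired trajectory, eye coordinates)

so that ``he`` equals the initial hand position ``HE`` during the delay and
the target ``TE`` at movement offset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "TaskCondition",
    "psi",
    "phi",
    "displacement_vector",
    "desired_trajectory",
    "phenomenological_hand_position",
    "T_MIN",
    "T_MAX",
]

T_MIN = -2.0
T_MAX = 1.0
_EPS = 1e-9


@dataclass(frozen=True)
class TaskCondition:
    """One (eye, hand, target) position triple, in degrees.

    Derived quantities are the eye-centered target ``TE = T - E``, the
    eye-centered initial hand position ``HE = H - E`` and the displacement
    vector ``TH = TE - HE = T - H``.
    """

    E: float
    H: float
    T: float

    def __post_init__(self) -> None:
        for name in ("E", "H", "T"):
            value = getattr(self, name)
            if not math.isfinite(value):
                raise ValueError(f"{name} must be finite, got {value!r}")

    @property
    def TE(self) -> float:
        return self.T - self.E

    @property
    def HE(self) -> float:
        return self.H - self.E

    @property
    def TH(self) -> float:
        return self.T - self.H


def _check_domain(t, lo: float, hi: float):
    t = np.asarray(t, dtype=float)
    if np.any(t < lo - _EPS) or np.any(t > hi + _EPS):
        raise ValueError(f"time {t} outside the task domain [{lo}, {hi}]")
    return t


def psi(t, form: str = "piecewise"):
    """Interpolation rate between movement endpoints, in [0, 1].

    ``psi`` is 1 for every delay-period (and back-extrapolated pre-target)
    time and decreases to 0 across the movement epoch.  The default is the
    piecewise-linear form ``1 - t`` on (0, 1]; ``form="smooth"`` substitutes
    a falling smoothstep sigmoid with the same endpoints (the qualitative
    results do not depend on this choice).

    Accepts scalars or arrays; raises for times outside [-2, 1].
    """
    t = _check_domain(t, T_MIN, T_MAX)
    tm = np.clip(t, 0.0, 1.0)
    if form == "piecewise":
        out = np.where(t <= 0.0, 1.0, 1.0 - tm)
    elif form == "smooth":
        out = np.where(t <= 0.0, 1.0, 1.0 - tm * tm * (3.0 - 2.0 * tm))
    else:
        raise ValueError(f"unknown psi form {form!r}")
    if np.ndim(t) == 0:
        return float(out)
    return out


def phi(t, form: str = "piecewise"):
    """Rising counterpart ``phi(t) = 1 - psi(t)``."""
    p = psi(t, form=form)
    return 1.0 - p


def displacement_vector(cond: TaskCondition) -> float:
    """Displacement vector ``TH = TE - HE = T - H`` (degrees); eye-invariant."""
    return cond.TE - cond.HE


def desired_trajectory(cond: TaskCondition, t, form: str = "piecewise"):
    """Desired hand trajectory in eye coordinates, ``he(t) = TE - psi(t) TH``.

    During the delay this reduces to ``HE`` (the hand where it currently is);
    at movement offset it equals ``TE`` (the target).
    """
    return cond.TE - psi(t, form=form) * displacement_vector(cond)


def phenomenological_hand_position(cond: TaskCondition, t, form: str = "piecewise"):
    """Descriptive extrinsic hand position ``h(t) = T - psi(t) (T - H)``.

    Defined on the movement epoch [0, 1] only; satisfies ``h(0) = H``,
    ``h(1) = T`` and the identity ``h(t) - E = he(t)``.
    """
    t = _check_domain(t, 0.0, T_MAX)
    return cond.T - psi(t, form=form) * (cond.T - cond.H)
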