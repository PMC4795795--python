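"""Condition sets for the simulated behavioral tasks.

Three tasks drive the simulations:

* the delay-period reference-frame task: 9 targets spanning ``-2 sigma`` to
  ``+2 sigma`` in steps of ``sigma / 2``, crossed with 5 eye/hand position
  pairs, probed at the end of the delay (t = 0);
* the screening task: eye and hand together at the center, targets at the
  same 9 locations (a center-out tuning probe);
* the gradient task: all 125 independent (E, H, T) combinations from
  ``{-20, -10, 0, 10, 20}`` degrees, followed across the whole trial in
  normalized-time steps of 0.1 (31 samples spanning pre-target, delay and
  movement epochs).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "ConditionSet",
    "DEFAULT_EH_PAIRS",
    "delay_task_conditions",
    "screening_task_conditions",
    "gradient_task_conditions",
    "gradient_time_grid",
]


@dataclass(frozen=True)
class ConditionSet:
    """An ordered set of (E, H, T) conditions plus probe times."""

    E: np.ndarray
    H: np.ndarray
    T: np.ndarray
    time_points: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        for name in ("E", "H", "T", "time_points"):
            object.__setattr__(self, name,
                               np.asarray(getattr(self, name), dtype=float))
        if not (self.E.shape == self.H.shape == self.T.shape):
            raise ValueError("E, H, T must have equal lengths")

    def __len__(self) -> int:
        return self.E.size

    @property
    def TE(self) -> np.ndarray:
        return self.T - self.E

    @property
    def HE(self) -> np.ndarray:
        return self.H - self.E

    @property
    def TH(self) -> np.ndarray:
        return self.T - self.H

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "condition_id": np.arange(len(self)),
            "E": self.E, "H": self.H, "T": self.T,
        })


def _targets(sigma: float) -> np.ndarray:
    # 9 targets, -2 sigma .. +2 sigma in steps of sigma / 2
    return np.linspace(-2.0 * sigma, 2.0 * sigma, 9)


def default_eh_pairs(sigma: float) -> Tuple[Tuple[float, float], ...]:
    """Five (E, H) configurations: symmetric eye-hand offsets about the origin.

    Eye and hand are displaced by equal and opposite amounts so the gaze-hand
    offset HE takes the five values {0, +-2 sigma, +-3 sigma} while every
    position stays on the sigma/2-spaced grid.  This dissociates TE, TH and
    HE in the reference-frame regression and drives the gain modulation
    across its full working range, including its lower saturation limit.
    """
    return ((0.0, 0.0), (1.5 * sigma, -1.5 * sigma), (-1.5 * sigma, 1.5 * sigma),
            (sigma, -sigma), (-sigma, sigma))


DEFAULT_EH_PAIRS = default_eh_pairs(15.0)


def delay_task_conditions(sigma: float = 15.0,
                          eh_pairs: Sequence[Tuple[float, float]] = None
                          ) -> ConditionSet:
    """45 delay-period conditions: 9 targets x 5 (eye, hand) pairs, t = 0.

    Targets vary fastest within each pair; all positions must lie within
    ``+-3 sigma``.
    """
    if eh_pairs is None:
        eh_pairs = default_eh_pairs(sigma)
    targets = _targets(sigma)
    E, H, T = [], [], []
    for e, h in eh_pairs:
        for t in targets:
            E.append(e)
            H.append(h)
            T.append(t)
    E, H, T = np.array(E), np.array(H), np.array(T)
    lim = 3.0 * sigma + 1e-9
    if np.any(np.abs(np.concatenate([E, H, T])) > lim):
        raise ValueError("positions outside +-3 sigma")
    return ConditionSet(E, H, T, np.array([0.0]), label="delay_task")


def screening_task_conditions(sigma: float = 15.0) -> ConditionSet:
    """Center-out screen: E = H = 0, targets at the 9 delay-task locations."""
    targets = _targets(sigma)
    zeros = np.zeros_like(targets)
    return ConditionSet(zeros, zeros, targets, np.array([0.0]),
                        label="screening_task")


def gradient_time_grid() -> np.ndarray:
    """31 normalized times, -2.0 .. 1.0 in steps of 0.1."""
    return np.round(np.linspace(-2.0, 1.0, 31), 10)


def gradient_task_conditions() -> ConditionSet:
    """All 125 (E, H, T) combinations from {-20..20} step 10, full time grid."""
    grid = np.array([-20.0, -10.0, 0.0, 10.0, 20.0])
    E, H, T = np.meshgrid(grid, grid, grid, indexing="ij")
    return ConditionSet(E.ravel(), H.ravel(), T.ravel(),
                        gradient_time_grid(), label="gradient_task")
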