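"""Tuning screen: restrict populations to units with a discernible peak.

Center-out responses (eye and hand at the center, 9 targets spanning the
working range) are fit to a four-parameter Gaussian
``r = a exp[-(T - mu)^2 / 2 s^2] + c`` under box constraints
(a in [0, 100], mu in [-45, 45] deg, s in [10, 30] deg, c in [0, 10]).
Fit quality is summarized by the spike-variance-explained statistic
``SVE = r^2 * a``.  A unit is accepted when its fitted peak lies at least
``s / 2`` inside the task range and ``SVE >= 10``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
import pandas as pd

from ._fitting import fit_gaussian_screen

__all__ = [
    "GaussianTuningFit",
    "fit_center_out_gaussian",
    "screen_unit",
    "screen_population",
]

SVE_THRESHOLD = 10.0


@dataclass(frozen=True)
class GaussianTuningFit:
    """Bounded center-out Gaussian fit and its quality statistics."""

    a: float
    mu: float
    s: float
    c: float
    r2: float
    degenerate: bool = False

    @property
    def sve(self) -> float:
        """Spike variance explained: the product ``r2 * a``."""
        return self.r2 * self.a


def fit_center_out_gaussian(responses: Sequence[float],
                            targets: Sequence[float]) -> GaussianTuningFit:
    """Fit the screening Gaussian to the 9 center-out responses.

    Variance-free (all-equal) responses return a degenerate fit with the
    amplitude at its lower bound and ``r2 = 0`` rather than raising.
    """
    res = fit_gaussian_screen(np.asarray(responses, float),
                              np.asarray(targets, float))
    return GaussianTuningFit(a=res["a"], mu=res["mu"], s=res["s"], c=res["c"],
                             r2=res["r2"], degenerate=res["degenerate"])


def screen_unit(fit: GaussianTuningFit,
                task_range: Tuple[float, float] = (-30.0, 30.0),
                sve_threshold: float = SVE_THRESHOLD) -> bool:
    """Accept a unit whose peak is in-range and whose SVE clears threshold.

    The peak criterion requires ``lo + s/2 <= mu <= hi - s/2``.
    """
    lo, hi = task_range
    if lo >= hi:
        raise ValueError("task range must satisfy lo < hi")
    in_range = (lo + fit.s / 2.0 <= fit.mu <= hi - fit.s / 2.0)
    return bool(in_range and fit.sve >= sve_threshold)


def screen_population(rates: np.ndarray, targets: Sequence[float], units,
                      task_range: Tuple[float, float] = (-30.0, 30.0),
                      sve_threshold: float = SVE_THRESHOLD) -> pd.DataFrame:
    """Screen many units at once.

    ``rates`` is (n_units, n_targets).  Returns the screening report with
    one row per unit: unit_id, node, a, mu, s, c, r2, sve, accepted.
    """
    rates = np.asarray(rates, dtype=float)
    rows = []
    for i, unit in enumerate(units):
        fit = fit_center_out_gaussian(rates[i], targets)
        rows.append({
            "unit_id": unit.unit_id, "node": unit.node,
            "a": fit.a, "mu": fit.mu, "s": fit.s, "c": fit.c,
            "r2": fit.r2, "sve": fit.sve,
            "accepted": screen_unit(fit, task_range, sve_threshold),
        })
    return pd.DataFrame(rows)
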