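"""Gradient (resultant-vector) analysis of condition-response matrices.

For a pair of analysis parameters (T and H, T and E, or H and E; the third
held at 0 deg) each unit's responses on the 5 x 5 position grid
{-20, -10, 0, 10, 20} deg form an activity matrix.  Finite-difference
gradients (central differences at interior points, one-sided at the edges;
grid step 10 deg in the denominators) are estimated per matrix element.
Because a relative variable is indistinguishable from its inverse
(T - H vs. H - T), each gradient's angle is doubled before vector summation,
so gradients along the two anti-diagonal directions reinforce instead of
cancel.  The per-element doubled vectors sum to a unit resultant; unit
resultants sum to node and population resultants.

Resultant directions are reported both raw (doubled-angle space) and halved
for interpretation against the parameter axes: in halved-angle (axial)
coordinates the first parameter of the pair lies at 0 deg, the second at
90 deg, and their difference along the -45/135 deg axis.
"""

from __future__ import annotations

from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .tasks import ConditionSet, gradient_time_grid
from .units import simulate_rates

__all__ = [
    "PAIRS",
    "GRID",
    "pair_conditions",
    "activity_matrix",
    "unit_gradient_resultant",
    "population_resultant",
    "gradient_series",
    "epoch_samples",
    "halved_angle_deg",
    "axial_distance_deg",
    "eye_axis_deg",
    "hand_axis_deg",
    "EPOCHS",
]

PAIRS = (("T", "H"), ("T", "E"), ("H", "E"))
GRID = np.array([-20.0, -10.0, 0.0, 10.0, 20.0])
GRID_STEP = 10.0
EPOCHS = {"pre_target": -1.5, "go": 0.0, "offset": 1.0}


def _pair_key(pair) -> str:
    return "x".join(pair)


def pair_conditions(pair, fixed_value: float = 0.0,
                    grid: np.ndarray = GRID) -> ConditionSet:
    """25 conditions scanning the pair on the grid, row parameter varying
    slowest (row-major order matching the activity matrix layout)."""
    pair = tuple(pair)
    if pair not in PAIRS:
        raise ValueError(f"unknown analysis pair {pair!r}")
    rows, cols = np.meshgrid(grid, grid, indexing="ij")
    values = {"E": np.full(rows.size, fixed_value),
              "H": np.full(rows.size, fixed_value),
              "T": np.full(rows.size, fixed_value)}
    values[pair[0]] = rows.ravel()
    values[pair[1]] = cols.ravel()
    return ConditionSet(values["E"], values["H"], values["T"],
                        np.array([0.0]), label=f"gradient_{_pair_key(pair)}")


def activity_matrix(unit, pair, t, fixed_value: float = 0.0,
                    network: str = "main") -> np.ndarray:
    """Noiseless 5 x 5 response matrix; rows follow the first pair parameter
    in ascending order, columns the second."""
    conds = pair_conditions(pair, fixed_value)
    rates = simulate_rates([unit], conds, t, network=network)
    return rates.reshape(GRID.size, GRID.size)


def _doubled_resultants(matrices: np.ndarray, step: float) -> np.ndarray:
    """Per-unit doubled-angle resultants for a stack of (n, 5, 5) matrices."""
    g_row = np.gradient(matrices, step, axis=1)
    g_col = np.gradient(matrices, step, axis=2)
    mag = np.hypot(g_row, g_col)
    theta = np.arctan2(g_col, g_row)
    x = (mag * np.cos(2.0 * theta)).sum(axis=(1, 2))
    y = (mag * np.sin(2.0 * theta)).sum(axis=(1, 2))
    return np.stack([x, y], axis=1)


def unit_gradient_resultant(matrix: np.ndarray,
                            step: float = GRID_STEP) -> np.ndarray:
    """Angle-doubled resultant vector of one activity matrix."""
    matrix = np.asarray(matrix, dtype=float)
    return _doubled_resultants(matrix[None], step)[0]


def _unit_resultants(units, pair, t, network, fixed_value=0.0):
    conds = pair_conditions(pair, fixed_value)
    rates = simulate_rates(units, conds, t, network=network)
    return _doubled_resultants(rates.reshape(-1, GRID.size, GRID.size),
                               GRID_STEP)


def population_resultant(units, pair, t,
                         weights: Optional[Dict[str, float]] = None,
                         network: str = "main",
                         fixed_value: float = 0.0) -> np.ndarray:
    """Population resultant for one pair at one time.

    Without ``weights`` the unit resultants are summed directly.  With a
    ``{node: weight}`` mapping (hybrid population; weights must sum to 1)
    each node contributes its mean unit resultant scaled by its weight, so
    the weights act as composition fractions of the blended population.
    """
    units = list(units)
    if weights is None:
        return _unit_resultants(units, pair, t, network,
                                fixed_value).sum(axis=0)
    total = sum(weights.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"hybrid weights must sum to 1, got {total}")
    out = np.zeros(2)
    for node, weight in weights.items():
        node_units = [u for u in units if u.node == node]
        if not node_units:
            raise ValueError(f"no units from node {node!r}")
        res = _unit_resultants(node_units, pair, t, network, fixed_value)
        out += weight * res.mean(axis=0)
    return out


def gradient_series(units, times: Optional[Sequence[float]] = None,
                    pairs=PAIRS, weights: Optional[Dict[str, float]] = None,
                    network: str = "main", fixed_value: float = 0.0,
                    label: Optional[str] = None) -> pd.DataFrame:
    """Resultant time series for each analysis pair.

    Columns: pair, t, population, resultant_x, resultant_y, magnitude,
    halved_angle_deg.  ``population`` is ``label`` if given, else "hybrid"
    when node weights are supplied or the node name(s) present.
    """
    units = list(units)
    if times is None:
        times = gradient_time_grid()
    if label is None:
        label = "hybrid" if weights else "+".join(sorted({u.node
                                                          for u in units}))
    rows = []
    for pair in pairs:
        for t in times:
            vec = population_resultant(units, pair, float(t), weights=weights,
                                       network=network,
                                       fixed_value=fixed_value)
            rows.append({
                "pair": _pair_key(pair), "t": float(t), "population": label,
                "resultant_x": vec[0], "resultant_y": vec[1],
                "magnitude": float(np.hypot(*vec)),
                "halved_angle_deg": halved_angle_deg(vec),
            })
    return pd.DataFrame(rows)


def epoch_samples(series: pd.DataFrame,
                  epochs: Dict[str, float] = EPOCHS) -> dict:
    """Unit-normalized resultants at the pre-target, go and offset epochs.

    Zero resultants stay zero.  Raises if a requested epoch time is not in
    the series.
    """
    out: dict = {}
    for pair_key, sub in series.groupby("pair"):
        out[pair_key] = {}
        for name, t in epochs.items():
            match = sub[np.isclose(sub["t"], t)]
            if match.empty:
                raise ValueError(f"epoch {name} (t={t}) not in series")
            vec = match[["resultant_x", "resultant_y"]].to_numpy()[0]
            norm = np.hypot(*vec)
            vec = vec / norm if norm > 0 else vec
            out[pair_key][name] = {
                "x": float(vec[0]), "y": float(vec[1]),
                "halved_angle_deg": halved_angle_deg(vec),
            }
    return out


def halved_angle_deg(vec) -> float:
    """Half the doubled-angle resultant direction, in (-90, 90] degrees.

    This is the axial direction to compare against the parameter axes.
    """
    angle = 0.5 * np.degrees(np.arctan2(vec[1], vec[0]))
    if angle <= -90.0:
        angle += 180.0
    return float(angle)


def axial_distance_deg(angle1: float, angle2: float) -> float:
    """Distance between two axial (mod-180) directions, in [0, 90]."""
    d = abs(angle1 - angle2) % 180.0
    return float(min(d, 180.0 - d))


def eye_axis_deg(pair) -> float:
    """Axial direction of a pure eye-centered (TE) dependence for a pair,
    with the third parameter fixed at 0."""
    key = _pair_key(tuple(pair))
    return {"TxH": 0.0, "TxE": -45.0, "HxE": 90.0}[key]


def hand_axis_deg(pair) -> float:
    """Axial direction of a pure hand-centered (TH) dependence for a pair."""
    key = _pair_key(tuple(pair))
    return {"TxH": -45.0, "TxE": 0.0, "HxE": 0.0}[key]
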