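"""Time-resolved reclassification during simulated movement execution.

Starting from the delay-period state, the delay-task simulation is repeated
at successive movement times (the interpolation ``psi(t)`` shrinking the
dynamic displacement-vector signal), with the tuning screen and the
reference-frame classification re-applied at every time point exactly as an
experimenter would.  The outputs are the per-class mean reference-frame
weight and the class sizes as fractions of their movement-onset values.

Class membership for the mean-weight series is re-evaluated at each time
point; the counterintuitive drift of the hand class past w = 0 reported for
this procedure is an artifact of exactly this re-evaluation and is
deliberately preserved.
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .reference_frames import classify_population
from .screening import screen_population
from .tasks import ConditionSet, delay_task_conditions, screening_task_conditions
from .units import NoiseModel, add_noise, simulate_rates

__all__ = ["linear_trend", "evolve_classification", "DEFAULT_MOVEMENT_TIMES"]

DEFAULT_MOVEMENT_TIMES = (0.0, 0.25, 0.5, 0.75, 1.0)
_CLASSES = ("eye", "hand", "intermediate")


def linear_trend(t: Sequence[float], values: Sequence[float]
                 ) -> Tuple[float, float]:
    """Unweighted ordinary least-squares line; returns (slope, intercept)."""
    t = np.asarray(t, dtype=float)
    values = np.asarray(values, dtype=float)
    ok = np.isfinite(values)
    if ok.sum() < 2:
        raise ValueError("need at least 2 points for a linear trend")
    slope, intercept = np.polyfit(t[ok], values[ok], 1)
    return float(slope), float(intercept)


def evolve_classification(units, sigma: float = 15.0,
                          time_points: Sequence[float] = DEFAULT_MOVEMENT_TIMES,
                          eh_pairs=None,
                          noise: Optional[NoiseModel] = None,
                          rng: Optional[np.random.Generator] = None,
                          network: str = "main",
                          sve_threshold: float = 10.0,
                          alpha: float = 0.01,
                          ) -> Tuple[pd.DataFrame, dict]:
    """Re-screen and re-classify the population at each movement time.

    ``units`` is the full (unscreened) population; screening for task
    responsiveness is re-applied at every time point, so units whose
    responses lose their tuning during movement drop out.  With ``noise``
    given, fresh draws are taken at each time point from ``rng`` (or from
    the noise model's own seed).

    Returns the trajectory table (t, cls, mean_w, n_units, size_fraction,
    including an "all" row for the classified population) and a dict of
    linear trends per series.
    """
    time_points = [float(t) for t in time_points]
    if any(t < 0 or t > 1 for t in time_points):
        raise ValueError("movement time points must lie in [0, 1]")
    screen_conds = screening_task_conditions(sigma)
    delay_conds = delay_task_conditions(sigma, eh_pairs)
    if noise is not None and rng is None:
        rng = np.random.default_rng(noise.seed)

    rows = []
    base_sizes = None
    for t in time_points:
        srates = simulate_rates(units, screen_conds, t, network=network)
        if noise is not None:
            srates = add_noise(srates, noise, rng=rng)
        report = screen_population(srates, screen_conds.T, units,
                                   sve_threshold=sve_threshold)
        acc_ids = set(report.loc[report["accepted"], "unit_id"])
        accepted = [u for u in units if u.unit_id in acc_ids]
        if accepted:
            drates = simulate_rates(accepted, delay_conds, t, network=network)
            if noise is not None:
                drates = add_noise(drates, noise, rng=rng)
            fits = classify_population(drates, delay_conds, accepted,
                                       alpha=alpha)
        else:
            fits = pd.DataFrame(columns=["cls", "w"])
        classified = fits[fits["cls"].isin(_CLASSES)] if len(fits) else fits
        sizes = {cls: int((fits["cls"] == cls).sum()) if len(fits) else 0
                 for cls in _CLASSES}
        sizes["all"] = len(classified)
        if base_sizes is None:
            base_sizes = sizes
        for cls in _CLASSES:
            members = fits[fits["cls"] == cls] if len(fits) else fits
            rows.append({
                "t": t, "cls": cls,
                "mean_w": float(members["w"].mean()) if len(members) else np.nan,
                "n_units": sizes[cls],
                "size_fraction": (sizes[cls] / base_sizes[cls]
                                  if base_sizes[cls] else 0.0),
            })
        rows.append({
            "t": t, "cls": "all",
            "mean_w": float(classified["w"].mean()) if len(classified) else np.nan,
            "n_units": sizes["all"],
            "size_fraction": (sizes["all"] / base_sizes["all"]
                              if base_sizes["all"] else 0.0),
        })
    trajectory = pd.DataFrame(rows)

    trends = {}
    for cls in _CLASSES + ("all",):
        sub = trajectory[trajectory["cls"] == cls]
        for what in ("mean_w", "size_fraction"):
            try:
                slope, intercept = linear_trend(sub["t"], sub[what])
            except ValueError:
                slope = intercept = float("nan")
            trends[f"{cls}_{what}"] = {"slope": slope, "intercept": intercept}
    return trajectory, trends
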