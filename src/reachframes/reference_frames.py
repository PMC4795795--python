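"""Reference-frame regression, nested F-tests and stepwise classification.

Each screened unit's 45 delay-task responses are fit to the six-parameter
model

    r = a exp[-(TX - mu)^2 / 2 s^2] (1 + g HE) + c,
    TX = w TE + (1 - w) TH,

where the weight ``w`` interpolates between a hand-centered (w = 0) and an
eye-centered (w = 1) encoding of the target and ``g`` is a linear gain
modulation by the eye-centered hand position.  Bounds follow the stated
constraints: a in [1, 100], s in [10, 30], g in [-0.15, 0.15],
mu in [-45, 45], c in [0, 10], w in [-1.5, 2.5].

Two nested submodels fix ``w`` at 0 ("hand-centered") and 1 ("eye-centered").
Comparing each against the full model with an F-test at P < 0.01 yields the
stepwise classification: both rejected -> intermediate; only the hand model
rejected -> eye; only the eye model rejected -> hand; neither -> indeterminate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from ._fitting import fit_refframe
from .tasks import ConditionSet

__all__ = [
    "RefFrameFit",
    "fit_full_model",
    "fit_submodel",
    "nested_f_test",
    "classify_unit",
    "classify_population",
    "reference_frame_distribution",
    "summarize_distribution",
    "CLASSES",
]

log = logging.getLogger(__name__)

CLASSES = ("eye", "hand", "intermediate", "indeterminate")
ALPHA = 0.01
N_FULL_PARAMS = 6
_RSS_ATOL = 1e-8


@dataclass(frozen=True)
class RefFrameFit:
    """Fitted reference-frame model parameters and goodness of fit."""

    a: float
    mu: float
    s: float
    g: float
    c: float
    w: float
    r2: float
    rss: float
    n: int
    w_fixed: Optional[float] = None


def _mu_starts(conditions: ConditionSet) -> np.ndarray:
    return np.unique(conditions.T)


def fit_full_model(responses, conditions: ConditionSet,
                   extra_starts=()) -> RefFrameFit:
    """Fit the six-parameter model to the delay-task responses.

    ``extra_starts`` may carry submodel solutions as additional polish
    starts, which guarantees the nesting inequality RSS_full <= RSS_sub.
    """
    responses = np.asarray(responses, dtype=float)
    if responses.size < N_FULL_PARAMS:
        raise ValueError("fewer conditions than free parameters")
    res = fit_refframe(responses, conditions.TE, conditions.TH, conditions.HE,
                       mu_starts=_mu_starts(conditions),
                       extra_starts=extra_starts)
    return RefFrameFit(**res)


def fit_submodel(responses, conditions: ConditionSet,
                 w_fixed: float) -> RefFrameFit:
    """Fit the pure-frame submodel with ``w`` frozen at 0 or 1."""
    if w_fixed not in (0, 1):
        raise ValueError("w_fixed must be 0 (hand) or 1 (eye)")
    responses = np.asarray(responses, dtype=float)
    res = fit_refframe(responses, conditions.TE, conditions.TH, conditions.HE,
                       mu_starts=_mu_starts(conditions), w_fixed=w_fixed)
    return RefFrameFit(**res, w_fixed=float(w_fixed))


def nested_f_test(full: RefFrameFit, sub: RefFrameFit,
                  n: Optional[int] = None) -> float:
    """P-value of the F-test comparing a pure-frame submodel to the full model.

    F = (RSS_sub - RSS_full) / (RSS_full / (n - 6)) with 1 and n - 6 degrees
    of freedom.  A vanishing full-model residual gives p = 0 when the
    submodel residual is positive and p = 1 when both vanish.
    """
    n = full.n if n is None else n
    rss_f, rss_s = full.rss, sub.rss
    if rss_s < rss_f - (1e-6 * rss_f + 1e-9):
        raise RuntimeError(
            f"submodel RSS {rss_s:.6g} below full-model RSS {rss_f:.6g}: "
            "optimizer failure")
    if rss_f <= _RSS_ATOL:
        return 1.0 if rss_s <= _RSS_ATOL else 0.0
    F = max(rss_s - rss_f, 0.0) / (rss_f / (n - N_FULL_PARAMS))
    return float(stats.f.sf(F, 1, n - N_FULL_PARAMS))


def classify_unit(p_eye: float, p_hand: float, alpha: float = ALPHA) -> str:
    """Stepwise class from the two submodel p-values.

    ``p_eye`` tests the eye-centered (w = 1) submodel, ``p_hand`` the
    hand-centered (w = 0) one; rejecting a submodel means the corresponding
    pure frame is inadequate.
    """
    eye_rejected = p_eye < alpha
    hand_rejected = p_hand < alpha
    if eye_rejected and hand_rejected:
        return "intermediate"
    if hand_rejected:
        return "eye"
    if eye_rejected:
        return "hand"
    return "indeterminate"


def classify_population(rates: np.ndarray, conditions: ConditionSet, units,
                        alpha: float = ALPHA) -> pd.DataFrame:
    """Fit and classify many units; one row per unit.

    ``rates`` is (n_units, n_conditions), aligned with ``units`` and
    ``conditions``.  Columns: unit_id, node, a, mu, s, g, c, w, r2,
    p_eye, p_hand, cls.
    """
    rates = np.asarray(rates, dtype=float)
    rows = []
    for i, unit in enumerate(units):
        y = rates[i]
        sub_eye = fit_submodel(y, conditions, 1)
        sub_hand = fit_submodel(y, conditions, 0)
        starts = [
            np.array([f.a, f.mu, f.s, f.g, f.c, f.w_fixed])
            for f in (sub_eye, sub_hand)
        ]
        full = fit_full_model(y, conditions, extra_starts=starts)
        p_eye = nested_f_test(full, sub_eye)
        p_hand = nested_f_test(full, sub_hand)
        rows.append({
            "unit_id": unit.unit_id, "node": unit.node,
            "a": full.a, "mu": full.mu, "s": full.s, "g": full.g,
            "c": full.c, "w": full.w, "r2": full.r2,
            "p_eye": p_eye, "p_hand": p_hand,
            "cls": classify_unit(p_eye, p_hand, alpha),
        })
    return pd.DataFrame(rows)


def reference_frame_distribution(units, rates: np.ndarray,
                                 conditions: ConditionSet,
                                 alpha: float = ALPHA) -> pd.DataFrame:
    """Classified reference-frame table for a pre-screened population.

    Thin wrapper over :func:`classify_population` that tolerates (and warns
    on) an empty screened population.
    """
    if len(units) == 0:
        log.warning("empty screened population; returning empty table")
        return pd.DataFrame(columns=["unit_id", "node", "a", "mu", "s", "g",
                                     "c", "w", "r2", "p_eye", "p_hand", "cls"])
    return classify_population(rates, conditions, units, alpha=alpha)


def summarize_distribution(fits: pd.DataFrame, w_bin: float = 0.1,
                           good_r2: float = 0.8) -> dict:
    """Histogram-ready summary of a classified population.

    Returns per-node class counts and percentages (indeterminate units are
    counted but excluded from the weight histogram), the weight histogram of
    classified units, the median r2 per weight bin, and the subset of
    well-fit units (r2 >= ``good_r2``).
    """
    per_node = {}
    for node, sub in fits.groupby("node"):
        counts = {cls: int((sub["cls"] == cls).sum()) for cls in CLASSES}
        n = len(sub)
        per_node[node] = {
            "n_included": n,
            "counts": counts,
            "percentages": {cls: 100.0 * counts[cls] / n if n else float("nan")
                            for cls in CLASSES},
        }
    classified = fits[fits["cls"] != "indeterminate"]
    edges = np.arange(-1.5, 2.5 + w_bin / 2, w_bin)
    hist, _ = np.histogram(classified["w"], bins=edges)
    bins = pd.cut(classified["w"], bins=edges, include_lowest=True)
    median_r2 = classified.groupby(bins, observed=True)["r2"].median()
    return {
        "per_node": per_node,
        "w_hist_edges": edges.tolist(),
        "w_hist_counts": hist.tolist(),
        "median_r2_per_bin": {str(k): float(v)
                              for k, v in median_r2.items()},
        "good_fit_unit_ids": fits.loc[fits["r2"] >= good_r2,
                                      "unit_id"].tolist(),
    }
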