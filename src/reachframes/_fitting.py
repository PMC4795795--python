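"""Bounded nonlinear least-squares machinery shared by the tuning screen and
the reference-frame regression.

Both objectives are multimodal in the Gaussian peak location, so fits use a
deterministic multistart: a coarse grid over the nonlinear parameters (peak
location, width, and for the full model the reference-frame weight), where
for each grid point the remaining parameters (amplitude, gain slope,
baseline) enter linearly and are solved in closed form.  The best grid
candidates are then polished with ``scipy.optimize.least_squares`` (TRF)
under the stated box constraints.  Ties in residual are broken
deterministically (smallest width then smallest |peak| for the screen;
weight closest to 0.5 for the reference-frame model).
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "S_STARTS",
    "W_STARTS",
    "fit_gaussian_screen",
    "fit_refframe",
]

S_STARTS = np.array([10.0, 15.0, 20.0, 25.0, 30.0])
W_STARTS = np.array([-1.0, 0.0, 0.25, 0.5, 0.75, 1.0, 2.0])

SCREEN_LB = np.array([0.0, -45.0, 10.0, 0.0])      # a, mu, s, c
SCREEN_UB = np.array([100.0, 45.0, 30.0, 10.0])
REF_LB = np.array([1.0, -45.0, 10.0, -0.15, 0.0, -1.5])   # a, mu, s, g, c, w
REF_UB = np.array([100.0, 45.0, 30.0, 0.15, 10.0, 2.5])

_RSS_TIE_RTOL = 1e-7
_grid_cache: dict = {}


def _cache_key(kind, *arrays, extra=()):
    parts = [kind]
    for a in arrays:
        parts.append(tuple(np.round(np.asarray(a, float).ravel(), 9).tolist()))
    parts.append(tuple(extra))
    return tuple(parts)


# ---------------------------------------------------------------------------
# center-out Gaussian screen: r = a exp[-(T - mu)^2 / 2 s^2] + c


class _ScreenGrid:
    def __init__(self, targets: np.ndarray, mu_starts: np.ndarray):
        MU, S = np.meshgrid(mu_starts, S_STARTS, indexing="ij")
        self.mu = MU.ravel()
        self.s = S.ravel()
        self.targets = targets
        self.n = targets.size
        self.G = np.exp(-((targets[None, :] - self.mu[:, None]) ** 2)
                        / (2.0 * self.s[:, None] ** 2))
        self.Sx = self.G.sum(axis=1)
        self.Sxx = (self.G ** 2).sum(axis=1)

    def score(self, y: np.ndarray):
        n = self.n
        Sy = y.sum()
        yty = float(y @ y)
        Sxy = self.G @ y
        denom = n * self.Sxx - self.Sx ** 2
        a = (n * Sxy - self.Sx * Sy) / np.maximum(denom, 1e-12)
        a = np.clip(a, SCREEN_LB[0], SCREEN_UB[0])
        c = np.clip((Sy - a * self.Sx) / n, SCREEN_LB[3], SCREEN_UB[3])
        rss = (yty - 2 * a * Sxy - 2 * c * Sy
               + a ** 2 * self.Sxx + 2 * a * c * self.Sx + c ** 2 * n)
        return a, c, rss


def _screen_grid(targets: np.ndarray) -> _ScreenGrid:
    key = _cache_key("screen", targets)
    if key not in _grid_cache:
        _grid_cache[key] = _ScreenGrid(targets, np.unique(targets))
    return _grid_cache[key]


def _polish_screen(y, targets, x0):
    x0 = np.clip(x0, SCREEN_LB, SCREEN_UB)

    def fun(p):
        a, mu, s, c = p
        return a * np.exp(-((targets - mu) ** 2) / (2.0 * s * s)) + c - y

    def jac(p):
        a, mu, s, c = p
        d = targets - mu
        G = np.exp(-(d ** 2) / (2.0 * s * s))
        J = np.empty((targets.size, 4))
        J[:, 0] = G
        J[:, 1] = a * G * d / (s * s)
        J[:, 2] = a * G * d ** 2 / (s ** 3)
        J[:, 3] = 1.0
        return J

    res = least_squares(fun, x0, jac=jac, bounds=(SCREEN_LB, SCREEN_UB),
                        method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12,
                        max_nfev=200)
    return res.x, 2.0 * res.cost


def _polish_order(rss, n_polish, prune_factor: float = 1.5):
    """Indices of the best grid candidates worth polishing.

    Keeps up to ``n_polish`` candidates but drops those whose grid residual
    already exceeds the best grid residual by ``prune_factor`` (a start that
    far off never wins after polishing; near-flat landscapes keep all)."""
    order = np.argsort(rss)[:n_polish]
    best = rss[order[0]]
    cut = prune_factor * best + 1e-9
    keep = [order[0]]
    keep.extend(i for i in order[1:] if rss[i] <= cut)
    return keep


def _pick(candidates, tiebreak):
    """Best (params, rss) candidate; RSS ties broken by ``tiebreak(params)``."""
    rmin = min(r for _, r in candidates)
    tol = _RSS_TIE_RTOL * (1.0 + rmin)
    tied = [(p, r) for p, r in candidates if r <= rmin + tol]
    return min(tied, key=lambda pr: tiebreak(pr[0]))


def fit_gaussian_screen(y, targets, n_polish: int = 3):
    """Bounded 4-parameter Gaussian fit to center-out responses.

    Returns a dict with a, mu, s, c, rss, r2 and a ``degenerate`` flag for
    variance-free inputs (the fit then pins the amplitude at its lower
    bound with r2 = 0 rather than raising).
    """
    y = np.asarray(y, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if y.shape != targets.shape:
        raise ValueError("responses and targets must align")
    sstot = float(((y - y.mean()) ** 2).sum())
    if sstot <= 1e-12:
        c = float(np.clip(y.mean(), SCREEN_LB[3], SCREEN_UB[3]))
        rss = float(((y - c) ** 2).sum())
        return dict(a=0.0, mu=0.0, s=float(S_STARTS[0]), c=c, rss=rss,
                    r2=0.0, degenerate=True)
    grid = _screen_grid(targets)
    a, c, rss = grid.score(y)
    order = _polish_order(rss, n_polish)
    candidates = []
    for i in order:
        x0 = np.array([a[i], grid.mu[i], grid.s[i], c[i]])
        params, prss = _polish_screen(y, targets, x0)
        candidates.append((params, prss))
    params, rss_best = _pick(candidates, lambda p: (p[2], abs(p[1])))
    r2 = 1.0 - rss_best / sstot
    return dict(a=float(params[0]), mu=float(params[1]), s=float(params[2]),
                c=float(params[3]), rss=float(rss_best), r2=float(r2),
                degenerate=False)


# ---------------------------------------------------------------------------
# reference-frame model: r = a exp[-(TX - mu)^2 / 2 s^2] (1 + g HE) + c,
# TX = w TE + (1 - w) TH = TH + w HE


class _RefGrid:
    def __init__(self, TE, TH, HE, mu_starts, w_values):
        n = TE.size
        combos = []
        for w in w_values:
            TX = TH + w * HE
            for mu in mu_starts:
                for s in S_STARTS:
                    combos.append((w, mu, s))
        self.w, self.mu, self.s = (np.array(x) for x in zip(*combos))
        TX_all = TH[None, :] + self.w[:, None] * HE[None, :]
        self.G = np.exp(-((TX_all - self.mu[:, None]) ** 2)
                        / (2.0 * self.s[:, None] ** 2))
        self.GH = self.G * HE[None, :]
        self.n = n
        ones = np.ones(n)
        # normal-equation blocks for columns [G, G*HE, 1]
        xtx = np.empty((self.G.shape[0], 3, 3))
        xtx[:, 0, 0] = (self.G * self.G).sum(1)
        xtx[:, 0, 1] = xtx[:, 1, 0] = (self.G * self.GH).sum(1)
        xtx[:, 0, 2] = xtx[:, 2, 0] = self.G @ ones
        xtx[:, 1, 1] = (self.GH * self.GH).sum(1)
        xtx[:, 1, 2] = xtx[:, 2, 1] = self.GH @ ones
        xtx[:, 2, 2] = n
        ridge = 1e-9 * (1.0 + np.trace(xtx, axis1=1, axis2=2))
        xtx = xtx + ridge[:, None, None] * np.eye(3)[None]
        self.xtx = xtx
        self.xtx_inv = np.linalg.inv(xtx)

    def score(self, y):
        b = np.empty((self.G.shape[0], 3))
        b[:, 0] = self.G @ y
        b[:, 1] = self.GH @ y
        b[:, 2] = y.sum()
        beta = np.einsum("cij,cj->ci", self.xtx_inv, b)
        yty = float(y @ y)
        rss = (yty - 2.0 * np.einsum("ci,ci->c", beta, b)
               + np.einsum("ci,cij,cj->c", beta, self.xtx, beta))
        return beta, rss


def _ref_grid(TE, TH, HE, mu_starts, w_values) -> _RefGrid:
    key = _cache_key("ref", TE, TH, HE, mu_starts, extra=tuple(w_values))
    if key not in _grid_cache:
        _grid_cache[key] = _RefGrid(TE, TH, HE, np.asarray(mu_starts, float),
                                    np.asarray(w_values, float))
    return _grid_cache[key]


def _ref_model(p, TE, TH, HE):
    a, mu, s, g, c, w = p
    TX = TH + w * HE
    return a * np.exp(-((TX - mu) ** 2) / (2.0 * s * s)) * (1.0 + g * HE) + c


def _ref_jac(p, TE, TH, HE):
    a, mu, s, g, c, w = p
    TX = TH + w * HE
    d = TX - mu
    G = np.exp(-(d ** 2) / (2.0 * s * s))
    gain = 1.0 + g * HE
    J = np.empty((TE.size, 6))
    J[:, 0] = G * gain
    J[:, 1] = a * G * gain * d / (s * s)
    J[:, 2] = a * G * gain * d ** 2 / (s ** 3)
    J[:, 3] = a * G * HE
    J[:, 4] = 1.0
    J[:, 5] = -a * G * gain * d * HE / (s * s)
    return J


def _polish_ref(y, TE, TH, HE, x0, w_fixed=None):
    if w_fixed is None:
        lb, ub = REF_LB, REF_UB
        x0 = np.clip(x0, lb, ub)

        def fun(p):
            return _ref_model(p, TE, TH, HE) - y

        def jac(p):
            return _ref_jac(p, TE, TH, HE)

        res = least_squares(fun, x0, jac=jac, bounds=(lb, ub), method="trf",
                            xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=300)
        return res.x, 2.0 * res.cost
    lb, ub = REF_LB[:5], REF_UB[:5]
    x0 = np.clip(x0[:5], lb, ub)

    def fun(p):
        return _ref_model(np.append(p, w_fixed), TE, TH, HE) - y

    def jac(p):
        return _ref_jac(np.append(p, w_fixed), TE, TH, HE)[:, :5]

    res = least_squares(fun, x0, jac=jac, bounds=(lb, ub), method="trf",
                        xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=300)
    return np.append(res.x, w_fixed), 2.0 * res.cost


def _starts_from_grid(grid, beta, rss, n_polish):
    order = _polish_order(rss, n_polish)
    starts = []
    for i in order:
        a = float(np.clip(beta[i, 0], REF_LB[0], REF_UB[0]))
        g = beta[i, 1] / beta[i, 0] if abs(beta[i, 0]) > 1e-9 else 0.0
        g = float(np.clip(g, REF_LB[3], REF_UB[3]))
        c = float(np.clip(beta[i, 2], REF_LB[4], REF_UB[4]))
        starts.append(np.array([a, grid.mu[i], grid.s[i], g, c, grid.w[i]]))
    return starts


def fit_refframe(y, TE, TH, HE, mu_starts, w_fixed=None, extra_starts=(),
                 n_polish: int = 3):
    """Bounded fit of the six-parameter reference-frame model.

    With ``w_fixed`` in {0, 1} the weight is frozen (the pure hand- or
    eye-centered submodel; 5 free parameters).  ``extra_starts`` accepts
    additional 6-vectors to polish from — used to seed the full model with
    its submodel solutions so the nested-model residual ordering holds by
    construction.  Returns a dict with the parameters, rss and r2.
    """
    y = np.asarray(y, dtype=float)
    TE, TH, HE = (np.asarray(x, float) for x in (TE, TH, HE))
    if y.size < 6:
        raise ValueError("need at least as many conditions as parameters")
    if w_fixed is not None and w_fixed not in (0, 1):
        raise ValueError("w_fixed must be 0 or 1")
    w_values = W_STARTS if w_fixed is None else np.array([float(w_fixed)])
    grid = _ref_grid(TE, TH, HE, mu_starts, w_values)
    beta, rss = grid.score(y)
    starts = _starts_from_grid(grid, beta, rss, n_polish)
    starts.extend(np.asarray(s, float) for s in extra_starts)
    candidates = [ _polish_ref(y, TE, TH, HE, x0, w_fixed=w_fixed)
                   for x0 in starts ]
    params, rss_best = _pick(candidates, lambda p: abs(p[5] - 0.5))
    sstot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss_best / sstot if sstot > 1e-12 else 0.0
    return dict(a=float(params[0]), mu=float(params[1]), s=float(params[2]),
                g=float(params[3]), c=float(params[4]), w=float(params[5]),
                rss=float(rss_best), r2=float(r2), n=int(y.size))
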