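"""Single-unit response models for the network nodes, and the noise model.

The main network has three internal nodes whose units carry Gaussian tuning
(length scale ``sigma``) with onset ``u`` and, where applicable, a semi-linear
gain modulation with onset ``v`` and alternating slope sign:

* ``eye``       r1 = A exp[-(TE-u)^2 / 2 sigma^2] * f[+-(HE - v)/sigma]
* ``hand``      r2 = A exp[-(psi(t) TH - u)^2 / 2 sigma^2]
* ``eye_hand``  r3 = A exp[-(TE-u)^2 / 2 sigma^2] * f[+-(psi(t) TH - v)/sigma]

where ``f(x) = max(x, 0)`` is the semi-linear gain function and ``psi`` the
interpolation function from :mod:`reachframes.kinematics`.  Before target
onset (pre-target epoch) the target-related factors are set to unity, giving
``r1 = A f[+-(HE-v)/sigma]``, ``r2 = A`` and ``r3 = A``.

Three alternative arrangements of the same trajectory computation are also
provided (``rising_phi``, ``dual_sigmoid``, ``static_hand``); they differ in
which dynamic quantity each node represents and serve as contrasts whose
predictions deviate from the cortical data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .kinematics import TaskCondition, phi, psi

__all__ = [
    "UnitSpec",
    "NoiseModel",
    "NodeDef",
    "Network",
    "NETWORKS",
    "MAIN_NODES",
    "semilinear_gain",
    "unit_response",
    "alt_unit_response",
    "add_noise",
    "simulate_rates",
]

PRETARGET_END = -1.0


def semilinear_gain(x):
    """Semi-linear gain modulation ``f(x) = x`` for ``x >= 0``, else 0."""
    x = np.asarray(x, dtype=float)
    out = np.maximum(x, 0.0)
    if np.ndim(x) == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class UnitSpec:
    """One model unit: node kind, tuning onsets, gain slope sign and scale."""

    unit_id: str
    node: str
    u: float
    v: Optional[float] = None
    gain_sign: int = 1
    A: float = 30.0
    sigma: float = 15.0

    def __post_init__(self) -> None:
        if self.A <= 0 or self.sigma <= 0:
            raise ValueError("A and sigma must be positive")
        if self.gain_sign not in (-1, 1):
            raise ValueError("gain_sign must be -1 or +1")


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian rate noise: zero mean, standard deviation ``sd``."""

    sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


def _gauss(x, u, sigma):
    x = np.asarray(x, dtype=float)
    return np.exp(-((x - u) ** 2) / (2.0 * sigma**2))


# Response functions receive task quantities (TE, HE, TH may be arrays) plus
# the interpolation values for the requested times, and the unit parameters.


def _r_eye(unit, TE, HE, TH, ps, ph):
    return unit.A * _gauss(TE, unit.u, unit.sigma) * semilinear_gain(
        unit.gain_sign * (HE - unit.v) / unit.sigma
    )


def _r_eye_pre(unit, TE, HE, TH, ps, ph):
    return unit.A * semilinear_gain(unit.gain_sign * (HE - unit.v) / unit.sigma)


def _r_hand(unit, TE, HE, TH, ps, ph):
    return unit.A * _gauss(ps * TH, unit.u, unit.sigma)


def _r_const(unit, TE, HE, TH, ps, ph):
    return unit.A * np.ones(np.broadcast(TE, ps).shape) if np.ndim(TE) or np.ndim(ps) else unit.A


def _r_eye_hand(unit, TE, HE, TH, ps, ph):
    return unit.A * _gauss(TE, unit.u, unit.sigma) * semilinear_gain(
        unit.gain_sign * (ps * TH - unit.v) / unit.sigma
    )


def _r_hand_static(unit, TE, HE, TH, ps, ph):
    return unit.A * _gauss(TH, unit.u, unit.sigma)


def _r_eye_hand_rising(unit, TE, HE, TH, ps, ph):
    return unit.A * _gauss(ph * TH, unit.u, unit.sigma) * semilinear_gain(
        unit.gain_sign * (HE - unit.v) / unit.sigma
    )


def _r_target_eye(unit, TE, HE, TH, ps, ph):
    return unit.A * _gauss(TE, unit.u, unit.sigma)


def _r_target_eye_dyn(unit, TE, HE, TH, ps, ph):
    return unit.A * _gauss(ph * TE, unit.u, unit.sigma)


def _r_hand_pos(unit, TE, HE, TH, ps, ph):
    return unit.A * _gauss(HE, unit.u, unit.sigma)


def _r_hand_pos_dyn(unit, TE, HE, TH, ps, ph):
    return unit.A * _gauss(ps * HE, unit.u, unit.sigma)


def _r_combined(unit, TE, HE, TH, ps, ph):
    return unit.A * _gauss(ph * TE, unit.u, unit.sigma) * semilinear_gain(
        unit.gain_sign * (ps * HE - unit.v) / unit.sigma
    )


@dataclass(frozen=True)
class NodeDef:
    """Response definition for one node kind."""

    name: str
    dual_onset: bool
    response: Callable
    pretarget: Optional[Callable] = None


@dataclass(frozen=True)
class Network:
    """A named collection of node kinds forming one network arrangement."""

    name: str
    nodes: tuple

    def node(self, name: str) -> NodeDef:
        for nd in self.nodes:
            if nd.name == name:
                return nd
        raise KeyError(f"network {self.name!r} has no node {name!r}")

    @property
    def node_names(self):
        return [nd.name for nd in self.nodes]


MAIN_NODES = ("eye", "hand", "eye_hand")

NETWORKS = {
    "main": Network(
        "main",
        (
            NodeDef("eye", True, _r_eye, _r_eye_pre),
            NodeDef("hand", False, _r_hand, _r_const),
            NodeDef("eye_hand", True, _r_eye_hand, _r_const),
        ),
    ),
    # Rearrangement he(t) = HE + phi(t) TH with a rising sigmoid and a static
    # displacement-vector node.
    "rising_phi": Network(
        "rising_phi",
        (
            NodeDef("eye", True, _r_eye, _r_eye_pre),
            NodeDef("hand_static", False, _r_hand_static),
            NodeDef("eye_hand_rising", True, _r_eye_hand_rising),
        ),
    ),
    # Rearrangement he(t) = psi(t) HE + phi(t) TE using both sigmoids.
    "dual_sigmoid": Network(
        "dual_sigmoid",
        (
            NodeDef("target_eye", False, _r_target_eye),
            NodeDef("target_eye_dyn", False, _r_target_eye_dyn),
            NodeDef("hand_pos", False, _r_hand_pos),
            NodeDef("hand_pos_dyn", False, _r_hand_pos_dyn),
            NodeDef("combined", True, _r_combined),
        ),
    ),
    # Main network with the dynamic hand-centered node replaced by a static
    # representation of the displacement vector.
    "static_hand": Network(
        "static_hand",
        (
            NodeDef("eye", True, _r_eye, _r_eye_pre),
            NodeDef("hand_static", False, _r_hand_static),
            NodeDef("eye_hand", True, _r_eye_hand, _r_const),
        ),
    ),
}


def _resolve_node(unit: UnitSpec, network) -> NodeDef:
    if isinstance(network, str):
        try:
            network = NETWORKS[network]
        except KeyError:
            raise ValueError(f"unknown network {network!r}") from None
    return network.node(unit.node)


def _evaluate(unit: UnitSpec, node: NodeDef, TE, HE, TH, t, form="piecewise"):
    t_arr = np.asarray(t, dtype=float)
    pre = t_arr < PRETARGET_END
    ps = psi(t, form=form)
    ph = 1.0 - np.asarray(ps)
    main = node.response(unit, TE, HE, TH, np.asarray(ps), ph)
    if not np.any(pre):
        return main
    if node.pretarget is None:
        raise ValueError(
            f"node {node.name!r} has no stated pre-target response form"
        )
    pre_rates = node.pretarget(unit, TE, HE, TH, np.asarray(ps), ph)
    return np.where(pre, pre_rates, main)


def unit_response(unit: UnitSpec, cond: TaskCondition, t, network="main",
                  form: str = "piecewise"):
    """Noiseless firing rate of ``unit`` for one condition at time(s) ``t``.

    For pre-target times (t < -1) the node's stated pre-target form is used;
    node kinds without one raise ``ValueError``.
    """
    node = _resolve_node(unit, network)
    out = _evaluate(unit, node, cond.TE, cond.HE, cond.TH, t, form=form)
    if np.ndim(t) == 0:
        return float(out)
    return np.asarray(out, dtype=float)


def alt_unit_response(unit: UnitSpec, cond: TaskCondition, t, network,
                      form: str = "piecewise"):
    """Response under one of the alternative network arrangements.

    ``network`` selects ``rising_phi``, ``dual_sigmoid`` or ``static_hand``;
    the unit's ``node`` field names the variant node kind.
    """
    if isinstance(network, str) and network == "main":
        raise ValueError("alt_unit_response is for the alternative networks")
    return unit_response(unit, cond, t, network=network, form=form)


def simulate_rates(units, condition_set, t, network="main",
                   form: str = "piecewise") -> np.ndarray:
    """Noiseless rates for many units over a condition set at a single time.

    Returns an array of shape ``(n_units, n_conditions)``.
    """
    net = NETWORKS[network] if isinstance(network, str) else network
    TE = np.asarray(condition_set.TE, dtype=float)
    HE = np.asarray(condition_set.HE, dtype=float)
    TH = np.asarray(condition_set.TH, dtype=float)
    out = np.empty((len(units), TE.size), dtype=float)
    for i, unit in enumerate(units):
        node = net.node(unit.node)
        out[i] = np.broadcast_to(
            _evaluate(unit, node, TE, HE, TH, t, form=form), (TE.size,)
        )
    return out


def add_noise(rates: np.ndarray, noise: NoiseModel,
              rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Add independent Gaussian perturbations to a rate array.

    With ``rng`` given, draws come from that stream (the experiment-level
    convention: one seeded stream per simulated dataset).  Otherwise a fresh
    generator is built from ``noise.seed`` so repeated calls with the same
    ``NoiseModel`` reproduce the same output.  Rates are not clipped at zero.
    """
    rates = np.asarray(rates, dtype=float)
    if noise.sd == 0:
        return rates.copy()
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    return rates + rng.normal(0.0, noise.sd, size=rates.shape)
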