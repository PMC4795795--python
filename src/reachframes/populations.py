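"""Construction of unit populations tiling onset space for each node kind.

Each node kind is tiled with ``N = 30`` onset values per onset dimension over
``-3 sigma .. +3 sigma`` degrees of eccentricity.  Single-onset nodes (the
dynamic hand-centered representation) therefore yield ``N`` units and
dual-onset nodes (tuning onset ``u`` crossed with gain onset ``v``) yield
``N^2`` units.  The slope sign of the semi-linear gain alternates between
adjacent units, starting positive.

By default onsets form a deterministic, evenly spaced grid; a seeded
uniform-random mode is available for robustness checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np
import pandas as pd

from .units import NETWORKS, Network, UnitSpec

__all__ = ["PopulationSpec", "build_population", "build_network_population",
           "population_manifest"]


@dataclass(frozen=True)
class PopulationSpec:
    """Parameters for tiling one node kind with units."""

    node: str
    network: str = "main"
    N: int = 30
    A: float = 30.0
    sigma: float = 15.0
    sampling: str = "grid"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("N must be >= 2 to tile onset space")
        if self.sampling not in ("grid", "uniform_random"):
            raise ValueError(f"unknown sampling mode {self.sampling!r}")


def _onsets(spec: PopulationSpec, rng) -> np.ndarray:
    lo, hi = -3.0 * spec.sigma, 3.0 * spec.sigma
    if spec.sampling == "grid":
        return np.linspace(lo, hi, spec.N)
    return np.sort(rng.uniform(lo, hi, size=spec.N))


def build_population(spec: PopulationSpec) -> List[UnitSpec]:
    """Return the full unit tiling for one node kind.

    Unit ids are ``<node>_<k>`` with ``k`` the row-major (u, v) index; gain
    signs alternate +/- in that enumeration order, starting with +.
    """
    network = NETWORKS[spec.network]
    node = network.node(spec.node)
    rng = np.random.default_rng(spec.seed)
    us = _onsets(spec, rng)
    units: List[UnitSpec] = []
    if node.dual_onset:
        vs = _onsets(spec, rng)
        k = 0
        for u in us:
            for v in vs:
                units.append(UnitSpec(
                    unit_id=f"{spec.node}_{k}", node=spec.node,
                    u=float(u), v=float(v),
                    gain_sign=1 if k % 2 == 0 else -1,
                    A=spec.A, sigma=spec.sigma))
                k += 1
    else:
        for k, u in enumerate(us):
            units.append(UnitSpec(
                unit_id=f"{spec.node}_{k}", node=spec.node,
                u=float(u), v=None,
                gain_sign=1 if k % 2 == 0 else -1,
                A=spec.A, sigma=spec.sigma))
    return units


def build_network_population(network: str = "main", N: int = 30,
                             A: float = 30.0, sigma: float = 15.0,
                             sampling: str = "grid",
                             seed: Optional[int] = None) -> dict:
    """Tile every node of a network; returns ``{node_name: [UnitSpec, ...]}``."""
    net: Network = NETWORKS[network]
    return {
        nd.name: build_population(PopulationSpec(
            node=nd.name, network=network, N=N, A=A, sigma=sigma,
            sampling=sampling, seed=seed))
        for nd in net.nodes
    }


def population_manifest(units) -> pd.DataFrame:
    """Manifest table: unit_id, node, u, v, gain_sign."""
    return pd.DataFrame({
        "unit_id": [u.unit_id for u in units],
        "node": [u.node for u in units],
        "u": [u.u for u in units],
        "v": [u.v if u.v is not None else np.nan for u in units],
        "gain_sign": [u.gain_sign for u in units],
    })
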