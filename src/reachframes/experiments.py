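"""Seeded, configured experiment runs with machine-readable outputs.

Each named experiment reproduces one simulated figure of the study:

* ``fig4_noiseless`` / ``fig4_noisy`` — delay-period reference-frame
  distribution for the main network (without / with rate noise);
* ``fig6`` — time-resolved reclassification across movement execution;
* ``fig7_pure`` / ``fig7_hybrid`` — gradient analysis of the pure dynamic
  hand-centered node and of the 25/50/25 hybrid population;
* ``fig8_variantA`` / ``fig8_variantB`` — delay-period classification under
  the rising-sigmoid and dual-sigmoid alternative networks;
* ``fig8_variantE`` — hybrid gradient analysis under the static
  displacement-vector network, compared against the main model.

A single experiment seed expands into per-stage substreams (population
sampling, noise) so stages are independently reproducible; identical
(name, config, seed) yield identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .dynamics import DEFAULT_MOVEMENT_TIMES, evolve_classification
from .gradients import (EPOCHS, axial_distance_deg, epoch_samples,
                        eye_axis_deg, gradient_series)
from .populations import build_network_population, population_manifest
from .reference_frames import classify_population, summarize_distribution
from .screening import screen_population
from .tasks import (ConditionSet, delay_task_conditions, gradient_time_grid,
                    screening_task_conditions)
from .units import NETWORKS, NoiseModel, UnitSpec, add_noise, simulate_rates

__all__ = [
    "ExperimentConfig",
    "EXPERIMENT_NAMES",
    "run_experiment",
    "run_delay_classification",
    "classification_summary",
    "multi_seed_percentages",
    "rate_frame",
    "load_rate_table",
    "classify_rate_table",
    "validate_summary",
]

log = logging.getLogger(__name__)

EXPERIMENT_NAMES = (
    "fig4_noiseless", "fig4_noisy", "fig6", "fig7_pure", "fig7_hybrid",
    "fig8_variantA", "fig8_variantB", "fig8_variantE",
)

# Five eye/hand configurations: symmetric eye-hand offsets 0, +-2 sigma,
# +-3 sigma about the origin, all positions on the sigma/2 grid.
DEFAULT_EH_OFFSET_FRACTIONS = (
    (0.0, 0.0), (1.5, -1.5), (-1.5, 1.5), (1.0, -1.0), (-1.0, 1.0))

HYBRID_WEIGHTS = {"eye": 0.25, "hand": 0.5, "eye_hand": 0.25}


@dataclass(frozen=True)
class ExperimentConfig:
    """Simulation parameters; defaults are the study's stated values."""

    A: float = 30.0
    sigma: float = 15.0
    N: int = 30
    sampling: str = "grid"
    noise_sd: float = 5.0
    sve_threshold: float = 10.0
    alpha: float = 0.01
    eh_pair_fractions: Tuple[Tuple[float, float], ...] = DEFAULT_EH_OFFSET_FRACTIONS
    movement_times: Tuple[float, ...] = DEFAULT_MOVEMENT_TIMES
    psi_form: str = "piecewise"

    def __post_init__(self) -> None:
        for name in ("A", "sigma", "noise_sd", "sve_threshold", "alpha"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def eh_pairs(self) -> Tuple[Tuple[float, float], ...]:
        """(E, H) pairs in degrees, scaled by sigma."""
        return tuple((e * self.sigma, h * self.sigma)
                     for e, h in self.eh_pair_fractions)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stage]))


def _all_units(pops: dict) -> list:
    return [u for node_units in pops.values() for u in node_units]


def run_delay_classification(config: ExperimentConfig, seed: int,
                             network: str = "main",
                             noisy: bool = True) -> dict:
    """Full delay-period pipeline: population, screen, fit, classify.

    Returns populations, the screening report, the per-unit fit table and
    the rate tables used (one simulated dataset per experiment: the screen
    and the regression share the seeded noise stream).
    """
    pops = build_network_population(network, N=config.N, A=config.A,
                                    sigma=config.sigma,
                                    sampling=config.sampling, seed=seed)
    units = _all_units(pops)
    screen_conds = screening_task_conditions(config.sigma)
    delay_conds = delay_task_conditions(config.sigma, config.eh_pairs)
    noise_rng = _rng(seed, 1)
    noise = NoiseModel(config.noise_sd, seed)

    screen_rates = simulate_rates(units, screen_conds, 0.0, network=network)
    if noisy:
        screen_rates = add_noise(screen_rates, noise, rng=noise_rng)
    report = screen_population(screen_rates, screen_conds.T, units,
                               task_range=(-2 * config.sigma, 2 * config.sigma),
                               sve_threshold=config.sve_threshold)
    acc_ids = set(report.loc[report["accepted"], "unit_id"])
    accepted = [u for u in units if u.unit_id in acc_ids]

    delay_rates = simulate_rates(accepted, delay_conds, 0.0, network=network)
    if noisy:
        delay_rates = add_noise(delay_rates, noise, rng=noise_rng)
    fits = classify_population(delay_rates, delay_conds, accepted,
                               alpha=config.alpha)
    return {
        "populations": pops,
        "units": units,
        "accepted_units": accepted,
        "screen_report": report,
        "screen_conditions": screen_conds,
        "delay_conditions": delay_conds,
        "screen_rates": screen_rates,
        "delay_rates": delay_rates,
        "fits": fits,
    }


def classification_summary(fits: pd.DataFrame) -> dict:
    """Per-node included counts, class counts and percentages."""
    return summarize_distribution(fits)["per_node"]


def multi_seed_percentages(config: ExperimentConfig, seeds: Sequence[int],
                           network: str = "main") -> pd.DataFrame:
    """Seed-averaged class percentages and included counts per node.

    One row per (seed, node) with the node's included count and the
    percentage of included units falling in each class.
    """
    rows = []
    for seed in seeds:
        res = run_delay_classification(config, seed, network=network,
                                       noisy=True)
        for node, stats in classification_summary(res["fits"]).items():
            row = {"seed": seed, "node": node,
                   "n_included": stats["n_included"]}
            row.update({f"pct_{cls}": pct
                        for cls, pct in stats["percentages"].items()})
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# rate-table I/O (analysis-only path)

RATE_COLUMNS = ["unit_id", "node", "u", "v", "gain_sign", "E", "H", "T", "t",
                "rate"]


def rate_frame(units, conditions: ConditionSet, t: float,
               rates: np.ndarray) -> pd.DataFrame:
    """Long-format rate table: one row per unit x condition."""
    rates = np.asarray(rates, dtype=float)
    n_units, n_cond = rates.shape
    frames = []
    for i, unit in enumerate(units):
        frames.append(pd.DataFrame({
            "unit_id": unit.unit_id, "node": unit.node,
            "u": unit.u, "v": np.nan if unit.v is None else unit.v,
            "gain_sign": unit.gain_sign,
            "E": conditions.E, "H": conditions.H, "T": conditions.T,
            "t": t, "rate": rates[i],
        }))
    return pd.concat(frames, ignore_index=True)


def load_rate_table(path) -> dict:
    """Load a unit-by-condition rate table from CSV.

    Validates the documented schema (missing columns raise a ``ValueError``
    naming the column; extra columns are ignored with a warning) and
    reconstructs the units, the condition set, and the (units x conditions)
    rate matrix for the analysis-only path.
    """
    df = pd.read_csv(path)
    for col in RATE_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"rate table is missing column {col!r}")
    extra = [c for c in df.columns if c not in RATE_COLUMNS]
    if extra:
        log.warning("ignoring extra rate-table columns: %s", extra)
    units = []
    for unit_id, sub in df.groupby("unit_id", sort=False):
        first = sub.iloc[0]
        units.append(UnitSpec(
            unit_id=str(unit_id), node=str(first["node"]),
            u=float(first["u"]),
            v=None if pd.isna(first["v"]) else float(first["v"]),
            gain_sign=int(first["gain_sign"])))
    first_unit = df[df["unit_id"] == units[0].unit_id]
    conditions = ConditionSet(first_unit["E"].to_numpy(),
                              first_unit["H"].to_numpy(),
                              first_unit["T"].to_numpy(),
                              np.unique(first_unit["t"]), label=str(path))
    rates = df["rate"].to_numpy().reshape(len(units), len(conditions))
    return {"units": units, "conditions": conditions, "rates": rates,
            "t": float(first_unit["t"].iloc[0])}


def classify_rate_table(path, alpha: float = 0.01) -> pd.DataFrame:
    """Analysis-only path: fit and classify an externally supplied table."""
    table = load_rate_table(path)
    return classify_population(table["rates"], table["conditions"],
                               table["units"], alpha=alpha)


# ---------------------------------------------------------------------------
# named experiments


def _rotation_magnitudes(samples: dict) -> dict:
    """Per-pair axial go->offset rotation and whether it heads to the eye axis."""
    out = {}
    for pair_key, sub in samples.items():
        pair = tuple(pair_key.split("x"))
        go = sub["go"]["halved_angle_deg"]
        off = sub["offset"]["halved_angle_deg"]
        eye_axis = eye_axis_deg(pair)
        out[pair_key] = {
            "go_angle_deg": go,
            "offset_angle_deg": off,
            "rotation_deg": axial_distance_deg(go, off),
            "toward_eye_axis": (axial_distance_deg(off, eye_axis)
                                < axial_distance_deg(go, eye_axis)),
        }
    return out


def _gradient_experiment(config: ExperimentConfig, seed: int, network: str,
                         hybrid: bool) -> dict:
    """Screen on delay-period responses, then run the gradient time-course.

    Networks whose replacement nodes have no stated pre-target response are
    analyzed over the delay and movement epochs only (their contrast with
    the main model is the go-to-offset rotation).
    """
    pops = build_network_population(network, N=config.N, A=config.A,
                                    sigma=config.sigma,
                                    sampling=config.sampling, seed=seed)
    units = _all_units(pops)
    screen_conds = screening_task_conditions(config.sigma)
    screen_rates = simulate_rates(units, screen_conds, 0.0, network=network)
    report = screen_population(screen_rates, screen_conds.T, units,
                               task_range=(-2 * config.sigma, 2 * config.sigma),
                               sve_threshold=config.sve_threshold)
    acc_ids = set(report.loc[report["accepted"], "unit_id"])
    accepted = [u for u in units if u.unit_id in acc_ids]
    if hybrid:
        node_names = NETWORKS[network].node_names
        weights = dict(zip(node_names, (0.25, 0.5, 0.25)))
        series_units = accepted
    else:
        weights = None
        hand_node = NETWORKS[network].node_names[1]
        series_units = [u for u in accepted if u.node == hand_node]
    times = gradient_time_grid()
    epochs = dict(EPOCHS)
    has_pretarget = all(nd.pretarget is not None
                        for nd in NETWORKS[network].nodes)
    if not has_pretarget:
        times = times[times >= -1.0]
        epochs.pop("pre_target")
    series = gradient_series(series_units, times=times, weights=weights,
                             network=network)
    samples = epoch_samples(series, epochs=epochs)
    return {
        "screen_report": report,
        "series": series,
        "epoch_samples": samples,
        "rotations": _rotation_magnitudes(samples),
        "weights": weights,
    }


def run_experiment(name: str, config: Optional[ExperimentConfig] = None,
                   seed: int = 0, out_dir=None) -> dict:
    """Run one named experiment; optionally write its artifact bundle.

    The result dict always carries a JSON-serializable ``summary``;
    with ``out_dir`` the manifest, rate tables, reports and summary are
    written as CSV/JSON files.
    """
    if name not in EXPERIMENT_NAMES:
        raise ValueError(f"unknown experiment {name!r}; "
                         f"choose from {EXPERIMENT_NAMES}")
    config = config or ExperimentConfig()
    result: dict = {"name": name, "seed": int(seed),
                    "config": config.to_dict()}

    if name in ("fig4_noiseless", "fig4_noisy", "fig8_variantA",
                "fig8_variantB"):
        network = {"fig4_noiseless": "main", "fig4_noisy": "main",
                   "fig8_variantA": "rising_phi",
                   "fig8_variantB": "dual_sigmoid"}[name]
        noisy = name != "fig4_noiseless"
        res = run_delay_classification(config, seed, network=network,
                                       noisy=noisy)
        dist = summarize_distribution(res["fits"])
        result.update(res)
        result["summary"] = {
            "network": network, "noisy": noisy,
            "n_screened": int(len(res["accepted_units"])),
            "per_node": dist["per_node"],
            "w_hist_edges": dist["w_hist_edges"],
            "w_hist_counts": dist["w_hist_counts"],
        }
    elif name == "fig6":
        pops = build_network_population("main", N=config.N, A=config.A,
                                        sigma=config.sigma,
                                        sampling=config.sampling, seed=seed)
        trajectory, trends = evolve_classification(
            _all_units(pops), sigma=config.sigma,
            time_points=config.movement_times, eh_pairs=config.eh_pairs,
            noise=NoiseModel(config.noise_sd, seed), rng=_rng(seed, 2),
            sve_threshold=config.sve_threshold, alpha=config.alpha)
        result["trajectory"] = trajectory
        result["trends"] = trends
        result["summary"] = {
            "trends": trends,
            "trajectory": trajectory.to_dict(orient="records"),
        }
    elif name in ("fig7_pure", "fig7_hybrid"):
        res = _gradient_experiment(config, seed, "main",
                                   hybrid=(name == "fig7_hybrid"))
        result.update(res)
        result["summary"] = {
            "network": "main", "hybrid": name == "fig7_hybrid",
            "epoch_samples": res["epoch_samples"],
            "rotations": res["rotations"],
        }
    elif name == "fig8_variantE":
        variant = _gradient_experiment(config, seed, "static_hand",
                                       hybrid=True)
        main = _gradient_experiment(config, seed, "main", hybrid=True)
        result.update(variant)
        result["main_rotations"] = main["rotations"]
        result["summary"] = {
            "network": "static_hand", "hybrid": True,
            "epoch_samples": variant["epoch_samples"],
            "rotations": variant["rotations"],
            "main_rotations": main["rotations"],
        }

    if out_dir is not None:
        _write_bundle(result, Path(out_dir))
    return result


def _write_bundle(result: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    name = result["name"]
    if "units" in result:
        population_manifest(result["units"]).to_csv(
            out_dir / f"{name}_manifest.csv", index=False)
    if "screen_report" in result:
        result["screen_report"].to_csv(
            out_dir / f"{name}_screening.csv", index=False)
    if "fits" in result:
        result["fits"].to_csv(out_dir / f"{name}_fits.csv", index=False)
    if "delay_rates" in result:
        rate_frame(result["accepted_units"], result["delay_conditions"], 0.0,
                   result["delay_rates"]).to_csv(
            out_dir / f"{name}_rates.csv", index=False)
    if "trajectory" in result:
        result["trajectory"].to_csv(
            out_dir / f"{name}_trajectory.csv", index=False)
    if "series" in result:
        result["series"].to_csv(out_dir / f"{name}_gradients.csv",
                                index=False)
    summary = {"name": name, "seed": result["seed"],
               "config": result["config"], "results": result["summary"]}
    validate_summary(summary)
    (out_dir / f"{name}_summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, allow_nan=True))


def _schema() -> dict:
    schema_path = Path(__file__).parent / "schemas" / "summary.schema.json"
    return json.loads(schema_path.read_text())


def validate_summary(summary: dict) -> None:
    """Check a summary object against the published schema (required keys
    and their JSON types)."""
    schema = _schema()
    types = {"object": dict, "string": str, "integer": int}
    for key in schema["required"]:
        if key not in summary:
            raise ValueError(f"summary missing required key {key!r}")
        expected = schema["properties"][key]["type"]
        if not isinstance(summary[key], types[expected]):
            raise ValueError(f"summary key {key!r} must be {expected}")
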