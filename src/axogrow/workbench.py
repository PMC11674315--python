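"""Run orchestration: synthetic fitting targets, manifests, and the pipeline.

``generate_synthetic_target`` runs the generative model itself to produce a
connectome usable as a fitting target, labelled with its true parameters so
parameter-recovery experiments need no external data.  ``run_pipeline``
executes simulate -> build -> analyze -> topology (-> fit) from a structured
YAML/JSON configuration, writing delimited-text artifacts and JSON manifests
that make every output reproducible from its recorded seed and parameters.
"""

from __future__ import annotations

import hashlib
import json
import math
import time
from dataclasses import asdict, dataclass
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigError
from .fitting import FitConfig, fit
from .geometry import perturb_nodes, place_nodes
from .growth import GrowthConfig, SimulationResult, simulate_axons, simulate_random_walk_null
from .network import WeightedNetwork, build_network, normalize_weights, write_adjacency
from .stats import fit_weight_distribution, scalefree_gof, weight_distance_correlation
from .topology import prepare_for_topology, topology_report


def _package_version() -> str:
    try:
        return version("axogrow")
    except PackageNotFoundError:
        return "unknown"


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Everything needed to reproduce a run bit-for-bit with the same code."""

    command: str
    parameters: dict
    seed: int
    version: str
    outputs: dict  # filename -> sha256 digest
    wall_time_s: float

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str))


def default_layout(
    radius: float = 30.0, n_nodes: int = 84, rho: float = 1.0, seed: int = 0
):
    """Convenience builder: place then perturb nodes from a layout substream."""
    base = place_nodes(radius, n_nodes)
    return perturb_nodes(base, rho, np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(100,))))


def generate_synthetic_target(
    beta: float,
    ls: float,
    n_nodes: int = 84,
    n_axons: int = 200_000,
    seed: int = 0,
    radius: float = 30.0,
    rho: float = 1.0,
    path: str | Path | None = None,
) -> WeightedNetwork:
    """Simulate a network at known (beta, L_s) for use as a fitting target.

    When ``path`` is given the adjacency is written as delimited text and a
    sidecar ``<path>.json`` records the true parameters for recovery tests.
    """
    layout = default_layout(radius, n_nodes, rho, seed)
    cfg = GrowthConfig(beta=beta, step_length=ls, n_axons=n_axons, seed=seed)
    net = build_network(simulate_axons(layout, cfg))
    if path is not None:
        path = Path(path)
        write_adjacency(net, path)
        Path(str(path) + ".json").write_text(
            json.dumps(
                {
                    "true_beta": beta,
                    "true_ls": ls,
                    "n_nodes": n_nodes,
                    "n_axons": n_axons,
                    "radius": radius,
                    "rho": rho,
                    "seed": seed,
                    "density": net.density,
                },
                indent=2,
            )
        )
    return net


def export_trajectories(
    result: SimulationResult, path: str | Path, max_axons: int = 200
) -> None:
    """Write up to ``max_axons`` re-propagated trajectories as a delimited
    table (axon_id, step_index, x, y, status) for visualization."""
    import pandas as pd

    rows = []
    for a in range(min(max_axons, result.n_axons)):
        traj = result.trajectory(a)
        for s, (x, y) in enumerate(traj.positions):
            rows.append({"axon_id": a, "step_index": s, "x": x, "y": y, "status": traj.status})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

_SIM_KEYS = {
    "R": 30.0, "N_n": 84, "rho": 1.0, "N_a": 200_000, "theta_deg": 15.0,
    "beta": 1.0, "L_s": 1.0, "S_max": None, "null_model": False,
}
_ANALYZE_KEYS = {"scalefree": False, "n_boot": 1000, "weights": True, "distance_corr": True,
                 "scalefree_density": 0.05}
_TOPOLOGY_KEYS = {"density": 0.10, "total": 2e5, "n_nulls": 20}
_FIT_KEYS = {
    "target": None, "beta_range": [0.99, 1.01], "ls_range": [0.1, 2.1],
    "grid": [5, 5], "n_landscapes": 5, "density": 0.10, "total": 2e5,
    "sds": [1.0, 1.0, 1.0], "n_axons": 20_000, "n_nulls": 10,
}
_TOP_KEYS = {"seed", "out_dir", "stages", "simulate", "analyze", "topology", "fit"}


def _validated(section: str, user: dict | None, defaults: dict) -> dict:
    user = dict(user or {})
    for key in user:
        if key not in defaults:
            raise ConfigError(f"unknown config key '{section}.{key}'")
    merged = dict(defaults)
    merged.update(user)
    return merged


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None) -> dict:
    """Execute the staged pipeline described by a YAML/JSON config.

    Stages (``stages`` list): ``simulate`` (always implied), ``analyze``,
    ``topology``, ``fit``.  Unknown keys are rejected with the offending field
    path.  Returns a dict of produced artifacts; files land in ``out_dir``.
    """
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    for key in config:
        if key not in _TOP_KEYS:
            raise ConfigError(f"unknown config key '{key}'")
    stages = config.get("stages", ["simulate"])
    known_stages = {"simulate", "analyze", "topology", "fit"}
    for s in stages:
        if s not in known_stages:
            raise ConfigError(f"unknown stage '{s}' in 'stages'")
    seed = int(config.get("seed", 0))
    out = Path(out_dir or config.get("out_dir", "."))
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    artifacts: dict = {}
    outputs: dict[str, str] = {}

    sim = _validated("simulate", config.get("simulate"), _SIM_KEYS)
    layout = default_layout(sim["R"], int(sim["N_n"]), sim["rho"], seed)
    cfg = GrowthConfig(
        beta=float(sim["beta"]),
        step_length=float(sim["L_s"]),
        theta=math.radians(float(sim["theta_deg"])),
        s_max=sim["S_max"],
        n_axons=int(sim["N_a"]),
        seed=seed,
    )
    runner = simulate_random_walk_null if sim["null_model"] else simulate_axons
    result = runner(layout, cfg)
    net = build_network(result)
    layout.to_json(out / "layout.json")
    write_adjacency(net, out / "network.tsv")
    outputs["layout.json"] = _sha256(out / "layout.json")
    outputs["network.tsv"] = _sha256(out / "network.tsv")
    artifacts["network"] = net
    artifacts["log"] = {
        "n_axons": result.n_axons,
        "n_successful": result.n_successful,
        "n_unsuccessful": result.n_unsuccessful,
        "self_connections": net.meta["self_connections"],
        "density": net.density,
    }

    if "analyze" in stages:
        an = _validated("analyze", config.get("analyze"), _ANALYZE_KEYS)
        report: dict = {}
        if an["weights"]:
            fitrep = fit_weight_distribution(normalize_weights(net))
            report["weight_distribution"] = {
                "best_family": fitrep.best_family,
                "ks_stats": fitrep.ks_stats(),
            }
        if an["distance_corr"]:
            report["weight_distance_r"] = weight_distance_correlation(net)
        if an["scalefree"]:
            from .network import threshold_to_density

            thr = threshold_to_density(net, an["scalefree_density"], binarize=True)
            sf = scalefree_gof(thr.degree, n_boot=int(an["n_boot"]), seed=seed)
            report["scalefree"] = {
                "k_min": sf.k_min, "alpha": sf.alpha, "gof_p": sf.gof_p,
                "plausible": sf.plausible,
            }
        (out / "analysis.json").write_text(json.dumps(report, indent=2))
        outputs["analysis.json"] = _sha256(out / "analysis.json")
        artifacts["analysis"] = report

    if "topology" in stages:
        tp = _validated("topology", config.get("topology"), _TOPOLOGY_KEYS)
        prepped = prepare_for_topology(net, tp["density"], tp["total"])
        rep = topology_report(prepped, n_nulls=int(tp["n_nulls"]), seed=seed)
        top = {
            "cc": rep.cc, "cpl": rep.cpl, "q": rep.q, "sw": rep.sw,
            "cc_normalized": rep.cc_normalized,
            "cpl_normalized": rep.cpl_normalized,
            "q_normalized": rep.q_normalized,
            "disconnected": rep.disconnected,
        }
        (out / "topology.json").write_text(json.dumps(top, indent=2))
        outputs["topology.json"] = _sha256(out / "topology.json")
        artifacts["topology"] = top

    if "fit" in stages:
        ft = _validated("fit", config.get("fit"), _FIT_KEYS)
        from .network import read_network

        target = read_network(ft["target"]) if ft["target"] else net
        fit_cfg = FitConfig(
            beta_range=tuple(ft["beta_range"]),
            ls_range=tuple(ft["ls_range"]),
            grid_size=tuple(int(g) for g in ft["grid"]),
            n_landscapes=int(ft["n_landscapes"]),
            analysis_density=float(ft["density"]),
            total_connectivity=float(ft["total"]),
            metric_sds=tuple(ft["sds"]),
            radius=sim["R"],
            n_nodes=int(sim["N_n"]),
            rho=sim["rho"],
            n_axons=int(ft["n_axons"]),
            n_nulls=int(ft["n_nulls"]),
            seed=seed,
        )
        res = fit(target, fit_cfg)
        fit_out = {
            "best_fit_beta": res.best_fit[0],
            "best_fit_ls": res.best_fit[1],
            "per_landscape_optima": res.per_landscape_optima.tolist(),
            "target_metrics": list(res.target_metrics),
        }
        (out / "fit.json").write_text(json.dumps(fit_out, indent=2))
        outputs["fit.json"] = _sha256(out / "fit.json")
        artifacts["fit"] = fit_out

    manifest = RunManifest(
        command="run_pipeline",
        parameters={k: v for k, v in config.items() if k != "seed"},
        seed=seed,
        version=_package_version(),
        outputs=outputs,
        wall_time_s=time.time() - t0,
    )
    manifest.write(out / "manifest.json")
    artifacts["manifest"] = manifest
    return artifacts
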