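"""Experiment drivers: one configuration = one reproducible output directory.

Each run writes a manifest (``manifest.json``) listing every produced file,
a parameter/seed snapshot, and CSV/JSON results: an ODE trajectory and
steady state, and/or per-replicate SSA trajectories with their average and
extinction summary. Re-running the same configuration with the same base
seed reproduces byte-identical CSVs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .model import Model
from .mr import MRParams
from .ode import STEADY_STATE_TOL, find_steady_state, scale_model, simulate_ode
from .presets import get_preset
from .ssa import average_trajectories, extinction_probability, ssa_simulate

log = logging.getLogger("mrpepa")


@dataclass
class ExperimentConfig:
    preset: str | None = None
    params: MRParams | None = None
    model: Model | None = None
    engine: str = "ode"  # ode | ssa | both
    t_end: float = 1000.0
    n_points: int = 1000
    n_reps: int = 1
    base_seed: int = 1
    out_dir: str | Path = "runs"
    scale: float | None = None
    steady_state_tol: float = STEADY_STATE_TOL

    def __post_init__(self):
        if self.engine not in ("ode", "ssa", "both"):
            raise ValueError(f"engine must be ode, ssa or both, not {self.engine!r}")
        if self.engine in ("ssa", "both") and self.n_reps < 1:
            raise ValueError("n_reps must be >= 1 when the SSA engine is requested")
        if sum(x is not None for x in (self.preset, self.params, self.model)) != 1:
            raise ValueError("exactly one of preset, params or model must be given")

    @classmethod
    def from_file(cls, path: str | Path) -> "ExperimentConfig":
        """Load a configuration from a JSON or YAML mirror of this dataclass."""
        text = Path(path).read_text(encoding="utf-8")
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            payload = yaml.safe_load(text)
        else:
            payload = json.loads(text)
        if "params" in payload and payload["params"] is not None:
            payload["params"] = MRParams(**payload["params"])
        return cls(**payload)

    def build_model(self) -> Model:
        from .mr import build_mr_model

        if self.model is not None:
            model = self.model
        elif self.params is not None:
            model = build_mr_model(self.params)
        else:
            model = get_preset(self.preset).build()
        if self.scale is not None and self.scale != 1:
            model = scale_model(model, self.scale)
        return model


def run_experiment(config: ExperimentConfig) -> dict:
    """Execute a configuration and return the manifest (also written to disk)."""
    model = config.build_model()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pts = max(config.n_points, 1)  # n_points 0 -> record initial and final only
    grid = np.linspace(0.0, config.t_end, pts + 1)

    manifest: dict = {
        "config": {
            "preset": config.preset,
            "engine": config.engine,
            "t_end": config.t_end,
            "n_points": config.n_points,
            "n_reps": config.n_reps,
            "base_seed": config.base_seed,
            "scale": config.scale,
        },
        "parameters": dict(model.parameters),
        "initial_counts": dict(model.initial_counts),
        "files": [],
    }

    def emit(name: str) -> Path:
        manifest["files"].append(name)
        return out / name

    if config.engine in ("ode", "both"):
        log.info("ODE integration to t = %g", config.t_end)
        traj = simulate_ode(model, config.t_end, n_points=pts)
        traj.to_csv(emit("ode.csv"))
        steady = find_steady_state(
            model, t_max=config.t_end, abs_tol=config.steady_state_tol
        )
        steady.to_json(emit("steady_state.json"))
        manifest["steady_state"] = steady.rounded_counts
        manifest["steady_state_converged"] = steady.converged

    if config.engine in ("ssa", "both"):
        trajectories = []
        reports = []
        for r in range(config.n_reps):
            seed = config.base_seed + r
            log.info("SSA replicate %d (seed %d)", r, seed)
            traj, report = ssa_simulate(
                model, config.t_end, seed, n_points=pts
            )
            traj.to_csv(emit(f"ssa_run_{r:03d}.csv"))
            trajectories.append(traj)
            reports.append(report)
        if len(trajectories) > 1:
            average_trajectories(trajectories, grid).to_csv(emit("ssa_mean.csv"))
        n_extinct = sum(r.extinct for r in reports)
        manifest["extinction"] = {
            "n_reps": config.n_reps,
            "n_extinct": n_extinct,
            "fraction": n_extinct / config.n_reps,
            "t_extinct": [r.t_extinct for r in reports],
            "seeds": [config.base_seed + r for r in range(config.n_reps)],
        }
        with open(emit("extinction.json"), "w", encoding="utf-8") as fh:
            json.dump(manifest["extinction"], fh, indent=2)

    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
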