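"""Time-series containers shared by both engines."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd


@dataclass
class Trajectory:
    """A time grid plus one quantity series per species.

    ``values`` has shape (len(times), len(species)); ``meta`` records the
    engine (``ode`` or ``ssa``), the seed for stochastic runs, and a
    parameter snapshot.
    """

    times: np.ndarray
    species: tuple[str, ...]
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.times), len(self.species)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.times)} times x {len(self.species)} species"
            )
        if np.any(np.diff(self.times) < 0):
            raise ValueError("times must be non-decreasing")

    def series(self, name: str) -> np.ndarray:
        return self.values[:, self.species.index(name)]

    def final_state(self) -> dict[str, float]:
        return dict(zip(self.species, self.values[-1]))

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.values, columns=list(self.species))
        frame.insert(0, "time", self.times)
        return frame

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, meta: Mapping | None = None) -> "Trajectory":
        frame = pd.read_csv(path)
        species = tuple(c for c in frame.columns if c != "time")
        return cls(
            frame["time"].to_numpy(),
            species,
            frame[list(species)].to_numpy(),
            dict(meta or {}),
        )

    def to_json(self, path=None) -> str:
        payload = {
            "times": self.times.tolist(),
            "series": {s: self.values[:, i].tolist() for i, s in enumerate(self.species)},
            "meta": self.meta,
        }
        text = json.dumps(payload)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, text: str) -> "Trajectory":
        payload = json.loads(text)
        species = tuple(payload["series"])
        values = np.column_stack([payload["series"][s] for s in species])
        return cls(np.asarray(payload["times"]), species, values, payload.get("meta", {}))

    def resample(self, grid: np.ndarray) -> "Trajectory":
        """Sample onto ``grid`` by last-value-carried-forward.

        Grid points before the first recorded time take the first value.
        """
        grid = np.asarray(grid, dtype=float)
        idx = np.searchsorted(self.times, grid, side="right") - 1
        idx = np.clip(idx, 0, len(self.times) - 1)
        return Trajectory(grid, self.species, self.values[idx], dict(self.meta))


@dataclass
class SteadyStateResult:
    """Outcome of steady-state detection on the deterministic semantics."""

    counts: dict[str, float]
    residual_norm: float
    converged: bool
    t_reached: float

    @property
    def rounded_counts(self) -> dict[str, int]:
        return {s: int(round(v)) for s, v in self.counts.items()}

    def to_json(self, path=None) -> str:
        payload = {
            "counts": self.counts,
            "rounded_counts": self.rounded_counts,
            "residual_norm": self.residual_norm,
            "converged": self.converged,
            "t_reached": self.t_reached,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text
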