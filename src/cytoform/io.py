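"""Configuration files, geometry export and run manifests.

All on-disk formats are plain text: YAML or JSON for configuration,
JSON for networks and states, CSV for plot-ready tables.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .config import EnsembleSpec, GenerationConfig, MaterialTable, SolverSettings
from .fecore import SystemState
from .model import NetworkModel


class RunConfig(BaseModel):
    """Top-level configuration file: generation, materials, solver, ensemble."""

    model_config = ConfigDict(extra="forbid")

    generation: GenerationConfig = Field(default_factory=GenerationConfig)
    materials: MaterialTable = Field(default_factory=MaterialTable)
    solver: SolverSettings = Field(default_factory=SolverSettings)
    n_samples: int = Field(default=20, ge=2)
    master_seed: int = Field(default=0, ge=0)
    sweep_variable: Optional[str] = None
    sweep_values: list[float] = Field(default_factory=list)
    measurement_strain: float = Field(default=0.01, gt=0)

    def ensemble_spec(self) -> EnsembleSpec:
        return EnsembleSpec(
            base_config=self.generation,
            materials=self.materials,
            solver=self.solver,
            n_samples=self.n_samples,
            master_seed=self.master_seed,
            sweep_variable=self.sweep_variable,
            sweep_values=self.sweep_values,
            measurement_strain=self.measurement_strain,
        )


def read_config(path: str | Path) -> RunConfig:
    """Read and schema-validate a YAML/JSON configuration file.

    Unknown keys are rejected with the offending key path in the error.
    An empty file yields all defaults.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text) if text.strip() else {}
    return RunConfig(**(data or {}))


def write_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=False))


def state_to_dict(state: SystemState) -> dict:
    return {
        "u": state.u.tolist(),
        "beam_forces": state.beam_forces.tolist(),
        "cable_tensions": state.cable_tensions.tolist(),
        "residual_norm": state.residual_norm,
        "converged": state.converged,
        "increments": state.increments,
        "iterations": list(state.iterations),
    }


def state_from_dict(d: dict) -> SystemState:
    return SystemState(
        u=np.asarray(d["u"], float),
        beam_forces=np.asarray(d["beam_forces"], float).reshape(-1, 4),
        cable_tensions=np.asarray(d["cable_tensions"], float),
        residual_norm=d["residual_norm"],
        converged=d["converged"],
        increments=d["increments"],
        iterations=d["iterations"],
    )


def export_geometry(
    network: NetworkModel,
    out_dir: str | Path,
    state: Optional[SystemState] = None,
    prefix: str = "network",
) -> dict[str, Path]:
    """Write node/element CSV tables and a plot-ready segment table.

    The segment table has columns x1,y1,x2,y2,kind with kind in
    {beam, cable} so filaments and cross-linkers can be styled apart.
    When ``state`` is given, coordinates are the deformed ones and
    displacement/force columns are appended to the node/element tables.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    coords = network.nodes if state is None else state.coordinates(network.nodes)

    nodes = pd.DataFrame(
        {"id": np.arange(network.n_nodes),
         "x": coords[:, 0] if network.n_nodes else [],
         "y": coords[:, 1] if network.n_nodes else [],
         "filament": network.node_filament if network.n_nodes else []}
    )
    if state is not None and network.n_nodes:
        nodes["ux"] = state.u[0::3]
        nodes["uy"] = state.u[1::3]
        nodes["rotation"] = state.u[2::3]

    beams = pd.DataFrame(
        {"id": np.arange(network.n_beams),
         "node_a": network.beams[:, 0] if network.n_beams else [],
         "node_b": network.beams[:, 1] if network.n_beams else [],
         "filament": network.beams[:, 2] if network.n_beams else []}
    )
    if state is not None and network.n_beams:
        beams["N"] = state.beam_forces[:, 0]
        beams["M_a"] = state.beam_forces[:, 1]
        beams["M_b"] = state.beam_forces[:, 2]
        beams["shear"] = state.beam_forces[:, 3]

    cables = pd.DataFrame(
        {"id": np.arange(network.n_cables),
         "node_a": network.cables[:, 0] if network.n_cables else [],
         "node_b": network.cables[:, 1] if network.n_cables else []}
    )
    if state is not None and network.n_cables:
        cables["tension"] = state.cable_tensions

    seg_rows = []
    for tbl, kind in ((beams, "beam"), (cables, "cable")):
        for _, row in tbl.iterrows():
            a, b = int(row["node_a"]), int(row["node_b"])
            seg_rows.append(
                (coords[a, 0], coords[a, 1], coords[b, 0], coords[b, 1], kind)
            )
    segments = pd.DataFrame(seg_rows, columns=["x1", "y1", "x2", "y2", "kind"])

    paths = {}
    for name, df in (("nodes", nodes), ("beams", beams),
                     ("cables", cables), ("segments", segments)):
        p = out / f"{prefix}_{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p
    return paths


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class RunManifest:
    """Record of one pipeline run, sufficient to reproduce it."""

    config: dict
    master_seed: int
    version: str = __version__
    stages: list[dict] = field(default_factory=list)

    def add_stage(
        self,
        name: str,
        inputs: list[str | Path],
        outputs: list[str | Path],
        wall_seconds: float,
    ) -> None:
        self.stages.append(
            {
                "stage": name,
                "inputs": {str(p): file_digest(p) for p in inputs},
                "outputs": {str(p): file_digest(p) for p in outputs},
                "wall_seconds": wall_seconds,
                "timestamp": time.time(),
            }
        )

    def write(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "version": self.version,
                    "master_seed": self.master_seed,
                    "config": self.config,
                    "stages": self.stages,
                },
                indent=2,
            )
        )
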