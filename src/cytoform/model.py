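"""In-memory containers for the cross-linked filament network.

A :class:`NetworkModel` is the object handed between every stage of the
pipeline: node coordinates, beam elements (filament segments), cable
elements (cross-linkers), the material table and the generation record.
Serialization is plain JSON so a network is inspectable with any editor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .config import GenerationConfig, MaterialTable


@dataclass
class Filament:
    """A straight actin filament before segmentation.

    ``angle`` is in radians in [0, 2π); ``node_ids`` is filled in by
    segmentation, ordered from one endpoint to the other.
    """

    id: int
    centroid: tuple[float, float]
    angle: float
    length: float
    node_ids: list[int] = field(default_factory=list)

    @property
    def endpoints(self) -> tuple[tuple[float, float], tuple[float, float]]:
        cx, cy = self.centroid
        hx = 0.5 * self.length * np.cos(self.angle)
        hy = 0.5 * self.length * np.sin(self.angle)
        return (cx - hx, cy - hy), (cx + hx, cy + hy)


@dataclass
class NetworkModel:
    """Node-element description of one cross-linked network realization.

    Arrays:
      nodes          (n, 2) float — x, y in μm
      node_filament  (n,)   int   — owning filament id per node
      beams          (nb, 3) int  — node_a, node_b, filament_id
      cables         (nc, 2) int  — node_a, node_b (always distinct filaments)
    """

    nodes: np.ndarray
    node_filament: np.ndarray
    beams: np.ndarray
    cables: np.ndarray
    materials: MaterialTable
    config: GenerationConfig
    achieved_relative_density: float
    filaments: list[Filament] = field(default_factory=list)
    n_components: int = 1
    metadata: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_beams(self) -> int:
        return len(self.beams)

    @property
    def n_cables(self) -> int:
        return len(self.cables)

    def beam_lengths(self) -> np.ndarray:
        d = self.nodes[self.beams[:, 1]] - self.nodes[self.beams[:, 0]]
        return np.hypot(d[:, 0], d[:, 1])

    def cable_lengths(self) -> np.ndarray:
        if self.n_cables == 0:
            return np.zeros(0)
        d = self.nodes[self.cables[:, 1]] - self.nodes[self.cables[:, 0]]
        return np.hypot(d[:, 0], d[:, 1])

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "nodes": [
                [int(i), float(x), float(y)]
                for i, (x, y) in enumerate(np.asarray(self.nodes))
            ],
            "node_filament": [int(f) for f in self.node_filament],
            "beams": [
                [int(i), int(a), int(b), int(f)]
                for i, (a, b, f) in enumerate(np.asarray(self.beams))
            ],
            "cables": [
                [int(i), int(a), int(b)]
                for i, (a, b) in enumerate(np.asarray(self.cables))
            ],
            "materials": self.materials.model_dump(),
            "config": self.config.model_dump(),
            "achieved_relative_density": float(self.achieved_relative_density),
            "n_components": int(self.n_components),
            "metadata": self.metadata,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkModel":
        nodes = np.array([[x, y] for _, x, y in d["nodes"]], dtype=float).reshape(-1, 2)
        beams = np.array(
            [[a, b, f] for _, a, b, f in d["beams"]], dtype=np.int64
        ).reshape(-1, 3)
        cables = np.array(
            [[a, b] for _, a, b in d["cables"]], dtype=np.int64
        ).reshape(-1, 2)
        return cls(
            nodes=nodes,
            node_filament=np.asarray(d["node_filament"], dtype=np.int64),
            beams=beams,
            cables=cables,
            materials=MaterialTable(**d["materials"]),
            config=GenerationConfig(**d["config"]),
            achieved_relative_density=d["achieved_relative_density"],
            n_components=d.get("n_components", 1),
            metadata=d.get("metadata", {}),
        )

    def to_json(self, path: str | Path, state: Optional[dict] = None) -> None:
        d = self.to_dict()
        if state is not None:
            d["state"] = state
        Path(path).write_text(json.dumps(d))

    @classmethod
    def from_json(cls, path: str | Path) -> "NetworkModel":
        return cls.from_dict(json.loads(Path(path).read_text()))
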