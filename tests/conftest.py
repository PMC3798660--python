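import numpy as np
import pytest

from cytoform.config import GenerationConfig, MaterialTable, SolverSettings
from cytoform.model import NetworkModel


class ScriptedRNG:
    """Deterministic stand-in for a Generator: replays scripted draws."""

    def __init__(self, normals=(), uniforms=(), randoms=()):
        self._normals = list(normals)
        self._uniforms = list(uniforms)
        self._randoms = list(randoms)

    def normal(self, loc=0.0, scale=1.0):
        return self._normals.pop(0)

    def uniform(self, low=0.0, high=1.0):
        return self._uniforms.pop(0)

    def random(self, n=None):
        if n is None:
            return self._randoms.pop(0)
        out = np.asarray(self._randoms[:n], dtype=float)
        del self._randoms[:n]
        return out


@pytest.fixture
def scripted_rng_factory():
    return ScriptedRNG


@pytest.fixture
def default_config():
    return GenerationConfig()


@pytest.fixture
def materials():
    return MaterialTable()


@pytest.fixture
def fast_settings():
    return SolverSettings(n_increments=2, regularization=0.0)


def beam_chain(n_segments, length, materials=None, y=0.0):
    """A straight horizontal filament discretized into equal beam elements."""
    xs = np.linspace(0.0, length, n_segments + 1)
    nodes = np.column_stack([xs, np.full(n_segments + 1, y)])
    beams = np.array([[i, i + 1, 0] for i in range(n_segments)], dtype=np.int64)
    return NetworkModel(
        nodes=nodes,
        node_filament=np.zeros(n_segments + 1, dtype=np.int64),
        beams=beams,
        cables=np.zeros((0, 2), dtype=np.int64),
        materials=materials or MaterialTable(),
        config=GenerationConfig(),
        achieved_relative_density=0.0,
    )


@pytest.fixture
def beam_chain_factory():
    return beam_chain


@pytest.fixture
def tiny_network_config():
    """Small but fully exercised generation problem (sub-second)."""
    return GenerationConfig(
        domain_width=4.0,
        domain_height=4.0,
        filament_length_mean=1.5,
        filament_length_std=0.3,
        target_relative_density=0.0008,
        seed=42,
    )
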