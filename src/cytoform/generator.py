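"""Random generation of cross-linked 2D filament networks.

The generator reproduces the Mikado-style construction used for cortical
actin: filaments are straight rods with Gaussian lengths placed uniformly
at random (and translated back inside the domain when they stick out),
divided into segments whose ends are cross-linker binding sites, and any
two binding sites on *distinct* filaments closer than the maximum
cross-linker length are joined by a cable element (optionally thinned to
a random fraction of candidates).
"""

from __future__ import annotations

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .config import GenerationConfig, MaterialTable
from .model import Filament, NetworkModel

_MAX_REJECTION_TRIES = 10_000
_MAX_PLACEMENT_ITER = 10_000_000


class GenerationError(RuntimeError):
    """Pathological configuration made a bounded sampling loop give up."""


def truncated_normal(
    rng, mean: float, std: float, lower: float = 0.0, upper: float = np.inf
) -> float:
    """One draw from Normal(mean, std) by rejection outside (lower, upper).

    Non-positive draws are thrown out and redrawn; an upper bound is used
    for filament lengths, which must fit inside the domain.
    """
    for _ in range(_MAX_REJECTION_TRIES):
        x = rng.normal(mean, std)
        if lower < x < upper:
            return float(x)
    raise GenerationError(
        f"rejection sampling from N({mean}, {std}) on ({lower}, {upper}) "
        f"failed after {_MAX_REJECTION_TRIES} tries"
    )


def _translate_into_domain(lo: float, hi: float, width: float) -> float:
    """Minimal shift bringing the interval [lo, hi] inside [0, width]."""
    if lo < 0.0:
        return -lo
    if hi > width:
        return width - hi
    return 0.0


def sample_filament(rng, cfg: GenerationConfig, fid: int = 0) -> Filament:
    """Sample one filament: truncated-Gaussian length, uniform centroid and angle.

    If an endpoint falls outside the domain the whole filament is rigidly
    translated by the minimal axis-aligned shift that brings both
    endpoints inside; angle and length are untouched.
    """
    length = truncated_normal(
        rng,
        cfg.filament_length_mean,
        cfg.filament_length_std,
        upper=cfg.max_filament_length,
    )
    cx = rng.uniform(0.0, cfg.domain_width)
    cy = rng.uniform(0.0, cfg.domain_height)
    angle = rng.uniform(0.0, 2.0 * np.pi)

    hx = 0.5 * length * np.cos(angle)
    hy = 0.5 * length * np.sin(angle)
    xs = sorted((cx - hx, cx + hx))
    ys = sorted((cy - hy, cy + hy))
    dx = _translate_into_domain(xs[0], xs[1], cfg.domain_width)
    dy = _translate_into_domain(ys[0], ys[1], cfg.domain_height)
    return Filament(
        id=fid, centroid=(cx + dx, cy + dy), angle=float(angle), length=length
    )


def relative_density(filaments: list[Filament], cfg: GenerationConfig) -> float:
    """Filament volume fraction: Σ (π d²/4 · Lᵢ) over the domain volume."""
    area = np.pi * cfg.filament_diameter**2 / 4.0
    total = sum(f.length for f in filaments)
    return area * total / cfg.domain_volume


def generate_filaments(cfg: GenerationConfig, rng) -> list[Filament]:
    """Place filaments sequentially until the target volume fraction is reached.

    The filament that crosses the threshold is kept, so the achieved
    density overshoots the target by at most one filament's contribution.
    """
    section = np.pi * cfg.filament_diameter**2 / 4.0
    target_volume = cfg.target_relative_density * cfg.domain_volume
    filaments: list[Filament] = []
    placed_volume = 0.0
    for i in range(_MAX_PLACEMENT_ITER):
        if placed_volume >= target_volume:
            return filaments
        fil = sample_filament(rng, cfg, fid=i)
        filaments.append(fil)
        placed_volume += section * fil.length
    raise GenerationError("filament placement did not reach target density")


def _segment_boundaries(length: float, cfg: GenerationConfig, rng) -> np.ndarray:
    """Interior + end boundaries (including 0 and length) of one filament.

    Segment lengths are truncated-Gaussian draws; drawing stops once the
    remainder is no longer than the mean segment length, and a final
    remainder shorter than half the mean is merged into the previous
    segment to avoid near-zero-length beam elements.
    """
    if length <= 0.0:
        raise ValueError("filament length must be positive")
    mean, std = cfg.segment_length_mean, cfg.segment_length_std
    bounds = [0.0]
    while length - bounds[-1] > mean * (1.0 + 1e-9):
        s = truncated_normal(rng, mean, std)
        if s >= length - bounds[-1]:
            break
        bounds.append(bounds[-1] + s)
    remainder = length - bounds[-1]
    if remainder < 0.5 * mean and len(bounds) > 1:
        bounds.pop()  # merge the short tail into the previous segment
    bounds.append(length)
    return np.asarray(bounds)


def segment_filaments(
    filaments: list[Filament], cfg: GenerationConfig, rng
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Divide filaments into beam elements at binding-site nodes.

    Returns ``(nodes, node_filament, beams)`` where nodes is (n, 2),
    node_filament maps each node to its owning filament and beams is
    (nb, 3) of ``(node_a, node_b, filament_id)``.  Fills each filament's
    ``node_ids`` in order along its axis.
    """
    xs: list[np.ndarray] = []
    fil_of_node: list[np.ndarray] = []
    beams: list[tuple[int, int, int]] = []
    offset = 0
    for fil in filaments:
        bounds = _segment_boundaries(fil.length, cfg, rng)
        (x0, y0), _ = fil.endpoints
        pts = np.column_stack(
            (x0 + bounds * np.cos(fil.angle), y0 + bounds * np.sin(fil.angle))
        )
        n = len(bounds)
        fil.node_ids = list(range(offset, offset + n))
        xs.append(pts)
        fil_of_node.append(np.full(n, fil.id, dtype=np.int64))
        beams.extend((offset + k, offset + k + 1, fil.id) for k in range(n - 1))
        offset += n
    if not filaments:
        return np.zeros((0, 2)), np.zeros(0, dtype=np.int64), np.zeros((0, 3), np.int64)
    return (
        np.concatenate(xs),
        np.concatenate(fil_of_node),
        np.asarray(beams, dtype=np.int64).reshape(-1, 3),
    )


def crosslink_candidates(
    nodes: np.ndarray, node_filament: np.ndarray, max_length: float
) -> np.ndarray:
    """All unordered node pairs on distinct filaments strictly closer than
    ``max_length``, found with a k-d tree (identical to brute force)."""
    if len(nodes) < 2:
        return np.zeros((0, 2), dtype=np.int64)
    tree = cKDTree(nodes)
    pairs = tree.query_pairs(max_length, output_type="ndarray")
    if len(pairs) == 0:
        return np.zeros((0, 2), dtype=np.int64)
    # query_pairs uses <=; the attachment rule is strictly less-than
    d = np.linalg.norm(nodes[pairs[:, 0]] - nodes[pairs[:, 1]], axis=1)
    pairs = pairs[d < max_length]
    pairs = pairs[node_filament[pairs[:, 0]] != node_filament[pairs[:, 1]]]
    order = np.lexsort((pairs[:, 1], pairs[:, 0]))
    return pairs[order]


def match_sites(candidates: np.ndarray, distances: np.ndarray, n_nodes: int) -> np.ndarray:
    """Greedy maximal matching of binding sites, nearest pairs first.

    Each site hosts at most one cross-linker — a bound actin-cross-linking
    protein occupies its site.  Ties in distance are broken by node ids
    (the candidate list is pre-sorted lexicographically).
    """
    order = np.argsort(distances, kind="stable")
    used = np.zeros(n_nodes, dtype=bool)
    keep = []
    for k in order:
        a, b = candidates[k]
        if not used[a] and not used[b]:
            used[a] = used[b] = True
            keep.append(k)
    keep = np.sort(np.asarray(keep, dtype=np.int64))
    return candidates[keep]


def generate_crosslinkers(
    nodes: np.ndarray,
    node_filament: np.ndarray,
    cfg: GenerationConfig,
    rng,
) -> np.ndarray:
    """Connect binding sites into cables.

    Candidates are all site pairs on distinct filaments strictly closer
    than the maximum cross-linker length.  Under the default
    ``site_matching`` rule each site then binds at most one partner
    (nearest first); under ``all_pairs`` every candidate becomes a
    cable.  Finally each cable is retained independently with
    probability ``crosslink_fraction``.
    """
    cand = crosslink_candidates(nodes, node_filament, cfg.max_crosslinker_length)
    if len(cand) and cfg.crosslink_rule == "site_matching":
        d = np.linalg.norm(nodes[cand[:, 0]] - nodes[cand[:, 1]], axis=1)
        cand = match_sites(cand, d, len(nodes))
    if cfg.crosslink_fraction >= 1.0 or len(cand) == 0:
        return cand
    keep = rng.random(len(cand)) < cfg.crosslink_fraction
    return cand[keep]


def count_components(n_nodes: int, beams: np.ndarray, cables: np.ndarray) -> int:
    edges = np.vstack((beams[:, :2], cables)) if len(cables) else beams[:, :2]
    if n_nodes == 0:
        return 0
    adj = sparse.coo_matrix(
        (np.ones(len(edges)), (edges[:, 0], edges[:, 1])), shape=(n_nodes, n_nodes)
    )
    ncomp, _ = connected_components(adj, directed=False)
    return int(ncomp)


def build_network(
    cfg: GenerationConfig, materials: MaterialTable | None = None
) -> NetworkModel:
    """Run the full generation pipeline deterministically from ``cfg.seed``."""
    if materials is None:
        materials = MaterialTable(filament_diameter=cfg.filament_diameter)
    rng = np.random.default_rng(cfg.seed)
    filaments = generate_filaments(cfg, rng)
    nodes, node_filament, beams = segment_filaments(filaments, cfg, rng)
    cables = generate_crosslinkers(nodes, node_filament, cfg, rng)
    ncomp = count_components(len(nodes), beams, cables)
    meta = {
        "seed": cfg.seed,
        "n_filaments": len(filaments),
        "n_nodes": int(len(nodes)),
        "n_beams": int(len(beams)),
        "n_cables": int(len(cables)),
        "disconnected": bool(ncomp > 1),
    }
    return NetworkModel(
        nodes=nodes,
        node_filament=node_filament,
        beams=beams,
        cables=cables,
        materials=materials,
        config=cfg,
        achieved_relative_density=relative_density(filaments, cfg),
        filaments=filaments,
        n_components=ncomp,
        metadata=meta,
    )
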