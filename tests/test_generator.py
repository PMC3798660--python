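"""Random network generation: sampling rules, segmentation, cross-linking."""

import numpy as np
import pytest
from pydantic import ValidationError
from scipy import stats

from cytoform.config import GenerationConfig
from cytoform.generator import (
    build_network,
    crosslink_candidates,
    generate_crosslinkers,
    generate_filaments,
    match_sites,
    relative_density,
    sample_filament,
    segment_filaments,
    truncated_normal,
)
from cytoform.model import Filament


class TestConfigValidation:
    def test_defaults_are_valid(self):
        cfg = GenerationConfig()
        assert cfg.domain_width == 10.0
        assert cfg.filament_length_mean == 5.0

    @pytest.mark.parametrize(
        "bad",
        [
            {"filament_diameter": -1.0},
            {"target_relative_density": 0.0},
            {"target_relative_density": 0.02},
            {"crosslink_fraction": 0.0},
            {"crosslink_fraction": 1.5},
            {"domain_width": 4.0},  # smaller than the mean filament length
        ],
    )
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ValidationError):
            GenerationConfig(**bad)


class TestSampleFilament:
    def test_centered_horizontal_filament(self, scripted_rng_factory):
        rng = scripted_rng_factory(normals=[5.0], uniforms=[5.0, 5.0, 0.0])
        fil = sample_filament(rng, GenerationConfig())
        (x0, y0), (x1, y1) = fil.endpoints
        assert (x0, y0) == pytest.approx((2.5, 5.0))
        assert (x1, y1) == pytest.approx((7.5, 5.0))

    def test_overhanging_filament_translated_minimally(self, scripted_rng_factory):
        # raw endpoints (6.5, 5), (11.5, 5): shifted left by 1.5
        rng = scripted_rng_factory(normals=[5.0], uniforms=[9.0, 5.0, 0.0])
        fil = sample_filament(rng, GenerationConfig())
        (x0, y0), (x1, y1) = fil.endpoints
        assert (x0, x1) == pytest.approx((5.0, 10.0))
        assert y0 == y1 == pytest.approx(5.0)
        assert fil.angle == 0.0
        assert fil.length == pytest.approx(5.0)

    def test_negative_length_draw_rejected(self, scripted_rng_factory):
        rng = scripted_rng_factory(normals=[-1.0, 4.0], uniforms=[5.0, 5.0, 0.0])
        fil = sample_filament(rng, GenerationConfig())
        assert fil.length == pytest.approx(4.0)

    def test_endpoints_always_inside_domain(self):
        cfg = GenerationConfig()
        rng = np.random.default_rng(7)
        for i in range(300):
            fil = sample_filament(rng, cfg, fid=i)
            for (x, y) in fil.endpoints:
                assert -1e-9 <= x <= cfg.domain_width + 1e-9
                assert -1e-9 <= y <= cfg.domain_height + 1e-9


class TestRelativeDensity:
    def test_empty_list_is_zero(self):
        assert relative_density([], GenerationConfig()) == 0.0

    def test_single_filament_volume_fraction(self):
        fil = Filament(id=0, centroid=(5, 5), angle=0.0, length=5.0)
        rho = relative_density([fil], GenerationConfig())
        assert rho == pytest.approx(np.pi * 0.007**2 / 4 * 5.0 / 100.0, rel=1e-12)
        assert rho == pytest.approx(1.924e-6, rel=1e-3)

    def test_filament_count_to_reach_default_density(self):
        # ~1040 filaments of 5 um are needed for 0.2% on the default domain
        per_fil = np.pi * 0.007**2 / 4 * 5.0
        assert int(np.ceil(0.002 * 100.0 / per_fil)) == 1040


class TestGenerateFilaments:
    def test_single_filament_reaches_tiny_target(self, scripted_rng_factory):
        target = np.pi * 0.007**2 / 4 * 5.0 / 100.0 * 0.999
        cfg = GenerationConfig(target_relative_density=target)
        rng = scripted_rng_factory(normals=[5.0], uniforms=[5.0, 5.0, 0.0])
        fils = generate_filaments(cfg, rng)
        assert len(fils) == 1

    def test_stopping_rule_overshoot_bound(self, tiny_network_config):
        cfg = tiny_network_config
        fils = generate_filaments(cfg, np.random.default_rng(3))
        rho = relative_density(fils, cfg)
        assert rho >= cfg.target_relative_density
        last = relative_density([fils[-1]], cfg)
        assert rho - cfg.target_relative_density < last

    def test_determinism(self, tiny_network_config):
        a = generate_filaments(tiny_network_config, np.random.default_rng(11))
        b = generate_filaments(tiny_network_config, np.random.default_rng(11))
        assert [(f.centroid, f.angle, f.length) for f in a] == [
            (f.centroid, f.angle, f.length) for f in b
        ]

    def test_length_and_angle_distributions(self):
        cfg = GenerationConfig(domain_width=30, domain_height=30)
        rng = np.random.default_rng(5)
        fils = [sample_filament(rng, cfg, i) for i in range(1000)]
        lengths = np.array([f.length for f in fils])
        angles = np.array([f.angle for f in fils])
        # 5 +/- 2 truncated at zero barely shifts the moments
        assert abs(lengths.mean() - 5.0) / 5.0 < 0.05
        assert abs(lengths.std() - 2.0) / 2.0 < 0.05
        p = stats.kstest(angles / (2 * np.pi), "uniform").pvalue
        assert p > 0.01


class TestSegmentation:
    def _segment(self, length, draws, cfg=None):
        cfg = cfg or GenerationConfig()
        fil = Filament(id=0, centroid=(5.0, 5.0), angle=0.0, length=length)

        class _R:
            def __init__(self, vals):
                self.vals = list(vals)

            def normal(self, loc, scale):
                return self.vals.pop(0)

        nodes, node_fil, beams = segment_filaments([fil], cfg, _R(draws))
        xs = nodes[:, 0]
        return np.diff(np.sort(xs)), nodes, beams

    def test_exact_division(self):
        segs, nodes, beams = self._segment(0.9, [0.3, 0.3])
        assert segs == pytest.approx([0.3, 0.3, 0.3])
        assert len(nodes) == 4 and len(beams) == 3

    def test_short_remainder_merged_into_previous(self):
        segs, nodes, beams = self._segment(1.0, [0.3, 0.3, 0.3])
        assert segs == pytest.approx([0.3, 0.3, 0.4])
        assert len(nodes) == 4 and len(beams) == 3

    def test_short_filament_single_segment(self):
        segs, nodes, beams = self._segment(0.2, [])
        assert segs == pytest.approx([0.2])
        assert len(nodes) == 2 and len(beams) == 1

    def test_nonpositive_length_rejected(self):
        from cytoform.generator import _segment_boundaries

        with pytest.raises(ValueError):
            _segment_boundaries(0.0, GenerationConfig(), np.random.default_rng(0))

    def test_segments_span_filament_and_are_collinear(self, tiny_network_config):
        rng = np.random.default_rng(2)
        fils = generate_filaments(tiny_network_config, rng)
        nodes, node_fil, beams = segment_filaments(fils, tiny_network_config, rng)
        for fil in fils:
            pts = nodes[fil.node_ids]
            d = pts[-1] - pts[0]
            assert np.hypot(*d) == pytest.approx(fil.length, rel=1e-9)
            seg = np.diff(pts, axis=0)
            cross = seg[:-1, 0] * seg[1:, 1] - seg[:-1, 1] * seg[1:, 0]
            assert np.abs(cross).max() < 1e-9


class TestCrosslinkers:
    def _two_parallel(self, gap=0.2, n=4, spacing=0.3):
        xs = np.arange(n) * spacing
        nodes = np.vstack([
            np.column_stack([xs, np.zeros(n)]),
            np.column_stack([xs, np.full(n, gap)]),
        ])
        membership = np.repeat([0, 1], n)
        return nodes, membership

    def test_opposing_nodes_linked_same_filament_never(self):
        nodes, mem = self._two_parallel(gap=0.2)
        cand = crosslink_candidates(nodes, mem, 0.3)
        # exactly the 4 vertical pairs: along-filament spacing 0.3 is excluded
        assert len(cand) == 4
        assert all(mem[a] != mem[b] for a, b in cand)

    def test_boundary_distance_excluded(self):
        nodes, mem = self._two_parallel(gap=0.3)
        cand = crosslink_candidates(nodes, mem, 0.3)
        assert len(cand) == 0

    def test_tree_matches_brute_force(self, tiny_network_config):
        rng = np.random.default_rng(9)
        fils = generate_filaments(tiny_network_config, rng)
        nodes, mem, _ = segment_filaments(fils, tiny_network_config, rng)
        nodes = nodes[:500]
        mem = mem[:500]
        cand = crosslink_candidates(nodes, mem, 0.3)
        brute = set()
        for i in range(len(nodes)):
            for j in range(i + 1, len(nodes)):
                if mem[i] != mem[j] and np.hypot(*(nodes[i] - nodes[j])) < 0.3:
                    brute.add((i, j))
        assert set(map(tuple, cand)) == brute

    def test_site_matching_each_site_hosts_at_most_one(self):
        nodes, mem = self._two_parallel(gap=0.2, n=6)
        cand = crosslink_candidates(nodes, mem, 0.3)
        matched = match_sites(
            cand, np.linalg.norm(nodes[cand[:, 0]] - nodes[cand[:, 1]], axis=1),
            len(nodes),
        )
        used = matched.ravel()
        assert len(used) == len(set(used.tolist()))

    def test_retention_fraction_binomial(self):
        nodes, mem = self._two_parallel(gap=0.1, n=10)
        cfg = GenerationConfig(crosslink_fraction=0.2, crosslink_rule="all_pairs")
        counts = []
        base = len(generate_crosslinkers(
            nodes, mem, cfg.model_copy(update={"crosslink_fraction": 1.0}),
            np.random.default_rng(0)))
        for s in range(2000):
            kept = generate_crosslinkers(nodes, mem, cfg, np.random.default_rng(s))
            counts.append(len(kept))
        frac = np.mean(counts) / base
        assert frac == pytest.approx(0.2, abs=0.01)

    def test_duplicate_free_unordered_pairs(self, tiny_network_config):
        net = build_network(tiny_network_config)
        pairs = {tuple(sorted(p)) for p in net.cables}
        assert len(pairs) == net.n_cables


class TestBuildNetwork:
    def test_deterministic_for_fixed_seed(self, tiny_network_config):
        a = build_network(tiny_network_config)
        b = build_network(tiny_network_config)
        assert np.array_equal(a.nodes, b.nodes)
        assert np.array_equal(a.beams, b.beams)
        assert np.array_equal(a.cables, b.cables)

    def test_invariants(self, tiny_network_config):
        net = build_network(tiny_network_config)
        # beams connect nodes of one filament; cables connect distinct filaments
        assert np.all(
            net.node_filament[net.beams[:, 0]] == net.node_filament[net.beams[:, 1]]
        )
        if net.n_cables:
            assert np.all(
                net.node_filament[net.cables[:, 0]]
                != net.node_filament[net.cables[:, 1]]
            )
            assert net.cable_lengths().max() < tiny_network_config.max_crosslinker_length
        assert net.achieved_relative_density >= tiny_network_config.target_relative_density

    def test_initial_folded_orientations_uniform(self):
        cfg = GenerationConfig(seed=12, target_relative_density=0.0015)
        net = build_network(cfg)
        # segments inherit their filament's angle, so independence holds at
        # the filament level; the chi-square is run on per-filament angles
        ang = np.degrees([f.angle for f in net.filaments]) % 180.0
        folded = np.where(ang > 90, 180 - ang, ang)
        counts, _ = np.histogram(folded, bins=9, range=(0, 90))
        assert stats.chisquare(counts).pvalue > 0.01
        # and the per-segment histogram is flat to within sampling noise
        d = net.nodes[net.beams[:, 1]] - net.nodes[net.beams[:, 0]]
        sang = np.degrees(np.arctan2(d[:, 1], d[:, 0])) % 180.0
        sfold = np.where(sang > 90, 180 - sang, sang)
        scounts, _ = np.histogram(sfold, bins=9, range=(0, 90))
        assert np.abs(scounts / scounts.mean() - 1).max() < 0.25


class TestTruncatedNormal:
    def test_rejects_until_inside_bounds(self, scripted_rng_factory):
        rng = scripted_rng_factory(normals=[-2.0, 0.0, 12.0, 3.0])
        assert truncated_normal(rng, 5, 2, lower=0.0, upper=10.0) == 3.0
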