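"""Finite-element kernel: corotational beams, cables, assembly, solver."""

import numpy as np
import pytest

from cytoform.config import MaterialTable, SolverSettings
from cytoform.fecore import (
    BeamElement,
    BoundaryConditions,
    CableElement,
    FESystem,
    beam_global_forces,
    beam_local_forces,
    beam_tangent,
    cable_force,
    residual_vector,
    solve_equilibrium,
    strain_energy,
)

MAT = MaterialTable()
EA = MAT.filament_EA
EI = MAT.filament_EI


def _beam(L0=0.3, angle=0.0):
    return BeamElement(0, 1, MAT.filament_modulus, MAT.filament_area,
                       MAT.filament_I, L0, angle)


class TestBeamElement:
    def test_unit_system_section_properties(self):
        assert EA == pytest.approx(53.88, abs=0.01)
        assert EI == pytest.approx(1.650e-4, rel=1e-3)

    def test_rigid_motion_gives_zero_forces(self):
        el = _beam(0.3)
        ang = 0.8
        R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        pa = R @ np.array([0.0, 0.0]) + [1.3, -0.4]
        pb = R @ np.array([0.3, 0.0]) + [1.3, -0.4]
        N, Ma, Mb, shear = beam_local_forces(el, (pa, pb), (ang, ang))
        assert abs(N) < 1e-10 * EA
        assert abs(Ma) < 1e-12 and abs(Mb) < 1e-12

    def test_pure_stretch_axial_force(self):
        el = _beam(0.3)
        N, Ma, Mb, _ = beam_local_forces(el, ((0, 0), (0.303, 0)), (0.0, 0.0))
        assert N == pytest.approx(EA * 0.01, rel=1e-12)
        assert N == pytest.approx(0.5388, abs=5e-4)

    def test_symmetric_rotations_pure_bending(self):
        el = _beam(0.3)
        phi = 0.02
        N, Ma, Mb, _ = beam_local_forces(el, ((0, 0), (0.3, 0)), (phi, -phi))
        assert abs(N) < 1e-12
        assert Ma == pytest.approx(-Mb, rel=1e-12)

    def test_tangent_matches_finite_differences(self):
        el = _beam(0.3, angle=0.0)
        rng = np.random.default_rng(4)
        d = rng.normal(0.0, 0.02, 6)
        pa = np.array([0.0 + d[0], d[1]])
        pb = np.array([0.3 + d[3], d[4]])
        K = beam_tangent(el, (pa, pb), (d[2], d[5]))
        h = 1e-7
        Kfd = np.zeros((6, 6))
        for i in range(6):
            dp = d.copy(); dp[i] += h
            dm = d.copy(); dm[i] -= h
            fp = beam_global_forces(
                el, ((dp[0], dp[1]), (0.3 + dp[3], dp[4])), (dp[2], dp[5]))
            fm = beam_global_forces(
                el, ((dm[0], dm[1]), (0.3 + dm[3], dm[4])), (dm[2], dm[5]))
            Kfd[:, i] = (fp - fm) / (2 * h)
        assert np.abs(K - Kfd).max() / np.abs(Kfd).max() < 1e-5

    def test_undeformed_axial_stiffness_entry(self):
        K = beam_tangent(_beam(0.3), ((0, 0), (0.3, 0)), (0.0, 0.0))
        assert K[0, 0] == pytest.approx(EA / 0.3, rel=1e-12)

    def test_zero_axial_force_no_geometric_stiffness(self):
        el = _beam(0.3)
        K = beam_tangent(el, ((0, 0), (0.3, 0)), (0.0, 0.0))
        # material-only: the transverse-transverse block is the Euler beam value
        assert K[1, 1] == pytest.approx(12 * EI / 0.3**3, rel=1e-9)


class TestCableElement:
    def test_constant_force_mode_carries_prestress(self):
        el = CableElement(0, 1, mode="constant_force", prestress=0.003)
        for sep in (0.05, 0.2, 0.7):
            T, f = cable_force(el, ((0, 0), (sep, 0)))
            assert T == pytest.approx(0.003)
            assert f[0] == pytest.approx([-0.003, 0.0])
            assert f[1] == pytest.approx([0.003, 0.0])

    def test_elastic_slack_under_compression(self):
        el = CableElement(0, 1, mode="elastic", prestress=0.003,
                          axial_stiffness=0.6, reference_length=0.2)
        T, f = cable_force(el, ((0, 0), (0.19, 0)))  # strain -5%: 3pN - 30pN < 0
        assert T == 0.0
        assert np.all(f == 0.0)

    def test_elastic_linear_law(self):
        el = CableElement(0, 1, mode="elastic", prestress=0.0,
                          axial_stiffness=0.6, reference_length=0.2)
        T, _ = cable_force(el, ((0, 0), (0.202, 0)))
        assert T == pytest.approx(0.6 * 0.01, rel=1e-9)


class TestAssembly:
    def test_zero_displacement_no_prestress_zero_residual(self, beam_chain_factory):
        net = beam_chain_factory(4, 1.2)
        s = FESystem(net)
        r = s.internal_force(np.zeros(s.ndof))
        assert np.abs(r).max() == 0.0

    def test_single_constant_force_cable_residual(self):
        from cytoform.config import GenerationConfig
        from cytoform.model import NetworkModel

        nodes = np.array([[0.0, 0.0], [0.2, 0.0]])
        net = NetworkModel(
            nodes=nodes, node_filament=np.array([0, 1]),
            beams=np.zeros((0, 3), dtype=np.int64),
            cables=np.array([[0, 1]]), materials=MAT,
            config=GenerationConfig(), achieved_relative_density=0.0,
        )
        s = FESystem(net, cable_mode="constant_force", prestress=0.003)
        r = s.internal_force(np.zeros(s.ndof))
        assert r[0] == pytest.approx(-0.003, rel=1e-4)
        assert r[3] == pytest.approx(0.003, rel=1e-4)

    def test_assembled_tangent_matches_finite_differences(self, beam_chain_factory):
        net = beam_chain_factory(3, 0.9)
        net.cables = np.array([[0, 3]])
        net.node_filament = np.array([0, 0, 1, 1])
        for mode in ("constant_force", "elastic"):
            s = FESystem(net, cable_mode=mode)
            u = np.random.default_rng(0).normal(0, 0.05, s.ndof)
            K = s.tangent(u).toarray()
            h = 1e-7
            Kfd = np.zeros_like(K)
            for i in range(s.ndof):
                up, um = u.copy(), u.copy()
                up[i] += h
                um[i] -= h
                Kfd[:, i] = (s.internal_force(up) - s.internal_force(um)) / (2 * h)
            assert np.abs(K - Kfd).max() / np.abs(Kfd).max() < 1e-5
            assert np.abs(K - K.T).max() / np.abs(K).max() < 1e-9

    def test_energy_gradient_is_internal_force(self, beam_chain_factory):
        net = beam_chain_factory(3, 0.9)
        net.cables = np.array([[0, 3]])
        net.node_filament = np.array([0, 0, 1, 1])
        s = FESystem(net, cable_mode="constant_force")
        u = np.random.default_rng(1).normal(0, 0.03, s.ndof)
        r = s.internal_force(u)
        h = 1e-7
        for i in range(0, s.ndof, 5):
            up, um = u.copy(), u.copy()
            up[i] += h
            um[i] -= h
            g = (s.potential_energy(up) - s.potential_energy(um)) / (2 * h)
            assert g == pytest.approx(r[i], rel=1e-5, abs=1e-10)


class TestSolver:
    def test_cantilever_tip_deflection(self, beam_chain_factory, fast_settings):
        net = beam_chain_factory(10, 3.0)
        s = FESystem(net)
        bc = BoundaryConditions.from_nodes([(0, 0, 0.0), (0, 1, 0.0), (0, 2, 0.0)])
        q = 1e-7
        f = np.zeros(s.ndof)
        f[3 * 10 + 1] = q
        st = solve_equilibrium(s, bc, fast_settings, external_force=f)
        assert st.u[3 * 10 + 1] == pytest.approx(q * 27.0 / (3 * EI), rel=0.01)

    def test_axial_bar_elongation(self, beam_chain_factory, fast_settings):
        net = beam_chain_factory(10, 3.0)
        s = FESystem(net)
        bc = BoundaryConditions.from_nodes([(0, 0, 0.0), (0, 1, 0.0), (0, 2, 0.0)])
        F = 0.01
        f = np.zeros(s.ndof)
        f[3 * 10] = F
        st = solve_equilibrium(s, bc, fast_settings, external_force=f)
        assert st.u[3 * 10] == pytest.approx(F * 3.0 / EA, rel=1e-6)

    def test_bit_reproducible(self, beam_chain_factory, fast_settings):
        def run():
            net = beam_chain_factory(6, 1.8)
            s = FESystem(net)
            bc = BoundaryConditions.from_nodes(
                [(0, 0, 0.0), (0, 1, 0.0), (0, 2, 0.0)])
            f = np.zeros(s.ndof)
            f[3 * 6 + 1] = 1e-6
            return solve_equilibrium(s, bc, fast_settings, external_force=f).u

        assert np.array_equal(run(), run())

    def test_newton_quadratic_convergence_near_solution(
        self, beam_chain_factory, fast_settings
    ):
        net = beam_chain_factory(6, 1.8)
        s = FESystem(net)
        bc = BoundaryConditions.from_nodes([(0, 0, 0.0), (0, 1, 0.0), (0, 2, 0.0)])
        f = np.zeros(s.ndof)
        f[3 * 6 + 1] = 5e-6  # geometrically noticeable but stable
        st = solve_equilibrium(s, bc, fast_settings, external_force=f,
                               n_increments=1)
        assert st.converged
        # warm-started re-solve sits in the quadratic region: <= 3 iterations
        st2 = solve_equilibrium(s, bc, fast_settings, external_force=f,
                                n_increments=1, u0=st.u)
        assert st2.iterations[-1] <= 3

    def test_frame_indifference_of_converged_state(self, beam_chain_factory):
        net = beam_chain_factory(4, 1.2)
        s = FESystem(net)
        u = np.random.default_rng(2).normal(0, 0.01, s.ndof)
        bf0 = s.beam_forces(u)
        ang = 0.6
        R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        x = s.X0 + u.reshape(-1, 3)[:, :2]
        xr = (x - [0.5, 0.5]) @ R.T + [2.0, -1.0]
        ur = np.zeros_like(u)
        ur[0::3] = xr[:, 0] - s.X0[:, 0]
        ur[1::3] = xr[:, 1] - s.X0[:, 1]
        ur[2::3] = u[2::3] + ang
        bf1 = s.beam_forces(ur)
        assert np.abs(bf1 - bf0).max() <= 1e-10 * max(1.0, np.abs(bf0).max())


class TestStrainEnergy:
    def test_pure_axial_energy(self, beam_chain_factory):
        net = beam_chain_factory(4, 1.2)
        s = FESystem(net)
        u = np.zeros(s.ndof)
        for i in range(5):
            u[3 * i] = 0.01 * (i * 0.3)  # uniform 1% stretch
        from cytoform.fecore import SystemState

        st = SystemState(u=u, beam_forces=s.beam_forces(u),
                         cable_tensions=np.zeros(0), residual_norm=0.0)
        se_ax, se_bend = strain_energy(net, st, s)
        assert se_bend[0] == pytest.approx(0.0, abs=1e-18)
        # SE = 1/2 EA eps^2 L
        assert se_ax[0] == pytest.approx(0.5 * EA * 1e-4 * 1.2, rel=1e-6)

    def test_cantilever_energy_balance_and_bending_dominance(
        self, beam_chain_factory, fast_settings
    ):
        net = beam_chain_factory(10, 3.0)
        s = FESystem(net)
        bc = BoundaryConditions.from_nodes([(0, 0, 0.0), (0, 1, 0.0), (0, 2, 0.0)])
        q = 1e-7
        f = np.zeros(s.ndof)
        f[3 * 10 + 1] = q
        st = solve_equilibrium(s, bc, fast_settings, external_force=f)
        se_ax, se_bend = strain_energy(net, st, s)
        total = se_ax.sum() + se_bend.sum()
        # external work 1/2 F u equals stored energy in the linear range
        assert total == pytest.approx(0.5 * q * st.u[3 * 10 + 1], rel=0.005)
        assert se_ax.sum() / total < 1e-3


class TestResidualVector:
    def test_matches_assemble_residual(self, beam_chain_factory):
        from cytoform.fecore import assemble

        net = beam_chain_factory(3, 0.9)
        s = FESystem(net)
        u = np.random.default_rng(3).normal(0, 0.01, s.ndof)
        anchor = np.zeros(s.ndof)
        r1 = residual_vector(s, u, None, 1.0, 1e-4, anchor)
        r2, _ = assemble(s, u, None, 1.0, 1e-4, anchor)
        assert np.array_equal(r1, r2)
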