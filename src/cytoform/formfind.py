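"""Form-finding: settle a generated network into self-equilibrium.

Freshly generated networks are geometrically random and force-free.  A
small constant tensile pre-stress (default 3 pN) is imposed in every
cross-linker to mimic the force state of a bound actin-cross-linking
protein, and equilibrium is found by incremental Newton iteration while
that cable force is held constant.  The converged configuration is the
baseline for any subsequent mechanical test: beams retain their
form-found internal forces, and cables either keep carrying the constant
pre-stress (the default during stretching) or switch to an elastic law
referenced to the form-found chord.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components

from .config import SolverSettings
from .fecore import (
    CABLE_SMOOTHING,
    BoundaryConditions,
    FESystem,
    SystemState,
    solve_equilibrium,
)
from .model import NetworkModel


class YieldExceededWarning(UserWarning):
    """A filament segment's axial force passed its tensile yield value."""


@dataclass
class FormFindingResult:
    network: NetworkModel
    state: SystemState
    prestress: float
    max_filament_force: float
    max_cable_elongation: float
    displacement_norm: float

    @property
    def equilibrated_coordinates(self) -> np.ndarray:
        return self.state.coordinates(self.network.nodes)

    @property
    def formfound_cable_lengths(self) -> np.ndarray:
        if self.network.n_cables == 0:
            return np.zeros(0)
        x = self.equilibrated_coordinates
        d = x[self.network.cables[:, 1]] - x[self.network.cables[:, 0]]
        return np.hypot(d[:, 0], d[:, 1])

    @property
    def equilibrated_network(self) -> NetworkModel:
        """Copy of the network with form-found coordinates (for export/plots)."""
        net = NetworkModel(
            nodes=self.equilibrated_coordinates,
            node_filament=self.network.node_filament,
            beams=self.network.beams,
            cables=self.network.cables,
            materials=self.network.materials,
            config=self.network.config,
            achieved_relative_density=self.network.achieved_relative_density,
            filaments=self.network.filaments,
            n_components=self.network.n_components,
            metadata={**self.network.metadata, "form_found": True},
        )
        return net


def _component_labels(network: NetworkModel) -> np.ndarray:
    edges = (
        np.vstack((network.beams[:, :2], network.cables))
        if network.n_cables
        else network.beams[:, :2]
    )
    n = network.n_nodes
    adj = sparse.coo_matrix(
        (np.ones(len(edges)), (edges[:, 0], edges[:, 1])), shape=(n, n)
    )
    _, labels = connected_components(adj, directed=False)
    return labels


def formfinding_pins(network: NetworkModel) -> BoundaryConditions:
    """Minimal pin set removing rigid-body modes during form-finding.

    Per connected component that carries at least one cable: both
    translations of the node nearest the component's centroid are fixed,
    plus the translation of the most distant node in the direction
    perpendicular to the radius (stopping rigid rotation).  Components
    with no cables carry no load and are fixed in place wholesale.
    """
    labels = _component_labels(network)
    has_cable = np.zeros(labels.max() + 1 if len(labels) else 0, dtype=bool)
    for a, b in network.cables:
        has_cable[labels[a]] = True
        has_cable[labels[b]] = True

    fixes: list[tuple[int, int, float]] = []
    for comp in range(len(has_cable)):
        idx = np.flatnonzero(labels == comp)
        pts = network.nodes[idx]
        if not has_cable[comp]:
            for i in idx:
                fixes.extend([(int(i), 0, 0.0), (int(i), 1, 0.0), (int(i), 2, 0.0)])
            continue
        center = pts.mean(axis=0)
        pin = idx[np.argmin(np.linalg.norm(pts - center, axis=1))]
        fixes.extend([(int(pin), 0, 0.0), (int(pin), 1, 0.0)])
        if len(idx) > 1:
            rad = pts - network.nodes[pin]
            far = idx[np.argmax(np.linalg.norm(rad, axis=1))]
            dx, dy = network.nodes[far] - network.nodes[pin]
            # rigid rotation moves `far` along (-dy, dx): fix the larger component
            fixes.append((int(far), 0 if abs(dy) >= abs(dx) else 1, 0.0))
    return BoundaryConditions.from_nodes(fixes)


def collapse_ansatz(network: NetworkModel) -> Optional[np.ndarray]:
    """Starting guess for form-finding: rigid per-filament drift.

    Each filament translates rigidly by the mean of its cross-linkers'
    half-gap closures, moving linked pairs toward each other without
    introducing any elastic energy into the start state.  Only used when
    each binding site hosts at most one cross-linker; returns ``None``
    otherwise.
    """
    if network.n_cables == 0:
        return None
    ends = np.bincount(network.cables.ravel(), minlength=network.n_nodes)
    if ends.max() > 1:
        return None
    a, b = network.cables[:, 0], network.cables[:, 1]
    gap = network.nodes[b] - network.nodes[a]
    nfil = int(network.node_filament.max()) + 1
    pull = np.zeros((nfil, 2))
    count = np.zeros(nfil)
    fa = network.node_filament[a]
    fb = network.node_filament[b]
    np.add.at(pull, fa, 0.5 * gap)
    np.add.at(pull, fb, -0.5 * gap)
    np.add.at(count, fa, 1.0)
    np.add.at(count, fb, 1.0)
    drift = pull / np.maximum(count, 1.0)[:, None]
    u0 = np.zeros(3 * network.n_nodes)
    u0[0::3] = drift[network.node_filament, 0]
    u0[1::3] = drift[network.node_filament, 1]
    return u0


def run_form_finding(
    network: NetworkModel,
    prestress: Optional[float] = None,
    settings: Optional[SolverSettings] = None,
    u0: Optional[np.ndarray] = None,
    linear_solver=None,
    strict: bool = True,
    init: str = "auto",
) -> FormFindingResult:
    """Equilibrate the network under constant cross-linker pre-stress.

    A fresh solve starts from the pre-collapse ansatz when available
    (``init="collapse"``, the default) or from the generated geometry
    (``init="straight"``), annealing the cable smoothing length over the
    load stages; when a starting state ``u0`` is supplied (e.g. re-running
    on an already form-found network) a single stage at the final
    smoothing is solved.  Emits :class:`YieldExceededWarning` if any
    segment's axial force exceeds the filament tensile yield.
    """
    settings = settings or SolverSettings()
    if init == "auto":
        # the pre-collapse ansatz trades path fidelity for speed; strict
        # solves anneal from the generated geometry
        init = "straight" if strict else "collapse"
    P = network.materials.crosslinker_prestress if prestress is None else prestress
    if P > network.materials.crosslinker_yield_force:
        raise ValueError("pre-stress exceeds the cross-linker yield force")
    system = FESystem(network, cable_mode="constant_force", prestress=P)
    bc = formfinding_pins(network)
    if linear_solver is None:
        linear_solver = system.make_linear_solver()

    # smoothing continuation: the load steps anneal the cable potential's
    # smoothing length from the cross-linker scale down to its final value,
    # each stage warm-starting the next — pre-stress ramping is ineffective
    # here because pure cable loading scales nearly uniformly with P
    eps_final = CABLE_SMOOTHING
    warm = u0 is not None
    if not warm and init == "collapse":
        u0 = collapse_ansatz(network)
        if u0 is not None:
            m = max(2, settings.n_increments // 3)
            schedule = np.geomspace(10 * eps_final, eps_final, m)
        else:
            m = max(settings.n_increments, 1)
            eps_start = max(10.0 * network.config.max_crosslinker_length,
                            10 * eps_final)
            schedule = np.geomspace(eps_start, eps_final, m)
    elif not warm:
        # start deep in the quadratic regime (tension << P) so the first
        # stage is nearly linear, then anneal geometrically
        m = max(settings.n_increments, 1)
        eps_start = max(10.0 * network.config.max_crosslinker_length,
                        10 * eps_final)
        schedule = np.geomspace(eps_start, eps_final, m)
    else:
        schedule = np.array([eps_final])
    # intermediate annealing stages only track the path: loose tolerance,
    # and a strong-to-weak regularization schedule that anchors the soft
    # collective modes early (they otherwise wander for many iterations)
    # while leaving the final equilibrium essentially unbiased
    reg_schedule = np.geomspace(
        max(1e-2, settings.regularization), settings.regularization, len(schedule)
    )
    u = u0
    state = None
    for i, (eps, reg) in enumerate(zip(schedule, reg_schedule)):
        system.cable_smoothing = float(eps)
        final = i == len(schedule) - 1
        stage_settings = settings.model_copy(
            update={
                "regularization": float(reg),
                "residual_tolerance": settings.residual_tolerance if final else 3e-3,
            }
        )
        state = solve_equilibrium(
            system, bc, stage_settings, u0=u, n_increments=1,
            linear_solver=linear_solver, best_effort=(not final) or (not strict),
        )
        u = state.u
    max_force = float(np.max(np.abs(state.beam_forces[:, 0]))) if network.n_beams else 0.0
    if max_force > network.materials.filament_yield_force:
        warnings.warn(
            f"form-found axial force {max_force:.3g} nN exceeds the filament "
            f"yield force {network.materials.filament_yield_force} nN",
            YieldExceededWarning,
        )
    if network.n_cables:
        x = network.nodes + state.displacements
        d = x[network.cables[:, 1]] - x[network.cables[:, 0]]
        l_now = np.hypot(d[:, 0], d[:, 1])
        d0 = network.nodes[network.cables[:, 1]] - network.nodes[network.cables[:, 0]]
        l_gen = np.hypot(d0[:, 0], d0[:, 1])
        max_elong = float(np.max(l_now - l_gen))
    else:
        max_elong = 0.0
    # fresh solves report displacement from the generated geometry; warm
    # re-runs report the additional displacement from the supplied state
    du = state.u - u0 if warm else state.u
    disp_norm = float(np.linalg.norm(du.reshape(-1, 3)[:, :2]))
    return FormFindingResult(
        network=network,
        state=state,
        prestress=P,
        max_filament_force=max_force,
        max_cable_elongation=max_elong,
        displacement_norm=disp_norm,
    )


def prestress_sensitivity(
    network: NetworkModel,
    prestress_levels: Sequence[float],
    settings: Optional[SolverSettings] = None,
    measurement_strain: float = 0.01,
    linear_solver=None,
):
    """Effective modulus at each pre-stress level on one realization.

    Returns ``(table, relative_spread)`` where table is a list of
    ``(prestress, modulus)`` pairs and the spread is (max−min)/min.
    """
    from .experiments import stretch_modulus  # local import: avoids module cycle

    settings = settings or SolverSettings()
    table = []
    for P in prestress_levels:
        ff = run_form_finding(network, prestress=P, settings=settings,
                              linear_solver=linear_solver)
        E = stretch_modulus(ff, settings, measurement_strain=measurement_strain,
                            linear_solver=linear_solver)
        table.append((float(P), float(E)))
    mods = [E for _, E in table]
    spread = (max(mods) - min(mods)) / min(mods) if len(mods) > 1 else 0.0
    return table, spread
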