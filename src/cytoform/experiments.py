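"""Virtual mechanical experiments on a form-found network.

Uniaxial extension under displacement control: nodes in a band at the
left edge are held at their form-found longitudinal position, nodes in
the band at the right edge are displaced by ε·W, lateral translations
and rotations stay free (σ_y = 0 plane-stress condition).  The effective
Young's modulus follows from Hooke's law

    E = (σx² − σy²) / (σx εx − σy εy)

which reduces to σx/εx with σy = 0; σx is the summed edge reaction over
the undeformed cross-section (domain height × thickness), so in μm–nN
units E is in kPa.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .config import MaterialTable, SolverSettings
from .fecore import (
    BoundaryConditions,
    FESystem,
    NonConvergenceError,
    SystemState,
    solve_equilibrium,
    strain_energy,
)
from .formfind import FormFindingResult
from .model import NetworkModel

DEFAULT_EDGE_BAND = 0.02  # fraction of domain width
ENERGY_FLOOR = 1e-18  # nN·μm; filaments below this total are "unstrained"


class EmptyBoundaryError(RuntimeError):
    """An edge band contains no nodes (degenerate low-density network)."""


@dataclass
class StretchResult:
    """Measured response of one network at one strain level."""

    strain_level: float
    reaction_force: float  # nN, summed x-reactions on the displaced edge
    sigma_x: float  # kPa
    sigma_y: float  # kPa (0: lateral edges are traction-free)
    epsilon_y: float
    effective_modulus: float  # kPa
    segment_angles: np.ndarray  # degrees, folded to [0, 90]
    energy_fractions: np.ndarray  # per-filament SE_axial / SE_total
    yielded_beams: int
    yielded_cables: int
    state: SystemState = field(repr=False, default=None)


def edge_bands(
    network: NetworkModel, band: float = DEFAULT_EDGE_BAND
) -> tuple[np.ndarray, np.ndarray]:
    """Node indices within ``band``·W of the left and right domain edges."""
    w = network.config.domain_width
    x = network.nodes[:, 0]
    left = np.flatnonzero(x <= band * w)
    right = np.flatnonzero(x >= (1.0 - band) * w)
    if len(left) == 0 or len(right) == 0:
        raise EmptyBoundaryError(
            f"edge band of {band:.0%} domain width contains no nodes "
            f"(left: {len(left)}, right: {len(right)})"
        )
    return left, right


def _stretch_bc(
    network: NetworkModel,
    u_ff: np.ndarray,
    strain: float,
    band: float,
) -> BoundaryConditions:
    left, right = edge_bands(network, band)
    w = network.config.domain_width
    ux_ff = u_ff[0::3]
    dofs = np.concatenate([3 * left, 3 * right])
    vals = np.concatenate([ux_ff[left], ux_ff[right] + strain * w])
    # one lateral pin removes the remaining rigid y-translation; the node
    # nearest mid-height on the fixed edge perturbs sigma_y = 0 least
    ymid = network.config.domain_height / 2.0
    pin = left[np.argmin(np.abs(network.nodes[left, 1] - ymid))]
    dofs = np.append(dofs, 3 * pin + 1)
    vals = np.append(vals, u_ff[3 * pin + 1])
    return BoundaryConditions(dofs.astype(np.int64), vals)


def uniaxial_stretch(
    ff: FormFindingResult,
    target_strain: float,
    settings: Optional[SolverSettings] = None,
    checkpoints: Optional[Sequence[float]] = None,
    band: float = DEFAULT_EDGE_BAND,
    cable_mode: str = "constant_force",
    linear_solver=None,
    strict: bool = True,
) -> list[tuple[float, SystemState]]:
    """Displacement-controlled extension of a form-found network.

    Returns the trajectory ``[(strain, state), ...]`` at the requested
    checkpoints (always starting from the form-found state at strain 0).
    Cross-linkers keep carrying the constant pre-stress by default — the
    behavior that reproduces the reported network moduli; the ``elastic``
    mode (tension = pre-stress + k·strain from the form-found reference
    length, slack when negative) is available for sensitivity studies.
    """
    settings = settings or SolverSettings()
    if target_strain < 0:
        raise ValueError("target_strain must be non-negative")
    network = ff.network
    system = FESystem(
        network,
        cable_mode=cable_mode,
        prestress=ff.prestress,
        cable_ref_lengths=ff.formfound_cable_lengths if network.n_cables else None,
    )
    if checkpoints is None:
        checkpoints = [target_strain]
    checkpoints = sorted({float(c) for c in checkpoints} | {0.0})
    if max(checkpoints) < target_strain:
        checkpoints.append(target_strain)

    traj: list[tuple[float, SystemState]] = [(0.0, ff.state)]
    if linear_solver is not None and cable_mode != "constant_force":
        linear_solver.invalidate()  # cable law changed from the form-finding stage
    u = ff.state.u
    prev = 0.0
    for eps in checkpoints:
        if eps <= 0.0:
            continue
        n_inc = max(1, int(np.ceil((eps - prev) / settings.max_strain_increment)))
        bc = _stretch_bc(network, ff.state.u, eps, band)
        state = None
        for attempt in range(3):  # sub-incrementation fallback
            try:
                state = solve_equilibrium(
                    system, bc, settings, u0=u, n_increments=n_inc,
                    linear_solver=linear_solver, best_effort=not strict)
                break
            except NonConvergenceError:
                if attempt == 2:
                    raise
                n_inc *= 4
        traj.append((eps, state))
        u = state.u
        prev = eps
    return traj


def hooke_plane_stress(sx: float, sy: float, ex: float, ey: float) -> float:
    """General plane-stress Hooke's-law modulus (σx²−σy²)/(σx εx − σy εy)."""
    denom = sx * ex - sy * ey
    if denom == 0.0:
        raise ZeroDivisionError("zero strain-energy denominator in Hooke's law")
    return (sx**2 - sy**2) / denom


def measure_stretch(
    ff: FormFindingResult,
    state: SystemState,
    strain: float,
    band: float = DEFAULT_EDGE_BAND,
    cable_mode: str = "constant_force",
) -> StretchResult:
    """Extract stresses, modulus, orientations and energy split at one strain."""
    network = ff.network
    system = FESystem(
        network,
        cable_mode=cable_mode,
        prestress=ff.prestress,
        cable_ref_lengths=ff.formfound_cable_lengths if network.n_cables else None,
    )
    _, right = edge_bands(network, band)
    f_int = system.internal_force(state.u)
    reaction = float(np.sum(f_int[3 * right]))
    area = network.config.domain_height * network.config.domain_thickness
    sigma_x = reaction / area
    modulus = sigma_x / strain if strain > 0 else float("nan")

    x_ff = ff.equilibrated_coordinates
    x_now = state.coordinates(network.nodes)
    h0 = network.config.domain_height
    eps_y = ((x_now[:, 1].max() - x_now[:, 1].min())
             - (x_ff[:, 1].max() - x_ff[:, 1].min())) / h0

    angles = orientation_angles(network, state)
    se_ax, se_bend = strain_energy(network, state, system)
    total = se_ax + se_bend
    mask = total > ENERGY_FLOOR
    fractions = se_ax[mask] / total[mask]
    nb_yield, nc_yield = yield_screen(state, network.materials)
    return StretchResult(
        strain_level=strain,
        reaction_force=reaction,
        sigma_x=sigma_x,
        sigma_y=0.0,
        epsilon_y=float(eps_y),
        effective_modulus=modulus,
        segment_angles=angles,
        energy_fractions=fractions,
        yielded_beams=nb_yield,
        yielded_cables=nc_yield,
        state=state,
    )


def effective_modulus(result: StretchResult) -> float:
    """Effective Young's modulus in kPa from a small-strain stretch."""
    if result.strain_level == 0:
        raise ZeroDivisionError("effective modulus undefined at zero strain")
    return hooke_plane_stress(
        result.sigma_x, result.sigma_y, result.strain_level, result.epsilon_y
    )


def stretch_modulus(
    ff: FormFindingResult,
    settings: Optional[SolverSettings] = None,
    measurement_strain: float = 0.01,
    band: float = DEFAULT_EDGE_BAND,
    cable_mode: str = "constant_force",
    linear_solver=None,
    strict: bool = True,
) -> float:
    """Secant modulus at the measurement strain (default 1%)."""
    traj = uniaxial_stretch(
        ff, measurement_strain, settings, band=band, cable_mode=cable_mode,
        linear_solver=linear_solver, strict=strict,
    )
    res = measure_stretch(
        ff, traj[-1][1], measurement_strain, band=band, cable_mode=cable_mode
    )
    return res.effective_modulus


def orientation_angles(network: NetworkModel, state: SystemState) -> np.ndarray:
    """Angle of each deformed segment chord to the +x axis, folded to [0°, 90°]."""
    x = state.coordinates(network.nodes)
    d = x[network.beams[:, 1]] - x[network.beams[:, 0]]
    ang = np.degrees(np.arctan2(d[:, 1], d[:, 0])) % 180.0
    return np.where(ang > 90.0, 180.0 - ang, ang)


def orientation_histogram(
    network: NetworkModel, state: SystemState, bins: int = 9
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of folded segment orientations over [0°, 90°]."""
    return np.histogram(orientation_angles(network, state), bins=bins, range=(0, 90))


def energy_partition_histogram(
    network: NetworkModel,
    state: SystemState,
    bins: int = 10,
    floor: float = ENERGY_FLOOR,
):
    """Distribution of per-filament axial energy fraction SE_axial/SE_total.

    Filaments whose total strain energy is below ``floor`` are excluded
    from the histogram and returned as a separate count.
    """
    se_ax, se_bend = strain_energy(network, state)
    total = se_ax + se_bend
    mask = total > floor
    fractions = se_ax[mask] / total[mask]
    counts, edges = np.histogram(fractions, bins=bins, range=(0.0, 1.0))
    return fractions, counts, edges, int(np.sum(~mask))


def yield_screen(state: SystemState, materials: MaterialTable) -> tuple[int, int]:
    """Count elements whose tensile force strictly exceeds its yield value."""
    nb = int(np.sum(state.beam_forces[:, 0] > materials.filament_yield_force))
    nc = int(np.sum(state.cable_tensions > materials.crosslinker_yield_force))
    return nb, nc
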