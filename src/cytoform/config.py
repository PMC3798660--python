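"""Configuration objects for network generation, materials and the solver.

Internal unit system: micrometres (μm) for length, nanonewtons (nN) for
force, hence nN/μm² for stress.  One nN/μm² equals one kPa, so effective
moduli computed from edge reactions come out in kPa with no conversion.
"""

from __future__ import annotations

import math
from typing import Literal, Optional, Sequence

from pydantic import BaseModel, ConfigDict, Field, model_validator


class GenerationConfig(BaseModel):
    """Geometry and sampling parameters for random network generation.

    Defaults describe a 10 μm × 10 μm × 1 μm slab of cortical actin:
    filament lengths 5 ± 2 μm (truncated Gaussian), binding sites every
    0.3 ± 0.06 μm along each filament, cross-linkers attaching any two
    binding sites on distinct filaments closer than 0.3 μm.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    domain_width: float = Field(default=10.0, gt=0, description="μm")
    domain_height: float = Field(default=10.0, gt=0, description="μm")
    domain_thickness: float = Field(
        default=1.0, gt=0, description="μm; used only for volume/stress normalization"
    )
    filament_length_mean: float = Field(default=5.0, gt=0, description="μm")
    filament_length_std: float = Field(default=2.0, gt=0, description="μm")
    segment_length_mean: float = Field(default=0.3, gt=0, description="μm")
    segment_length_std: float = Field(default=0.06, gt=0, description="μm")
    filament_diameter: float = Field(default=0.007, gt=0, description="μm")
    target_relative_density: float = Field(
        default=0.002, gt=0, le=0.01, description="filament volume fraction"
    )
    max_crosslinker_length: float = Field(default=0.3, gt=0, description="μm")
    crosslink_rule: Literal["site_matching", "all_pairs"] = Field(
        default="site_matching",
        description=(
            "site_matching: every binding site hosts at most one cross-linker "
            "(nearest eligible partner first); all_pairs: every eligible "
            "site pair is linked"
        ),
    )
    crosslink_fraction: float = Field(
        default=1.0, gt=0, le=1.0,
        description="probability that a candidate cross-linker is actually connected",
    )
    seed: int = Field(default=0, ge=0)

    @model_validator(mode="after")
    def _domain_exceeds_filaments(self) -> "GenerationConfig":
        dmin = min(self.domain_width, self.domain_height)
        if dmin <= self.filament_length_mean:
            raise ValueError(
                "domain dimensions must exceed the mean filament length "
                f"({dmin} <= {self.filament_length_mean}); filaments must fit "
                "inside the domain (length draws longer than the domain are rejected)"
            )
        return self

    @property
    def max_filament_length(self) -> float:
        """Longest filament that can be translated inside the domain."""
        return min(self.domain_width, self.domain_height)

    @property
    def domain_volume(self) -> float:
        return self.domain_width * self.domain_height * self.domain_thickness


class MaterialTable(BaseModel):
    """Elastic and yield properties of filaments and cross-linkers.

    The filament is a uniform circular rod: its section area and second
    moment are always derived from the diameter, never stored.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    filament_modulus: float = Field(
        default=1.4e6, gt=0, description="nN/μm² (1.4e6 nN/μm² = 1.4 GPa)"
    )
    filament_diameter: float = Field(default=0.007, gt=0, description="μm")
    filament_yield_force: float = Field(default=0.25, gt=0, description="nN")
    crosslinker_yield_force: float = Field(default=0.060, gt=0, description="nN")
    crosslinker_prestress: float = Field(default=0.003, gt=0, description="nN")
    crosslinker_axial_stiffness: float = Field(
        default=0.6, gt=0,
        description="nN per unit strain; default reaches the 60 pN yield at 10% strain",
    )

    @model_validator(mode="after")
    def _prestress_below_yield(self) -> "MaterialTable":
        if self.crosslinker_prestress > self.crosslinker_yield_force:
            raise ValueError(
                "crosslinker_prestress must not exceed crosslinker_yield_force"
            )
        return self

    @property
    def filament_area(self) -> float:
        """Cross-section area π d²/4 in μm²."""
        return math.pi * self.filament_diameter**2 / 4.0

    @property
    def filament_I(self) -> float:
        """Second moment of area π d⁴/64 in μm⁴."""
        return math.pi * self.filament_diameter**4 / 64.0

    @property
    def filament_EA(self) -> float:
        return self.filament_modulus * self.filament_area

    @property
    def filament_EI(self) -> float:
        return self.filament_modulus * self.filament_I


class SolverSettings(BaseModel):
    """Newton solver controls for equilibrium analyses.

    ``residual_tolerance`` is relative to a characteristic internal force
    (the largest element force magnitude in the current state, floored at
    the cross-linker pre-stress scale).  ``regularization`` adds a weak
    spring (nN/μm) from every translational DOF to its anchor position so
    floppy mechanisms (filaments dangling from a single cross-linker)
    stay bounded; it is small enough not to influence converged forces.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    residual_tolerance: float = Field(default=1e-6, gt=0, description="relative")
    max_newton_iterations: int = Field(default=40, ge=1)
    n_increments: int = Field(default=10, ge=1)
    regularization: float = Field(default=1e-6, ge=0, description="nN/μm")
    max_strain_increment: float = Field(
        default=0.05, gt=0, description="strain per load step during stretching"
    )
    wall_clock_limit: float = Field(
        default=0.0, ge=0,
        description="seconds per equilibrium solve; 0 = unlimited. Bounded "
                    "solves exit best-effort (or raise when strict), trading "
                    "bit-reproducibility across machines for a hard runtime",
    )
    verbose: bool = Field(default=False, description="log increments and residuals")
    units: Literal["um-nN"] = "um-nN"


class EnsembleSpec(BaseModel):
    """A seeded Monte-Carlo sweep over one generation parameter."""

    model_config = ConfigDict(extra="forbid")

    base_config: GenerationConfig = Field(default_factory=GenerationConfig)
    materials: MaterialTable = Field(default_factory=MaterialTable)
    solver: SolverSettings = Field(default_factory=SolverSettings)
    n_samples: int = Field(default=20, ge=2)
    master_seed: int = Field(default=0, ge=0)
    sweep_variable: Optional[
        Literal[
            "relative_density",
            "filament_length",
            "crosslink_fraction",
            "domain_size",
            "prestress",
        ]
    ] = None
    sweep_values: Sequence[float] = ()
    measurement_strain: float = Field(default=0.01, gt=0)

    @model_validator(mode="after")
    def _sweep_consistent(self) -> "EnsembleSpec":
        if self.sweep_variable is not None and len(self.sweep_values) == 0:
            raise ValueError("sweep_values required when sweep_variable is set")
        return self
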