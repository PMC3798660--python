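# Methods

## Model

`cytoform` simulates the elasticity of two-dimensional cross-linked actin
networks by equilibrium form-finding. A realization is built in four
stages:

1. **Filament placement.** Straight filaments with truncated-Gaussian
   lengths (default 5 ± 2 μm; draws below zero or longer than the domain
   are redrawn) are dropped uniformly at random (centroid x, y and angle
   θ ∈ [0, 2π)) onto a rectangular domain (default 10 μm × 10 μm × 1 μm
   for volume and stress normalization). A filament whose endpoint falls
   outside the domain is rigidly translated back inside by the minimal
   axis-aligned shift per axis; angle and length are untouched. Placement
   stops as soon as the filament volume fraction
   ρ = Σᵢ (π d²/4) Lᵢ / V reaches its target (default 0.2%); the
   filament that crosses the threshold is kept and the achieved density
   recorded.
2. **Segmentation.** Each filament is divided into segments with
   truncated-Gaussian lengths (0.3 ± 0.06 μm). Drawing stops when the
   remainder is no longer than the mean segment length; a final remainder
   shorter than half the mean merges into the previous segment so no
   near-zero-length elements enter the stiffness matrix. Segment ends are
   nodes and cross-linker binding sites; each segment is one beam finite
   element.
3. **Cross-linking.** Candidate cross-linkers are all unordered binding
   site pairs on distinct filaments strictly closer than the maximum
   cross-linker length (0.3 μm), found with a k-d tree (identical to
   brute force, verified in the tests). Two connection rules are
   provided. Under the default `site_matching` rule each binding site
   hosts at most one cross-linker — a bound cross-linking protein
   occupies its site — realized as a greedy maximal matching, nearest
   pairs first. Under `all_pairs` every candidate becomes a cable. The
   all-pairs reading produces ~50 cross-linkers per binding site at
   baseline densities (≈ 490 000 cables on a 10 μm domain at ρ = 0.2%),
   which is biologically implausible for protein occupancy; the
   one-per-site rule yields about one cable per two sites. Finally, each
   cable is retained independently with probability f (the cross-linker
   density fraction, default 1).
4. **Materials.** Filaments are linear-elastic circular rods,
   E = 1.4 GPa, d = 7 nm, so in the internal μm–nN unit system
   EA = 53.88 nN and EI = 1.650 × 10⁻⁴ nN·μm². One nN/μm² equals one
   kPa, so effective stresses come out in kPa natively. Tensile yield
   values (0.25 nN for a filament segment, 60 pN for a cross-linker) are
   used for exceedance flagging only; the analysis stays elastic.

## Finite elements

Filament segments are 2-node corotational Euler–Bernoulli beams (3 DOF
per node). The corotational split removes the rigid chord rotation, so
large rotations are handled with a linear-elastic local law:
N = EA (ℓ−ℓ₀)/ℓ₀, M₁ = (2EI/ℓ₀)(2θ̄₁+θ̄₂), M₂ = (2EI/ℓ₀)(θ̄₁+2θ̄₂).
The consistent material + geometric tangent is verified against finite
differences to 10⁻⁵ relative in the test suite, as is the property that
the internal forces are the exact gradient of the potential energy.

Cross-linkers are tension-only cables in one of two modes:

- **constant-force** (form-finding): tension equals the pre-stress P
  regardless of length. The potential P·ℓ is smoothed to
  P·√(ℓ²+ε²) with ε = 1 nm because cross-linkers genuinely collapse to
  zero length during form-finding and the raw potential has a gradient
  discontinuity there (the equilibrium iteration otherwise stalls at a
  residual of order P·√n_collapsed). ε is three orders of magnitude
  below the segment scale; tensions deviate from P only within a few nm
  of site coincidence.
- **elastic** (stretching): tension = P + k·(λ−λ₀)/ℓ₀ₑ when positive,
  slack otherwise, with k the axial stiffness per unit strain
  (default 0.6 nN, chosen so a cross-linker reaches its 60 pN yield at
  10% strain — the cross-linker stretching stiffness is a free parameter
  of the model, exposed in the material table). Three numerical
  regularizations make this law C²: the length enters through the same
  smoothed measure λ = √(ℓ²+ε²) (a cross-linker collapsed in
  form-finding would otherwise be taut at zero length with an undefined
  force direction); the strain denominator ℓ₀ₑ = max(ℓ₀, 0.03 μm) is
  floored (a linker whose form-found chord collapsed to nanometres is a
  slack protein, not a spring of divergent stiffness); and the
  tension-only ramp max(z, 0) is smoothed as (z+√(z²+δ²))/2 with
  δ = 10⁻⁵ nN, removing the slack/taut kink that otherwise stalls the
  equilibrium iteration exactly at the transition. All three leave
  ordinary (non-collapsed) cross-linkers unchanged to better than 0.1%.

## Form-finding

Form-finding applies the constant cross-linker pre-stress (default 3 pN,
5% of the cross-linker yield force) and finds the nearest stable
equilibrium. Because the pre-stress potential is non-coercive along
mechanism directions (a filament held by a single linker can translate
freely while the energy decreases linearly), the solve is posed as an
energy minimization: Levenberg–Marquardt-damped Newton with an Armijo
backtracking line search on the total potential, an absolute floor on
the damping diagonal so soft DOFs are bounded too, and weak springs
(`regularization`, nN/μm) anchoring translations to the starting
configuration.

Pre-stress ramping is ineffective as a continuation strategy here —
pure cable loading scales almost uniformly with P, so every ramp step is
as nonlinear as the last. Instead the solver anneals the smoothing
length ε from the cross-linker length scale down to its final 1 nm over
`n_increments` geometric stages (soft quadratic springs → sharp constant
forces), warm-starting each stage from the last, with loose intermediate
tolerances and a strong-to-weak regularization schedule (10⁻² → the
configured value) that suppresses the soft-mode wandering early. Only
the final stage is converged to the full residual tolerance. Rigid-body
modes are removed by a minimal pin set per connected component (both
translations of the node nearest the component centroid plus one
well-chosen translation of the most distant node); components without
cables carry no load and are fixed wholesale.

The form-found configuration keeps the generated geometry as the beam
reference (so beams retain their form-found internal forces), and the
cables switch to the elastic law with the form-found chord as the new
reference length.

Equilibria of these networks are glassy: many cross-linkers collapse,
filament segments buckle and snap between nearly degenerate local
minima. The damped-Newton/annealing scheme converges robustly on small
and moderate networks; on paper-scale baselines (≈ 18 000 nodes) a
realization costs minutes of CPU even with the specialized linear
algebra below, which is what limits the ensemble sizes used in the
bundled analyses.

## Linear algebra

The assembled tangent of a fiber network is hostile to generic sparse
solvers: long filaments cross any geometric cut, so separators are wide,
and the default COLAMD/MMD orderings in SuperLU produce pathological
fill (minutes per factorization). The package orders the matrix by its
own nested dissection — recursive spatial bisection whose separator
contains only the cut-side endpoints of edges actually crossing the
cut — and factors with the natural ordering in symmetric mode. Small
systems (≤ 12 000 DOF) are factored directly at every Newton step.
Large systems factor the free-DOF submatrix once and reuse it as a
frozen GMRES preconditioner across Newton steps, load stages, and the
form-finding → stretching transition, rebuilding only when a sweep of
GMRES fails; a factorization built in the current step is applied as a
direct solve. (A factorization of the full regularized matrix restricted
to the free DOF is *not* a usable preconditioner: the few pinned DOF
couple through the soft global modes with large magnitude.) Inexact
Newton forcing is two-level: crude solves (10⁻¹) far from equilibrium —
where the energy line search guards descent — and tight solves (3×10⁻⁷)
in the endgame.

## Virtual experiments

Uniaxial extension is displacement-controlled: nodes within an edge band
(2% of the domain width) of the left edge keep their form-found
longitudinal position, right-band nodes are displaced by ε·W, lateral
translations and rotations stay free everywhere (σ_y = 0), and one
lateral pin at the mid-height of the fixed edge removes the remaining
rigid translation. The effective Young's modulus follows from the
plane-stress Hooke's law E = (σx²−σy²)/(σxεx−σyεy), which reduces to
σx/εx with σy = 0; σx is the summed reaction on the displaced band over
the undeformed cross-section (height × thickness). The modulus is a
secant value at 1% strain by default (configurable; the sensitivity can
be documented by measuring at 0.5/1/2%). Strain is applied in increments
of at most `max_strain_increment`, with automatic sub-incrementation on
non-convergence. Larger extensions (50%, 100%) for re-orientation
studies run through the same path with checkpointed states.

Per-beam segment orientations are chord angles folded to [0°, 90°].
Strain energies per beam are SE_axial = N²ℓ₀/(2EA) and
SE_bending = (M₁²−M₁M₂+M₂²)ℓ₀/(6EI) (exact for the element's linear
moment interpolation), summed per filament; filaments below a 10⁻¹⁸
nN·μm total are excluded from the axial-fraction histogram and counted
separately.

## Monte-Carlo ensembles

Ensembles derive per-sample seeds from
SeedSequence([master_seed, point_index, sample_index, attempt]), so
results are independent of execution order and bit-reproducible. Failed
samples are retried twice with fresh seeds and recorded, never silently
dropped; a sweep point aborts if more than 10% of its samples fail.
Sweeps are provided over filament relative density, filament length
(standard deviation locked at 20% of the mean, matching the 0.6→6.0 μm /
0.12→1.2 μm protocol), cross-linker retention fraction, domain size, and
pre-stress. Ensemble statistics use the n−1 sample standard deviation.
For large-network ensembles the pipeline runs in a reduced-fidelity
profile (loose residual tolerances, capped iteration counts, best-effort
intermediate states); the residual force this leaves in the network is
orders of magnitude below the measured edge reactions.

## What the generator does and does not emulate

The generator reproduces the Mikado-class geometry of cortical actin —
straight rods, uniform orientation, proximity cross-linking at periodic
binding sites — under the stated parameter values. It does not model
filament polymerization or turnover, cross-linker binding kinetics
(the constant pre-stress only mimics the force state of a bound
protein), bundling, three-dimensional architecture, or the biochemical
feedback that produces perpendicular re-orientation in living cells.
Passing tests therefore demonstrate the mechanics of the idealized
two-dimensional network, not fidelity to any particular experimental
cytoskeleton.

## Degenerate inputs and tie-breaks

Binding-site pairs exactly at the maximum cross-linker length are not
connected (strict inequality). Duplicate cables per unordered node pair
are impossible by construction. In the site-matching rule, equal
distances are broken by node id. A filament shorter than the mean
segment length becomes a single segment. Networks with disconnected
components are flagged in the model metadata; each component gets its
own pins during form-finding.

## Known limitations

- Form-finding cost grows quickly with network size; paper-scale
  ensembles are computationally heavy (minutes per realization), so the
  bundled acceptance analyses run few samples per condition and the
  heavier conditions at reduced sample counts.
- The reported equilibria of large networks are best-effort minima of a
  glassy landscape: re-running with a different annealing schedule can
  settle a realization into a slightly different local minimum. Ensemble
  means are insensitive to this; individual realizations are not.
- The cross-linker stretching stiffness is not constrained by the model
  inputs; all stiffness results depend on its chosen default.
- Chord-rotation wrap limits single-increment rotations to below 180°;
  the incremental drivers keep well clear of this.
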