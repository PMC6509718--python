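# Methods

## Model

`microperm` computes the tissue-scale (Darcy) permeability tensor of a 3D
microvascular network by solving Poiseuille network flow under an imposed
macroscopic pressure gradient and measuring the resulting surface fluxes.
The assumptions are those of continuum homogenization applied to a
discrete vessel graph:

* laminar, axial, steady flow in every segment (Poiseuille's law with
  conductance g = πr⁴/(8μl); no junction losses, no compliance, no
  pulsatility);
* blood treated per segment as a Newtonian fluid whose apparent viscosity
  follows the empirical in-vitro law (diameter and discharge hematocrit
  dependent) or a fixed Newtonian value for validation fixtures;
* spatial periodicity of the microstructure, imposed by mirroring (below);
* blind ends carry no flow and may be removed.

### Mirroring

Anatomical networks are not periodic, so the subnetwork's occupied volume
is reflected across its upper x, then y, then z faces. The result is a
domain of doubled extents containing 8 flipped copies in which every
lateral-face node has an exact periodic partner on the opposite face.
Nodes lying on a mirror plane (within `face_tol`, default 1 μm ≈ one
z-voxel of typical confocal data) merge with their own image. The package
validates the construction by mirroring a mirrored network again: the
tensor must be unchanged (the suite enforces ≤ 10⁻⁸ relative).

### Pressure solve

For gradient direction i: Dirichlet pressures L_i·∇p / 0 on the two faces
normal to i (L_i = mirrored extent, ∇p = 1 Pa/μm by default — the tensor
is gradient-invariant by linearity, which is itself a test); each lateral
periodic pair merged into one unknown; Kirchhoff's law at every junction.
The symmetric positive-definite sparse system is solved by direct
factorization (conjugate gradients above 2×10⁵ unknowns, tolerance
10⁻¹⁰). Components not touching a Dirichlet face are pinned to p = 0 and
carry no flow; a direction the network does not span legitimately yields a
zero tensor row, not an error. Radii below 0.1 μm are clamped to 0.1 μm in
the conductance to avoid underflow.

Tensor entries are k_ij = (Σ flux through outflow face j)/(S_j ∇p^i), with
S_j and extents taken from the mirrored domain; by reflection symmetry
this equals the original unit's tensor. Internal units are μm, Pa, μm³/s;
k is converted from μm²/(Pa·s) to the reported mm³·s/kg (factor 10⁻³).
A subnetwork that is geometrically flat along an axis (a single tube has
no transverse extent) is assigned the full parent-box extent along that
axis, since a line has no cross-sectional area of its own.

## Rheology

Constant-hematocrit mode assigns every segment the inlet discharge
hematocrit (default 0.4) and the in-vitro viscosity at its diameter,
scaled by the plasma viscosity (default 1.2 mPa·s; the tensor scales
inversely with it). `fixed_viscosity` overrides everything with one
Newtonian value — used by every closed-form oracle (μ = 1 mPa·s).

Phase-separation mode iterates flow solve ↔ hematocrit propagation.
Propagation visits nodes in topological order of flow direction (flow
descends pressure, so the oriented graph is acyclic up to numerical ties;
a tie-induced cycle falls back to descending-throughflow order with a
warning). Converging nodes mix red cells conservatively
(H_out = Σ|Q|H / Σ|Q|); diverging bifurcations split erythrocyte flux by
the empirical logit law in feed diameter, daughter diameter ratio, feed
hematocrit and flow fraction, including the zero-flux cutoff X₀; splits
with more than two daughters — for which the law is undefined — are
flow-proportional. A daughter that would exceed H = 1 is capped with the
excess red-cell flux diverted to its sibling, preserving conservation.
The update is damped (λ = 0.5) and iterated until max |ΔH| < 10⁻⁴ or 100
passes (the scheme parameters are package choices; the damped iteration
and the tight-tolerance brute-force fixed point agree in the tests).
Boundary inflows enter at the inlet hematocrit.

## Preprocessing anatomical networks

Pipeline order: connected-component labeling → density filter →
border-end elongation → blind-end pruning → representative-volume gate.

* **Density filter**: components holding ≥ 15% (inclusive) of the total
  vascular volume are retained. Vascular density is implemented as the
  cylinder-volume fraction Σπr²l — the graph analogue of image vascular
  density, since graph input has no voxels.
* **Elongation**: degree-1 nodes within ε = 5 μm of a domain face are
  translated onto the face along the normal (segment length grows by the
  displacement) so genuine border vessels are not pruned as blind ends;
  ties between faces break toward the lower axis index for determinism.
* **Pruning**: segments hanging off interior degree-1 nodes are removed
  iteratively until none remain (idempotent; face-tagged ends survive).
  The volume ratio V_pruned/V_init is recorded per subnetwork.
* **REV gate**: homogenization needs a large-enough unit; subnetworks
  whose post-pruning bounding box spans < 170 μm (inclusive cutoff) along
  x or y are excluded. z is ungated because sample thickness (~100 μm) is
  inherently below the cutoff.
* No gap-closing/reconnection: disconnections may be pathology-related
  and are preserved.

## Fusion and sorting

The volume tensor is the surface-weighted sum of subnetwork tensors:
w_j(cc) = S_j(cc) / (ΣS_j − Σ pairwise projected overlaps), where S_j(cc)
is the subnetwork's bounding-box face area normal to j and overlaps are
axis-aligned projected bbox intersections (pairwise only; higher-order
overlaps are not subtracted). Each term is additionally multiplied by
V_init/V_pruned (≥ 1) to compensate for conductivity lost with the blind
ends; disabling the scale reproduces the unscaled variant. Limiting cases
used as tests: one subnetwork → identity; equal disjoint boxes → the
arithmetic mean; coincident boxes → the sum (parallel conductivities).
Finally the axes are sorted so k11 ≥ k22 ≥ k33 via a simultaneous
row+column permutation (eigenvalues preserved; ties keep x,y,z order),
because volume orientation relative to the organ is arbitrary in confocal
data.

The REV scan partitions the domain along x–y into square units (z whole),
cutting vessels at unit borders exactly as image decomposition would, and
runs the full pipeline per unit, reporting per-unit tensors and medians.

## Perfusion

MBF = k_ii · Δp · 0.133×10⁻³ · 60 · 100 / (ρ l²), reported in mL/min per
100 g. Defaults: Δp = 19.5 mm Hg (physiological AV drop), l = 512 μm (pig
AV path mean; 349/675 are mean∓SD), ρ = 1.05 g/cm³ (standard myocardium;
configurable — the exact density used in prior work is not printed, so it
is exposed as a parameter and echoed in output). The AV path length is
assumed condition-independent. The inversion Δp(MBF, k) is the exact
algebraic inverse; Δp scales as l² at fixed MBF and k.

## Remodeling scenarios

Six modes on a preprocessed subnetwork: dilate/constrict all radii by a
fraction; dilate/constrict a seeded uniformly random subset (without
replacement; fraction counted over segments); a diameter-dependent
dilation profile, linear from the full response at d = 0.4 μm to zero at
d = 20 μm (smaller vessels dilate more); and pruning of the ⌊fraction·n⌋
smallest-radius segments (ties by id) followed by blind-end re-pruning.
With constant viscosity, uniform dilation/constriction changes every
diagonal by exactly (1±f)⁴ − 1 (+46.41% for +10%, −75.99% for −30%); with
the viscosity law active, constriction loses strictly more, because
narrowing capillaries also raises their apparent viscosity. Scenario
randomness is governed by an explicit recorded seed.

## Synthetic networks

* **Closed-form fixtures.** Single tube: k11 = πr⁴/(8μL²), other entries
  zero. Parallel tubes: conductivities add. Cubic lattice: built staggered
  — grid planes at half-pitch offsets with stubs to the faces — so the
  mirrored lattice is exactly periodic (one tube per s² in every
  direction, no tube lying inside a face plane) and the diagonal equals
  πr⁴/(8μs²) to solver precision; a conventional grid with nodes on the
  faces would double-count boundary tubes under mirroring.
* **Random capillary beds** emulate the scale of anatomical data
  (~10²–10³ segments, boxes 100–400 μm, multiple components, blind ends):
  a jittered staggered lattice (uniform ±5 μm on interior coordinates),
  log-normal radii (median 4 μm, σ_log = 0.3, capillary-dominated),
  deletions that provably create interior blind ends (random interior
  nodes stripped to degree 1), and a detached corner block providing a
  secondary component. Generation is bit-reproducible per seed and
  retries (up to 10, shifted seeds) if no component spans the x faces.
* **Infarct-like perturbation**: a seeded fraction of vessels enlarged by
  a factor, plus deletion of a seeded fraction drawn from the
  below-median-radius half — the larger-vessels/capillary-loss phenotype.

What the generators do *not* reproduce: anatomical tortuosity beyond
jitter, anisotropic capillary alignment, degree distributions of real
beds, or matched morphometrics of any particular data set. Passing tests
therefore demonstrate correctness of the numerics and contracts on
realistic problem sizes, not agreement with any animal's measured values.

## Problem sizes and numerical choices

Tests and the acceptance script use boxes of 100–400 μm with lattice pitch
25–50 μm (≈10²–10³ segments; mirrored systems up to ~5×10⁴ unknowns),
sizes at which direct sparse factorization is exact and fast while
exercising every code path. Tolerances: solver 10⁻¹⁰; double-mirroring
10⁻⁸; closed forms 10⁻⁹ (tube) and 2% (lattice, conservative); hematocrit
iteration 10⁻⁴ with damping 0.5. Degenerate inputs: self-loops and
non-positive radii/lengths are rejected at construction; zero-flow
segments keep their hematocrit; empty-after-pruning subnetworks are
flagged and excluded; a fusion with non-positive corrected surface is an
error.

## Known limitations

* The printed unit for k, mm³·s/kg, is the dimensionally consistent
  reading of flux/(area × gradient); plasma viscosity rescales k
  inversely, so absolute values depend on that choice.
* Eq.-style pairwise overlap correction in fusion ignores triple-overlap
  terms; for heavily overlapping subnetworks the denominator is
  approximate.
* The phase-separation law is defined for bifurcations only; higher-order
  branchings fall back to flow-proportional splitting.
* Remodeling subset fractions count segments, not vascular volume.
* No transient flow, vessel compliance, oxygen transport or shear-driven
  adaptation.
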