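# Methods

`jawmorph` re-implements, as a tested pipeline on synthetic data, an
analysis of mechanoregulated anisotropic growth in the larval zebrafish
jaw joint: how the Meckel's cartilage (MC) of the lower jaw grows between
4 and 5 days post fertilisation (dpf), how jaw movements alter that
growth, and which mechanical stimulus best explains the movement-dependent
component. This note records the models, the parameters that matter, the
numerical choices, and what the synthetic data can and cannot show.

## Units and frames

All computations use the μm / nN / s system, in which stress is
nN·μm⁻² = kPa, so published cartilage moduli (kPa) and muscle forces (nN)
enter verbatim. The canonical anatomical frame is x = anteroposterior
(AP, anterior positive), y = mediolateral (ML), z = ventrodorsal (VD,
dorsal positive), with the joint line at the origin. Hydrostatic stress is
tr(σ)/3 with compression negative.

## Synthetic rudiment and ground-truth growth

The half-jaw assembly is a parametric solid, not a reconstruction: the MC
is a tapered, gently curved rod (length 90 μm, radius 12 → 8 μm) with a
hemispherical joint head (radius 14 μm) whose flat articular face lies in
the joint plane; the palatoquadrate (PQ) is a mirrored block; a compliant
interzone slab (gap 4 μm) bridges the two; a ceratohyal (CH) anchor bar
hangs from the PQ and provides the fixed support. The mechanics only
requires this topology — two stiff elements bridged by a very soft
interzone, loaded like a lever.

Meshing subdivides a regular lattice (spacing `target_edge_length`,
default 3 μm) into six Kuhn tetrahedra per cube and keeps tetrahedra whose
centroid lies inside the solid; neighbouring cubes triangulate shared
faces identically, so the mesh is conforming and its surface closed.
Linear 4-node tetrahedra are used instead of the quadratic elements of the
original study; the finer default lattice compensates, and the element
choice is validated by patch tests (uniform-strain states exact to
machine precision) and a beam-bending convergence study.

The ground-truth deformation is a separable growth-velocity field
`v_i = A_i · φ_i(|x_AP|) · x_i` with per-axis amplitudes and the smooth
axial profile `φ_i(s) = (1-β_i) + β_i·exp(-(s/λ)²)` (λ = 40 μm) peaking
at the joint line. AP elongation is distributed along the rod (β_AP = 0)
while ML/VD growth concentrates at the joint (β = 0.4); with the
organ-level targets below this makes the free-to-move field VD-dominant
near the joint, as observed in tracked-cell data. The amplitudes are not
free parameters: for each condition they are solved (scalar root finding,
the AP flow first since it is autonomous) so that advecting the MC node
cloud over 24 h reproduces the reported organ-level percent changes —
free-to-move: length +37 %, depth +43 %, width +11 %; immobilised:
+15 %, −6 %, +4 %. Flows are integrated with classical RK4, 100 sub-steps
per 12 h window (exponential-flow error far below 1e-8 at these rates).

Tracked cells: 30 chondrocyte centroids are Poisson-disk sampled in the
MC (minimum spacing 9 μm), advected by the true flow, and observed with
isotropic Gaussian localisation noise of SD 0.3 μm per image (a
configuration choice — roughly half a confocal voxel; the source data do
not state a noise level). Longitudinal series share the noisy middle
image between consecutive windows, as real re-imaged specimens would.
Proliferation is neglected (near-zero over the period studied), so cell
identities are conserved and every link survives both timepoints.

## Growth quantification

The local growth measure is the statistical symmetrised velocity
gradient: with link vectors *l* joining neighbouring centroids, texture
`M = ⟨l⊗l⟩` and link change `C = ⟨l⊗(l'−l)⟩/Δt` over conserved links,
the tensor is `sym(M⁻¹C)` (units s⁻¹). Neighbours are 3D Delaunay edges
cut at 2.5× the median nearest-neighbour distance (the neighbour rule is
isolated behind `LinkSet.neighbour_rule` so it can be swapped). Tensors
are computed per 15 μm cubic ROI anchored at the joint line, each ROI
using every conserved link with at least one endpoint inside it; ROIs
with fewer than 4 links or a texture condition number above 1e6 are
flagged invalid and excluded from interpolation support rather than
silently zeroed. Eigenvectors are labelled VD/AP/ML by the bijection
minimising total angular mismatch to the anatomical axes (sign-free
angles), ties broken VD > AP > ML. Growth maps interpolate componentwise
trilinearly between ROI centres, with the nearest ROI's tensor outside
the lattice hull.

The estimator measures the finite-window (secant) rate `(e^{gΔt}−1)/Δt`
rather than the instantaneous rate; the growth-application step uses the
matching convention (strain = rate × window), so the chain is consistent:
noise-free round trips reproduce the ground-truth deformed mesh to a mean
surface distance below 0.1 μm.

## Morphometrics

Shapes are aligned with the joint line at the origin; a mesh carries its
anatomical frame, giving full rigid recovery, while the two-landmark
fallback (joint line → retroarticular direction) resolves rotations about
the ML axis only (documented limitation). Measurements on the aligned MC:
length = AP extent, depth = VD extent, width = maximal ML extent within a
±5 μm slab at the joint level (the slab half-width quantifies "at the
level of the joint", which is not stated numerically). Average shapes are
built per transversal slice by arc-length resampling with angular
correspondence from the slice centroid — adequate for convex, roughly
tubular outlines; strongly non-star-shaped slices would break the
correspondence.

## Jaw-motion mechanics

Small-strain, quasi-static linear elasticity on the labelled assembly:
isotropic materials per region (cartilage E from the nanoindentation
table, 142.01 kPa for free-to-move larvae; ν = 0.3; interzone
E = 0.025 % of cartilage E), constant-strain tetrahedra assembled
sparsely, element stresses volume-averaged to nodes. Boundary conditions:
CH anterior end fixed, PQ posterior end restricted to AP translation, MC
anterior tip ML-constrained (half-jaw symmetry). The four jaw muscles
(adductor mandibularis am — closure; intermandibularis anterior/posterior
ima/imp and interhyal ih — opening) act as point loads in fixed,
near-anteroposterior directions, spread over nodes within a 6 μm
insertion radius to avoid point-load singularities. Because the model is
linear, a cycle of closure and opening (each ramped over 5 increments) is
two solves; the published force ratios are scaled by a single multiplier
so the VD displacement of the MC anterior tip at peak opening equals the
physiological 37.2 μm (closed-form scale by linearity; the multiplier is
applied to all four muscles to preserve the published ratio).

The resulting fields mirror the reported pattern: dorsal compression and
ventral tension at peak closure, reversed at peak opening, and a
compression peak at the joint in the cycle average. Nodal gradients of
hydrostatic stress are least-squares affine fits over edge-connected
neighbourhoods (exact for linear fields, including boundaries); corner
nodes whose one-sided neighbourhoods are numerically rank-deficient fall
back to volume-averaged element gradients.

## Mechanobiological growth laws

Three laws supplement the immobilised baseline G_imm (interpolated to
mesh nodes) with a mechanical increment:

* `G_ave = G_imm − a·S·I₃` — isotropic; S is the cycle-average
  hydrostatic stress, so compression promotes growth;
* `G_grad = G_imm + b·|∇σ_h(peak opening) − ∇σ_h(peak closure)|` —
  anisotropic; the gradients are diagonal (one entry per anatomical
  axis) and the absolute difference is taken entrywise;
* `G_comp_grad` — as `G_grad` after clamping both hydrostatic fields to
  their compressive part, with the same b.

In the internal unit system a is in μm²·nN⁻¹·s⁻¹ and b in μm³·nN⁻¹·s⁻¹.
The published magnitudes of a and b were tuned in another model's unit
system and do not port; the package instead reruns the selection
procedure on its own geometry: sweep the variable, simulate one growth
window per value, keep the value whose predicted MC depth change is
closest to the physiological one. The a-sweep is anchored at the tensile
stability limit (beyond it the isotropic law shrinks insertion-site
tension spots by more than 100 % per window and collapses elements) with
the published 4× span; the b-sweep is centred on the joint-region
stimulus response with the published 15× span. b's depth criterion is
evaluated on the compressive-gradient law — the concluded stimulus — and
the same value is reused for the full-gradient law, whose stability in
both windows is checked for every candidate. On this synthetic geometry
the peak stress fields are closer to pure bending (larger tensile
regions) than in the original jaw model, which is why the calibration
law matters here; this is a geometry effect, not a property of the laws.

## Morphogenesis simulation

Growth is applied over each 12 h window as spatially varying anisotropic
expansion, per-element strain = rate × window. Default mode is
*eigenstrain*: per sub-step (10 per window) the incremental growth strain
enters an elastic solve as stress-free strain with rigid-body modes
removed (self-equilibrated loads allow an exact 6-dof pinning), the
best-fit rigid motion is subtracted and the joint line re-anchored, and
node coordinates are updated; this reproduces expansion-subroutine
mechanics including residual-stress effects of incompatible growth.
Sub-step increments are the multiplicative n-th root of the window strain
(so sub-steps compose exactly for uniform fields); if a sub-step inverts
elements it is retried at half the fraction. A *kinematic* mode (line
integral of the sub-step strain field along axis-aligned paths from the
joint line) serves as a fast oracle, exact for compatible fields; the two
modes agree within 2 % on all morphometrics for the default maps.

The full pipeline synthesises mesh and tracks, estimates G_free and
G_imm per window, simulates the jaw cycle on the free-to-move shape of
each window, calibrates a and b in the first window (reusing them in the
second), grows the window's starting shape under all five maps, and
compares each outcome against the G_free-grown shape by mean symmetric
surface distance. Distances are evaluated on the MC joint region after a
fixed 40 μm anteroposterior crop, mirroring the protocol of consistently
cropping MC outlines before comparison. On the default configuration the
distances order `G_comp_grad ≤ G_grad ≤ G_ave`, reproducing the headline
ranking; the average-stress law both misses the anisotropy and develops
the characteristic non-physiological growth spots near the joint.

## Problem sizes and determinism

Defaults are chosen so a full pipeline runs in a few minutes on one CPU:
3 μm lattice (≈3 300 nodes, ≈14 000 tetrahedra), 30 tracked cells, 10
growth sub-steps, 5-value sweeps. Every stochastic step takes an explicit
seed; fixed seeds give bit-identical meshes, tracks, maps and manifests.

## Known limitations

* Voxel meshes have staircase surfaces; sub-voxel surface detail (e.g.
  the retroarticular process) exists only as a landmark coordinate.
* The interzone is linear elastic and transmits tension; a yielding or
  cavitating interface would shift the compression/tension split at the
  peaks and likely strengthen the compressive-gradient law further.
* The synthetic ground truth is a smooth separable field: it emulates
  magnitudes, anisotropy and axial profiles of real growth but not cell
  intercalation, division, or spatially rough growth; passing round-trip
  tests therefore validates the estimation/simulation machinery, not the
  biology of any particular specimen.
* The two-landmark alignment fallback leaves roll about the joint →
  retroarticular axis unresolved; meshes carry frames, so this only
  affects frameless inputs.
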