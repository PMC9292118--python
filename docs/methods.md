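# Methods

This note documents the models, numerical choices and limitations behind
`myotract`. Everything quantitative stated here is computed by the test
suite or by `scripts/acceptance.py`; nothing is quoted from external data.

## The synthetic two-ventricle phantom

All stages are exercised on a parametric phantom rather than scanner
data, so every quantity has analytic ground truth.

**Geometry.** The left ventricle is an annulus around the z (long) axis:
inner radius 5.4 mm, outer radius 10.8 mm, base–apex extent ±12 mm at
0.6 mm isotropic voxels on a 48³ grid (defaults; all configurable). An RV
crescent of 2.4 mm wall thickness attaches to the LV epicardium over a
120° sector, and the overlapping wall sector is labelled septum. An
optional base–apex taper widens the basal end (`radius × (1 + taper·(z̃ −
½))`); the default phantom is straight (taper 0), while the groupwise
experiments use a tapered, more prolate variant (inner/outer radii
3.0/7.8 mm, ±13 mm, taper 0.35) so the inertia axes are well separated
and the base–apex direction is identifiable — a straight annulus of the
default proportions has nearly degenerate second moments, which is a
property of the idealised shape, not of real ventricles.

**Fibers.** Inside the walls the fiber direction is the circumferential
tangent tilted out of the short-axis plane by the transmural helix angle
`HA(d) = α_endo + (α_epi − α_endo)·d`, with depth `d ∈ [0,1]` the
normalised radial position in the wall (each wall uses its own
thickness). Defaults: α_endo = +60°, α_epi = −60°. A cylindrical
"junction bundle" (default: mid-wall at the 90° sector, radius 2.8 mm so
it spans the full wall thickness) overrides the rule with fibers parallel
to the long axis — an idealisation of the base–apex-oriented bundle found
at the posterior ventricular junction, deliberately orthogonal to the
surrounding circumferential fibers.

**Signal.** Ground-truth tensors are `D = Σ λᵢ vᵢvᵢᵀ` with v1 the fiber
direction and a deterministic orthonormal completion for v2, v3.
Default eigenvalues (12, 8, 6)×10⁻⁴ mm²/s give FA ≈ 0.34 and
ADC ≈ 8.7×10⁻⁴ mm²/s, within the range reported for fixed myocardium;
they are defaults, not fitted values. DWI follows the monoexponential
model `S = S0·exp(−b gᵀDg)` on a one-b0 + six-direction b = 1000 s/mm²
scheme (the standard dual-gradient set (±1,±1,0)/√2 — any well-spread
six-direction set is equivalent here, and a Fibonacci-sphere scheme of
arbitrary size is available for redundant acquisitions). Background
voxels carry no tissue signal, so the b0 doubles as an anatomical
channel. Rician noise replaces each measurement by
`√((S+n₁)² + n₂²)`, n₁,n₂ ~ N(0, σ²), bit-reproducible for a fixed seed.

**What the phantom does not emulate:** sheetlet (v2/v3) architecture,
atria and valves, wall-thickness variation beyond the taper, perfusion
or fixation artifacts, susceptibility/eddy-current distortion, and
spatially correlated noise. Passing tests therefore certify the
*algorithms* under controlled conditions, not performance on scanner
data.

## Tensor estimation and maps

The estimator is plain log-linear least squares on
`ln S_i = ln S0 − b_i g_iᵀ D g_i` (7 parameters). With the minimal
7-measurement scheme the system is exactly determined, so noiseless
round-trips recover tensors to machine precision (measured ~4×10⁻¹⁵
relative); a one-pass weighted refinement (weights = predicted squared
signals) is available for noisy data. Signals below `1e-6 × Ŝ0` are
floored before the log (logged when triggered); negative eigenvalues are
clamped to zero for scalar maps. FA and mean diffusivity use the
standard eigenvalue definitions. Cardiac masking is the conjunction of
band-pass tests on FA, trace and mean DW signal, optionally keeping only
the largest 26-connected component (an automated stand-in for manual
mask editing); all thresholds are caller-supplied because sensible
values depend on the noise floor.

## Spatial normalisation of tensors

Warping interpolates matrix logarithms (log-Euclidean framework) with
mask-weighted trilinear interpolation — out-of-mask neighbours get zero
weight and the remainder is renormalised, which avoids background
contamination without a separate extrapolation step. An output voxel is
considered inside when it collects ≥ 0.5 in-mask weight.

Reorientation applies the local rotation of the spatial map to the
sampled tensor. The default is preservation of principal directions
(PPD): v1 maps to the normalised image of v1 under the local linear map,
v2 to the orthogonalised image of v2. Finite strain (the rotation polar
factor of the Jacobian, via SVD with a determinant correction) is
selectable. For rigid maps both reduce to the rigid rotation, leaving
eigenvalues exactly unchanged — the warp contract is tested on a rotated
lattice, where resampling is exact and FA/λ deviations are at machine
precision. Dense displacement fields follow the pullback convention
(template point x samples native point x + u(x)); their Jacobians come
from central differences chained through the grid affine.

Averaging is `exp(mean(log D_k))` per voxel with eigenvalues floored at
10⁻¹² mm²/s before the log; a Euclidean option exists. Voxels present in
fewer than a quorum of subjects (default: all) are zeroed. Retrospective
downsampling bins source voxel centres into the coarse grid and averages
log-tensors with mask weighting; it reports the voxel-volume ratio
(0.6 mm iso → 2.5×2.5×8 mm³ gives 50/0.216 = 231.48).

## Groupwise template

Subjects are auto-aligned by principal axes of inertia: the dominant
covariance eigenvector goes to +z, the sign chosen so the half with the
larger radial spread (the base) sits at high z, the centroid goes to the
world origin, and eigenvector signs are canonicalised so degenerate
shapes still produce a deterministic transform. Registration maximises
weighted normalised cross-correlation over modalities (anatomical
weight 1, FA weight 0.5 by default) with Powell's method over a scaled
parameter space (rotations ~0.1 rad, translations ~1 mm, log-scales and
shears ~0.05 per unit), over an internal image pyramid (factors 4, 2, 1)
plus a restarted polishing pass at the finest level. NCC was chosen over
mutual information because the channels are same-modality across
subjects; everything is deterministic for fixed inputs.

The template loop per resolution level: warp subjects with their current
transforms, average channels voxel-wise (masks by majority), register
each subject to the average compositionally, then factor out the mean
4×4 transform so the template stays unbiased. The shipped transform
models are rigid and affine; a nonlinear stage is a pluggable backend
callable returning a displacement-field transform, intended as the final
level (its reference grid is the level grid). The default schedule for
the phantom experiments is two levels (2.4 mm rigid, 1.2 mm affine) —
proportionally scaled-down from coarse-to-fine schedules used on real
hearts, which is sufficient for the ~27 mm phantom FOV.

Template quality is evaluated with Dice/Jaccard overlap
(empty ∪ empty ≔ 1 by convention). For the jittered-phantom experiment
the warped masks are produced by voxelizing each subject's *analytic*
geometry through the recovered transform: binarized resampling of thin
(2.4–4.8 mm) walls caps Dice near 0.96 regardless of registration
accuracy, so the analytic evaluation isolates transform error. Under two
rigidly posed subjects (rotations up to ~8°, translations ~1 mm) the
rigid+affine build reaches Dice ≈ 0.98–0.99; with a 4% inter-subject
size difference the overlap increases strictly along
none → principal axes → rigid → affine.

## Tractography

All three trackers share bidirectional seeding (both orientations of the
initial axis, halves concatenated), exact step-size spacing, and the
termination rules: local FA below threshold, turning angle above the
maximum, leaving the volume/mask, or reaching the length cap (each half
is capped at half the maximum length). Tracks shorter than the minimum
length are discarded. Defaults: FA stop 0.1, 60° maximum angle, 0.05 mm
steps, lengths 1–40 mm. Directions are axial: each step sign-aligns with
the previous direction, and negating the whole eigenvector field only
reverses traversal order.

- **FACT** reads v1 of the containing voxel (half-open convention:
  voxel i owns [i−½, i+½)) with no interpolation.
- **DET** eigen-decomposes the component-wise trilinearly interpolated
  tensor at the continuous position (mask-weighted, as in warping).
  Because background mixing scales all eigenvalues equally, interpolated
  FA is unbiased near the wall boundary.
- **PROB** perturbs the DET direction. The default *dispersion* mode
  draws from a Watson distribution around v1 with concentration
  `κ(FA) = κ₀·FA/(1−FA+ε)` (κ₀ = 60 by default — monotone in FA,
  divergent as FA→1, so coherent regions disperse little). Sampling uses
  rejection from an angular-central-Gaussian envelope, whose acceptance
  rate is bounded below for all κ, so the κ→∞ limit converges to DET
  without a performance cliff. The *bootstrap* mode refits the local
  tensor from residual-bootstrapped log-signals; it requires more than
  six diffusion directions, because the minimal scheme fits exactly and
  leaves no residuals — requesting it on six-direction data raises an
  error pointing to dispersion mode.

The stepper is vectorised across streamlines (arrays of active heads
advance together), which keeps 5000-seed connectivity queries in the
tens of seconds on one CPU.

## Pathway analysis

ROI membership is "any vertex inside the region" — safe because step
sizes (0.05 mm) are far below region radii (≥ 1.5 mm). Filtering modes:
unordered (`all`, the default) and ordered (regions visited in listed
order along either traversal direction). The pathway ratio counts raw
surviving tracks out of N requested seeds. The propagation angle between
consecutive step vectors uses the atan2 formulation (accurate near 0°);
voxel maps aggregate per-vertex angles by mean or max. Bundle geometry
uses the exposed-voxel-face convention for surface area — deterministic
and exact for voxel regions, but it overestimates smooth surfaces
relative to a meshed isosurface.

On the junction phantom the connectivity pattern is structural: a
free-wall pathway 60° of arc away connects at ~100%; a pathway crossing
the orthogonal bundle connects at ~0% under the 60° angle limit (the
90° interface either stops tracks or deflects them axially, away from
the target); and under Rician noise (σ = 40 on S0 = 1000, i.e. SNR 25)
nearest-voxel FACT loses substantially more tracks than interpolated
DET on the same seeds — the interpolation averages orientation noise.

## Problem sizes and numerical conventions

The shipped experiments use 48³ phantoms (56³ for evaluation grids and
posed shapes that would otherwise crop), 5000 seeds per connectivity
query, and two-level template schedules; these sizes put every
documented quantity well inside its asymptotic regime while keeping the
full suite fast on a single CPU. All coordinates are world-mm RAS;
conversions happen only at I/O boundaries. NIfTI affines round-trip at
float32 header precision (~10⁻⁷); tck streamlines at float32 vertex
precision. Stochastic components (noise, seeding, Watson draws,
bootstrap) all flow from explicit seeds, and identical configurations
reproduce outputs exactly.

## Known limitations

- The tensor model constrains each voxel to a single fiber axis; no
  crossing-fiber or higher-order models.
- Nonlinear (diffeomorphic) registration is consumed through the backend
  contract, not implemented.
- The phantom's analytic geometry makes boundary behaviour cleaner than
  real data; partial-volume effects at the epicardial fat interface,
  residual fixative signal, and B1 inhomogeneity are out of scope.
- Registration assumes the multi-modality channels are already
  co-registered within each subject.
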