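# myotract

Groupwise cardiac diffusion-tensor (DTI) template building and myofiber
tractography, exercised end to end on synthetic two-ventricle fiber
phantoms.

Ex vivo cardiac DTI resolves the local myofiber axis as the primary
eigenvector **v1** of a per-voxel diffusion tensor **D**. Pooling several
hearts into a common atlas and tracing streamlines through the averaged
eigenvector field makes it possible to characterise structures that are
hard to see in any single scan — in particular the ventricular junctions
(right-ventricular insertion points), where a base–apex-oriented fiber
bundle sits orthogonal to the surrounding circumferential fibers. This
package implements that full analysis chain for anyone who wants to
study such fiber-field discontinuities quantitatively, with every stage
testable against analytic ground truth:

- **phantom** — a parametric two-ventricle phantom: LV annulus with the
  linear transmural helix-angle rule
  `HA(d) = α_endo + (α_epi − α_endo)·d`, an RV crescent, and a long-axis
  "junction bundle" orthogonal to the wall fibers; monoexponential DWI
  simulation `S_i = S0·exp(−b_i gᵀ D g)` with Rician noise.
- **tensor_model** — trilinear DWI upsampling, log-linear least-squares
  tensor fitting, eigenvalue/FA/ADC/cFA maps
  (`FA = √(3/2)·√Σ(λᵢ−λ̄)² / √Σλᵢ²`), and threshold-based cardiac
  masking.
- **tensor_transform** — tensor warping with finite-strain or
  preservation-of-principal-directions reorientation, log-Euclidean
  averaging `exp(mean(log D_k))`, and retrospective downsampling to
  in vivo resolution.
- **groupwise** — principal-axes auto-alignment, multi-resolution
  rigid/affine registration on weighted normalised cross-correlation,
  iterative unbiased template construction, Dice/Jaccard overlap metrics.
- **tracking** — FACT (nearest-voxel eigenvector), DET (interpolated
  tensor) and PROB (Watson-dispersion or residual-bootstrap) streamline
  tractography with FA/angle/length termination rules.
- **pathway** — ROI-based streamline filtering, connectivity ratios
  (surviving / requested streamlines), per-vertex propagation angles and
  their voxel maps, streamline cutting, bundle volume/surface.

## Worked example

```python
import numpy as np
import myotract as mt

# simulate the default 48³ phantom at 0.6 mm with a 6-direction b=1000 scheme
spec = mt.PhantomSpec()
field, gt_tensors, dwi = mt.make_phantom(spec)

# fit tensors and derive maps
fit = mt.fit_dti(dwi, spec.scheme(), field.mask)
maps = mt.tensor_metrics(fit)
print(f"mean FA  = {maps.fa[field.mask].mean():.3f}")
print(f"mean ADC = {maps.adc[field.mask].mean():.2e} mm^2/s")

# connectivity across the junction bundle vs along the free wall
a = np.deg2rad(150)
seed = mt.SeedRegion(kind="cylinder", center=(8.1*np.cos(a), 8.1*np.sin(a), 0),
                     axis=(0, 0, 1), radius=1.5, half_height=3.0)
def roi(angle):
    a = np.deg2rad(angle)
    return mt.SeedRegion(kind="cylinder", center=(8.1*np.cos(a), 8.1*np.sin(a), 0),
                         axis=(0, 0, 1), radius=1.5, half_height=10.0)
params = mt.TrackingParams()         # FA stop 0.1, 60 deg, 0.05 mm steps
for name, target in [("free wall", roi(210)), ("across bundle", roi(30))]:
    rule = mt.PathwayRule(seed=seed, include=[target], n_requested=1000)
    ratio = mt.pathway_ratio(fit, rule, "det", params, rng=0)
    print(f"{name}: {ratio:.1f}%")
```

Output:

```
mean FA  = 0.339
mean ADC = 8.67e-04 mm^2/s
free wall: 99.9%
across bundle: 0.0%
```

The FA/ADC values sit in the range typical for fixed myocardium with the
default eigenvalues (12, 8, 6)×10⁻⁴ mm²/s. The two ratios show the
junction pattern the analysis is built to expose: streamlines follow the
circumferential wall to a target on the same side essentially without
loss, while none survive the 90° orientation discontinuity at the
long-axis bundle under the default 60° turning limit.

A CLI wraps the same stages (`myotract simulate | fit | metrics | mask |
warp | average | downsample | track | pa-map | geometry | run`); `myotract
run --out DIR` executes a small demonstration pipeline end to end and
stamps every artifact with the config hash and seed.

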