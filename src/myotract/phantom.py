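"""Synthetic two-ventricle cardiac fiber phantom.

The phantom emulates the geometry the pipeline is meant to analyse on real
ex vivo hearts: a left-ventricular (LV) annulus whose fibers follow the
transmural helix-angle rule, a right-ventricular (RV) crescent attached to
it, and a base–apex-oriented "junction bundle" at the posterior LV/RV
insertion point whose fibers run parallel to the long axis — orthogonal to
the surrounding circumferential fibers, reproducing the fiber-field
discontinuity that the connectivity analysis probes.

Conventions
-----------
* The long axis of the heart is the grid z-axis.
* Transmural depth ``d`` is the normalised radial position inside the
  wall: 0 at the endocardium (inner surface), 1 at the epicardium.
* The helix angle at depth ``d`` is linear:
  ``HA(d) = alpha_endo + (alpha_epi - alpha_endo) * d`` (degrees).  The
  fiber direction is the circumferential tangent tilted out of the
  short-axis plane by HA toward the long axis.

Labels
------
0 background, 1 LV wall, 2 RV wall, 3 septum (wall overlap region),
4 junction bundle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tensor_model import DiffusionScheme, default_scheme
from .volumes import DWIVolume, TensorVolume, voxel_to_world

__all__ = [
    "PhantomSpec",
    "FiberField",
    "LABELS",
    "make_helix_field",
    "field_to_tensors",
    "simulate_dwi",
    "make_phantom",
]

LABELS = {"background": 0, "lv": 1, "rv": 2, "septum": 3, "bundle": 4}


@dataclass
class PhantomSpec:
    """Parametric description of the synthetic two-ventricle phantom.

    Defaults mirror the emulated acquisition: 0.6 mm isotropic voxels, a
    6-direction b=1000 s/mm^2 scheme + one b0, and myocardial eigenvalues
    (12, 8, 6)x10^-4 mm^2/s giving FA ~= 0.26 and ADC ~= 8.7x10^-4 mm^2/s,
    inside the range reported for fixed myocardium.
    """

    shape: tuple[int, int, int] = (48, 48, 48)
    voxel_size: tuple[float, float, float] = (0.6, 0.6, 0.6)

    # LV annulus (axis = z through lv_center)
    lv_center: tuple[float, float] = (0.0, 0.0)   # mm, world x/y
    lv_inner_radius: float = 5.4                  # mm
    lv_outer_radius: float = 10.8                 # mm
    z_extent: tuple[float, float] = (-12.0, 12.0)  # mm, base-apex coverage

    # RV crescent attached to the LV epicardium
    rv_enabled: bool = True
    rv_wall_thickness: float = 2.4                # mm
    rv_angular_extent: tuple[float, float] = (30.0, 150.0)  # deg, around +x

    # base-apex taper: radii scale by 1 + taper*((z-z0)/(z1-z0) - 1/2), so the
    # basal end (high z) is wider; 0 = straight cylinder
    taper: float = 0.0

    # transmural helix rule
    alpha_endo: float = 60.0                      # deg
    alpha_epi: float = -60.0                      # deg

    # junction bundle: cylinder parallel to the long axis
    bundle_enabled: bool = True
    bundle_center: tuple[float, float] = (0.0, 8.1)  # mm (mid-wall)
    bundle_radius: float = 2.8                    # mm (spans the wall thickness)

    # diffusion eigenvalues, mm^2/s
    evals_myo: tuple[float, float, float] = (12e-4, 8e-4, 6e-4)
    evals_bundle: tuple[float, float, float] = (12e-4, 8e-4, 6e-4)

    # acquisition
    s0: float = 1000.0
    noise_sigma: float = 0.0
    seed: int = 0

    # optional grid-to-world affine override (non-canonical voxel lattice)
    world_affine: np.ndarray | None = None
    # optional rigid/affine pose of the heart in world space: the anatomy is
    # built in its own "heart frame" (long axis = z, centred at the origin)
    # and placed into the scanner at this pose — emulates the arbitrary
    # positioning of each specimen
    pose: np.ndarray | None = None

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")
        if self.lv_inner_radius >= self.lv_outer_radius:
            raise ValueError("degenerate annulus: inner radius >= outer radius")
        for ev in (self.evals_myo, self.evals_bundle):
            l1, l2, l3 = ev
            if not (l1 >= l2 >= l3 > 0):
                raise ValueError("eigenvalues must satisfy l1 >= l2 >= l3 > 0")
        if self.alpha_endo < self.alpha_epi:
            raise ValueError("default helix rule requires alpha_endo >= alpha_epi")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be non-negative")

    @property
    def affine(self) -> np.ndarray:
        """World affine centring the grid on the origin (RAS, mm)."""
        if self.world_affine is not None:
            return np.asarray(self.world_affine, dtype=float)
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.voxel_size)
        aff[:3, 3] = -(np.asarray(self.shape) - 1) / 2.0 * np.asarray(self.voxel_size)
        return aff

    def scheme(self) -> DiffusionScheme:
        return default_scheme()


@dataclass
class FiberField:
    """Ground-truth principal fiber direction field.

    ``vectors`` holds a unit vector per in-mask voxel (world frame);
    ``labels`` marks the substructures; ``depth`` stores the transmural
    depth d in [0, 1] where defined (NaN elsewhere).
    """

    vectors: np.ndarray       # (x, y, z, 3)
    mask: np.ndarray          # bool
    labels: np.ndarray        # uint8
    affine: np.ndarray
    depth: np.ndarray = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        norms = np.linalg.norm(self.vectors[self.mask], axis=-1)
        if norms.size and np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("in-mask fiber vectors must be unit norm")


def helix_angle(alpha_endo: float, alpha_epi: float, depth: np.ndarray) -> np.ndarray:
    """Linear transmural helix-angle rule, degrees."""
    return alpha_endo + (alpha_epi - alpha_endo) * np.asarray(depth)


def _helix_vector(circ: np.ndarray, ha_deg: np.ndarray) -> np.ndarray:
    """Tilt the circumferential tangent toward +z by the helix angle."""
    ha = np.deg2rad(ha_deg)[..., None]
    z = np.zeros_like(circ)
    z[..., 2] = 1.0
    return np.cos(ha) * circ + np.sin(ha) * z


def make_helix_field(spec: PhantomSpec) -> FiberField:
    """Build the ground-truth fiber field for a phantom specification.

    Inside the LV annulus the fiber direction at transmural depth ``d`` is
    the circumferential unit tangent tilted out of the short-axis plane by
    ``HA(d)``; the RV crescent follows the same rule with its own wall
    thickness; the junction bundle overrides the rule with fibers parallel
    to the long axis.
    """
    shape = tuple(spec.shape)
    affine = spec.affine
    ii, jj, kk = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    ijk = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
    xyz = voxel_to_world(affine, ijk).reshape(shape + (3,))

    # geometry is evaluated in the heart frame; fiber vectors are rotated
    # back into world coordinates at the end
    if spec.pose is not None:
        pose = np.asarray(spec.pose, dtype=float)
        inv_pose = np.linalg.inv(pose)
        pose_rot = pose[:3, :3] / np.cbrt(np.linalg.det(pose[:3, :3]))
        xyz = xyz @ inv_pose[:3, :3].T + inv_pose[:3, 3]
    else:
        pose_rot = None

    cx, cy = spec.lv_center
    dx = xyz[..., 0] - cx
    dy = xyz[..., 1] - cy
    r = np.hypot(dx, dy)
    z = xyz[..., 2]
    z0, z1 = spec.z_extent
    in_z = (z >= z0) & (z <= z1)
    # base-apex taper: effective radius at height z is s(z) * nominal radius
    s = 1.0 + spec.taper * ((z - z0) / (z1 - z0) - 0.5)
    r_eff = r / np.clip(s, 1e-6, None)

    labels = np.zeros(shape, dtype=np.uint8)
    depth = np.full(shape, np.nan)

    # LV annulus
    lv = in_z & (r_eff >= spec.lv_inner_radius) & (r_eff <= spec.lv_outer_radius)
    labels[lv] = LABELS["lv"]
    depth[lv] = ((r_eff[lv] - spec.lv_inner_radius)
                 / (spec.lv_outer_radius - spec.lv_inner_radius))

    # RV crescent: annulus attached outside the LV epicardium over an
    # angular sector; its own transmural depth across rv_wall_thickness.
    if spec.rv_enabled:
        theta = np.degrees(np.arctan2(dy, dx))
        a0, a1 = spec.rv_angular_extent
        in_sector = (theta >= a0) & (theta <= a1)
        rv_inner = spec.lv_outer_radius
        rv_outer = rv_inner + spec.rv_wall_thickness
        rv = in_z & in_sector & (r_eff > rv_inner) & (r_eff <= rv_outer)
        labels[rv] = LABELS["rv"]
        depth[rv] = (r_eff[rv] - rv_inner) / spec.rv_wall_thickness
        # septum: LV wall portion shared with the RV sector
        septum = lv & in_sector & (r_eff >= spec.lv_inner_radius + 0.6 * (
            spec.lv_outer_radius - spec.lv_inner_radius))
        labels[septum] = LABELS["septum"]

    mask = labels > 0
    vectors = np.zeros(shape + (3,))
    with np.errstate(invalid="ignore", divide="ignore"):
        circ = np.stack([-dy / r, dx / r, np.zeros_like(r)], axis=-1)
    ha = helix_angle(spec.alpha_endo, spec.alpha_epi, np.nan_to_num(depth))
    helix = _helix_vector(circ, ha)
    vectors[mask] = helix[mask]

    # junction bundle: long-axis-parallel fibers override the rule
    if spec.bundle_enabled:
        bx, by = spec.bundle_center
        if spec.world_affine is None:
            half = (np.asarray(shape) - 1) / 2.0 * np.asarray(spec.voxel_size)
            if (abs(bx) + spec.bundle_radius > half[0]
                    or abs(by) + spec.bundle_radius > half[1]):
                raise ValueError("junction bundle lies outside the grid")
        bundle = in_z & (np.hypot(xyz[..., 0] - bx, xyz[..., 1] - by)
                         <= spec.bundle_radius)
        labels[bundle] = LABELS["bundle"]
        mask = labels > 0
        vectors[bundle] = (0.0, 0.0, 1.0)
        depth[bundle] = np.nan

    norms = np.linalg.norm(vectors[mask], axis=-1, keepdims=True)
    vectors[mask] /= norms
    if pose_rot is not None:
        # rigid (or similarity) poses only: directions rotate with the heart
        vectors[mask] = vectors[mask] @ pose_rot.T
    return FiberField(vectors=vectors, mask=mask, labels=labels,
                      affine=affine, depth=depth)


def _orthonormal_complement(v1: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic orthonormal completion of a batch of unit vectors."""
    v1 = np.asarray(v1, dtype=float)
    # pick the world axis least aligned with v1 as helper
    helper = np.zeros_like(v1)
    idx = np.argmin(np.abs(v1), axis=-1)
    helper[np.arange(len(v1)), idx] = 1.0
    v2 = np.cross(v1, helper)
    v2 /= np.linalg.norm(v2, axis=-1, keepdims=True)
    v3 = np.cross(v1, v2)
    return v2, v3


def field_to_tensors(field: FiberField, spec: PhantomSpec) -> TensorVolume:
    """Ground-truth tensors: D = l1 v1 v1^T + l2 v2 v2^T + l3 v3 v3^T.

    ``v1`` is the fiber direction; ``v2, v3`` are a deterministic
    orthonormal completion.  Bundle voxels use the bundle eigenvalues.
    Out-of-mask voxels are zero tensors.
    """
    if field.vectors.shape[:3] != tuple(spec.shape):
        raise ValueError("field grid does not match spec grid")
    mask = field.mask
    v1 = field.vectors[mask]
    norms = np.linalg.norm(v1, axis=-1)
    if np.any(np.abs(norms - 1.0) > 1e-6):
        raise ValueError("fiber field contains non-unit vectors")

    v2, v3 = _orthonormal_complement(v1)
    evals = np.where(
        (field.labels[mask] == LABELS["bundle"])[:, None],
        np.asarray(spec.evals_bundle), np.asarray(spec.evals_myo))
    mats = (evals[:, 0, None, None] * v1[:, :, None] * v1[:, None, :]
            + evals[:, 1, None, None] * v2[:, :, None] * v2[:, None, :]
            + evals[:, 2, None, None] * v3[:, :, None] * v3[:, None, :])

    full = np.zeros(tuple(spec.shape) + (3, 3))
    full[mask] = mats
    return TensorVolume.from_matrices(full, field.affine, mask,
                                      meta={"source": "phantom"})


def simulate_dwi(tensors: TensorVolume, scheme: DiffusionScheme,
                 s0: float = 1000.0, sigma: float = 0.0,
                 seed: int | None = 0) -> DWIVolume:
    """Forward-simulate DWI signals with the monoexponential tensor model.

    Noiseless signal per measurement: ``S_i = S0 exp(-b_i g_i^T D g_i)``
    inside the tensor mask; outside it the tissue signal is zero (the
    phantom emulates a background with negligible signal, so the b0 doubles
    as an anatomical channel).  With ``sigma > 0`` each measurement is
    replaced by the Rician magnitude ``sqrt((S + n1)^2 + n2^2)`` with
    ``n1, n2 ~ N(0, sigma^2)`` drawn from a generator seeded by ``seed``
    (bit-reproducible), which leaves a noise floor in the background.
    """
    if sigma < 0:
        raise ValueError("noise sigma must be non-negative")
    b = scheme.bvals
    g = scheme.bvecs
    # g^T D g per voxel and measurement, via the 6-component contraction
    d = tensors.data
    quad = (d[..., None, 0] * g[:, 0] ** 2
            + 2 * d[..., None, 1] * g[:, 0] * g[:, 1]
            + 2 * d[..., None, 2] * g[:, 0] * g[:, 2]
            + d[..., None, 3] * g[:, 1] ** 2
            + 2 * d[..., None, 4] * g[:, 1] * g[:, 2]
            + d[..., None, 5] * g[:, 2] ** 2)
    signal = s0 * np.exp(-b * quad) * tensors.mask[..., None]
    if sigma > 0:
        rng = np.random.default_rng(seed)
        n1 = rng.normal(0.0, sigma, signal.shape)
        n2 = rng.normal(0.0, sigma, signal.shape)
        signal = np.sqrt((signal + n1) ** 2 + n2 ** 2)
    return DWIVolume(signal, tensors.affine.copy())


def make_phantom(spec: PhantomSpec) -> tuple[FiberField, TensorVolume, DWIVolume]:
    """Convenience: field -> ground-truth tensors -> simulated DWI."""
    field = make_helix_field(spec)
    tensors = field_to_tensors(field, spec)
    dwi = simulate_dwi(tensors, spec.scheme(), s0=spec.s0,
                       sigma=spec.noise_sigma, seed=spec.seed)
    return field, tensors, dwi
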