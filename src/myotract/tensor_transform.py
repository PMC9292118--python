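"""Tensor-aware spatial operations: warping, averaging, downsampling.

Diffusion tensors cannot be moved like scalar images: resampling must
interpolate them without swelling (done here on matrix logarithms, the
log-Euclidean framework) and the local rotation of the spatial map must be
re-applied to the tensor orientation ("reorientation").  Two standard
reorientation strategies are provided:

* finite strain (FS): the rotation polar factor of the local Jacobian;
* preservation of principal directions (PPD, the default): the rotation
  that maps the primary eigenvector exactly through the local linear map
  and the secondary eigenvector onto its projection.

For rigid transforms both strategies reduce to the rigid rotation and the
eigenvalues (hence FA/ADC) are untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg as sla

from .volumes import (
    ImageVolume,
    TensorVolume,
    matrices_to_tensors,
    tensors_to_matrices,
    voxel_to_world,
    world_to_voxel,
)

__all__ = [
    "SpatialTransform",
    "warp_tensor",
    "log_euclidean_mean",
    "downsample_tensor",
    "log_tensor_volume",
    "exp_tensor_volume",
]

#: SPD floor applied to eigenvalues before a matrix logarithm (mm^2/s).
SPD_EPS = 1e-12


@dataclass
class SpatialTransform:
    """A world-space spatial map, either affine or a dense displacement field.

    ``affine``: 4x4 world-to-world matrix mapping native points to template
    points (direction tag "forward": native -> template).

    ``displacement``: pullback field on the *reference* (template) grid —
    for a template-grid point at world position x, the native point sampled
    is ``x + u(x)`` (the convention of ANTs-style forward warp fields).
    ``reference_affine``/``reference_shape`` define that grid.
    """

    affine: np.ndarray | None = None
    displacement: np.ndarray | None = None       # (x, y, z, 3), mm
    reference_affine: np.ndarray | None = None
    reference_shape: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        if (self.affine is None) == (self.displacement is None):
            raise ValueError("provide exactly one of affine or displacement")
        if self.affine is not None:
            self.affine = np.asarray(self.affine, dtype=float)
            if self.affine.shape != (4, 4):
                raise ValueError("affine must be 4x4")
            if abs(np.linalg.det(self.affine)) < 1e-12:
                raise ValueError("affine must be invertible")
        else:
            self.displacement = np.asarray(self.displacement, dtype=float)
            if self.displacement.ndim != 4 or self.displacement.shape[-1] != 3:
                raise ValueError("displacement must have shape (x, y, z, 3)")
            if not np.all(np.isfinite(self.displacement)):
                raise ValueError("displacement field must be finite")
            if self.reference_affine is None:
                raise ValueError("displacement field needs a reference affine")
            self.reference_affine = np.asarray(self.reference_affine, dtype=float)
            if self.reference_shape is None:
                self.reference_shape = tuple(self.displacement.shape[:3])

    @property
    def is_affine(self) -> bool:
        return self.affine is not None

    def inverse(self) -> "SpatialTransform":
        if not self.is_affine:
            raise ValueError("only affine transforms can be inverted analytically")
        return SpatialTransform(affine=np.linalg.inv(self.affine))

    @classmethod
    def identity(cls) -> "SpatialTransform":
        return cls(affine=np.eye(4))

    @classmethod
    def from_rigid(cls, rotation: np.ndarray, translation: np.ndarray) -> "SpatialTransform":
        aff = np.eye(4)
        aff[:3, :3] = np.asarray(rotation, dtype=float)
        aff[:3, 3] = np.asarray(translation, dtype=float)
        return cls(affine=aff)


# ---------------------------------------------------------------------------
# matrix log/exp in the log-Euclidean framework

def _logm_spd(mats: np.ndarray, eps: float = SPD_EPS) -> np.ndarray:
    """Batched matrix logarithm of symmetric matrices with SPD flooring."""
    evals, evecs = np.linalg.eigh(mats)
    evals = np.clip(evals, eps, None)
    logl = np.log(evals)
    return np.einsum("...ij,...j,...kj->...ik", evecs, logl, evecs)


def _expm_sym(mats: np.ndarray) -> np.ndarray:
    """Batched matrix exponential of symmetric matrices."""
    evals, evecs = np.linalg.eigh(mats)
    return np.einsum("...ij,...j,...kj->...ik", evecs, np.exp(evals), evecs)


def log_tensor_volume(tensors: TensorVolume, eps: float = SPD_EPS) -> np.ndarray:
    """(x, y, z, 6) log-tensor components over the mask (zeros elsewhere)."""
    out = np.zeros_like(tensors.data)
    mask = tensors.mask
    if mask.any():
        out[mask] = matrices_to_tensors(_logm_spd(tensors.as_matrices()[mask], eps))
    return out


def exp_tensor_volume(log_data: np.ndarray, mask: np.ndarray) -> np.ndarray:
    out = np.zeros_like(log_data)
    if mask.any():
        out[mask] = matrices_to_tensors(_expm_sym(tensors_to_matrices(log_data[mask])))
    return out


# ---------------------------------------------------------------------------
# mask-weighted trilinear sampling (shared with tracking via volumes grid math)

def trilinear_weighted(values: np.ndarray, mask: np.ndarray,
                       coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mask-weighted trilinear interpolation at fractional voxel coords.

    ``values``: (x, y, z, c); ``coords``: (n, 3) voxel-space positions.
    Out-of-mask (or out-of-grid) corners contribute zero weight; the result
    is renormalised over the remaining weight.  Returns (samples (n, c),
    total in-mask weight (n,)).
    """
    shape = np.asarray(values.shape[:3])
    coords = np.asarray(coords, dtype=float)
    base = np.floor(coords).astype(int)
    frac = coords - base
    n = coords.shape[0]
    c = values.shape[-1]
    acc = np.zeros((n, c))
    wsum = np.zeros(n)
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                idx = base + (dx, dy, dz)
                inside = np.all((idx >= 0) & (idx < shape), axis=1)
                w = (np.where(dx, frac[:, 0], 1 - frac[:, 0])
                     * np.where(dy, frac[:, 1], 1 - frac[:, 1])
                     * np.where(dz, frac[:, 2], 1 - frac[:, 2]))
                ic = np.clip(idx, 0, shape - 1)
                valid = inside & mask[ic[:, 0], ic[:, 1], ic[:, 2]]
                w = np.where(valid, w, 0.0)
                acc += w[:, None] * values[ic[:, 0], ic[:, 1], ic[:, 2]]
                wsum += w
    with np.errstate(invalid="ignore", divide="ignore"):
        out = acc / wsum[:, None]
    out[wsum == 0] = 0.0
    return out, wsum


def _rotation_polar(linear: np.ndarray) -> np.ndarray:
    """Proper-rotation polar factor of a batch (or single) 3x3 linear map."""
    single = linear.ndim == 2
    mats = linear[None] if single else linear
    u, _, vt = np.linalg.svd(mats)
    r = u @ vt
    # enforce det +1 (reflective maps get their smallest singular direction flipped)
    det = np.linalg.det(r)
    flip = det < 0
    if np.any(flip):
        u = u.copy()
        u[flip, :, 2] *= -1
        r = u @ vt
    return r[0] if single else r


def _ppd_rotate_tensors(mats: np.ndarray, linear: np.ndarray) -> np.ndarray:
    """Preservation-of-principal-directions reorientation.

    ``mats``: (n, 3, 3) tensors; ``linear``: (n, 3, 3) or (3, 3) local
    linear map (native -> template).  The rotated tensor keeps its
    eigenvalues; v1 maps to the normalised image of v1 under the map, v2 to
    the component of its image orthogonal to the new v1.
    """
    evals, evecs = np.linalg.eigh(mats)
    evals = evals[..., ::-1]
    evecs = evecs[..., ::-1]
    v1, v2 = evecs[..., :, 0], evecs[..., :, 1]
    if linear.ndim == 2:
        lv1 = v1 @ linear.T
        lv2 = v2 @ linear.T
    else:
        lv1 = np.einsum("nij,nj->ni", linear, v1)
        lv2 = np.einsum("nij,nj->ni", linear, v2)
    n1 = lv1 / np.linalg.norm(lv1, axis=-1, keepdims=True)
    proj = lv2 - np.sum(lv2 * n1, axis=-1, keepdims=True) * n1
    norm2 = np.linalg.norm(proj, axis=-1, keepdims=True)
    # degenerate image of v2 (map collapses it onto n1): fall back to any
    # orthonormal direction so the output stays a valid tensor
    bad = (norm2[..., 0] < 1e-12)
    if np.any(bad):
        helper = np.zeros_like(n1[bad])
        helper[:, np.argmin(np.abs(n1[bad]), axis=-1)] = 1.0
        proj[bad] = np.cross(n1[bad], helper)
        norm2 = np.linalg.norm(proj, axis=-1, keepdims=True)
    n2 = proj / norm2
    n3 = np.cross(n1, n2)
    return (evals[..., 0, None, None] * n1[..., :, None] * n1[..., None, :]
            + evals[..., 1, None, None] * n2[..., :, None] * n2[..., None, :]
            + evals[..., 2, None, None] * n3[..., :, None] * n3[..., None, :])


def _displacement_jacobian(t: SpatialTransform) -> np.ndarray:
    """Jacobian of x -> x + u(x) w.r.t. world coordinates, per grid voxel."""
    inv_lin = np.linalg.inv(t.reference_affine[:3, :3])
    grads = np.stack(
        [np.stack(np.gradient(t.displacement[..., c], axis=(0, 1, 2)), axis=-1)
         for c in range(3)], axis=-2)          # du_c/d(index)
    jac = grads @ inv_lin                       # du/dx, (x, y, z, 3, 3)
    jac += np.eye(3)
    return jac


def warp_tensor(tensors: TensorVolume, t: SpatialTransform,
                strategy: str = "ppd", interpolation: str = "log-euclidean",
                target_affine: np.ndarray | None = None,
                target_shape: tuple[int, int, int] | None = None,
                mask_threshold: float = 0.5) -> TensorVolume:
    """Warp a tensor volume into template space with reorientation.

    For each target-grid voxel the native location is found (inverse affine,
    or the pullback displacement), the log-tensor is interpolated there
    (mask-weighted trilinear by default; ``interpolation="nearest"`` for
    nearest-neighbour), and the result is reoriented by the local rotation
    of the forward map.

    ``strategy``: ``"ppd"`` (preservation of principal directions, default)
    or ``"fs"`` (finite strain).
    """
    if strategy not in ("ppd", "fs", "finite-strain",
                        "preservation-of-principal-directions"):
        raise ValueError(f"unknown reorientation strategy: {strategy!r}")
    use_ppd = strategy in ("ppd", "preservation-of-principal-directions")
    if interpolation not in ("log-euclidean", "nearest"):
        raise ValueError(f"unknown interpolation: {interpolation!r}")

    if target_affine is None:
        target_affine = (t.reference_affine if not t.is_affine
                         else tensors.affine)
    if target_shape is None:
        target_shape = (t.reference_shape if not t.is_affine
                        else tensors.shape3)
    target_affine = np.asarray(target_affine, dtype=float)
    target_shape = tuple(int(v) for v in target_shape)

    ii, jj, kk = np.meshgrid(*[np.arange(n) for n in target_shape], indexing="ij")
    ijk = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
    x_world = voxel_to_world(target_affine, ijk)            # template points

    if t.is_affine:
        inv = np.linalg.inv(t.affine)
        y_world = x_world @ inv[:3, :3].T + inv[:3, 3]
        linear = t.affine[:3, :3]
        if abs(np.linalg.det(linear)) < 1e-12:
            raise ValueError("non-invertible local Jacobian")
        per_voxel_linear = None
    else:
        disp = t.displacement.reshape(-1, 3)
        if t.displacement.shape[:3] != target_shape:
            raise ValueError("displacement grid must match the target grid")
        y_world = x_world + disp
        jac = _displacement_jacobian(t).reshape(-1, 3, 3)   # template->native
        det = np.linalg.det(jac)
        if np.any(np.abs(det) < 1e-12):
            bad = int(np.argmin(np.abs(det)))
            raise ValueError(
                f"non-invertible local Jacobian at voxel {tuple(ijk[bad])}")
        per_voxel_linear = np.linalg.inv(jac)               # native->template
        linear = None

    y_vox = world_to_voxel(tensors.affine, y_world)

    if interpolation == "nearest":
        idx = np.rint(y_vox).astype(int)
        inside = np.all((idx >= 0) & (idx < np.asarray(tensors.shape3)), axis=1)
        ic = np.clip(idx, 0, np.asarray(tensors.shape3) - 1)
        in_mask = inside & tensors.mask[ic[:, 0], ic[:, 1], ic[:, 2]]
        sampled = np.zeros((len(y_vox), 6))
        sampled[in_mask] = tensors.data[ic[in_mask, 0], ic[in_mask, 1],
                                        ic[in_mask, 2]]
        mats = tensors_to_matrices(sampled[in_mask])
    else:
        log_data = log_tensor_volume(tensors)
        samples, wsum = trilinear_weighted(log_data, tensors.mask, y_vox)
        in_mask = wsum >= mask_threshold
        mats = _expm_sym(tensors_to_matrices(samples[in_mask]))

    if in_mask.any():
        if per_voxel_linear is None:
            lin = linear
        else:
            lin = per_voxel_linear[in_mask]
        if use_ppd:
            mats = _ppd_rotate_tensors(mats, lin)
        else:
            r = _rotation_polar(lin)
            if r.ndim == 2:
                mats = r @ mats @ r.T
            else:
                mats = r @ mats @ np.swapaxes(r, -1, -2)

    out = np.zeros(target_shape + (6,))
    out_mask = in_mask.reshape(target_shape)
    out.reshape(-1, 6)[in_mask] = matrices_to_tensors(mats)
    return TensorVolume(out, target_affine, out_mask,
                        meta={"reorientation": "ppd" if use_ppd else "fs",
                              "interpolation": interpolation})


def log_euclidean_mean(volumes: list[TensorVolume], quorum: int | None = None,
                       mode: str = "log-euclidean") -> TensorVolume:
    """Voxel-wise mean of co-registered tensor volumes.

    Default is the log-Euclidean mean ``exp(mean(log D_k))`` (SPD-safe,
    geometric in the eigenvalues); ``mode="euclidean"`` averages the raw
    components.  Voxels present in fewer than ``quorum`` subjects (default:
    all of them — intersection) are zeroed.
    """
    if not volumes:
        raise ValueError("need at least one tensor volume")
    if mode not in ("log-euclidean", "euclidean"):
        raise ValueError(f"unknown averaging mode: {mode!r}")
    shape = volumes[0].shape3
    affine = volumes[0].affine
    for v in volumes[1:]:
        if v.shape3 != shape or not np.allclose(v.affine, affine, atol=1e-9):
            raise ValueError("tensor volumes are not on a common grid")
    if quorum is None:
        quorum = len(volumes)
    if not (1 <= quorum <= len(volumes)):
        raise ValueError("quorum must be in [1, n_volumes]")

    counts = np.sum([v.mask for v in volumes], axis=0)
    out_mask = counts >= quorum

    acc = np.zeros(shape + (6,))
    for v in volumes:
        data = log_tensor_volume(v) if mode == "log-euclidean" else v.data
        acc += np.where(v.mask[..., None], data, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        acc /= counts[..., None]
    acc[counts == 0] = 0.0
    acc[~out_mask] = 0.0
    if mode == "log-euclidean":
        acc = exp_tensor_volume(acc, out_mask)
    else:
        acc = np.where(out_mask[..., None], acc, 0.0)
    return TensorVolume(acc, affine.copy(), out_mask,
                        meta={"n_subjects": len(volumes), "mode": mode,
                              "quorum": quorum})


def downsample_tensor(tensors: TensorVolume,
                      target_voxel_size: tuple[float, float, float]
                      ) -> TensorVolume:
    """Retrospective downsampling to a coarser grid in log-Euclidean space.

    Each output voxel is ``exp`` of the mask-weighted average of the
    log-tensors of all source voxels whose centres fall inside it.  The
    source affine must be axis-aligned.  The output metadata records
    ``voxel_volume_ratio`` — how many times larger the new voxel is.
    """
    target = np.asarray(target_voxel_size, dtype=float)
    src = tensors.voxel_size
    if np.any(target < src - 1e-9):
        raise ValueError("target voxel size must be >= source voxel size")
    lin = tensors.affine[:3, :3]
    if not np.allclose(lin, np.diag(np.diag(lin)), atol=1e-9):
        raise ValueError("downsampling requires an axis-aligned affine")

    ratio = float(np.prod(target) / np.prod(src))
    if np.allclose(target, src, atol=1e-12):
        out = tensors.copy()
        out.meta["voxel_volume_ratio"] = ratio
        return out

    shape = np.asarray(tensors.shape3)
    # world position of the low corner of the source grid (edge of voxel 0)
    corner = voxel_to_world(tensors.affine, -0.5 * np.ones(3))[0]
    extent = shape * src
    out_shape = np.maximum(np.ceil(extent / target - 1e-9).astype(int), 1)

    ii, jj, kk = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    centers = voxel_to_world(tensors.affine,
                             np.stack([ii, jj, kk], axis=-1).reshape(-1, 3))
    bins = np.floor((centers - corner) / target).astype(int)
    bins = np.clip(bins, 0, out_shape - 1)
    flat = np.ravel_multi_index((bins[:, 0], bins[:, 1], bins[:, 2]), out_shape)

    log_data = log_tensor_volume(tensors).reshape(-1, 6)
    w = tensors.mask.reshape(-1).astype(float)
    acc = np.zeros((int(np.prod(out_shape)), 6))
    np.add.at(acc, flat, log_data * w[:, None])
    wsum = np.bincount(flat, weights=w, minlength=acc.shape[0])
    out_mask = (wsum > 0).reshape(tuple(out_shape))
    with np.errstate(invalid="ignore", divide="ignore"):
        acc /= wsum[:, None]
    acc[wsum == 0] = 0.0
    out_data = exp_tensor_volume(acc.reshape(tuple(out_shape) + (6,)), out_mask)

    out_affine = np.eye(4)
    out_affine[:3, :3] = np.diag(target * np.sign(np.diag(lin)))
    out_affine[:3, 3] = corner + 0.5 * target * np.sign(np.diag(lin))
    return TensorVolume(out_data, out_affine, out_mask,
                        meta={"voxel_volume_ratio": ratio,
                              "source_voxel_size": tuple(src),
                              "target_voxel_size": tuple(target)})
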