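"""Groupwise template construction from anatomical + FA channels.

The template loop follows the classic unbiased-atlas recipe: subjects are
first auto-aligned by principal axes of inertia (long axis of the
ventricular mask to +z), then iteratively registered to the evolving
average over a pyramid of resolutions, with the average of the per-subject
transforms factored out at every iteration ("shape centering") so the
template does not drift toward any one subject.  Registration maximises
weighted normalised cross-correlation (NCC) across modalities; rigid and
affine models are built in, and a nonlinear stage can be plugged in as an
external backend returning a displacement-field transform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

from .tensor_transform import SpatialTransform
from .volumes import ImageVolume, voxel_to_world

logger = logging.getLogger(__name__)

__all__ = [
    "TemplateLevelPlan",
    "OverlapMetrics",
    "overlap",
    "principal_axis_align",
    "register_pair",
    "build_template",
    "resample_to_grid",
]


@dataclass
class TemplateLevelPlan:
    """Multi-resolution schedule for template construction."""

    resolutions_mm: tuple = (2.4, 1.2, 0.6)
    models: tuple = ("rigid", "rigid", "affine")
    iterations: tuple = (2, 2, 2)
    modality_weights: tuple = (1.0, 0.5)

    def __post_init__(self) -> None:
        res = np.asarray(self.resolutions_mm, dtype=float)
        if np.any(np.diff(res) >= 0):
            raise ValueError("resolutions must be strictly decreasing")
        if len(self.models) != len(res) or len(self.iterations) != len(res):
            raise ValueError("models/iterations must match the resolution levels")
        if any(m not in ("rigid", "affine", "external-nonlinear")
               for m in self.models):
            raise ValueError("transform model must be rigid | affine | external-nonlinear")
        if any(w <= 0 for w in self.modality_weights):
            raise ValueError("modality weights must be positive")


@dataclass
class OverlapMetrics:
    dice: float
    jaccard: float


def overlap(mask_a: np.ndarray, mask_b: np.ndarray) -> OverlapMetrics:
    """Dice and Jaccard overlap of two binary masks on the same grid.

    ``Dice = 2|A∩B| / (|A|+|B|)``, ``Jaccard = |A∩B| / |A∪B|``.  Two empty
    masks are defined as perfectly overlapping (both metrics 1).
    """
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must share a grid")
    inter = float(np.sum(a & b))
    union = float(np.sum(a | b))
    total = float(a.sum() + b.sum())
    if union == 0:
        return OverlapMetrics(1.0, 1.0)
    return OverlapMetrics(2.0 * inter / total, inter / union)


# ---------------------------------------------------------------------------

def _grid_center_world(vol: ImageVolume) -> np.ndarray:
    center_ijk = (np.asarray(vol.shape3) - 1) / 2.0
    return voxel_to_world(vol.affine, center_ijk)[0]


def principal_axis_align(mask: ImageVolume,
                         target: np.ndarray | None = None) -> SpatialTransform:
    """Rigid transform aligning a mask's principal inertia axis to +z.

    The centroid maps to ``target`` (default: the world origin, the centre
    of the template field of view) and the most elongated covariance
    eigenvector to the z-axis, with the sign fixed so that the wider
    (basal) half of the shape ends up at high z.  Eigenvector signs are
    canonicalised (largest-magnitude component positive), so degenerate
    shapes such as spheres still yield a deterministic transform.
    """
    m = np.asarray(mask.data, dtype=bool)
    if not m.any():
        raise ValueError("cannot align an empty mask")
    ijk = np.argwhere(m)
    xyz = voxel_to_world(mask.affine, ijk)
    centroid = xyz.mean(axis=0)
    cov = np.cov((xyz - centroid).T)
    evals, evecs = np.linalg.eigh(cov)        # ascending; long axis = last
    order = np.argsort(evals)[::-1]
    axes = evecs[:, order]                    # columns: long, mid, short
    # canonical signs for determinism
    for c in range(3):
        if axes[np.argmax(np.abs(axes[:, c])), c] < 0:
            axes[:, c] *= -1
    long_axis = axes[:, 0]

    # wider half at +z: compare radial spread about the long axis
    proj = (xyz - centroid) @ long_axis
    radial = np.linalg.norm((xyz - centroid) - proj[:, None] * long_axis, axis=1)
    upper = radial[proj > 0]
    lower = radial[proj <= 0]
    if upper.size and lower.size and upper.mean() < lower.mean():
        long_axis = -long_axis

    # rotation sending long_axis -> +z (minimal rotation about their cross product)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(long_axis, z)
    c = float(np.dot(long_axis, z))
    if np.linalg.norm(v) < 1e-12:
        rot = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        rot = np.eye(3) + vx + vx @ vx / (1.0 + c)

    if target is None:
        target = np.zeros(3)
    translation = np.asarray(target, dtype=float) - rot @ centroid
    return SpatialTransform.from_rigid(rot, translation)


# ---------------------------------------------------------------------------
# pairwise registration

# internal parameter scaling so one Powell unit moves each parameter a
# comparable amount: rotations ~0.1 rad, translations ~1 mm, log-scales and
# shears ~0.05
_PARAM_SCALE_RIGID = np.array([0.1, 0.1, 0.1, 1.0, 1.0, 1.0])
_PARAM_SCALE_AFFINE = np.concatenate([_PARAM_SCALE_RIGID,
                                      [0.05, 0.05, 0.05, 0.05, 0.05, 0.05]])


def _params_to_affine(p: np.ndarray, model: str, center: np.ndarray) -> np.ndarray:
    """Parameter vector -> 4x4 world affine (rotation about ``center``)."""
    rx, ry, rz, tx, ty, tz = p[:6]
    cx, cy, cz = np.cos([rx, ry, rz])
    sx, sy, sz = np.sin([rx, ry, rz])
    rot_x = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    rot_y = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rot_z = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    lin = rot_z @ rot_y @ rot_x
    if model == "affine":
        scale = np.diag(np.exp(p[6:9]))
        shear = np.eye(3)
        shear[0, 1], shear[0, 2], shear[1, 2] = p[9:12]
        lin = lin @ scale @ shear
    aff = np.eye(4)
    aff[:3, :3] = lin
    aff[:3, 3] = np.asarray([tx, ty, tz]) + center - lin @ center
    return aff


def resample_to_grid(img: ImageVolume, transform: SpatialTransform,
                     target_affine: np.ndarray, target_shape,
                     order: int = 1, cval: float = 0.0) -> np.ndarray:
    """Resample an image into a target grid under a forward world transform.

    ``transform`` maps native -> target world; each target voxel pulls the
    value from the native location through the inverse map.
    """
    target_affine = np.asarray(target_affine, dtype=float)
    if transform.is_affine:
        # native voxel = inv(native_affine) @ inv(T) @ target_affine @ target voxel
        full = np.linalg.inv(img.affine) @ np.linalg.inv(transform.affine) @ target_affine
        return ndimage.affine_transform(
            np.asarray(img.data, dtype=float), full[:3, :3], offset=full[:3, 3],
            output_shape=tuple(int(s) for s in target_shape), order=order,
            mode="constant", cval=cval)
    # displacement field: target point x samples native point x + u(x)
    if tuple(transform.reference_shape) != tuple(int(s) for s in target_shape):
        raise ValueError("displacement reference grid must match the target grid")
    shape = tuple(int(s) for s in target_shape)
    ii, jj, kk = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    ijk = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
    x = voxel_to_world(target_affine, ijk) + transform.displacement.reshape(-1, 3)
    inv = np.linalg.inv(img.affine)
    vox = x @ inv[:3, :3].T + inv[:3, 3]
    out = ndimage.map_coordinates(np.asarray(img.data, dtype=float), vox.T,
                                  order=order, mode="constant", cval=cval)
    return out.reshape(shape)


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return 0.0
    return float((a * b).sum() / denom)


def _pyramid(data: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return data
    sm = ndimage.gaussian_filter(data, sigma=factor / 2.0)
    return sm[::factor, ::factor, ::factor]


def register_pair(moving: list, fixed: list, weights=None,
                  model: str = "rigid",
                  init: SpatialTransform | None = None,
                  pyramid_factors: tuple = (4, 2, 1),
                  maxiter: int = 40) -> SpatialTransform:
    """Estimate a rigid or affine world transform maximising weighted NCC.

    ``moving``/``fixed`` are matched lists of modality volumes (e.g.
    anatomical + FA).  Optimisation is multi-resolution Powell over a
    scaled parameter space and is deterministic for fixed inputs.
    """
    if model not in ("rigid", "affine"):
        raise ValueError("model must be 'rigid' or 'affine'")
    if not isinstance(moving, (list, tuple)):
        moving, fixed = [moving], [fixed]
    if len(moving) != len(fixed) or not moving:
        raise ValueError("need matched non-empty modality lists")
    weights = np.ones(len(moving)) if weights is None else np.asarray(weights, float)
    weights = weights / weights.sum()

    init_aff = np.eye(4) if init is None else init.affine
    center = _grid_center_world(fixed[0])
    scale = _PARAM_SCALE_RIGID if model == "rigid" else _PARAM_SCALE_AFFINE
    p = np.zeros(len(scale))

    fixed_native = [np.asarray(f.data, dtype=float) for f in fixed]
    if all(f.sum() == 0 for f in fixed_native):
        raise ValueError("fixed volumes are empty; fields of view do not overlap")

    for factor in pyramid_factors:
        fixed_level = []
        for f in fixed:
            data = _pyramid(np.asarray(f.data, dtype=float), factor)
            aff = f.affine.copy()
            aff[:3, :3] *= factor
            fixed_level.append(ImageVolume(data, aff))
        mov_level = [ImageVolume(_pyramid(np.asarray(m.data, float), factor),
                                 _scaled_affine(m.affine, factor))
                     for m in moving]

        def loss(ps: np.ndarray) -> float:
            aff = _params_to_affine(ps * scale, model, center) @ init_aff
            t = SpatialTransform(affine=aff)
            total = 0.0
            for w, mv, fx in zip(weights, mov_level, fixed_level):
                res = resample_to_grid(mv, t, fixed_level[0].affine,
                                       fixed_level[0].shape3, order=1)
                total += w * _ncc(res, np.asarray(fx.data, float))
            return -total

        res = optimize.minimize(loss, p, method="Powell",
                                options={"maxiter": maxiter, "xtol": 1e-4,
                                         "ftol": 1e-7})
        p = res.x
        if factor == pyramid_factors[-1]:
            # polishing pass at the finest level (Powell restarts reset the
            # direction set, which helps coupled scale/translation modes)
            res = optimize.minimize(loss, p, method="Powell",
                                    options={"maxiter": maxiter,
                                             "xtol": 1e-6, "ftol": 1e-9})
            p = res.x
    final = _params_to_affine(p * scale, model, center) @ init_aff
    return SpatialTransform(affine=final)


def _scaled_affine(affine: np.ndarray, factor: int) -> np.ndarray:
    aff = affine.copy()
    aff[:3, :3] = aff[:3, :3] * factor
    return aff


# ---------------------------------------------------------------------------
# template construction

def _template_grid(subjects, resolution: float, margin_mm: float = 2.0):
    """Symmetric grid about the world origin covering every aligned subject."""
    half = 0.0
    for anat, _fa, _mask in subjects:
        shape = np.asarray(anat.shape3)
        corners = np.array(np.meshgrid([0, shape[0] - 1], [0, shape[1] - 1],
                                       [0, shape[2] - 1])).reshape(3, -1).T
        xyz = voxel_to_world(anat.affine, corners)
        half = max(half, float(np.abs(xyz).max()))
    half += margin_mm
    n = int(np.ceil(2 * half / resolution))
    aff = np.eye(4)
    aff[:3, :3] = np.diag([resolution] * 3)
    aff[:3, 3] = -(n - 1) / 2.0 * resolution
    return aff, (n, n, n)


def build_template(subjects: list, plan: TemplateLevelPlan,
                   nonlinear_backend=None) -> tuple[dict, list]:
    """Iterative multi-resolution groupwise template.

    ``subjects``: list of ``(anatomical, fa, mask)`` :class:`ImageVolume`
    triples in native space.  Per level the current template is resampled
    to the level resolution, every subject is registered to it (the level's
    model, compositional updates on top of the running transform), the
    average transform is factored out, and the warped channels are averaged
    voxel-wise.  Returns the template channels (``anatomical``, ``fa``,
    ``mask`` on the final grid) and the per-subject forward transforms.

    ``nonlinear_backend``: optional callable ``(moving_channels,
    fixed_channels) -> SpatialTransform`` applied at levels whose model is
    ``"external-nonlinear"``; the shipped default is none (rigid/affine
    only).
    """
    if len(subjects) < 2:
        raise ValueError("template construction needs at least 2 subjects")

    # initialization: principal-axes alignment
    transforms = []
    for i, (_anat, _fa, mask) in enumerate(subjects):
        try:
            transforms.append(principal_axis_align(mask))
        except ValueError as exc:
            raise ValueError(f"subject {i}: {exc}") from exc

    template = None
    grid_affine, grid_shape = None, None
    for level, resolution in enumerate(plan.resolutions_mm):
        model = plan.models[level]
        grid_affine, grid_shape = _template_grid(subjects, resolution)

        def warp_all(trs):
            chans = {"anatomical": [], "fa": [], "mask": []}
            for (anat, fa, mask), t in zip(subjects, trs):
                chans["anatomical"].append(
                    resample_to_grid(anat, t, grid_affine, grid_shape))
                chans["fa"].append(resample_to_grid(fa, t, grid_affine, grid_shape))
                chans["mask"].append(
                    resample_to_grid(mask, t, grid_affine, grid_shape) >= 0.5)
            return chans

        chans = warp_all(transforms)
        template = {k: np.mean(chans[k], axis=0) for k in ("anatomical", "fa")}
        template["mask"] = np.mean(chans["mask"], axis=0) >= 0.5

        for it in range(plan.iterations[level]):
            fixed = [ImageVolume(template["anatomical"], grid_affine),
                     ImageVolume(template["fa"], grid_affine)]
            deltas = []
            for i, ((anat, fa, _mask), t) in enumerate(zip(subjects, transforms)):
                if model == "external-nonlinear":
                    if nonlinear_backend is None:
                        raise ValueError(
                            f"level {level} requests an external nonlinear "
                            "backend but none was provided")
                    warped = [ImageVolume(resample_to_grid(anat, t, grid_affine,
                                                           grid_shape), grid_affine),
                              ImageVolume(resample_to_grid(fa, t, grid_affine,
                                                           grid_shape), grid_affine)]
                    delta = nonlinear_backend(warped, fixed)
                else:
                    try:
                        delta = register_pair(
                            [anat, fa], fixed, weights=plan.modality_weights,
                            model=model, init=transforms[i])
                        delta = SpatialTransform(
                            affine=delta.affine @ np.linalg.inv(t.affine))
                    except Exception as exc:
                        raise RuntimeError(
                            f"registration failed for subject {i} at level "
                            f"{level} (resolution {resolution} mm): {exc}") from exc
                deltas.append(delta)

            if model == "external-nonlinear":
                # displacement transforms compose with the running affines
                # outside this loop; the contract returns template-grid fields
                transforms = [
                    _compose_displacement(d, t) for d, t in zip(deltas, transforms)]
            else:
                transforms = [SpatialTransform(affine=d.affine @ t.affine)
                              for d, t in zip(deltas, transforms)]
                # shape centering: remove the average affine component
                mean_aff = np.mean([t.affine for t in transforms], axis=0)
                inv_mean = np.linalg.inv(mean_aff)
                transforms = [SpatialTransform(affine=inv_mean @ t.affine)
                              for t in transforms]

            chans = warp_all(transforms)
            template = {k: np.mean(chans[k], axis=0) for k in ("anatomical", "fa")}
            template["mask"] = np.mean(chans["mask"], axis=0) >= 0.5
            logger.info("template level %d (%.2f mm) iteration %d done",
                        level, resolution, it)

    out = {k: ImageVolume(np.asarray(v, dtype=float), grid_affine)
           for k, v in template.items()}
    return out, transforms


def _compose_displacement(delta: SpatialTransform,
                          base: SpatialTransform) -> SpatialTransform:
    """Compose an incremental template-grid displacement with a base affine.

    The composite pullback field maps a template point x to the native
    point ``inv(base)(x + u(x))``; it is stored as a displacement on the
    same reference grid.
    """
    if delta.is_affine:
        return SpatialTransform(affine=delta.affine @ base.affine)
    shape = delta.reference_shape
    ii, jj, kk = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    ijk = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
    x = voxel_to_world(delta.reference_affine, ijk)
    y = x + delta.displacement.reshape(-1, 3)
    inv = np.linalg.inv(base.affine)
    native = y @ inv[:3, :3].T + inv[:3, 3]
    u = (native - x).reshape(tuple(shape) + (3,))
    return SpatialTransform(displacement=u,
                            reference_affine=delta.reference_affine,
                            reference_shape=shape)
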