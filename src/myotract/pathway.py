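"""ROI-pathway connectivity analysis and streamline-derived maps.

A *pathway rule* is a connectivity query: streamlines seeded in one region
must pass through an ordered (or unordered) list of inclusion regions to
count as connecting.  The *pathway ratio* — surviving streamlines over
requested streamlines, as a percentage — quantifies structural continuity
between regions; a fiber-field discontinuity (such as the long-axis
junction bundle sitting orthogonal to circumferential wall fibers) blocks
tracking and drives the ratio toward zero.

The *propagation angle* is the turning angle between adjacent step vectors
along a streamline; aggregated per voxel it maps curvature and flags
fiber-discontinuity regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tracking import (
    SeedRegion,
    Tractogram,
    TrackingParams,
    seed_points,
    track_det,
    track_fact,
    track_prob,
)
from .volumes import world_to_voxel

__all__ = [
    "PathwayRule",
    "PropagationAngleMap",
    "filter_by_rois",
    "pathway_ratio",
    "propagation_angle",
    "pa_map",
    "cut_to_region",
    "bundle_geometry",
]


@dataclass
class PathwayRule:
    """Seed region + inclusion (and optional exclusion) regions."""

    seed: SeedRegion
    include: list
    exclude: list = field(default_factory=list)
    n_requested: int = 1000
    name: str = ""

    def __post_init__(self) -> None:
        if len(self.include) < 1:
            raise ValueError("a pathway rule needs at least one inclusion region")
        if self.n_requested < 1:
            raise ValueError("requested streamline count must be >= 1")


@dataclass
class PropagationAngleMap:
    """Per-voxel aggregated propagation angle (degrees)."""

    values: np.ndarray        # NaN where undefined
    counts: np.ndarray        # vertices per voxel
    affine: np.ndarray
    aggregation: str

    @property
    def defined(self) -> np.ndarray:
        return self.counts > 0


def _first_hit(streamline: np.ndarray, region: SeedRegion) -> int:
    """Index of the first vertex inside the region, or -1."""
    hits = np.nonzero(region.contains(streamline))[0]
    return int(hits[0]) if hits.size else -1


def filter_by_rois(tractogram: Tractogram, rule: PathwayRule,
                   mode: str = "all") -> Tractogram:
    """Keep streamlines satisfying a pathway rule.

    ``mode="all"``: the streamline must intersect every inclusion region,
    in any order.  ``mode="ordered"``: the regions must be visited in the
    listed order along the streamline, in either traversal direction
    (streamline orientation is arbitrary).  Streamlines touching any
    exclusion region are dropped.  Intersection means any vertex inside
    the region (step sizes are far smaller than region radii).
    """
    if mode not in ("all", "ordered"):
        raise ValueError(f"unknown filter mode: {mode!r}")
    kept = []
    for sl in tractogram.streamlines:
        if any(region.contains(sl).any() for region in rule.exclude):
            continue
        if mode == "all":
            if all(region.contains(sl).any() for region in rule.include):
                kept.append(sl)
        else:
            fwd = [_first_hit(sl, r) for r in rule.include]
            ok_fwd = all(h >= 0 for h in fwd) and fwd == sorted(fwd)
            rev = [_first_hit(sl[::-1], r) for r in rule.include]
            ok_rev = all(h >= 0 for h in rev) and rev == sorted(rev)
            if ok_fwd or ok_rev:
                kept.append(sl)
    header = dict(tractogram.header)
    header["pathway"] = rule.name or "unnamed"
    header["filter_mode"] = mode
    return Tractogram(kept, tractogram.affine.copy(), header)


def pathway_ratio(tensors_or_metrics, rule: PathwayRule, algorithm: str,
                  params: TrackingParams | None = None,
                  rng: np.random.Generator | int | None = 0,
                  mode: str = "all") -> float:
    """Percentage of requested streamlines that satisfy a pathway rule.

    Seeds ``rule.n_requested`` streamlines from the rule's seed region,
    tracks with the chosen algorithm, filters by the rule, and returns
    ``100 * surviving / requested``.  Raw tracks are counted: every
    requested seed contributes one potential streamline.
    """
    params = params or TrackingParams()
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    seeds = seed_points(rule.seed, rule.n_requested, rng)
    algorithm = algorithm.lower()
    if algorithm == "fact":
        from .tensor_model import tensor_metrics
        from .volumes import TensorVolume
        metrics = (tensor_metrics(tensors_or_metrics)
                   if isinstance(tensors_or_metrics, TensorVolume)
                   else tensors_or_metrics)
        tg = track_fact(metrics, seeds=seeds, params=params)
    elif algorithm == "det":
        tg = track_det(tensors_or_metrics, seeds, params)
    elif algorithm == "prob":
        tg = track_prob(tensors_or_metrics, seeds, params, rng=rng)
    else:
        raise ValueError(f"unknown algorithm: {algorithm!r}")
    surviving = len(filter_by_rois(tg, rule, mode=mode))
    return 100.0 * surviving / rule.n_requested


def propagation_angle(streamline: np.ndarray) -> np.ndarray:
    """Per-vertex turning angles (degrees) along a streamline.

    ``angle_i = arccos(u_i . u_{i+1})`` for normalised consecutive step
    vectors; endpoints have no angle, so the result has ``n - 2`` entries.
    Fewer than 3 vertices yields an empty array.
    """
    sl = np.asarray(streamline, dtype=float)
    if len(sl) < 3:
        return np.empty(0)
    steps = np.diff(sl, axis=0)
    norms = np.linalg.norm(steps, axis=1)
    u = steps / norms[:, None].clip(min=1e-300)
    # atan2 formulation: accurate near 0 and 180 deg, unlike arccos
    cross = np.linalg.norm(np.cross(u[:-1], u[1:]), axis=1)
    dot = np.sum(u[:-1] * u[1:], axis=1)
    return np.degrees(np.arctan2(cross, dot))


def pa_map(tractogram: Tractogram, grid_shape: tuple[int, int, int],
           grid_affine: np.ndarray, aggregation: str = "mean") -> PropagationAngleMap:
    """Aggregate per-vertex propagation angles into a scalar volume.

    Each interior vertex deposits its angle into its containing voxel;
    per-voxel aggregation is the mean or the max.  Voxels receiving no
    vertex are NaN (undefined).
    """
    if aggregation not in ("mean", "max"):
        raise ValueError(f"unknown aggregation: {aggregation!r}")
    grid_affine = np.asarray(grid_affine, dtype=float)
    shape = np.asarray(grid_shape, dtype=int)
    acc = np.zeros(int(np.prod(shape)))
    counts = np.zeros(int(np.prod(shape)), dtype=int)
    mx = np.full(int(np.prod(shape)), -np.inf)

    for sl in tractogram.streamlines:
        angles = propagation_angle(sl)
        if angles.size == 0:
            continue
        vox = world_to_voxel(grid_affine, sl[1:-1])
        idx = np.floor(vox + 0.5).astype(int)
        inside = np.all((idx >= 0) & (idx < shape), axis=1)
        if not inside.any():
            continue
        flat = np.ravel_multi_index(
            (idx[inside, 0], idx[inside, 1], idx[inside, 2]), tuple(shape))
        np.add.at(acc, flat, angles[inside])
        np.add.at(counts, flat, 1)
        np.maximum.at(mx, flat, angles[inside])

    counts3 = counts.reshape(tuple(shape))
    if aggregation == "mean":
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = acc / counts
    else:
        vals = mx
    vals = vals.reshape(tuple(shape))
    vals = np.where(counts3 > 0, vals, np.nan)
    return PropagationAngleMap(vals, counts3, grid_affine.copy(), aggregation)


def cut_to_region(tractogram: Tractogram, region: SeedRegion,
                  min_length_mm: float = 0.0) -> Tractogram:
    """Truncate streamlines to their contiguous vertex runs inside a region.

    A streamline leaving and re-entering the region splits into several
    fragments; fragments shorter than ``min_length_mm`` are dropped.
    """
    out = []
    for sl in tractogram.streamlines:
        inside = region.contains(sl)
        if not inside.any():
            continue
        # contiguous runs of in-region vertices
        padded = np.concatenate([[False], inside, [False]])
        starts = np.nonzero(padded[1:] & ~padded[:-1])[0]
        ends = np.nonzero(~padded[1:] & padded[:-1])[0]
        for s, e in zip(starts, ends):
            frag = sl[s:e]
            if len(frag) < 2:
                continue
            length = float(np.linalg.norm(np.diff(frag, axis=0), axis=1).sum())
            if length >= min_length_mm:
                out.append(frag)
    header = dict(tractogram.header)
    header["cut"] = region.name or "region"
    return Tractogram(out, tractogram.affine.copy(), header)


def bundle_geometry(mask: np.ndarray,
                    voxel_size: tuple[float, float, float]
                    ) -> tuple[float, float]:
    """Volume (mm^3) and surface (mm^2) of a binary voxel region.

    Volume is voxel count x voxel volume.  Surface counts exposed voxel
    faces: for each axis, face area times the number of in/out transitions
    (including grid borders).  A meshed isosurface would smooth this; the
    voxel-face convention is exact for the blocky regions used here and
    deterministic.
    """
    mask = np.asarray(mask, dtype=bool)
    voxel_size = np.asarray(voxel_size, dtype=float)
    if not mask.any():
        return 0.0, 0.0
    vol = float(mask.sum() * np.prod(voxel_size))
    surface = 0.0
    for axis in range(3):
        face_area = float(np.prod(np.delete(voxel_size, axis)))
        padded = np.pad(mask, [(1, 1) if a == axis else (0, 0)
                               for a in range(3)])
        transitions = np.diff(padded.astype(np.int8), axis=axis) != 0
        surface += face_area * float(transitions.sum())
    return vol, surface
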