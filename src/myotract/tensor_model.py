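"""Diffusion tensor estimation and derived maps.

The estimator is the classic log-linear least-squares DTI fit: for each
voxel the model ``ln S_i = ln S0 - b_i g_i^T D g_i`` is solved for the 7
parameters ``(ln S0, Dxx, Dxy, Dxz, Dyy, Dyz, Dzz)``.  With the minimal
acquisition used here (6 diffusion directions + one b0) the system is
exactly determined, so the fit reproduces noiseless forward-simulated
signals to machine precision.

Derived scalar maps follow the standard definitions: mean diffusivity
(ADC) is the eigenvalue average and fractional anisotropy is

    FA = sqrt(3/2) * sqrt(sum_i (lam_i - <lam>)^2) / sqrt(sum_i lam_i^2)

with ``lam_1 >= lam_2 >= lam_3`` the sorted eigenvalues.  The colour-coded
FA map (cFA) encodes the primary eigenvector direction as RGB channels
scaled by FA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volumes import DWIVolume, ImageVolume, TensorVolume

logger = logging.getLogger(__name__)

__all__ = [
    "DiffusionScheme",
    "TensorMetrics",
    "MaskThresholds",
    "upsample_dwi",
    "fit_dti",
    "tensor_metrics",
    "compute_mask",
]


@dataclass
class DiffusionScheme:
    """Acquisition scheme: per-measurement b-value (s/mm^2) and unit direction.

    b0 entries carry a zero b-value; their direction is irrelevant and is
    stored as the zero vector.
    """

    bvals: np.ndarray
    bvecs: np.ndarray  # (n, 3)

    def __post_init__(self) -> None:
        self.bvals = np.asarray(self.bvals, dtype=float).ravel()
        self.bvecs = np.atleast_2d(np.asarray(self.bvecs, dtype=float))
        if self.bvecs.shape != (self.bvals.size, 3):
            raise ValueError("bvecs must have shape (n, 3) matching bvals")
        if np.any(self.bvals < 0):
            raise ValueError("b-values must be non-negative")
        dw = self.bvals > 0
        norms = np.linalg.norm(self.bvecs[dw], axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("diffusion-weighted directions must be unit vectors")
        self.bvecs = self.bvecs.copy()
        self.bvecs[~dw] = 0.0

    @property
    def n_measurements(self) -> int:
        return self.bvals.size

    @property
    def n_b0(self) -> int:
        return int(np.sum(self.bvals == 0))

    @property
    def n_dw(self) -> int:
        return int(np.sum(self.bvals > 0))

    def design_matrix(self) -> np.ndarray:
        """Rows ``[1, -b gx^2, -2b gxgy, -2b gxgz, -b gy^2, -2b gygz, -b gz^2]``.

        Column order after the intercept matches the tensor component
        storage order (Dxx, Dxy, Dxz, Dyy, Dyz, Dzz).
        """
        b = self.bvals
        g = self.bvecs
        return np.column_stack([
            np.ones_like(b),
            -b * g[:, 0] ** 2,
            -2 * b * g[:, 0] * g[:, 1],
            -2 * b * g[:, 0] * g[:, 2],
            -b * g[:, 1] ** 2,
            -2 * b * g[:, 1] * g[:, 2],
            -b * g[:, 2] ** 2,
        ])

    def validate_for_fit(self) -> None:
        if self.n_b0 < 1:
            raise ValueError("scheme needs at least one b0 measurement")
        if self.n_dw < 6:
            raise ValueError("scheme needs at least 6 diffusion-weighted measurements")
        x = self.design_matrix()
        if np.linalg.matrix_rank(x) < 7:
            raise ValueError("diffusion directions are collinear; design matrix is singular")


def default_scheme(b: float = 1000.0, n_b0: int = 1) -> DiffusionScheme:
    """6-direction dual-gradient scheme plus b0(s), the acquisition emulated here.

    The directions are the standard six-fold set ``(±1, ±1, 0)/sqrt(2)``
    and permutations — rotationally well spread and the conventional
    choice for a minimal DTI protocol.
    """
    dirs = np.array([
        [1, 1, 0], [1, -1, 0],
        [1, 0, 1], [1, 0, -1],
        [0, 1, 1], [0, 1, -1],
    ], dtype=float) / np.sqrt(2.0)
    bvals = np.concatenate([np.zeros(n_b0), np.full(6, float(b))])
    bvecs = np.vstack([np.zeros((n_b0, 3)), dirs])
    return DiffusionScheme(bvals, bvecs)


def dense_scheme(n_dirs: int = 30, b: float = 1000.0, n_b0: int = 1) -> DiffusionScheme:
    """Scheme with ``n_dirs`` directions spread by a Fibonacci sphere lattice.

    Needed when the residual-bootstrap probabilistic tracker requires
    redundant measurements (> 6 directions).
    """
    i = np.arange(n_dirs)
    golden = (1 + 5 ** 0.5) / 2
    theta = 2 * np.pi * i / golden
    z = 1 - (2 * i + 1) / n_dirs
    r = np.sqrt(np.clip(1 - z ** 2, 0, None))
    dirs = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_dirs, float(b))])
    bvecs = np.vstack([np.zeros((n_b0, 3)), dirs])
    return DiffusionScheme(bvals, bvecs)


@dataclass
class TensorMetrics:
    """Scalar and eigenvector maps derived from a tensor volume."""

    evals: np.ndarray        # (x, y, z, 3) sorted descending, mm^2/s
    evecs: np.ndarray        # (x, y, z, 3, 3); evecs[..., :, k] pairs with evals[..., k]
    fa: np.ndarray           # (x, y, z), unitless in [0, 1]
    adc: np.ndarray          # (x, y, z), mm^2/s
    cfa: np.ndarray          # (x, y, z, 3) RGB = FA * |v1|
    mask: np.ndarray
    affine: np.ndarray

    @property
    def trace(self) -> np.ndarray:
        return self.evals.sum(axis=-1)

    @property
    def v1(self) -> np.ndarray:
        return self.evecs[..., :, 0]

    @property
    def v2(self) -> np.ndarray:
        return self.evecs[..., :, 1]

    @property
    def v3(self) -> np.ndarray:
        return self.evecs[..., :, 2]


def upsample_dwi(dwi: DWIVolume, factor: int) -> DWIVolume:
    """Upsample each 3-D volume by an integer factor with trilinear interpolation.

    The grid dimensions multiply by ``factor`` and the voxel size divides by
    it; the affine is updated so voxel centres keep their world positions
    (centre-aligned resampling: old index ``(i_new + 0.5)/f - 0.5``).
    """
    factor = int(factor)
    if factor < 1:
        raise ValueError("upsampling factor must be >= 1")
    if factor == 1:
        return DWIVolume(dwi.data.copy(), dwi.affine.copy())

    nx, ny, nz, nvol = dwi.data.shape
    new_shape = (nx * factor, ny * factor, nz * factor)
    # voxel-index map: i_old = (i_new + 0.5)/f - 0.5
    scale = np.full(3, 1.0 / factor)
    offset = 0.5 / factor - 0.5
    out = np.empty(new_shape + (nvol,), dtype=float)
    matrix = np.diag(scale)
    off = np.full(3, offset)
    for v in range(nvol):
        out[..., v] = ndimage.affine_transform(
            dwi.data[..., v].astype(float), matrix, offset=off,
            output_shape=new_shape, order=1, mode="nearest")
    new_affine = dwi.affine.copy()
    new_affine[:3, :3] = dwi.affine[:3, :3] * scale
    new_affine[:3, 3] = dwi.affine[:3, 3] + dwi.affine[:3, :3] @ off
    return DWIVolume(out, new_affine)


def fit_dti(dwi: DWIVolume, scheme: DiffusionScheme,
            mask: np.ndarray | None = None,
            weighted: bool = False,
            signal_floor_frac: float = 1e-6) -> TensorVolume:
    """Log-linear least-squares diffusion tensor fit.

    Parameters
    ----------
    dwi
        4-D signal volume; measurement axis ordered as the scheme.
    scheme
        Acquisition scheme (>= 1 b0, >= 6 non-collinear DW directions).
    mask
        Boolean volume restricting the fit; defaults to voxels with
        positive mean b0 signal.
    weighted
        If True, a second weighted-least-squares pass with weights
        ``S_pred^2`` (the standard WLS refinement) follows the plain
        log-linear solve.
    signal_floor_frac
        Signals below ``signal_floor_frac *`` the voxel's estimated S0 are
        clipped before the log transform; occurrences are logged.
    """
    scheme.validate_for_fit()
    if dwi.n_volumes != scheme.n_measurements:
        raise ValueError(
            f"DWI has {dwi.n_volumes} volumes but scheme has "
            f"{scheme.n_measurements} measurements")

    b0_mean = dwi.data[..., scheme.bvals == 0].mean(axis=-1)
    if mask is None:
        mask = b0_mean > 0
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != dwi.shape3:
        raise ValueError("mask shape must match DWI grid")
    if np.any(b0_mean[mask] <= 0):
        raise ValueError("non-positive b0 signal inside the fitting mask")

    signals = dwi.data[mask].astype(float)                 # (n_vox, n_meas)
    s0_hat = b0_mean[mask][:, None]
    floor = signal_floor_frac * s0_hat
    n_clipped = int(np.sum(signals < floor))
    if n_clipped:
        logger.info("fit_dti: clipped %d non-positive/low signals to the log floor",
                    n_clipped)
    log_s = np.log(np.maximum(signals, floor))

    x = scheme.design_matrix()                             # (n_meas, 7)
    params = np.linalg.lstsq(x, log_s.T, rcond=None)[0].T  # (n_vox, 7)

    if weighted:
        # one WLS pass, weights = predicted squared signals
        pred = np.exp(params @ x.T)
        for i in range(params.shape[0]):
            w = pred[i]
            xw = x * w[:, None]
            params[i] = np.linalg.lstsq(xw, w * log_s[i], rcond=None)[0]

    tensors = np.zeros(dwi.shape3 + (6,), dtype=float)
    tensors[mask] = params[:, 1:]
    return TensorVolume(tensors, dwi.affine.copy(), mask,
                        meta={"estimator": "wls" if weighted else "lls"})


def _eigh_sorted_desc(mats: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Batched symmetric eigen-decomposition, eigenvalues sorted descending."""
    evals, evecs = np.linalg.eigh(mats)        # ascending
    evals = evals[..., ::-1]
    evecs = evecs[..., ::-1]
    return evals, evecs


def fa_from_evals(evals: np.ndarray) -> np.ndarray:
    """Fractional anisotropy from (already sorted) eigenvalues."""
    evals = np.asarray(evals, dtype=float)
    mean = evals.mean(axis=-1, keepdims=True)
    num = np.sqrt((np.square(evals - mean)).sum(axis=-1))
    den = np.sqrt(np.square(evals).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * num / den
    return np.where(den > 0, np.clip(fa, 0.0, 1.0), 0.0)


def tensor_metrics(tensors: TensorVolume, clamp_negative: bool = True) -> TensorMetrics:
    """Eigen-decompose a tensor volume into eigenvalue/eigenvector/FA/ADC/cFA maps.

    Negative eigenvalues (possible on noisy fits) are clamped to zero for
    the scalar maps; the count of clamped voxels is logged.
    """
    if np.any(~np.isfinite(tensors.data[tensors.mask])):
        bad = np.argwhere(~np.isfinite(tensors.data).all(axis=-1) & tensors.mask)[0]
        raise ValueError(f"NaN/inf tensor components at voxel {tuple(bad)}")

    mask = tensors.mask
    evals = np.zeros(tensors.shape3 + (3,))
    evecs = np.zeros(tensors.shape3 + (3, 3))
    evecs[..., 0, 0] = evecs[..., 1, 1] = evecs[..., 2, 2] = 1.0

    mats = tensors.as_matrices()[mask]
    if mats.size:
        ev, evec = _eigh_sorted_desc(mats)
        if clamp_negative:
            n_neg = int(np.sum(ev < 0))
            if n_neg:
                logger.info("tensor_metrics: clamped %d negative eigenvalues", n_neg)
            ev = np.clip(ev, 0.0, None)
        evals[mask] = ev
        evecs[mask] = evec

    fa = np.zeros(tensors.shape3)
    fa[mask] = fa_from_evals(evals[mask])
    adc = evals.mean(axis=-1)
    adc[~mask] = 0.0
    cfa = np.abs(evecs[..., :, 0]) * fa[..., None]
    return TensorMetrics(evals=evals, evecs=evecs, fa=fa, adc=adc, cfa=cfa,
                         mask=mask.copy(), affine=tensors.affine.copy())


@dataclass
class MaskThresholds:
    """Band-pass (low, high) bounds per channel; infinities disable a side."""

    fa: tuple[float, float] = (0.0, np.inf)
    trace: tuple[float, float] = (0.0, np.inf)
    dw: tuple[float, float] = (0.0, np.inf)

    def __post_init__(self) -> None:
        for name in ("fa", "trace", "dw"):
            low, high = getattr(self, name)
            if low > high:
                raise ValueError(f"{name} threshold low > high ({low} > {high})")


def compute_mask(metrics: TensorMetrics, dwi: DWIVolume,
                 thresholds: MaskThresholds,
                 largest_component: bool = True) -> ImageVolume:
    """Threshold-based myocardium mask from FA, trace and mean DW signal.

    The mask is the conjunction of the three band-pass tests; optionally
    only the largest 26-connected component is retained (automated
    replacement for manual mask editing).
    """
    mean_dw = dwi.data.mean(axis=-1)
    if mean_dw.shape != metrics.fa.shape:
        raise ValueError("DWI grid does not match metrics grid")

    def band(x, lo_hi):
        lo, hi = lo_hi
        return (x >= lo) & (x <= hi)

    mask = (band(metrics.fa, thresholds.fa)
            & band(metrics.trace, thresholds.trace)
            & band(mean_dw, thresholds.dw)
            & np.isfinite(mean_dw))

    if largest_component and mask.any():
        labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))
        if n > 1:
            counts = np.bincount(labels.ravel())
            counts[0] = 0
            mask = labels == np.argmax(counts)
    return ImageVolume(mask.astype(np.uint8), metrics.affine.copy())
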