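"""In-memory volume containers shared across the pipeline.

All volumes carry a 4x4 world affine mapping voxel indices (i, j, k) to
world coordinates in millimetres (RAS convention).  Conversions between
voxel and world space happen only through :func:`voxel_to_world` and
:func:`world_to_voxel`; everything downstream (tracking, ROI filtering,
warping) works in world mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Fixed storage order of the 6 unique symmetric-tensor components.
TENSOR_COMPONENTS = ("Dxx", "Dxy", "Dxz", "Dyy", "Dyz", "Dzz")

# index pairs (row, col) of each stored component in the 3x3 matrix
_COMP_IDX = ((0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2))


def voxel_sizes(affine: np.ndarray) -> np.ndarray:
    """Voxel edge lengths (mm) implied by an affine: column norms of the 3x3 part."""
    return np.linalg.norm(np.asarray(affine)[:3, :3], axis=0)


def voxel_to_world(affine: np.ndarray, ijk: np.ndarray) -> np.ndarray:
    ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
    return (ijk @ np.asarray(affine)[:3, :3].T) + np.asarray(affine)[:3, 3]


def world_to_voxel(affine: np.ndarray, xyz: np.ndarray) -> np.ndarray:
    inv = np.linalg.inv(np.asarray(affine))
    xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
    return (xyz @ inv[:3, :3].T) + inv[:3, 3]


def tensors_to_matrices(six: np.ndarray) -> np.ndarray:
    """(..., 6) component array -> (..., 3, 3) symmetric matrices."""
    six = np.asarray(six)
    out = np.empty(six.shape[:-1] + (3, 3), dtype=six.dtype)
    for c, (i, j) in enumerate(_COMP_IDX):
        out[..., i, j] = six[..., c]
        out[..., j, i] = six[..., c]
    return out


def matrices_to_tensors(mat: np.ndarray) -> np.ndarray:
    """(..., 3, 3) symmetric matrices -> (..., 6) component array."""
    mat = np.asarray(mat)
    out = np.empty(mat.shape[:-2] + (6,), dtype=mat.dtype)
    for c, (i, j) in enumerate(_COMP_IDX):
        out[..., c] = mat[..., i, j]
    return out


@dataclass
class ImageVolume:
    """A scalar (3-D) or multi-channel (4-D) volume with a world affine."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if not np.isfinite(np.linalg.det(self.affine)) or np.linalg.det(self.affine) == 0:
            raise ValueError("affine must be invertible")

    @property
    def shape3(self) -> tuple[int, int, int]:
        return tuple(self.data.shape[:3])

    @property
    def voxel_size(self) -> np.ndarray:
        return voxel_sizes(self.affine)

    def copy(self) -> "ImageVolume":
        return replace(self, data=self.data.copy(), affine=self.affine.copy())


@dataclass
class DWIVolume(ImageVolume):
    """4-D diffusion-weighted signal volume; last axis follows the scheme order."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.data.ndim != 4:
            raise ValueError("DWI data must be 4-D (x, y, z, measurement)")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]


@dataclass
class TensorVolume:
    """Voxel grid of symmetric diffusion tensors.

    ``data`` stores the 6 unique components per voxel in the fixed order
    ``(Dxx, Dxy, Dxz, Dyy, Dyz, Dzz)`` (mm^2/s).  ``mask`` marks voxels with
    a valid tensor; out-of-mask voxels are zero tensors.
    """

    data: np.ndarray
    affine: np.ndarray
    mask: np.ndarray = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4 or self.data.shape[-1] != 6:
            raise ValueError("tensor data must have shape (x, y, z, 6)")
        if self.mask is None:
            self.mask = np.any(self.data != 0, axis=-1)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.data.shape[:3]:
            raise ValueError("mask shape must match tensor grid")

    @property
    def shape3(self) -> tuple[int, int, int]:
        return tuple(self.data.shape[:3])

    @property
    def voxel_size(self) -> np.ndarray:
        return voxel_sizes(self.affine)

    def as_matrices(self) -> np.ndarray:
        return tensors_to_matrices(self.data)

    @classmethod
    def from_matrices(cls, mat: np.ndarray, affine: np.ndarray,
                      mask: np.ndarray = None, meta: dict = None) -> "TensorVolume":
        return cls(matrices_to_tensors(mat), affine, mask, meta or {})

    def copy(self) -> "TensorVolume":
        return TensorVolume(self.data.copy(), self.affine.copy(),
                            self.mask.copy(), dict(self.meta))
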