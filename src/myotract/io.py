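"""Readers and writers for the pipeline's on-disk formats.

NIfTI volumes go through nibabel; gradient tables use the FSL bval/bvec
dialect (one whitespace-separated row of b-values, three rows of direction
components); streamlines use the tck format via nibabel's streamlines API
(world-mm coordinates).  Affine transforms are plain 4x4 text matrices and
displacement fields are 3-component vector NIfTIs on their reference grid.
"""

from __future__ import annotations

import logging
from pathlib import Path

import nibabel as nib
import numpy as np

from .tensor_model import DiffusionScheme
from .tensor_transform import SpatialTransform
from .tracking import Tractogram
from .volumes import DWIVolume, ImageVolume, TensorVolume

logger = logging.getLogger(__name__)

__all__ = [
    "read_nifti", "write_nifti",
    "read_dwi", "write_dwi",
    "read_tensor_volume", "write_tensor_volume",
    "read_gradients", "write_gradients",
    "read_tck", "write_tck",
    "read_affine_transform", "write_affine_transform",
    "read_displacement_field", "write_displacement_field",
]


def read_nifti(path) -> ImageVolume:
    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise IOError(f"cannot read NIfTI file {path}: {exc}") from exc
    return ImageVolume(np.asarray(img.dataobj), np.asarray(img.affine))


def write_nifti(volume: ImageVolume, path) -> None:
    img = nib.Nifti1Image(np.asarray(volume.data), np.asarray(volume.affine))
    nib.save(img, str(path))


def read_dwi(path) -> DWIVolume:
    vol = read_nifti(path)
    return DWIVolume(vol.data, vol.affine)


def write_dwi(dwi: DWIVolume, path) -> None:
    write_nifti(ImageVolume(dwi.data, dwi.affine), path)


def write_tensor_volume(tensors: TensorVolume, path) -> None:
    """6-component 4-D NIfTI, component order Dxx Dxy Dxz Dyy Dyz Dzz."""
    img = nib.Nifti1Image(tensors.data, tensors.affine)
    img.header["descrip"] = b"tensor comps: Dxx Dxy Dxz Dyy Dyz Dzz"
    nib.save(img, str(path))


def read_tensor_volume(path, mask: np.ndarray | None = None) -> TensorVolume:
    vol = read_nifti(path)
    return TensorVolume(vol.data, vol.affine, mask)


def read_gradients(bval_path, bvec_path) -> DiffusionScheme:
    """FSL-style gradient table: bvals one row; bvecs three rows (x, y, z)."""
    bvals = np.loadtxt(str(bval_path), ndmin=1)
    bvecs = np.loadtxt(str(bvec_path), ndmin=2)
    if bvals.size == 0:
        raise ValueError(f"empty bval file: {bval_path}")
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T
    if bvecs.shape != (bvals.size, 3):
        raise ValueError(
            f"bval/bvec count mismatch: {bvals.size} b-values vs "
            f"{bvecs.shape[0]} directions")
    dw = bvals > 0
    norms = np.linalg.norm(bvecs[dw], axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-6):
        logger.warning("non-unit gradient directions in %s were normalised",
                       bvec_path)
        bvecs = bvecs.copy()
        bvecs[dw] /= norms[:, None]
    return DiffusionScheme(bvals, bvecs)


def write_gradients(scheme: DiffusionScheme, bval_path, bvec_path) -> None:
    np.savetxt(str(bval_path), scheme.bvals[None, :], fmt="%.6g")
    np.savetxt(str(bvec_path), scheme.bvecs.T, fmt="%.9f")


#: tck header fields managed by the format writer itself
_TCK_RESERVED = {"magic_number", "count", "datatype", "file", "endianness",
                 "_dtype", "_offset_data", "nb_streamlines", "voxel_to_rasmm",
                 "timestamp"}


def write_tck(tractogram: Tractogram, path) -> None:
    sls = [np.asarray(s, dtype=np.float32) for s in tractogram.streamlines]
    nb_tg = nib.streamlines.Tractogram(sls, affine_to_rasmm=np.eye(4))
    header = {str(k): str(v) for k, v in tractogram.header.items()
              if str(k) not in _TCK_RESERVED}
    tck = nib.streamlines.TckFile(nb_tg, header=header)
    tck.save(str(path))


def read_tck(path) -> Tractogram:
    try:
        tck = nib.streamlines.load(str(path))
    except Exception as exc:
        raise IOError(f"cannot read tck file {path}: {exc}") from exc
    sls = [np.asarray(s, dtype=float) for s in tck.streamlines]
    header = {k: v for k, v in tck.header.items()}
    return Tractogram(sls, np.eye(4), header)


def write_affine_transform(t: SpatialTransform, path) -> None:
    if not t.is_affine:
        raise ValueError("use write_displacement_field for dense transforms")
    np.savetxt(str(path), t.affine, fmt="%.12g")


def read_affine_transform(path) -> SpatialTransform:
    aff = np.loadtxt(str(path))
    if aff.shape != (4, 4):
        raise ValueError(f"transform file {path} is not a 4x4 matrix")
    return SpatialTransform(affine=aff)


def write_displacement_field(t: SpatialTransform, path) -> None:
    """Displacement field as a 3-component vector NIfTI on its reference grid."""
    if t.is_affine:
        raise ValueError("use write_affine_transform for affine transforms")
    img = nib.Nifti1Image(t.displacement, t.reference_affine)
    img.header["descrip"] = b"pullback displacement, mm, x->x+u(x)"
    nib.save(img, str(path))


def read_displacement_field(path) -> SpatialTransform:
    vol = read_nifti(path)
    return SpatialTransform(displacement=vol.data,
                            reference_affine=vol.affine)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
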