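"""NIfTI volume I/O and sensitivity-matrix serialization."""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np

from .decompose import SensitivityMatrix

__all__ = ["read_volume", "write_volume", "read_sensitivity", "write_sensitivity"]

_NIFTI_SUFFIXES = (".nii", ".nii.gz")


def _check_suffix(path: Path):
    name = path.name
    if not any(name.endswith(s) for s in _NIFTI_SUFFIXES):
        raise ValueError(
            f"unsupported volume format {path.suffix!r} for {name}; "
            "expected a NIfTI file (.nii or .nii.gz)"
        )


def read_volume(path) -> tuple:
    """Read a NIfTI volume; returns ``(data, voxel_size_mm)``.

    Warns when the header spacing is anisotropic (the pipeline assumes
    isotropic voxels) and returns the mean spacing in that case.
    """
    path = Path(path)
    _check_suffix(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    zooms = img.header.get_zooms()[:3]
    if not np.allclose(zooms, zooms[0]):
        warnings.warn(
            f"{path.name}: anisotropic spacing {zooms}; pipeline assumes "
            "isotropic voxels",
            stacklevel=2,
        )
    return data, float(np.mean(zooms))


def write_volume(volume: np.ndarray, path, voxel_size_mm: float):
    """Write a volume as NIfTI-1 with isotropic spacing in the header."""
    path = Path(path)
    _check_suffix(path)
    volume = np.asarray(volume)
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    img = nib.Nifti1Image(volume, affine)
    img.header.set_zooms((voxel_size_mm,) * 3)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))


def write_sensitivity(A: SensitivityMatrix, path):
    Path(path).write_text(json.dumps(A.to_dict(), indent=2))


def read_sensitivity(path) -> SensitivityMatrix:
    return SensitivityMatrix.from_dict(json.loads(Path(path).read_text()))
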