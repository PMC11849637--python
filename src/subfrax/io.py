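"""NIfTI input/output for masks, dose grids and displacement fields.

Files are written with a diagonal voxel-to-world affine following the
package axis convention (LR, AP, SI).  On read, files in other axis-aligned
orientations are reoriented to the closest canonical orientation; oblique
affines are rejected.  Spacing and origin round-trip bit-exactly because the
affine is stored in float64.
"""

from __future__ import annotations

import os

import nibabel as nib
import numpy as np

from .grids import DoseGrid, ImageGrid, StructureMask

__all__ = [
    "read_mask",
    "write_mask",
    "read_dose",
    "write_dose",
    "read_field",
    "write_field",
]

_OBLIQUE_TOL = 1e-6


def _load_canonical(path):
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such file: {path}")
    img = nib.load(str(path))
    img = nib.as_closest_canonical(img)
    aff = img.affine
    if aff is None:
        raise ValueError(f"{path}: NIfTI affine (spacing/origin metadata) is absent")
    off_diag = aff[:3, :3] - np.diag(np.diag(aff[:3, :3]))
    if np.abs(off_diag).max() > _OBLIQUE_TOL * max(1.0, np.abs(aff).max()):
        raise ValueError(
            f"{path}: oblique orientation is not supported; affine must be axis-aligned"
        )
    spacing = np.diag(aff[:3, :3])
    if np.any(spacing <= 0):
        raise ValueError(f"{path}: non-positive spacing in affine: {spacing}")
    grid_of = lambda shape: ImageGrid(tuple(shape), tuple(spacing), tuple(aff[:3, 3]))
    return img, grid_of


def read_mask(path) -> StructureMask:
    """Read a binary structure mask from a NIfTI file.

    Nonzero voxels map to True.  The structure name is taken from the file
    stem.
    """
    img, grid_of = _load_canonical(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D payload, got ndim={data.ndim}")
    name = os.path.basename(str(path))
    for ext in (".nii.gz", ".nii"):
        if name.endswith(ext):
            name = name[: -len(ext)]
    return StructureMask(grid_of(data.shape), name, data != 0)


def write_mask(mask: StructureMask, path) -> None:
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), mask.grid.affine())
    img.header.set_zooms(mask.grid.spacing)
    nib.save(img, str(path))


def read_dose(path) -> DoseGrid:
    """Read a dose grid (cGy, full-scheme scale) from a NIfTI file."""
    img, grid_of = _load_canonical(path)
    data = np.asanyarray(img.dataobj).astype(float)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D dose payload, got ndim={data.ndim}")
    return DoseGrid(grid_of(data.shape), data)  # DoseGrid validates >= 0, finite


def write_dose(dose: DoseGrid, path) -> None:
    img = nib.Nifti1Image(dose.dose.astype(np.float64), dose.grid.affine())
    img.header.set_zooms(dose.grid.spacing)
    nib.save(img, str(path))


def read_field(path):
    """Read a displacement field stored as 4-D NIfTI (last axis = 3, mm)."""
    from .motion import DisplacementField

    img, grid_of = _load_canonical(path)
    data = np.asanyarray(img.dataobj).astype(float)
    if data.ndim != 4 or data.shape[-1] != 3:
        raise ValueError(
            f"{path}: displacement field must be 4-D with last dimension 3, got {data.shape}"
        )
    return DisplacementField(grid_of(data.shape[:3]), data)


def write_field(field, path) -> None:
    grid = field.grid
    img = nib.Nifti1Image(field.vectors.astype(np.float64), grid.affine())
    img.header.set_zooms(grid.spacing + (1.0,))
    nib.save(img, str(path))
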