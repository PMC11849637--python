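"""Dose-volume histogram metrics: V_D, D_cc, D_mean and the cumulative DVH.

Conventions (package-wide): a voxel belongs to a structure if its center
does; every voxel contributes its full volume; the V_D threshold is
inclusive (dose >= D counts).  D_cc is linearly interpolated between the
bracketing sorted voxels of the cumulative hottest-volume curve.
"""

from __future__ import annotations

import warnings

import numpy as np

from .grids import DoseGrid, GridMismatchError, StructureMask

__all__ = ["v_dose", "d_cc", "d_mean", "dvh_curve"]


def _structure_doses(dose: DoseGrid, mask: StructureMask) -> np.ndarray:
    if dose.grid.shape != mask.grid.shape:
        raise GridMismatchError(
            f"dose grid {dose.grid.shape} does not match mask '{mask.name}' {mask.grid.shape}"
        )
    if mask.is_empty:
        raise ValueError(f"structure '{mask.name}' is empty")
    return dose.dose[mask.voxels]


def v_dose(dose: DoseGrid, mask: StructureMask, threshold_cGy: float) -> float:
    """Percent of the structure volume receiving at least ``threshold_cGy``."""
    d = _structure_doses(dose, mask)
    return 100.0 * float(np.count_nonzero(d >= threshold_cGy)) / d.size


def d_cc(dose: DoseGrid, mask: StructureMask, volume_cc: float) -> float:
    """Minimum dose (cGy) to the hottest ``volume_cc`` cm3 of the structure.

    If the structure is smaller than the queried volume, the structure's
    minimum dose is returned with a warning.
    """
    if volume_cc <= 0:
        raise ValueError(f"volume_cc must be > 0, got {volume_cc}")
    d = np.sort(_structure_doses(dose, mask))[::-1]
    voxvol = mask.grid.voxel_volume_cc
    total = d.size * voxvol
    if total < volume_cc:
        warnings.warn(
            f"structure '{mask.name}' volume {total:.3f} cc is smaller than the "
            f"queried {volume_cc} cc; returning the structure minimum dose",
            stacklevel=2,
        )
        return float(d[-1])
    # cumulative hottest volume after k voxels is k * voxvol; the dose at
    # which it first reaches volume_cc interpolates between bracketing voxels
    k = volume_cc / voxvol  # fractional voxel count, in (0, d.size]
    lo = int(np.ceil(k)) - 1  # 0-based index of the voxel that completes the volume
    if lo <= 0:
        return float(d[0])
    frac = k - lo  # in (0, 1]: position between sorted voxels lo-1 and lo
    return float(d[lo - 1] + (d[lo] - d[lo - 1]) * frac)


def d_mean(dose: DoseGrid, mask: StructureMask) -> float:
    """Arithmetic mean dose (cGy) over the structure voxels."""
    return float(_structure_doses(dose, mask).mean())


def dvh_curve(dose: DoseGrid, mask: StructureMask, bin_width_cGy: float = 10.0):
    """Cumulative DVH: (bin edges cGy, percent volume receiving >= edge).

    The curve starts at 100 % (edge 0) and is monotone non-increasing;
    ``v_dose`` at a bin edge equals the curve value there exactly.
    """
    if bin_width_cGy <= 0:
        raise ValueError(f"bin_width_cGy must be > 0, got {bin_width_cGy}")
    d = _structure_doses(dose, mask)
    n_bins = int(np.floor(d.max() / bin_width_cGy)) + 2
    edges = np.arange(n_bins) * bin_width_cGy
    percent = 100.0 * (d[None, :] >= edges[:, None]).sum(axis=1) / d.size
    return edges, percent
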