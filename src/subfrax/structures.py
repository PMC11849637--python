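"""Clinical margin recipe: GTV+4mm, CTV and PTV from a structure set.

The recipe mirrors the margin policy used clinically for hypofractionated
prostate treatments on the MR-linac:

* ``gtv4mm`` — the GTV expanded by an isotropic margin (default 4 mm) while
  staying outside the rectum and bladder;
* ``ctv``    — the union of the prostate and ``gtv4mm``;
* ``ptv``    — the CTV expanded by anisotropic setup margins, default
  2 mm LR, 3 mm AP, 2 mm SI.

Margin expansion is an ellipsoidal dilation measured between voxel centers
in world mm: voxel ``p`` belongs to the expansion of mask ``M`` by margins
``(m_LR, m_AP, m_SI)`` iff

    min over q in M of sqrt(sum_axis ((p - q)_axis / m_axis)^2) <= 1.

The isotropic case reduces to classical Euclidean dilation by a ball of the
margin radius.  It is computed with an exact Euclidean distance transform on
anisotropically scaled spacings, so it agrees voxel-for-voxel with a
brute-force pairwise-distance oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grids import GridMismatchError, StructureMask, StructureSet

__all__ = ["MarginSpec", "expand_margin", "recreate_targets"]

# slack on the scaled distance <= 1 test, so that offsets lying exactly on the
# margin ellipsoid are included regardless of float rounding
_BOUNDARY_EPS = 1e-9

# per-axis pseudo-spacing used for zero-margin axes: any whole-voxel step along
# such an axis pushes the scaled distance far beyond 1 (no growth on that axis)
_ZERO_MARGIN_SAMPLING = 1e9


@dataclass(frozen=True)
class MarginSpec:
    """Margins of the clinical target recipe.

    ``gtv_margin_mm`` is the isotropic GTV expansion; ``ptv_margins_mm`` are
    the per-axis (LR, AP, SI) CTV-to-PTV setup margins.
    """

    gtv_margin_mm: float = 4.0
    ptv_margins_mm: tuple[float, float, float] = (2.0, 3.0, 2.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "gtv_margin_mm", float(self.gtv_margin_mm))
        object.__setattr__(
            self, "ptv_margins_mm", tuple(float(m) for m in self.ptv_margins_mm)
        )
        if self.gtv_margin_mm < 0:
            raise ValueError(f"gtv_margin_mm must be >= 0, got {self.gtv_margin_mm}")
        if len(self.ptv_margins_mm) != 3 or any(m < 0 for m in self.ptv_margins_mm):
            raise ValueError(
                f"ptv_margins_mm must be three non-negative values, got {self.ptv_margins_mm}"
            )


def expand_margin(
    mask: StructureMask,
    margins_mm,
    exclude: list[StructureMask] | None = None,
    name: str | None = None,
) -> StructureMask:
    """Expand a mask by per-axis margins (mm), then subtract exclusion masks.

    A scalar margin is treated as isotropic.  Margins of zero on some axes
    degenerate to no growth along those axes; all-zero margins return the
    input (minus exclusions).  Exclusion is subtractive — applied after the
    expansion, it constrains membership, not growth paths.
    """
    margins = np.asarray(margins_mm, dtype=float)
    if margins.ndim == 0:
        margins = np.repeat(margins, 3)
    if margins.shape != (3,):
        raise ValueError(f"margins_mm must be a scalar or length-3, got {margins_mm}")
    if np.any(margins < 0) or not np.all(np.isfinite(margins)):
        raise ValueError(f"margins must be finite and >= 0, got {margins}")
    # margins below a nanometer are physically zero; clamping also keeps the
    # scaled sampling finite
    margins = np.where(margins < 1e-6, 0.0, margins)
    for other in exclude or []:
        if other.grid.shape != mask.grid.shape:
            raise GridMismatchError(
                f"exclusion mask '{other.name}' is not on the same grid as '{mask.name}'"
            )

    if np.all(margins == 0) or mask.is_empty:
        out = mask.voxels.copy()
    else:
        sampling = np.full(3, _ZERO_MARGIN_SAMPLING)
        np.divide(
            np.asarray(mask.grid.spacing), margins, out=sampling, where=margins > 0
        )
        # distance from every voxel center to the nearest in-mask voxel center,
        # in margin-scaled units; <= 1 is the ellipsoidal structuring element
        dist = ndimage.distance_transform_edt(~mask.voxels, sampling=sampling)
        out = dist <= 1.0 + _BOUNDARY_EPS

    for other in exclude or []:
        out &= ~other.voxels
    return StructureMask(mask.grid, name if name is not None else f"{mask.name}_expanded", out)


def recreate_targets(
    structures: StructureSet, spec: MarginSpec = MarginSpec()
) -> StructureSet:
    """Fill in ``gtv4mm``, ``ctv`` and ``ptv`` from prostate/GTV/OAR masks.

    Requires ``prostate``, ``gtv``, ``bladder`` and ``rectum`` with
    gtv ⊆ prostate.  The PTV is expanded without OAR carving.  Returns a new
    StructureSet; the input is not modified.
    """
    for required in ("prostate", "gtv", "bladder", "rectum"):
        if required not in structures:
            raise KeyError(f"recreate_targets: structure '{required}' is missing")
    prostate = structures["prostate"]
    gtv = structures["gtv"]
    if np.any(gtv.voxels & ~prostate.voxels):
        raise ValueError("recreate_targets: gtv is not contained in the prostate")

    gtv4 = expand_margin(
        gtv,
        spec.gtv_margin_mm,
        exclude=[structures["rectum"], structures["bladder"]],
        name="gtv4mm",
    )
    ctv = StructureMask(structures.grid, "ctv", prostate.voxels | gtv4.voxels)
    ptv = expand_margin(ctv, spec.ptv_margins_mm, name="ptv")

    out = structures.copy()
    for m in (gtv4, ctv, ptv):
        out.add(m)
    # recipe postconditions
    assert not np.any(gtv.voxels & ~ctv.voxels)
    assert not np.any(prostate.voxels & ~ctv.voxels)
    assert not np.any(ctv.voxels & ~ptv.voxels)
    return out
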