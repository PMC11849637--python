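"""Voxel-grid data model shared by every stage of the pipeline.

All masks, dose grids and displacement fields live on a common rectilinear
:class:`ImageGrid`.  The package-wide axis convention is fixed:

* axis 0 — left–right (LR)
* axis 1 — anterior–posterior (AP, positive = posterior)
* axis 2 — inferior–superior (SI, positive = superior)

World coordinates are millimetres; the world coordinate of voxel ``(i, j, k)``
is ``origin + (i * sx, j * sy, k * sz)`` with 0-based indices.  Membership of
a voxel in a structure is decided at the voxel center everywhere in the
package — no partial-volume weighting — so every metric can be reproduced by
a brute-force oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImageGrid", "StructureMask", "DoseGrid", "StructureSet", "GridMismatchError"]


class GridMismatchError(ValueError):
    """Raised when two objects that must share a grid do not."""


@dataclass(frozen=True)
class ImageGrid:
    """A rectilinear voxel lattice.

    Parameters
    ----------
    shape
        Number of voxels per axis, ``(nx, ny, nz)``.
    spacing
        Voxel spacing in mm per axis.
    origin
        World-mm coordinate of the center of voxel ``(0, 0, 0)``.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("shape, spacing and origin must be length-3")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if any(n < 1 for n in self.shape):
            raise ValueError(f"all shape entries must be >= 1, got {self.shape}")
        if any(not np.isfinite(s) or s <= 0 for s in self.spacing):
            raise ValueError(f"all spacings must be strictly positive, got {self.spacing}")
        if any(not np.isfinite(o) for o in self.origin):
            raise ValueError(f"origin must be finite, got {self.origin}")

    @classmethod
    def centered(cls, shape=(96, 96, 96), spacing=(2.0, 2.0, 2.0)) -> "ImageGrid":
        """Grid whose world origin (0,0,0) is the geometric center of the lattice."""
        shape = tuple(int(n) for n in shape)
        spacing = tuple(float(s) for s in spacing)
        origin = tuple(-(n - 1) * s / 2.0 for n, s in zip(shape, spacing))
        return cls(shape, spacing, origin)

    @property
    def voxel_volume_cc(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz / 1000.0

    def world_coordinates(self):
        """Per-axis 1-D arrays of voxel-center world coordinates (broadcastable)."""
        return tuple(
            (self.origin[a] + self.spacing[a] * np.arange(self.shape[a])).reshape(
                [-1 if b == a else 1 for b in range(3)]
            )
            for a in range(3)
        )

    def index_to_world(self, idx) -> np.ndarray:
        idx = np.asarray(idx, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def world_to_index(self, world) -> np.ndarray:
        world = np.asarray(world, dtype=float)
        return (world - np.asarray(self.origin)) / np.asarray(self.spacing)

    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world-mm affine (diagonal by construction)."""
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff


def _require_same_grid(a, b) -> None:
    ga, gb = a.grid, b.grid
    same = (
        ga.shape == gb.shape
        and np.allclose(ga.spacing, gb.spacing)
        and np.allclose(ga.origin, gb.origin)
    )
    if not same:
        raise GridMismatchError(f"grids differ: {ga} vs {gb}")


@dataclass
class StructureMask:
    """A named binary structure on an :class:`ImageGrid`."""

    grid: ImageGrid
    name: str
    voxels: np.ndarray

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.shape != self.grid.shape:
            raise ValueError(
                f"mask '{self.name}': voxel array shape {self.voxels.shape} "
                f"does not match grid shape {self.grid.shape}"
            )

    @property
    def volume_cc(self) -> float:
        return float(self.voxels.sum()) * self.grid.voxel_volume_cc

    @property
    def is_empty(self) -> bool:
        return not bool(self.voxels.any())

    def centroid_mm(self) -> np.ndarray:
        """World-mm centroid of the voxel centers inside the mask."""
        if self.is_empty:
            raise ValueError(f"mask '{self.name}' is empty; centroid undefined")
        idx = np.argwhere(self.voxels).mean(axis=0)
        return self.grid.index_to_world(idx)

    def with_voxels(self, voxels: np.ndarray, name: str | None = None) -> "StructureMask":
        return StructureMask(self.grid, self.name if name is None else name, voxels)


@dataclass
class DoseGrid:
    """Scalar dose in cGy per voxel, at full-treatment-scheme scale."""

    grid: ImageGrid
    dose: np.ndarray

    def __post_init__(self) -> None:
        self.dose = np.asarray(self.dose, dtype=float)
        if self.dose.shape != self.grid.shape:
            raise ValueError(
                f"dose array shape {self.dose.shape} does not match grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.dose)):
            raise ValueError("dose grid contains non-finite values")
        if self.dose.min() < 0:
            raise ValueError(f"dose grid contains negative values (min {self.dose.min():.3g} cGy)")


@dataclass
class StructureSet:
    """Named structure masks sharing one grid.

    The anatomy structures are ``prostate``, ``gtv``, ``bladder``, ``rectum``,
    ``sphincter`` and ``body``; the margin recipe adds the derived targets
    ``gtv4mm``, ``ctv`` and ``ptv``.
    """

    grid: ImageGrid
    masks: dict[str, StructureMask] = field(default_factory=dict)

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    def __getitem__(self, name: str) -> StructureMask:
        try:
            return self.masks[name]
        except KeyError:
            raise KeyError(
                f"structure '{name}' not present; available: {sorted(self.masks)}"
            ) from None

    def add(self, mask: StructureMask) -> None:
        _require_same_grid(self, mask)
        self.masks[mask.name] = mask

    def names(self) -> list[str]:
        return sorted(self.masks)

    def copy(self) -> "StructureSet":
        return StructureSet(
            self.grid,
            {k: StructureMask(m.grid, m.name, m.voxels.copy()) for k, m in self.masks.items()},
        )
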