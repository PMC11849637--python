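"""Synthetic pelvic phantoms: the stand-in for the daily pre-treatment anatomy.

Each phantom consists of analytic shapes rasterized at voxel centers on a
shared grid:

* prostate — ellipsoid at the grid center (semi-axes ~20/18/22 mm LR/AP/SI);
* GTV      — sphere fully inside the prostate (the dominant lesion);
* bladder  — ellipsoid superior-anterior of the prostate;
* rectum   — gently curved tube posterior of the prostate, running SI;
* sphincter— disc inferior of the prostate;
* body     — elliptical soft-tissue cylinder containing everything.

Analytic shapes give exact ground truth for volume and distance oracles.
Where shapes overlap, voxels are carved away with the fixed priority
prostate > bladder > rectum > sphincter, so the organs are pairwise
disjoint.  Cohorts are produced by jittering sizes and offsets per patient
from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .grids import ImageGrid, StructureMask, StructureSet

__all__ = ["PhantomParams", "generate_patient", "cohort_patients"]


@dataclass(frozen=True)
class PhantomParams:
    """Sizes (mm), relative positions (mm) and jitter scales of one phantom.

    Offsets are relative to the prostate centroid in (LR, AP, SI) with
    AP positive = posterior, SI positive = superior.
    """

    prostate_semiaxes_mm: tuple[float, float, float] = (20.0, 18.0, 22.0)
    gtv_radius_mm: float = 6.0
    gtv_offset_mm: tuple[float, float, float] = (3.0, 2.0, -4.0)
    bladder_semiaxes_mm: tuple[float, float, float] = (34.0, 30.0, 28.0)
    bladder_offset_mm: tuple[float, float, float] = (0.0, -18.0, 38.0)
    rectum_radius_mm: float = 11.0
    rectum_ap_offset_mm: float = 28.0
    rectum_curvature_mm: float = 6.0
    rectum_halflength_mm: float = 62.0
    sphincter_radius_mm: float = 9.0
    sphincter_height_mm: float = 14.0
    sphincter_si_offset_mm: float = -30.0
    body_semiaxes_mm: tuple[float, float] = (88.0, 85.0)
    boundary_margin_mm: float = 16.0
    size_jitter_frac: float = 0.08
    offset_jitter_mm: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        positive = {
            "gtv_radius_mm": self.gtv_radius_mm,
            "rectum_radius_mm": self.rectum_radius_mm,
            "rectum_halflength_mm": self.rectum_halflength_mm,
            "sphincter_radius_mm": self.sphincter_radius_mm,
            "sphincter_height_mm": self.sphincter_height_mm,
        }
        for key, val in positive.items():
            if val <= 0:
                raise ValueError(f"{key} must be strictly positive, got {val}")
        for key, triple in (
            ("prostate_semiaxes_mm", self.prostate_semiaxes_mm),
            ("bladder_semiaxes_mm", self.bladder_semiaxes_mm),
            ("body_semiaxes_mm", self.body_semiaxes_mm),
        ):
            if any(v <= 0 for v in triple):
                raise ValueError(f"{key} entries must be strictly positive, got {triple}")
        if self.size_jitter_frac < 0 or self.offset_jitter_mm < 0:
            raise ValueError("jitter scales must be >= 0")
        if not self._gtv_inside_prostate():
            raise ValueError(
                "gtv sphere (radius + offset) is not fully inside the prostate ellipsoid"
            )

    def _gtv_inside_prostate(self, n_dirs: int = 512) -> bool:
        """Check the offset GTV sphere lies inside the prostate ellipsoid."""
        rng = np.random.default_rng(12345)  # fixed probe directions, not a model seed
        v = rng.standard_normal((n_dirs, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        pts = np.asarray(self.gtv_offset_mm) + self.gtv_radius_mm * v
        a = np.asarray(self.prostate_semiaxes_mm)
        return bool(np.all(((pts / a) ** 2).sum(axis=1) <= 1.0))


def _ellipsoid(coords, center, semiaxes) -> np.ndarray:
    x, y, z = coords
    cx, cy, cz = center
    ax, ay, az = semiaxes
    return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0


def generate_patient(
    params: PhantomParams = PhantomParams(), grid: ImageGrid | None = None
) -> tuple[ImageGrid, StructureSet]:
    """Rasterize one phantom anatomy.

    Returns masks for prostate, gtv, bladder, rectum, sphincter and body on a
    common grid (default 96^3 voxels at 2 mm, origin centered on the prostate
    centroid).  Organs are carved to be pairwise disjoint; an error is raised
    if any structure comes within ``boundary_margin_mm`` of the grid edge.
    """
    if grid is None:
        grid = ImageGrid.centered()
    coords = grid.world_coordinates()
    x, y, z = coords

    prostate = _ellipsoid(coords, (0.0, 0.0, 0.0), params.prostate_semiaxes_mm)
    gx, gy, gz = params.gtv_offset_mm
    gtv = (x - gx) ** 2 + (y - gy) ** 2 + (z - gz) ** 2 <= params.gtv_radius_mm**2
    bladder = _ellipsoid(coords, params.bladder_offset_mm, params.bladder_semiaxes_mm)

    # rectum: tube along SI whose centerline bows posteriorly away from the prostate
    ap_center = params.rectum_ap_offset_mm + params.rectum_curvature_mm * (
        z / params.rectum_halflength_mm
    ) ** 2
    rectum = (x**2 + (y - ap_center) ** 2 <= params.rectum_radius_mm**2) & (
        np.abs(z) <= params.rectum_halflength_mm
    )

    sphincter = (x**2 + y**2 <= params.sphincter_radius_mm**2) & (
        np.abs(z - params.sphincter_si_offset_mm) <= params.sphincter_height_mm / 2.0
    )

    bx, by = params.body_semiaxes_mm
    body = (x / bx) ** 2 + (y / by) ** 2 <= 1.0
    body = np.broadcast_to(body, grid.shape).copy()

    # disjointness by carving, fixed priority
    bladder &= ~prostate
    rectum &= ~(prostate | bladder)
    sphincter &= ~(prostate | bladder | rectum)

    structures = StructureSet(grid)
    for name, vox in (
        ("prostate", prostate),
        ("gtv", gtv),
        ("bladder", bladder),
        ("rectum", rectum),
        ("sphincter", sphincter),
        ("body", body),
    ):
        vox = np.broadcast_to(vox, grid.shape).copy()
        structures.add(StructureMask(grid, name, vox))

    _check_placement(grid, structures, params.boundary_margin_mm)
    return grid, structures


def _check_placement(grid: ImageGrid, structures: StructureSet, margin_mm: float) -> None:
    body = structures["body"].voxels
    spacing = np.asarray(grid.spacing)
    for name in ("prostate", "gtv", "bladder", "rectum", "sphincter"):
        vox = structures[name].voxels
        if not vox.any():
            raise ValueError(f"phantom structure '{name}' rasterized empty; enlarge it or refine the grid")
        if np.any(vox & ~body):
            raise ValueError(f"phantom structure '{name}' extends outside the body")
        idx = np.argwhere(vox)
        lo_mm = idx.min(axis=0) * spacing
        hi_mm = (np.asarray(grid.shape) - 1 - idx.max(axis=0)) * spacing
        if np.any(lo_mm < margin_mm) or np.any(hi_mm < margin_mm):
            raise ValueError(
                f"phantom structure '{name}' is within {margin_mm} mm of the grid "
                "boundary; use a larger grid or smaller anatomy"
            )


def _jittered(params: PhantomParams, rng: np.random.Generator) -> PhantomParams:
    """One random anatomy variation around the template parameters."""
    if params.size_jitter_frac == 0 and params.offset_jitter_mm == 0:
        return params

    def size(v):
        factor = 1.0 + rng.normal(0.0, params.size_jitter_frac)
        return max(factor, 0.5)  # keep sizes positive under extreme draws

    def sizes(t):
        return tuple(v * max(1.0 + rng.normal(0.0, params.size_jitter_frac), 0.5) for v in t)

    def offset(t):
        return tuple(v + rng.normal(0.0, params.offset_jitter_mm) for v in t)

    for _ in range(20):
        try:
            return replace(
                params,
                prostate_semiaxes_mm=sizes(params.prostate_semiaxes_mm),
                gtv_radius_mm=params.gtv_radius_mm
                * max(1.0 + rng.normal(0.0, params.size_jitter_frac), 0.5),
                gtv_offset_mm=offset(params.gtv_offset_mm),
                bladder_semiaxes_mm=sizes(params.bladder_semiaxes_mm),
                bladder_offset_mm=offset(params.bladder_offset_mm),
                rectum_radius_mm=params.rectum_radius_mm
                * max(1.0 + rng.normal(0.0, params.size_jitter_frac), 0.5),
                sphincter_si_offset_mm=params.sphincter_si_offset_mm
                + rng.normal(0.0, params.offset_jitter_mm),
            )
        except ValueError:
            continue  # jitter pushed the GTV out of the prostate; redraw
    raise ValueError("could not draw a valid jittered phantom in 20 attempts")


def cohort_patients(
    n: int, params: PhantomParams = PhantomParams(), seed: int | None = None
) -> list[tuple[ImageGrid, StructureSet]]:
    """Generate ``n`` independent phantoms by jittering the template params.

    Reproducible for a fixed seed (defaults to ``params.seed``).
    """
    if n < 1:
        raise ValueError(f"cohort size must be >= 1, got {n}")
    base = params.seed if seed is None else seed
    rng = np.random.default_rng(base)
    return [generate_patient(_jittered(params, rng)) for _ in range(n)]
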