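"""Translation-based registration — the computation behind the ATP step.

The adapt-to-position correction updates the plan isocenter from a
translation-only registration of the pre-treatment anatomy to the current
position-verification anatomy.  Here the registration operates on the
prostate mask (target alignment, as clinically intended): it finds the
translation maximizing the Dice overlap of the moving mask shifted back by
the candidate translation against the fixed mask.

The integer-voxel stage is an exhaustive search over all voxel offsets
within the search radius, evaluated for every offset at once through an FFT
cross-correlation (overlap counts are rounded back to exact integers so the
tie-breaking is deterministic: smaller shift norm first, then lexicographic
order).  An optional sub-voxel stage refines each axis by fitting a parabola
through the overlap profile at the optimum and its two neighbours.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .grids import GridMismatchError, StructureMask
from .motion import RigidMotion

__all__ = ["register_translation", "registration_error"]


def register_translation(
    fixed: StructureMask,
    moving: StructureMask,
    search_radius_mm: float = 15.0,
    subvoxel: bool = True,
) -> np.ndarray:
    """Estimate the translation (mm) mapping ``fixed`` onto ``moving``.

    Returns t such that shifting ``moving`` by -t best matches ``fixed``
    (equivalently: ``moving`` looks like ``fixed`` displaced by t).  The true
    motion magnitude must be within ``search_radius_mm``; an optimum on the
    search boundary raises an error advising a larger radius.
    """
    if fixed.grid.shape != moving.grid.shape:
        raise GridMismatchError("fixed and moving masks must share a grid")
    if fixed.is_empty or moving.is_empty:
        raise ValueError("registration requires two non-empty masks")
    spacing = np.asarray(fixed.grid.spacing)

    # crop to the union bounding box padded by the search radius: every voxel
    # outside is zero in both masks, so the overlap counts are unchanged
    radius_vox = np.ceil(search_radius_mm / spacing).astype(int) + 1
    union = fixed.voxels | moving.voxels
    idx = np.argwhere(union)
    lo = np.maximum(idx.min(axis=0) - radius_vox, 0)
    hi = np.minimum(idx.max(axis=0) + radius_vox + 1, fixed.grid.shape)
    box = tuple(slice(a, b) for a, b in zip(lo, hi))
    f = fixed.voxels[box].astype(np.float32)
    m = moving.voxels[box].astype(np.float32)

    # full cross-correlation: corr[k] = sum_x fixed(x) * moving(x + (N-1-k))
    corr = signal.fftconvolve(f, m[::-1, ::-1, ::-1], mode="full")
    counts = np.rint(corr).astype(np.int64)

    shape = np.asarray(f.shape)
    # corr index k along an axis of length n corresponds to lag (n-1) - k
    lags = np.meshgrid(*[(n - 1) - np.arange(2 * n - 1) for n in shape], indexing="ij")
    lag_mm = [lags[a] * spacing[a] for a in range(3)]
    dist = np.sqrt(sum(lm**2 for lm in lag_mm))
    in_ball = dist <= search_radius_mm
    if not in_ball.any():
        raise ValueError(
            f"search_radius_mm={search_radius_mm} admits no voxel offsets at "
            f"spacing {tuple(spacing)}"
        )

    masked = np.where(in_ball, counts, -1)
    best = masked.max()
    if best <= 0:
        raise ValueError(
            "no overlap found within the search radius; increase search_radius_mm"
        )
    cand = np.argwhere(masked == best)
    cand_lags = np.stack([lags[a][tuple(cand.T)] for a in range(3)], axis=1)
    cand_mm = cand_lags * spacing
    norms = np.linalg.norm(cand_mm, axis=1)
    order = np.lexsort(
        (cand_lags[:, 2], cand_lags[:, 1], cand_lags[:, 0], np.round(norms, 9))
    )
    lag = cand_lags[order[0]]
    k_index = cand[order[0]]

    # the 3x3x3 neighbourhood of the optimum must lie inside the searched ball,
    # both to detect a boundary optimum and to support the parabolic refinement
    neighbourhood = in_ball[
        tuple(slice(k - 1, k + 2) for k in k_index)
    ]
    if neighbourhood.shape != (3, 3, 3) or not neighbourhood.all():
        raise ValueError(
            f"registration optimum {tuple(lag * spacing)} mm lies on the search "
            f"boundary; increase search_radius_mm beyond {search_radius_mm}"
        )

    t_vox = lag.astype(float)
    if subvoxel:
        for axis in range(3):
            idx_m = list(k_index)
            idx_p = list(k_index)
            idx_m[axis] -= 1
            idx_p[axis] += 1
            # note: corr index k decreasing corresponds to lag increasing
            y_plus = float(counts[tuple(idx_m)])
            y_minus = float(counts[tuple(idx_p)])
            y0 = float(best)
            denom = y_minus - 2.0 * y0 + y_plus
            if denom < 0:
                p = 0.5 * (y_minus - y_plus) / denom
                # a mask-overlap profile is triangular, not parabolic, near
                # its peak: a profile A - c|j - f| puts the parabola vertex
                # at p = f / (2(1-f)); invert to undo the bias
                offset = 2.0 * p / (1.0 + 2.0 * abs(p))
                t_vox[axis] += float(np.clip(offset, -0.5, 0.5))
    return t_vox * spacing


def registration_error(t_estimated, rigid_true: RigidMotion) -> float:
    """Euclidean norm (mm) of the difference between the estimated shift and
    the ground-truth rigid translation."""
    t = np.asarray(t_estimated, dtype=float)
    return float(np.linalg.norm(t - np.asarray(rigid_true.translation_mm)))
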