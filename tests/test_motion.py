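"""Motion model: sampling, calibration, field inversion and mask warping."""

import numpy as np
import pytest

import subfrax as sx
from subfrax.motion import (
    PhaseMotionParams,
    folded_normal_parameters,
    invert_field,
    sample_drift_magnitude,
)

ZERO_PHASE = PhaseMotionParams(0.0, 0.0, 0.0, 0.0)


def _constant_field(grid, vec):
    vectors = np.broadcast_to(np.asarray(vec, float), grid.shape + (3,)).copy()
    return sx.DisplacementField(grid, vectors)


class TestSampling:
    def test_zero_amplitudes_give_identity(self, phantom):
        grid, structures = phantom
        params = sx.MotionParams(pv1=ZERO_PHASE, pv2=ZERO_PHASE)
        rigid, field = sx.sample_motion(
            params, "pv1", structures["prostate"].centroid_mm(), grid=grid,
            rng=np.random.default_rng(0),
        )
        assert rigid.translation_mm == (0.0, 0.0, 0.0)
        assert rigid.rotation_deg == (0.0, 0.0, 0.0)
        assert np.abs(field.vectors).max() == 0.0

    def test_translation_only_constant_inside_taper(self, phantom):
        grid, structures = phantom
        centroid = structures["prostate"].centroid_mm()
        phase = PhaseMotionParams(3.0, 0.0, 0.0, 0.0)  # fixed 3 mm magnitude
        params = sx.MotionParams(pv1=phase, pv2=phase)
        rigid, field = sx.sample_motion(
            params, "pv1", centroid, grid=grid, rng=np.random.default_rng(5)
        )
        t = np.asarray(rigid.translation_mm)
        assert np.linalg.norm(t) == pytest.approx(3.0)
        # inside the inner taper radius the field is exactly the translation
        x, y, z = grid.world_coordinates()
        r = np.sqrt((x - centroid[0]) ** 2 + (y - centroid[1]) ** 2 + (z - centroid[2]) ** 2)
        inner = r < 45.0
        diff = field.vectors[inner] - t
        assert np.abs(diff).max() < 1e-9

    def test_folded_normal_calibration_matches_targets(self):
        for mean, sd in ((3.0, 2.2), (3.5, 2.0)):
            mu, sigma = folded_normal_parameters(mean, sd)
            rng = np.random.default_rng(0)
            draws = np.abs(rng.normal(mu, sigma, 200_000))
            assert draws.mean() == pytest.approx(mean, abs=0.05)
            assert draws.std(ddof=1) == pytest.approx(sd, abs=0.05)

    def test_unreachable_cv_rejected(self):
        with pytest.raises(ValueError, match="folded normal"):
            folded_normal_parameters(1.0, 2.0)

    def test_pv2_mean_drift_at_least_pv1(self):
        params = sx.MotionParams()
        rng1, rng2 = np.random.default_rng(0), np.random.default_rng(0)
        pv1 = np.mean([sample_drift_magnitude(params.pv1, rng1) for _ in range(5000)])
        pv2 = np.mean([sample_drift_magnitude(params.pv2, rng2) for _ in range(5000)])
        assert pv2 >= pv1


class TestWarping:
    def test_identity_field_preserves_mask(self, phantom):
        grid, structures = phantom
        field = _constant_field(grid, (0, 0, 0))
        warped = sx.warp_mask(structures["prostate"], field)
        assert np.array_equal(warped.voxels, structures["prostate"].voxels)

    def test_constant_field_is_exact_voxel_shift(self, phantom):
        grid, structures = phantom
        field = _constant_field(grid, (4.0, 0.0, 0.0))  # 2 voxels along LR
        warped = sx.warp_mask(structures["prostate"], field)
        expected = np.roll(structures["prostate"].voxels, 2, axis=0)
        assert np.array_equal(warped.voxels, expected)

    def test_warp_then_inverse_warp_recovers_mask(self, phantom):
        grid, structures = phantom
        prostate = structures["prostate"]
        rigid, field = sx.sample_motion(
            sx.MotionParams(), "pv1", prostate.centroid_mm(), grid=grid,
            rng=np.random.default_rng(11),
        )
        warped = sx.warp_mask(prostate, field)
        inverse = invert_field(field)
        back = sx.warp_mask(warped, inverse)
        inter = np.count_nonzero(back.voxels & prostate.voxels)
        dice = 2 * inter / (back.voxels.sum() + prostate.voxels.sum())
        assert dice >= 0.99

    def test_rigid_only_warp_preserves_volume(self, phantom):
        grid, structures = phantom
        prostate = structures["prostate"]
        phase = PhaseMotionParams(3.0, 2.2, 2.0, 0.0)  # no deformation
        rigid, field = sx.sample_motion(
            sx.MotionParams(pv1=phase, pv2=phase), "pv1", prostate.centroid_mm(),
            grid=grid, rng=np.random.default_rng(3),
        )
        warped = sx.warp_mask(prostate, field)
        rel_change = abs(warped.volume_cc / prostate.volume_cc - 1.0)
        assert rel_change <= 0.02

    def test_forward_inverse_composition_residual(self, phantom):
        """max |u(y + v(y)) + v(y)| <= 0.1 mm over the body for default draws."""
        grid, structures = phantom
        centroid = structures["prostate"].centroid_mm()
        from subfrax.motion import _sample_field

        spacing = np.asarray(grid.spacing)
        base = np.meshgrid(*[np.arange(n, dtype=float) for n in grid.shape], indexing="ij")
        for seed in range(3):
            _, field = sx.sample_motion(
                sx.MotionParams(), "pv2", centroid, grid=grid,
                rng=np.random.default_rng(seed),
            )
            v = invert_field(field).vectors
            coords = [b + v[..., a] / spacing[a] for a, b in enumerate(base)]
            resid = np.linalg.norm(_sample_field(field.vectors, coords) + v, axis=-1)
            assert resid[structures["body"].voxels].max() <= 0.1

    def test_grid_mismatch_rejected(self, phantom):
        _, structures = phantom
        other = sx.ImageGrid.centered((10, 10, 10), (2.0, 2.0, 2.0))
        field = _constant_field(other, (1, 0, 0))
        with pytest.raises(sx.GridMismatchError):
            sx.warp_mask(structures["prostate"], field)


class TestMeanDisplacement:
    def test_identity_and_constant(self, phantom):
        grid, structures = phantom
        roi = structures["prostate"]
        assert sx.mean_displacement(_constant_field(grid, (0, 0, 0)), roi) == 0.0
        assert sx.mean_displacement(_constant_field(grid, (3.0, 0, 0)), roi) == pytest.approx(3.0)

    def test_rotation_about_si_matches_quadrature_oracle(self):
        """10 deg rotation of a spherical ROI about its centroid: the mean
        displacement equals the dense numerical quadrature of |R p - p|."""
        grid = sx.ImageGrid.centered((48, 48, 48), (2.0, 2.0, 2.0))
        x, y, z = grid.world_coordinates()
        radius = 25.0
        roi_vox = np.broadcast_to(x**2 + y**2 + z**2 <= radius**2, grid.shape).copy()
        roi = sx.StructureMask(grid, "sphere", roi_vox)

        rigid = sx.RigidMotion((0, 0, 0), (0, 0, 10.0))
        rel = np.stack(np.broadcast_arrays(x, y, z), axis=-1)
        vectors = rel @ (rigid.matrix().T - np.eye(3))
        field = sx.DisplacementField(grid, vectors)
        got = sx.mean_displacement(field, roi)

        # oracle: fine-lattice quadrature of 2 sin(theta/2) * r_perp
        theta = np.deg2rad(10.0)
        h = 0.5
        axis = np.arange(-radius, radius + h, h)
        gx, gy, gz = np.meshgrid(axis, axis, axis, indexing="ij")
        inside = gx**2 + gy**2 + gz**2 <= radius**2
        r_perp = np.sqrt(gx[inside] ** 2 + gy[inside] ** 2)
        oracle = float(np.mean(2.0 * np.sin(theta / 2.0) * r_perp))
        assert got == pytest.approx(oracle, rel=0.02)

    def test_empty_roi_rejected(self, phantom):
        grid, structures = phantom
        empty = sx.StructureMask(grid, "none", np.zeros(grid.shape, bool))
        with pytest.raises(ValueError, match="empty"):
            sx.mean_displacement(_constant_field(grid, (1, 0, 0)), empty)
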