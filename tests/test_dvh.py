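"""DVH metrics against hand counts and brute-force oracles."""

import warnings

import numpy as np
import pytest

import subfrax as sx
from subfrax.experiments import (
    brute_force_d_cc,
    brute_force_d_mean,
    brute_force_v_dose,
    random_dose_mask,
)


def _uniform_case(value, shape=(10, 10, 10)):
    grid = sx.ImageGrid.centered(shape, (2.0, 2.0, 2.0))
    dose = sx.DoseGrid(grid, np.full(shape, float(value)))
    mask = sx.StructureMask(grid, "roi", np.ones(shape, bool))
    return dose, mask


class TestVDose:
    def test_uniform_full_and_zero_coverage(self):
        dose, mask = _uniform_case(3625.0)
        assert sx.v_dose(dose, mask, 3444) == 100.0
        zero, _ = _uniform_case(0.0)
        assert sx.v_dose(zero, mask, 3444) == 0.0

    def test_hand_counted_half_coverage(self):
        grid = sx.ImageGrid.centered((4, 1, 1), (2.0, 2.0, 2.0))
        dose = sx.DoseGrid(grid, np.array([3500.0, 3450.0, 3440.0, 3000.0]).reshape(4, 1, 1))
        mask = sx.StructureMask(grid, "roi", np.ones((4, 1, 1), bool))
        assert sx.v_dose(dose, mask, 3444) == 50.0  # 2 of 4 at or above, inclusive

    def test_threshold_inclusive(self):
        dose, mask = _uniform_case(3444.0)
        assert sx.v_dose(dose, mask, 3444) == 100.0

    def test_empty_mask_rejected(self):
        dose, mask = _uniform_case(100.0)
        empty = mask.with_voxels(np.zeros_like(mask.voxels))
        with pytest.raises(ValueError, match="empty"):
            sx.v_dose(dose, empty, 50)


class TestDcc:
    def test_uniform_dose(self):
        dose, mask = _uniform_case(1800.0)  # 8 cc structure
        assert sx.d_cc(dose, mask, 5.0) == 1800.0

    def test_rank_ordered_doses_bracket(self):
        # 1000 voxels of 0.008 cc, doses 1000..1 descending; 1 cc = 125 voxels
        grid = sx.ImageGrid.centered((10, 10, 10), (2.0, 2.0, 2.0))
        dose = sx.DoseGrid(grid, np.arange(1000, 0, -1, dtype=float).reshape(10, 10, 10))
        mask = sx.StructureMask(grid, "roi", np.ones((10, 10, 10), bool))
        got = sx.d_cc(dose, mask, 1.0)
        hottest = np.sort(dose.dose.ravel())[::-1]
        assert hottest[125] <= got <= hottest[124]

    def test_one_voxel_volume_gives_max_dose(self, rng):
        dose, mask = random_dose_mask(rng)
        voxvol = mask.grid.voxel_volume_cc
        assert sx.d_cc(dose, mask, voxvol) == dose.dose[mask.voxels].max()

    def test_small_structure_warns_and_returns_min(self):
        grid = sx.ImageGrid.centered((4, 4, 4), (2.0, 2.0, 2.0))
        vox = np.zeros((4, 4, 4), bool)
        vox[:4, 0, 0] = True  # 4 voxels = 0.032 cc
        dose = sx.DoseGrid(grid, np.arange(64, dtype=float).reshape(4, 4, 4))
        mask = sx.StructureMask(grid, "tiny", vox)
        with pytest.warns(UserWarning, match="smaller"):
            got = sx.d_cc(dose, mask, 1.0)
        assert got == dose.dose[vox].min()

    def test_non_positive_volume_rejected(self):
        dose, mask = _uniform_case(10.0)
        with pytest.raises(ValueError):
            sx.d_cc(dose, mask, 0.0)

    def test_monotone_in_volume(self, rng):
        dose, mask = random_dose_mask(rng)
        vols = np.linspace(0.01, mask.volume_cc, 20)
        vals = [sx.d_cc(dose, mask, v) for v in vols]
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))


class TestDMean:
    def test_uniform_and_two_voxel_average(self):
        dose, mask = _uniform_case(1500.0)
        assert sx.d_mean(dose, mask) == 1500.0
        grid = sx.ImageGrid.centered((2, 1, 1), (2.0, 2.0, 2.0))
        dose2 = sx.DoseGrid(grid, np.array([1000.0, 3000.0]).reshape(2, 1, 1))
        mask2 = sx.StructureMask(grid, "two", np.ones((2, 1, 1), bool))
        assert sx.d_mean(dose2, mask2) == 2000.0


class TestOracleAgreement:
    def test_metrics_match_brute_force(self, rng):
        for _ in range(10):
            dose, mask = random_dose_mask(rng)
            thr = float(rng.uniform(0, 4000))
            vol = float(rng.uniform(0.05, mask.volume_cc))
            assert sx.v_dose(dose, mask, thr) == brute_force_v_dose(dose, mask, thr)
            assert sx.d_cc(dose, mask, vol) == pytest.approx(
                brute_force_d_cc(dose, mask, vol), abs=1e-9
            )
            assert sx.d_mean(dose, mask) == pytest.approx(
                brute_force_d_mean(dose, mask), abs=1e-9
            )

    def test_v_dose_non_increasing_in_threshold(self, rng):
        dose, mask = random_dose_mask(rng)
        thresholds = np.sort(rng.uniform(0, 4000, 30))
        vals = [sx.v_dose(dose, mask, t) for t in thresholds]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_voxel_order_invariance(self, rng):
        dose, mask = random_dose_mask(rng)
        perm = rng.permutation(np.prod(mask.grid.shape))
        dose_p = sx.DoseGrid(mask.grid, dose.dose.ravel()[perm].reshape(mask.grid.shape))
        mask_p = mask.with_voxels(mask.voxels.ravel()[perm].reshape(mask.grid.shape))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for vol in (0.1, 1.0):
                assert sx.d_cc(dose, mask, vol) == pytest.approx(
                    sx.d_cc(dose_p, mask_p, vol), abs=1e-9
                )
        assert sx.d_mean(dose, mask) == pytest.approx(sx.d_mean(dose_p, mask_p), abs=1e-9)


class TestDvhCurve:
    def test_uniform_dose_is_step_function(self):
        dose, mask = _uniform_case(1000.0)
        edges, percent = sx.dvh_curve(dose, mask, 100.0)
        assert percent[0] == 100.0
        assert np.all(percent[edges <= 1000.0] == 100.0)
        assert np.all(percent[edges > 1000.0] == 0.0)

    def test_monotone_non_increasing(self, rng):
        dose, mask = random_dose_mask(rng)
        _, percent = sx.dvh_curve(dose, mask, 50.0)
        assert np.all(np.diff(percent) <= 0)

    def test_consistent_with_v_dose_at_edges(self, rng):
        dose, mask = random_dose_mask(rng)
        edges, percent = sx.dvh_curve(dose, mask, 37.0)
        pick = rng.choice(len(edges), size=50)
        for i in pick:
            assert percent[i] == sx.v_dose(dose, mask, edges[i])

    def test_bad_bin_width_rejected(self):
        dose, mask = _uniform_case(10.0)
        with pytest.raises(ValueError):
            sx.dvh_curve(dose, mask, 0.0)
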