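"""DVH metrics against sort/count oracles, objective checking, deltas."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import latticert as lt
from latticert.dvh import (check_objectives, compare_plans, dose_at_volume,
                           dvh_curve, mean_dose, rtog_ci, volume_at_dose)

from conftest import make_grid, random_blob
from _oracles import brute_dose_at_volume, brute_volume_at_dose_pct


def _uniform_case(level=10.0, dims=20, spacing=2.0):
    grid = make_grid(dims, spacing)
    mask = lt.StructureMask(grid, "PTV", "PTV_High", np.ones(grid.dims, bool))
    return lt.DoseGrid(grid, np.full(grid.dims, level)), mask


class TestDoseAtVolume:
    def test_uniform_dose_near_max(self):
        dose, mask = _uniform_case(10.0)
        assert dose_at_volume(dose, mask, 0.03) == pytest.approx(10.0)

    def test_two_level_structure(self):
        # 1 cc at 15 Gy + 99 cc at 4 Gy (1 mm voxels -> 0.001 cc each)
        grid = make_grid((100, 100, 10), 1.0)
        d = np.full(grid.dims, 4.0)
        d.flat[:1000] = 15.0
        dose = lt.DoseGrid(grid, d)
        mask = lt.StructureMask(grid, "S", "PTV_Low", np.ones(grid.dims, bool))
        assert dose_at_volume(dose, mask, 0.03) == pytest.approx(15.0)
        assert dose_at_volume(dose, mask, 95.0, relative=True) == pytest.approx(4.0)

    def test_matches_sorted_cumulative_oracle(self):
        grid = make_grid(14, 2.0)
        rng = np.random.default_rng(5)
        dose = lt.DoseGrid(grid, rng.uniform(0, 16, grid.dims))
        mask = random_blob(grid, seed=5, density=0.6)
        for v_cc in (0.03, 0.5, 2.0):
            assert dose_at_volume(dose, mask, v_cc) == pytest.approx(
                brute_dose_at_volume(dose, mask, v_cc), abs=1e-9)

    def test_request_beyond_structure_volume_rejected(self):
        dose, mask = _uniform_case()
        with pytest.raises(ValueError, match="exceeds structure volume"):
            dose_at_volume(dose, mask, mask.volume_cc * 2)


class TestVolumeAtDose:
    def test_uniform_full_coverage(self):
        dose, mask = _uniform_case(12.0)
        assert volume_at_dose(dose, mask, 12.0) == 100.0

    def test_half_coverage(self):
        grid = make_grid((10, 10, 10), 2.0)
        d = np.full(grid.dims, 4.0)
        d[:5] = 12.0
        dose = lt.DoseGrid(grid, d)
        mask = lt.StructureMask(grid, "S", "PTV_Low", np.ones(grid.dims, bool))
        assert volume_at_dose(dose, mask, 12.0) == 50.0

    def test_matches_count_oracle(self):
        grid = make_grid(12, 2.0)
        rng = np.random.default_rng(8)
        dose = lt.DoseGrid(grid, rng.uniform(0, 16, grid.dims))
        mask = random_blob(grid, seed=8, density=0.5)
        for t in (2.0, 8.0, 15.0):
            assert volume_at_dose(dose, mask, t) == pytest.approx(
                brute_volume_at_dose_pct(dose, mask, t), abs=1e-12)

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_galois_consistency(self, seed):
        grid = make_grid(8, 2.0)
        rng = np.random.default_rng(seed)
        dose = lt.DoseGrid(grid, rng.uniform(0, 16, grid.dims))
        mask = lt.StructureMask(grid, "S", "PTV_Low", np.ones(grid.dims, bool))
        one_voxel_pct = 100.0 / dose.dose_gy.size
        v = float(rng.uniform(5, 95))
        d_at_v = dose_at_volume(dose, mask, v, relative=True)
        # consistent up to interpolation inside the cut voxel
        assert volume_at_dose(dose, mask, d_at_v) >= v - one_voxel_pct
        t = float(rng.uniform(1, 15))
        v_at_t = volume_at_dose(dose, mask, t)
        if v_at_t > 0:
            assert dose_at_volume(dose, mask, v_at_t, relative=True) >= t - 1e-9


class TestMeanAndCI:
    def test_mean_of_linear_ramp(self):
        grid = make_grid((40, 8, 8), 1.0)
        ramp = np.broadcast_to(np.linspace(0, 8, 40)[:, None, None],
                               grid.dims).copy()
        dose = lt.DoseGrid(grid, ramp)
        mask = lt.StructureMask(grid, "S", "PTV_Low", np.ones(grid.dims, bool))
        assert mean_dose(dose, mask) == pytest.approx(4.0, abs=0.15)

    def test_ci_of_exact_prescription_isodose(self):
        grid = make_grid(40, 1.0)
        target = lt.voxelize_solid(lt.Sphere((0, 0, 0), 12.0), grid,
                                   "PTV_High", "PTV_High")
        body = lt.StructureMask(grid, "Body", "Body", np.ones(grid.dims, bool))
        d = np.where(target.occupancy, 12.0, 3.0)
        dose = lt.DoseGrid(grid, d)
        assert rtog_ci(dose, target, 12.0, body) == pytest.approx(1.0)

    def test_ci_ratio_arithmetic(self):
        grid = make_grid(20, 2.0)
        body = lt.StructureMask(grid, "Body", "Body", np.ones(grid.dims, bool))
        target = lt.StructureMask(grid, "T", "PTV_High",
                                  np.zeros(grid.dims, bool))
        target.occupancy[:10] = True  # half the grid
        d = np.zeros(grid.dims)
        d.flat[: int(0.625 * d.size)] = 12.0  # isodose = 1.25x target volume
        dose = lt.DoseGrid(grid, d)
        assert rtog_ci(dose, target, 12.0, body) == pytest.approx(1.25)

    def test_metrics_scale_with_uniform_dose_scaling(self):
        grid = make_grid(10, 2.0)
        rng = np.random.default_rng(2)
        d = rng.uniform(0, 10, grid.dims)
        mask = random_blob(grid, seed=2, density=0.5)
        a = lt.DoseGrid(grid, d)
        b = lt.DoseGrid(grid, 2.0 * d)
        assert mean_dose(b, mask) == pytest.approx(2 * mean_dose(a, mask))
        assert volume_at_dose(b, mask, 8.0) == pytest.approx(
            volume_at_dose(a, mask, 4.0))


class TestDVHCurveAndObjectives:
    def test_curve_monotone_and_starts_at_100(self):
        grid = make_grid(12, 2.0)
        rng = np.random.default_rng(4)
        dose = lt.DoseGrid(grid, rng.uniform(0, 14, grid.dims))
        mask = random_blob(grid, seed=4, density=0.5)
        curve = dvh_curve(dose, mask)
        assert curve.volume_pct[0] == 100.0
        assert np.all(np.diff(curve.volume_pct) <= 1e-12)

    def test_uniform_plan_passes_coverage_fails_on_hotspot(self):
        grid = make_grid(20, 2.0)
        high = lt.StructureMask(grid, "PTV_High", "PTV_High",
                                np.ones(grid.dims, bool))
        ok = check_objectives(lt.DoseGrid(grid, np.full(grid.dims, 12.0)),
                              {"PTV_High": high})
        row = [r for r in ok.rows
               if r["structure"] == "PTV_High" and r["metric"] == "V12Gy"][0]
        assert row["passed"] and row["value"] == 100.0

        hot = np.full(grid.dims, 12.0)
        hot[:2, :2, :2] = 16.0  # 0.064 cc hot region, larger than the 0.03 cc cut
        bad = check_objectives(lt.DoseGrid(grid, hot), {"PTV_High": high})
        dmax_row = [r for r in bad.rows
                    if r["structure"] == "PTV_High" and r["metric"] == "D0.03cc"][0]
        assert not dmax_row["passed"]

    def test_missing_structure_reported_not_raised(self):
        grid = make_grid(8, 2.0)
        report = check_objectives(lt.DoseGrid(grid, np.zeros(grid.dims)), {})
        assert not report.overall_pass
        assert all(r["reason"] == "structure missing" for r in report.rows)


class TestComparePlans:
    @staticmethod
    def _setting():
        grid = make_grid(30, 2.0)
        structures = {
            "PTV_High": lt.voxelize_solid(lt.Sphere((0, 0, 0), 8.0), grid,
                                          "PTV_High", "PTV_High"),
            "PTV_Low": lt.voxelize_solid(lt.Sphere((0, 0, 0), 20.0), grid,
                                         "PTV_Low", "PTV_Low"),
            "Body": lt.StructureMask(grid, "Body", "Body",
                                     np.ones(grid.dims, bool)),
        }
        rng = np.random.default_rng(9)
        dose = lt.DoseGrid(grid, rng.uniform(0, 14, grid.dims))
        return grid, structures, dose

    def test_plan_vs_itself_all_deltas_zero(self):
        grid, structures, dose = self._setting()
        deltas = compare_plans(dose, dose, structures)
        assert (deltas["abs_delta"] == 0).all()

    def test_uniform_offset_shifts_dmean_exactly(self):
        grid, structures, dose = self._setting()
        shifted = lt.DoseGrid(grid, dose.dose_gy + 0.1)
        deltas = compare_plans(dose, shifted, structures)
        dmean = deltas[(deltas.structure == "PTV_High")
                       & (deltas.metric == "Dmean")]["abs_delta"].iloc[0]
        assert dmean == pytest.approx(0.1, abs=1e-9)

    def test_symmetric_in_plans(self):
        grid, structures, dose = self._setting()
        rng = np.random.default_rng(10)
        other = lt.DoseGrid(grid, rng.uniform(0, 14, grid.dims))
        ab = compare_plans(dose, other, structures)
        ba = compare_plans(other, dose, structures)
        assert np.allclose(ab["abs_delta"], ba["abs_delta"])
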