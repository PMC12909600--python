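"""Sphere-lattice generation and GTV-based cropping."""

import numpy as np
import pytest

import latticert as lt
from latticert.lattice import (LatticeSpec, SphereSet, crop_to_ptv_high,
                               generate_lattice, voxelize_lattice)

from conftest import make_grid


class TestGenerateLattice:
    def test_default_matrix_has_11_planes_per_axis(self):
        spheres = generate_lattice(LatticeSpec())
        assert len(spheres) == 11 ** 3 == 1331
        # counting oracle: integer offsets o with |o| * 20 <= 100, cubed
        per_axis = sum(1 for o in range(-10, 11) if abs(o) * 20 <= 100)
        assert len(spheres) == per_axis ** 3

    def test_small_matrix_includes_boundary_planes(self):
        spheres = generate_lattice(LatticeSpec(matrix_extent_mm=(20, 20, 20)))
        assert len(spheres) == 27
        offsets = np.unique(spheres.centers_mm[:, 0])
        assert np.allclose(offsets, [-20.0, 0.0, 20.0])

    def test_minimum_center_spacing_is_exactly_the_template_spacing(self):
        spheres = generate_lattice(LatticeSpec())
        assert spheres.min_center_spacing_mm() == pytest.approx(20.0, abs=1e-12)

    def test_overlapping_spec_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            LatticeSpec(sphere_diameter_mm=10.0, center_spacing_mm=8.0)

    def test_deterministic_for_fixed_spec(self):
        a = generate_lattice(LatticeSpec(center_point_mm=(1.5, -2.0, 3.0)))
        b = generate_lattice(LatticeSpec(center_point_mm=(1.5, -2.0, 3.0)))
        assert np.array_equal(a.centers_mm, b.centers_mm)


class TestVoxelizeLattice:
    def test_disjoint_spheres_add_volume(self):
        grid = make_grid(71, 1.0)  # odd dims align voxel centers with sphere centers
        spheres = generate_lattice(LatticeSpec(matrix_extent_mm=(20,) * 3))
        mask = voxelize_lattice(spheres, grid)
        assert mask.volume_cc == pytest.approx(27 * 4 / 3 * np.pi * 0.5 ** 3,
                                               rel=0.05)

    def test_empty_set_gives_empty_mask(self):
        grid = make_grid(16, 1.0)
        assert voxelize_lattice(SphereSet(np.zeros((0, 3)), 5.0), grid).is_empty

    def test_equals_union_of_per_sphere_voxelizations(self):
        grid = make_grid(50, 2.0)
        spheres = generate_lattice(LatticeSpec(matrix_extent_mm=(40,) * 3))
        mask = voxelize_lattice(spheres, grid)
        union = np.zeros(grid.dims, dtype=bool)
        for c in spheres.centers_mm:
            union |= lt.Sphere(tuple(c), spheres.radius_mm).inside(grid)
        assert np.array_equal(mask.occupancy, union)


class TestCropToPtvHigh:
    @staticmethod
    def _gtv(radius, dims=160, spacing=2.0):
        grid = make_grid(dims // int(spacing), spacing)
        return lt.voxelize_solid(lt.Sphere((0, 0, 0), radius), grid, "GTV", "GTV")

    def test_small_spherical_gtv_keeps_only_central_sphere(self):
        # neighbours at 20 mm exceed the allowable 30-10-5=15 mm center distance
        gtv = self._gtv(30.0)
        spheres = generate_lattice(LatticeSpec(matrix_extent_mm=(100,) * 3))
        ptv, kept, removed = crop_to_ptv_high(spheres, gtv)
        assert len(kept) == 1
        assert np.allclose(kept.centers_mm[0], 0.0)
        assert len(kept) + len(removed) == len(spheres)

    def test_large_spherical_gtv_matches_analytic_center_criterion(self):
        gtv = self._gtv(65.0, dims=200)
        spheres = generate_lattice(LatticeSpec())
        ptv, kept, removed = crop_to_ptv_high(spheres, gtv)
        r_allow = 65.0 - 10.0 - 5.0
        oracle = {tuple(c) for c in spheres.centers_mm
                  if np.linalg.norm(c) <= r_allow}
        assert {tuple(c) for c in kept.centers_mm} == oracle

    def test_gtv_outside_matrix_removes_everything(self):
        grid = make_grid(100, 2.0)
        gtv = lt.voxelize_solid(lt.Sphere((80, 80, 80), 15.0), grid, "GTV", "GTV")
        spheres = generate_lattice(LatticeSpec(matrix_extent_mm=(40,) * 3))
        with pytest.warns(UserWarning, match="no lattice sphere survives"):
            ptv, kept, removed = crop_to_ptv_high(spheres, gtv)
        assert ptv.is_empty and len(kept) == 0

    def test_kept_spheres_inside_gtv_and_monotone(self):
        spheres = generate_lattice(LatticeSpec(matrix_extent_mm=(100,) * 3))
        small = self._gtv(35.0)
        big = self._gtv(50.0)
        _, kept_small, _ = crop_to_ptv_high(spheres, small)
        ptv_big, kept_big, _ = crop_to_ptv_high(spheres, big)
        # enlarging the GTV never decreases the kept count
        assert len(kept_big) >= len(kept_small)
        # every kept-sphere voxel is a GTV voxel
        assert not (ptv_big.occupancy & ~big.occupancy).any()
        # increasing retraction never increases the kept count
        _, kept_more, _ = crop_to_ptv_high(spheres, big, retraction_mm=15.0)
        assert len(kept_more) <= len(kept_big)

    def test_structure_mask_input_equivalent_to_sphere_set(self):
        gtv = self._gtv(40.0)
        spheres = generate_lattice(LatticeSpec(matrix_extent_mm=(60,) * 3))
        matrix = voxelize_lattice(spheres, gtv.grid)
        ptv_a, kept_a, _ = crop_to_ptv_high(spheres, gtv)
        ptv_b, kept_b, _ = crop_to_ptv_high(matrix, gtv)
        assert len(kept_a) == len(kept_b)
        assert np.array_equal(ptv_a.occupancy, ptv_b.occupancy) or \
            lt.dice(ptv_a, ptv_b) > 0.99  # centroid-recovered radii may differ
        assert np.allclose(
            np.sort(kept_a.centers_mm, axis=0),
            np.sort(kept_b.centers_mm, axis=0), atol=gtv.grid.spacing_mm[0])

    def test_empty_gtv_rejected(self):
        grid = make_grid(20, 2.0)
        empty = lt.StructureMask(grid, "GTV", "GTV", np.zeros(grid.dims, bool))
        with pytest.raises(ValueError, match="non-empty GTV"):
            crop_to_ptv_high(SphereSet(np.zeros((1, 3)), 5.0), empty)
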