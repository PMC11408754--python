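"""Shape-family geometry, the surface cut, and ground-truth depth maps."""

import numpy as np
import pytest
import trimesh

from fluordepth import shapes
from fluordepth.grid import DEFAULT_GRID, GridSpec
from fluordepth.shapes import (
    CSHParams,
    ShapeVolume,
    SphericalHarmonicParams,
    cut_above_surface,
    ground_truth_maps,
    make_csh,
    make_cylinder,
    make_spherical_harmonic,
)


def column_scan_oracle(occ, grid, allow_protrusion=False):
    """Independent per-column brute-force depth map (pure python loops)."""
    depth = np.zeros((grid.nx, grid.ny))
    z = grid.z_mm
    half = grid.dz_mm / 2.0
    for i in range(grid.nx):
        for j in range(grid.ny):
            ks = np.nonzero(occ[i, j])[0]
            if ks.size == 0:
                continue
            ztop = z[ks[0]] - half
            zbot = z[ks[-1]] + half
            depth[i, j] = zbot - min(ztop, 0.0)
    return depth


class TestCylinder:
    def test_geometry_forced_by_definition(self, grid):
        shape = make_cylinder(20.0, 5.0, grid)
        x, y, z = grid.x_mm, grid.y_mm, grid.z_mm
        for i, j in [(50, 50), (60, 50), (50, 68)]:
            r = np.hypot(x[i], y[j])
            span = z[shape.occupancy[i, j]]
            if r <= 10.0:
                assert span.min() == pytest.approx(0.25)
                assert span.max() == pytest.approx(4.75)
            else:
                assert span.size == 0

    def test_columns_outside_radius_unoccupied(self, grid):
        shape = make_cylinder(20.0, 5.0, grid)
        rr = np.hypot(grid.x_mm[:, None], grid.y_mm[None, :])
        assert not shape.footprint[rr > 10.0].any()

    def test_voxel_count_matches_point_in_cylinder_oracle(self, grid):
        shape = make_cylinder(20.0, 5.0, grid)
        count = 0
        for i in range(grid.nx):
            for j in range(grid.ny):
                if grid.x_mm[i] ** 2 + grid.y_mm[j] ** 2 > 100.0:
                    continue
                for k in range(grid.nz):
                    if 0.0 <= grid.z_mm[k] <= 5.0:
                        count += 1
        assert shape.occupancy.sum() == count

    @pytest.mark.parametrize("width,depth", [(5.0, 5.0), (45.0, 5.0), (20.0, 0.5), (20.0, 12.0)])
    def test_out_of_range_rejected(self, width, depth):
        with pytest.raises(ValueError):
            make_cylinder(width, depth)


class TestSphericalHarmonic:
    def test_zero_amplitude_is_a_sphere(self, grid):
        params = SphericalHarmonicParams(l=5, m=3, amplitude=0.0)
        shape = make_spherical_harmonic(params, (1.0, 1.0, 0.6), grid)
        # cut hemisphere of a 10 mm sphere scaled x0.6 in z: max thickness 6 mm
        gt = ground_truth_maps(shape, 1.0)
        assert gt.depth_mm.max() == pytest.approx(6.0, abs=grid.dz_mm)
        # footprint is a disc of radius 10
        rr = np.hypot(grid.x_mm[:, None], grid.y_mm[None, :])
        assert not shape.footprint[rr > 10.0 + grid.pixel_mm].any()
        assert shape.footprint[rr < 9.5].all()

    def test_negative_radius_amplitude_rejected(self):
        with pytest.raises(ValueError):
            SphericalHarmonicParams(l=4, m=2, amplitude=1.2)

    @pytest.mark.parametrize("l,m,amplitude", [(2, 1, 0.3), (20, -13, 0.3), (11, 0, 0.25)])
    def test_star_convex_single_interval_per_ray(self, l, m, amplitude, grid):
        """Ray-marching oracle: each radial ray crosses the surface once."""
        params = SphericalHarmonicParams(l=l, m=m, amplitude=amplitude)
        rng = np.random.default_rng(5)
        for _ in range(40):
            theta = rng.uniform(0.0, np.pi / 2)
            phi = rng.uniform(0.0, 2 * np.pi)
            t = np.linspace(1e-3, 14.0, 600)
            inside = t <= shapes._sh_radius(params, np.full_like(t, theta), np.full_like(t, phi))
            switches = np.count_nonzero(np.diff(inside.astype(int)))
            assert switches == 1

    def test_fixed_seed_repeatable(self, grid):
        a = shapes.random_spherical_harmonic(np.random.default_rng(77), grid)
        b = shapes.random_spherical_harmonic(np.random.default_rng(77), grid)
        assert np.array_equal(a.occupancy, b.occupancy)


class TestCSH:
    def _identical_quadrant_params(self, **kw):
        q = SphericalHarmonicParams(l=6, m=2, amplitude=0.2)
        defaults = dict(
            quadrants=(q, q, q, q), c1_mm2=10.0, c2_mm2=-10.0,
            rot_x_deg=0.0, rot_y_deg=0.0, rot_z_deg=0.0, z_shift_mm=0.0,
            target_width_x_mm=25.0, target_width_y_mm=25.0, target_depth_mm=6.0,
        )
        defaults.update(kw)
        return CSHParams(**defaults)

    def test_identical_quadrants_reduce_to_single_sh(self, grid):
        """Merging four copies of one SH is the identity on that SH."""
        params = self._identical_quadrant_params()
        csh = make_csh(params, grid)
        single = params.quadrants[0]
        scale = csh.provenance["scale_xyz"]
        sh = make_spherical_harmonic(single, scale, grid)
        assert np.array_equal(csh.occupancy, sh.occupancy)

    def test_positive_z_shift_buries_top_surface(self, grid):
        params = self._identical_quadrant_params(z_shift_mm=2.0)
        csh = make_csh(params, grid)
        occ = csh.occupancy
        iz0 = int(np.argmin(np.abs(grid.z_mm - 0.25)))  # shallowest slice
        fp = csh.footprint
        buried = fp & ~occ[:, :, iz0]
        assert buried.any()  # some columns start strictly below the surface

    def test_determinism(self, grid):
        a = shapes.random_csh(np.random.default_rng(3), grid)
        b = shapes.random_csh(np.random.default_rng(3), grid)
        assert np.array_equal(a.occupancy, b.occupancy)

    def test_random_draws_within_training_ranges(self, grid):
        rng = np.random.default_rng(11)
        for _ in range(25):
            c = shapes.random_csh(rng, grid)
            wx, wy = shapes.footprint_width_mm(c)
            assert 10.0 <= wx <= 40.0 and 10.0 <= wy <= 40.0
            assert 1.0 <= shapes.max_depth_mm(c) <= 10.0
            assert not c.occupancy[:, :, grid.z_mm < 0].any()


class TestCutAboveSurface:
    def test_no_op_when_nothing_protrudes(self, grid):
        shape = make_cylinder(20.0, 5.0, grid)
        assert np.array_equal(cut_above_surface(shape).occupancy, shape.occupancy)

    def test_half_buried_sphere_keeps_lower_hemisphere(self, grid):
        x, y, z = np.meshgrid(grid.x_mm, grid.y_mm, grid.z_mm, indexing="ij")
        occ = x**2 + y**2 + z**2 <= 16.0
        shape = ShapeVolume(grid=grid, occupancy=occ)
        cut = cut_above_surface(shape)
        assert np.array_equal(cut.occupancy, occ & (z >= 0))
        assert cut.occupancy.sum() * 2 == pytest.approx(occ.sum(), rel=0.1)

    def test_idempotent_and_never_grows(self, grid, rng):
        for _ in range(5):
            occ = rng.random((grid.nx, grid.ny, grid.nz)) < 0.2
            shape = ShapeVolume(grid=grid, occupancy=occ)
            once = cut_above_surface(shape)
            twice = cut_above_surface(once)
            assert np.array_equal(once.occupancy, twice.occupancy)
            assert once.occupancy.sum() <= occ.sum()
            assert not (once.occupancy & ~occ).any()


class TestGroundTruthMaps:
    def _column_shape(self, grid, iz_lo, iz_hi):
        occ = np.zeros((grid.nx, grid.ny, grid.nz), dtype=bool)
        occ[50, 50, iz_lo:iz_hi] = True
        return ShapeVolume(grid=grid, occupancy=occ)

    def test_buried_column_depth_from_surface(self, grid):
        # occupied centers 2.25..6.75 -> span [2, 7] mm, buried: depth 7
        iz = np.searchsorted(grid.z_mm, 2.25)
        shape = self._column_shape(grid, iz, iz + 10)
        gt = ground_truth_maps(shape, 5.0)
        assert gt.depth_mm[50, 50] == pytest.approx(7.0)

    def test_protruding_column_full_thickness(self, grid):
        # span [-2, 5] mm with protrusion allowed: depth 7
        iz_lo = np.searchsorted(grid.z_mm, -1.75)
        iz_hi = np.searchsorted(grid.z_mm, 4.75) + 1
        shape = self._column_shape(grid, iz_lo, iz_hi)
        gt = ground_truth_maps(shape, 5.0, allow_protrusion=True)
        assert gt.depth_mm[50, 50] == pytest.approx(7.0)
        with pytest.raises(ValueError):
            ground_truth_maps(shape, 5.0, allow_protrusion=False)

    def test_concentration_constant_on_footprint(self, grid):
        shape = make_cylinder(16.0, 4.0, grid)
        gt = ground_truth_maps(shape, 7.5)
        fp = shape.footprint
        assert np.all(gt.concentration[fp] == 7.5)
        assert np.all(gt.concentration[~fp] == 0.0)
        assert np.all(gt.depth_mm[~fp] == 0.0)

    def test_matches_column_scan_oracle_on_random_lattices(self, grid, rng):
        for _ in range(5):
            occ = rng.random((grid.nx, grid.ny, grid.nz)) < 0.05
            shape = ShapeVolume(grid=grid, occupancy=occ)
            gt = ground_truth_maps(shape, 1.0, allow_protrusion=True)
            oracle = column_scan_oracle(occ, grid, allow_protrusion=True)
            np.testing.assert_array_equal(gt.depth_mm, oracle)


class TestMeshes:
    def test_identity_transform_voxelizes_raw_mesh(self, grid):
        mesh = trimesh.creation.icosphere(subdivisions=2, radius=8.0)
        mesh.vertices[:, 2] += 4.0  # mostly buried
        sv = shapes.augment_mesh(mesh, (1.0, 1.0, 1.0), 0.0, grid)
        raw = shapes.voxelize_mesh(mesh, grid)
        assert np.array_equal(sv.occupancy, raw.occupancy)

    def test_half_turn_on_mirror_symmetric_mesh(self, grid):
        mesh = trimesh.creation.box(extents=(20.0, 12.0, 6.0))
        mesh.vertices[:, 2] += 3.0
        a = shapes.augment_mesh(mesh, (1.0, 1.0, 1.0), 0.0, grid)
        b = shapes.augment_mesh(mesh, (1.0, 1.0, 1.0), 180.0, grid)
        assert np.array_equal(a.occupancy, b.occupancy)

    def test_scaled_cube_volume_matches_analytic(self, grid):
        mesh = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
        mesh.vertices[:, 2] += 0.5  # unit cube sitting on the surface
        sv = shapes.augment_mesh(mesh, (20.0, 20.0, 5.0), 0.0, grid)
        vol = sv.occupancy.sum() * grid.voxel_volume_mm3
        analytic = 20.0 * 20.0 * 5.0
        # one voxel shell tolerance on a 40x40x10 voxel solid
        shell = 2 * (40 * 40 + 2 * 40 * 10) * grid.voxel_volume_mm3
        assert abs(vol - analytic) <= shell

    def test_non_watertight_mesh_rejected(self, grid):
        mesh = trimesh.creation.icosphere(subdivisions=1, radius=8.0)
        open_mesh = trimesh.Trimesh(
            vertices=mesh.vertices, faces=mesh.faces[:-5], process=False
        )
        with pytest.raises(ValueError, match="watertight"):
            shapes.augment_mesh(open_mesh, (1.0, 1.0, 1.0), 0.0, grid)

    def test_synthetic_tumor_mesh_protrudes_and_closes(self):
        mesh = shapes.synthetic_tumor_mesh(np.random.default_rng(0))
        assert mesh.is_watertight
        assert mesh.bounds[0, 2] < 0 < mesh.bounds[1, 2]


class TestIO:
    def test_volume_roundtrip(self, tmp_path, grid):
        shape = make_cylinder(18.0, 3.0, grid)
        shapes.save_volume(tmp_path / "v.npz", shape)
        back = shapes.load_volume(tmp_path / "v.npz")
        assert np.array_equal(back.occupancy, shape.occupancy)
        assert back.grid == grid

    def test_stl_export_roundtrip_extents(self, tmp_path, grid):
        shape = make_cylinder(18.0, 3.0, grid)
        mesh = shapes.shape_to_mesh(shape)
        mesh.export(tmp_path / "c.stl")
        back = trimesh.load(tmp_path / "c.stl")
        assert back.bounds[1][0] - back.bounds[0][0] == pytest.approx(18.0, abs=1.5)
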