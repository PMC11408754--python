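"""Forward-physics kernels against independent numerical oracles."""

import numpy as np
import pytest

from fluordepth import optics, reference
from fluordepth.grid import GridSpec
from fluordepth.optics import FluorophoreSpec, OpticalProperties
from fluordepth.shapes import ShapeVolume, make_cylinder

PROPS = OpticalProperties(0.0045, 1.0)
CORNERS = [
    OpticalProperties(0.0015, 0.75),
    OpticalProperties(0.015, 0.75),
    OpticalProperties(0.0015, 2.0),
    OpticalProperties(0.015, 2.0),
]


class TestDiffuseReflectance:
    def test_monotone_decreasing_in_fx(self):
        fx = np.array(optics.SPATIAL_FREQUENCIES_MM)
        rd = optics.diffuse_reflectance(PROPS, fx)
        assert np.all(np.diff(rd) < 0)
        assert np.all((rd > 0) & (rd < 1))

    def test_absorbing_limit(self):
        rds = [optics.diffuse_reflectance(OpticalProperties(mu, 1.0), 0.0)
               for mu in (0.5, 5.0, 50.0, 500.0)]
        assert np.all(np.diff(rds) < 0)
        assert rds[-1] < 1e-3

    @pytest.mark.parametrize("props", [PROPS] + CORNERS)
    @pytest.mark.parametrize("fx", [0.0, 0.2])
    def test_matches_fd_oracle(self, props, fx):
        rd = optics.diffuse_reflectance(props, fx)
        rd_num = reference.fd_reflectance(fx, props)
        assert rd == pytest.approx(rd_num, rel=5e-3)

    def test_invalid_props_rejected(self):
        with pytest.raises(ValueError):
            OpticalProperties(-0.001, 1.0)


class TestExcitationFluence:
    def test_decays_to_zero(self):
        z = np.array([10.0, 50.0, 150.0])
        phi = optics.excitation_fluence(z, 0.0, PROPS)
        assert np.all(np.diff(phi) < 0)
        assert phi[-1] < 1e-3 * optics.excitation_fluence(0.0, 0.0, PROPS)

    def test_frequency_ratio_nonincreasing_in_depth(self):
        z = np.linspace(0.0, 12.0, 60)
        lo = optics.excitation_fluence(z, 0.05, PROPS)
        hi = optics.excitation_fluence(z, 0.2, PROPS)
        ratio = hi / lo
        assert np.all(np.diff(ratio) <= 1e-12)

    @pytest.mark.parametrize("props", [PROPS] + CORNERS)
    def test_matches_fd_oracle(self, props):
        z = np.array([0.25, 0.5, 1.0, 2.0, 5.0, 10.0])
        for fx in (0.0, 0.1, 0.25):
            a = optics.excitation_fluence(z, fx, props)
            b = reference.fd_fluence(z, fx, props)
            assert np.abs(a / b - 1.0).max() < 5e-3

    def test_point_value_against_oracle(self):
        a = optics.excitation_fluence(0.5, 0.1, PROPS)
        b = float(reference.fd_fluence(0.5, 0.1, PROPS))
        assert a == pytest.approx(b, rel=5e-3)

    def test_negative_depth_rejected(self):
        with pytest.raises(ValueError):
            optics.excitation_fluence(-1.0, 0.0, PROPS)


class TestEmissionEscape:
    def test_radial_symmetry(self):
        rho = np.array([-3.0, 3.0])
        e = optics.emission_escape(rho, 5.0, PROPS)
        assert e[0] == e[1]

    def test_lateral_integral_decreases_with_depth(self):
        vals = [reference.escape_lateral_integral(z, PROPS) for z in (1.0, 3.0, 6.0, 10.0)]
        assert np.all(np.diff(vals) < 0)

    def test_deeper_source_escapes_less_on_axis(self):
        assert optics.emission_escape(0.0, 10.0, PROPS) < optics.emission_escape(0.0, 5.0, PROPS)

    def test_plane_integral_closed_form_matches_quadrature(self):
        for z in (0.5, 2.0, 8.0):
            closed = optics.emission_escape_plane(z, PROPS)
            quad = reference.escape_lateral_integral(z, PROPS)
            assert closed == pytest.approx(quad, rel=1e-4)


class TestBornFluorescence:
    def test_zero_concentration_gives_zero_image(self, grid):
        shape = make_cylinder(20.0, 5.0, grid)
        img = optics.simulate_fluorescence(shape, PROPS, FluorophoreSpec(concentration=0.0))
        assert np.all(img == 0.0)

    def test_linear_in_concentration(self, grid):
        shape = make_cylinder(20.0, 5.0, grid)
        one = optics.simulate_fluorescence(shape, PROPS, FluorophoreSpec(concentration=2.0))
        two = optics.simulate_fluorescence(shape, PROPS, FluorophoreSpec(concentration=4.0))
        np.testing.assert_allclose(two, 2.0 * one, rtol=1e-12)

    @pytest.mark.parametrize("props", [PROPS, CORNERS[0], CORNERS[3]])
    @pytest.mark.parametrize("depth", [1.0, 4.0, 8.0])
    def test_infinite_slab_limit_matches_quadrature(self, props, depth):
        """Center pixel of a wide slab equals the 1-D Born integral."""
        g = GridSpec(nx=201, ny=201)
        occ = np.zeros((g.nx, g.ny, g.nz), dtype=bool)
        occ[:, :, (g.z_mm >= 0) & (g.z_mm <= depth)] = True
        slab = ShapeVolume(grid=g, occupancy=occ)
        fluor = FluorophoreSpec(concentration=5.0)
        img = optics.simulate_fluorescence(slab, props, fluor, fx=[0.0, 0.1, 0.25])
        for i, fx in enumerate([0.0, 0.1, 0.25]):
            oracle = reference.slab_fluorescence_center(depth, fx, props, fluor)
            assert img[i, 100, 100] == pytest.approx(oracle, rel=0.01)

    def test_frequency_decay_steeper_for_deeper_slab(self, grid):
        """Normalized fx-decay of the tumor-mean signal steepens with depth."""
        fx = list(optics.SPATIAL_FREQUENCIES_MM)
        decays = []
        for depth in (2.0, 8.0):
            shape = make_cylinder(30.0, depth, grid)
            img = optics.simulate_fluorescence(shape, PROPS, FluorophoreSpec(concentration=5.0), fx)
            fp = shape.footprint
            means = np.array([img[i][fp].mean() for i in range(len(fx))])
            decays.append(means / means[0])
        assert np.all(decays[1][1:] < decays[0][1:])


class TestPoissonNoise:
    def test_zero_image_unchanged(self, rng):
        img = np.zeros((8, 8))
        out = optics.add_poisson_noise(img, 1e4, rng)
        assert np.all(out == 0.0)

    def test_mean_and_variance(self, rng):
        img = np.array([[1.0, 4.0], [0.25, 2.0]])
        budget = 100.0
        draws = np.stack([optics.add_poisson_noise(img, budget, rng) for _ in range(10000)])
        mean = draws.mean(axis=0)
        se = np.sqrt(img * (img.max() / budget) / draws.shape[0])
        assert np.all(np.abs(mean - img) < 3.5 * se)
        peak_var = draws[:, 0, 1].var()
        assert peak_var == pytest.approx(img.max() ** 2 / budget, rel=0.1)


class TestSimulateSample:
    def test_noiseless_limit(self, grid, rng):
        shape = make_cylinder(20.0, 5.0, grid)
        fluor = FluorophoreSpec(concentration=5.0)
        clean, _ = optics.simulate_sample(shape, PROPS, fluor, rng, photon_budget=None)
        noisy, _ = optics.simulate_sample(
            shape, PROPS, fluor, np.random.default_rng(0), photon_budget=1e9
        )
        assert np.abs(noisy.fluorescence - clean.fluorescence).max() < 1e-3 * clean.fluorescence.max()

    def test_seeded_reproducibility(self, grid):
        shape = make_cylinder(20.0, 5.0, grid)
        fluor = FluorophoreSpec(concentration=5.0)
        a, _ = optics.simulate_sample(shape, PROPS, fluor, np.random.default_rng(9))
        b, _ = optics.simulate_sample(shape, PROPS, fluor, np.random.default_rng(9))
        assert np.array_equal(a.fluorescence, b.fluorescence)
        assert np.array_equal(a.reflectance, b.reflectance)

    def test_reflectance_is_flat_before_noise(self, grid, rng):
        shape = make_cylinder(20.0, 5.0, grid)
        stack, _ = optics.simulate_sample(
            shape, PROPS, FluorophoreSpec(concentration=5.0), rng, photon_budget=None
        )
        for i, fx in enumerate(stack.fx):
            assert np.ptp(stack.reflectance[i]) == 0.0
            assert stack.reflectance[i, 0, 0] == pytest.approx(
                optics.diffuse_reflectance(PROPS, fx)
            )

    def test_stack_roundtrip(self, tmp_path, grid, rng):
        shape = make_cylinder(20.0, 5.0, grid)
        stack, _ = optics.simulate_sample(shape, PROPS, FluorophoreSpec(concentration=5.0), rng)
        optics.save_stack(tmp_path / "s.tiff", stack)
        back = optics.load_stack(tmp_path / "s.tiff")
        assert back.fx == stack.fx
        np.testing.assert_array_equal(back.reflectance, stack.reflectance)
        np.testing.assert_array_equal(back.fluorescence, stack.fluorescence)
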