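"""Spectral-library construction, SAM matching and mixture inversion."""

import numpy as np
import pytest

from watercolumn.forward_models import (
    BOTTOM_LABELS,
    CANONICAL_DEPTHS,
    Scenario,
    deep_water_reflectance,
    l99_forward,
    make_bottom,
    mix_bottoms,
)
from watercolumn.matching import (
    DEFAULT_MIXTURE_BOUNDS,
    _mixture_forward,
    add_noise,
    build_library,
    canonical_library_waters,
    classify_batch,
    lut_classify,
    mixture_invert,
    spectral_angle,
)
from watercolumn.optics_core import (
    Geometry,
    Kind,
    Side,
    Spectrum,
    WATER_TYPES,
    build_iops,
    convert_interface,
    phytoplankton_absorption_shape,
    water_absorption,
)


class TestSpectralAngle:
    def test_zero_for_identical(self):
        x = np.array([1.0, 2.0, 3.0])
        assert spectral_angle(x, x) == pytest.approx(0.0, abs=1e-9)

    def test_right_angle_for_orthogonal(self):
        assert spectral_angle([1.0, 0.0], [0.0, 1.0]) == pytest.approx(np.pi / 2)

    def test_scale_invariance(self):
        x = np.array([0.3, 0.1, 0.7])
        assert spectral_angle(x, 2.0 * x) == pytest.approx(0.0, abs=1e-7)

    def test_zero_norm_rejected(self):
        with pytest.raises(ValueError, match="zero-norm"):
            spectral_angle([0.0, 0.0], [1.0, 1.0])


@pytest.fixture(scope="module")
def small_library(grid, geom):
    waters = [WATER_TYPES[n] for n in ("water-a", "water-b", "water-c", "water-d")]
    bottoms = [make_bottom(lbl, grid) for lbl in BOTTOM_LABELS]
    return build_library(waters, CANONICAL_DEPTHS, bottoms, grid=grid, geom=geom)


class TestBuildLibrary:
    def test_cartesian_product_count(self, small_library):
        assert len(small_library) == 4 * 4 * 3 == 48

    def test_single_cell_equals_direct_forward(self, grid, geom):
        w = WATER_TYPES["water-b"]
        b = make_bottom("green_algae", grid)
        lib = build_library([w], [5.0], [b], grid=grid, geom=geom)
        iops = build_iops(w, geom, grid)
        deep = deep_water_reflectance(iops)
        below = l99_forward(Scenario(w, b, 5.0, geom), iops, deep)
        above = convert_interface(below, "below_to_above")
        np.testing.assert_allclose(lib.values[0], above.values, rtol=1e-12)

    def test_deterministic_ordering_and_hash(self, grid, geom, small_library):
        waters = [WATER_TYPES[n] for n in ("water-a", "water-b", "water-c", "water-d")]
        bottoms = [make_bottom(lbl, grid) for lbl in BOTTOM_LABELS]
        again = build_library(waters, CANONICAL_DEPTHS, bottoms, grid=grid, geom=geom)
        assert again.content_hash() == small_library.content_hash()

    def test_empty_grid_rejected(self, grid, geom):
        with pytest.raises(ValueError, match="nonempty"):
            build_library([], [5.0], [make_bottom("coral_sand", grid)], grid=grid)

    def test_canonical_water_grid_size(self):
        assert len(canonical_library_waters()) == 16 * 7 * 7

    def test_concat_requires_same_grid(self, small_library, geom):
        other_grid = np.arange(450.0, 651.0, 5.0)
        other = build_library(
            [WATER_TYPES["water-a"]], [5.0], [make_bottom("coral_sand", other_grid)],
            grid=other_grid, geom=geom,
        )
        with pytest.raises(ValueError):
            small_library.concat(other)


class TestLutClassify:
    def test_library_member_self_retrieval(self, small_library):
        q = Spectrum(small_library.wavelengths, small_library.values[17], Kind.RRS, Side.ABOVE)
        entry, angle, label = lut_classify(q, small_library)
        assert angle == pytest.approx(0.0, abs=1e-7)
        assert label == small_library.params.iloc[17]["bottom"]

    def test_invariant_to_query_scaling(self, small_library):
        q1 = Spectrum(small_library.wavelengths, small_library.values[5], Kind.RRS, Side.ABOVE)
        q2 = q1.with_values(q1.values * 2.0)
        assert lut_classify(q1, small_library)[2] == lut_classify(q2, small_library)[2]

    def test_entry_carries_generating_parameters(self, small_library):
        entry, _, _ = lut_classify(
            Spectrum(small_library.wavelengths, small_library.values[30], Kind.RRS, Side.ABOVE),
            small_library,
        )
        row = small_library.params.iloc[30]
        assert entry.depth == row["depth"]
        assert entry.water.chl == row["chl"]

    @pytest.mark.parametrize("seed", [0, 1, 7])
    def test_clear_water_noisy_queries_all_correct(self, grid, geom, small_library, seed):
        """5% noise in the clearest water never flips the assigned bottom."""
        w = WATER_TYPES["water-a"]
        iops = build_iops(w, geom, grid)
        deep = deep_water_reflectance(iops)
        rng = np.random.default_rng(seed)
        for z in CANONICAL_DEPTHS:
            for lbl in BOTTOM_LABELS:
                below = l99_forward(Scenario(w, make_bottom(lbl, grid), z, geom), iops, deep)
                noisy = add_noise(convert_interface(below, "below_to_above"), 0.05, rng)
                _, _, assigned = lut_classify(noisy, small_library)
                assert assigned == lbl

    def test_empty_library_rejected(self, small_library):
        with pytest.raises(ValueError):
            classify_batch(small_library.values[:1], small_library.__class__(
                small_library.wavelengths,
                np.empty((0, small_library.wavelengths.size)),
                small_library.params.iloc[:0],
            ))


class TestAddNoise:
    def test_zero_level_identity(self, grid):
        s = Spectrum(grid, np.linspace(0.01, 0.05, grid.size), Kind.RRS, Side.ABOVE)
        np.testing.assert_array_equal(add_noise(s, 0.0, 1).values, s.values)

    def test_seed_reproducibility(self, grid):
        s = Spectrum(grid, np.linspace(0.01, 0.05, grid.size), Kind.RRS, Side.ABOVE)
        a = add_noise(s, 0.05, 123).values
        b = add_noise(s, 0.05, 123).values
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, add_noise(s, 0.05, 124).values)

    def test_sample_sd_matches_level(self):
        wl = np.linspace(400.0, 700.0, 10000)
        s = Spectrum(wl, np.ones(wl.size), Kind.RRS, Side.ABOVE)
        eps = add_noise(s, 0.05, 5).values - 1.0
        assert np.std(eps) == pytest.approx(0.05, rel=0.02)

    def test_negative_level_rejected(self, grid):
        s = Spectrum(grid, np.ones(grid.size), Kind.RRS, Side.ABOVE)
        with pytest.raises(ValueError):
            add_noise(s, -0.1, 0)


@pytest.fixture(scope="module")
def coarse_grid():
    return np.arange(400.0, 701.0, 10.0)


@pytest.fixture(scope="module")
def endmembers(coarse_grid):
    return [make_bottom(lbl, coarse_grid) for lbl in BOTTOM_LABELS]


def render_mixture(theta, grid, endmembers, geom=Geometry()):
    emat = np.stack([e.values for e in endmembers])
    return _mixture_forward(
        theta, grid, emat, geom,
        water_absorption(grid), phytoplankton_absorption_shape(grid),
        0.00144 * (grid / 500.0) ** -4.32, (grid / 440.0) ** -1.0,
    )


class TestMixtureInvert:
    def test_parameter_recovery_noiseless(self, coarse_grid, endmembers):
        theta = [0.02, 0.05, 0.005, 0.6, 0.3, 0.1, 4.0]
        rrs = render_mixture(theta, coarse_grid, endmembers)
        fit = mixture_invert(
            Spectrum(coarse_grid, rrs, Kind.RRS, Side.BELOW), endmembers, seed=0
        )
        est = np.array([fit.aphy440, fit.ag440, fit.bbp440, *fit.b_weights, fit.z_est])
        np.testing.assert_allclose(est, theta, rtol=0.01)
        assert fit.residual < 1e-8

    def test_pure_endmember_shallow_clear_water(self, coarse_grid, endmembers):
        theta = [0.001, 0.002, 0.0005, 1.0, 0.0, 0.0, 0.3]
        rrs = render_mixture(theta, coarse_grid, endmembers)
        fit = mixture_invert(
            Spectrum(coarse_grid, rrs, Kind.RRS, Side.BELOW), endmembers, seed=1
        )
        w = fit.normalized_weights
        assert w[0] == pytest.approx(1.0, abs=0.02)
        assert w[1] == pytest.approx(0.0, abs=0.02)
        assert w[2] == pytest.approx(0.0, abs=0.02)

    def test_two_endmember_matches_linear_bottom_model(self, coarse_grid):
        """With weights (g, 1-g) the fitted bottom equals the two-substrate
        convex-combination model."""
        sand = make_bottom("coral_sand", coarse_grid)
        brown = make_bottom("brown_algae", coarse_grid)
        g = 0.7
        mixed = mix_bottoms([brown, sand], [g, 1.0 - g])
        theta = [0.01, 0.02, 0.002, g, 1.0 - g, 2.5]
        rrs = render_mixture(theta, coarse_grid, [brown, sand])
        fit = mixture_invert(
            Spectrum(coarse_grid, rrs, Kind.RRS, Side.BELOW), [brown, sand], seed=2
        )
        fitted_bottom = fit.b_weights[0] * brown.values + fit.b_weights[1] * sand.values
        np.testing.assert_allclose(fitted_bottom, mixed.values, rtol=0.01)

    def test_residual_grows_with_noise(self, coarse_grid, endmembers):
        theta = [0.02, 0.05, 0.005, 0.6, 0.3, 0.1, 4.0]
        rrs = render_mixture(theta, coarse_grid, endmembers)
        clean = Spectrum(coarse_grid, rrs, Kind.RRS, Side.BELOW)
        res = []
        for level in (0.0, 0.02, 0.08):
            noisy = add_noise(clean, level, 11)
            res.append(mixture_invert(noisy, endmembers, seed=3, n_starts=2).residual)
        assert res[0] < res[1] < res[2]

    def test_endmember_count_bounds(self, coarse_grid, endmembers):
        q = Spectrum(coarse_grid, np.full(coarse_grid.size, 0.01), Kind.RRS, Side.BELOW)
        with pytest.raises(ValueError, match="1-3"):
            mixture_invert(q, [], seed=0)
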