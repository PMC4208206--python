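"""Contribution accounting, validity rules, uncertainty and sensitivity."""

import math

import numpy as np
import pytest

from watercolumn.algebraic_correctors import RetrievalResult, l99_invert, m94_invert
from watercolumn.benchmark import (
    ConfusionMatrix,
    SensitivityCase,
    apply_validity,
    bottom_contribution_l99,
    bottom_contribution_m94,
    detectable_wavelength_range,
    retrieval_uncertainty,
    sensitivity_analysis,
    sensitivity_single,
    standard_bottom,
)
from watercolumn.forward_models import (
    BottomSpectrum,
    DeepWaterReference,
    Scenario,
    deep_water_reflectance,
    l99_forward,
    make_bottom,
)
from watercolumn.optics_core import Geometry, Kind, Side, Spectrum, WATER_TYPES, build_iops
from watercolumn.validity import ValidityConfig


def single(value, kind=Kind.R, side=Side.BELOW):
    return Spectrum(np.array([550.0]), np.array([value]), kind, side)


class TestContributionM94:
    def test_no_contrast_gives_zero(self):
        deep = DeepWaterReference(np.array([550.0]), np.array([0.05 / math.pi]))
        res = RetrievalResult(np.array([550.0]), deep.r_inf.copy(), "m94")
        pct = bottom_contribution_m94(res, deep, 0.1, 5.0, single(0.2))
        assert pct[0] == pytest.approx(0.0, abs=1e-12)

    def test_exposed_bottom_no_deep_signal_is_total(self):
        deep = DeepWaterReference(np.array([550.0]), np.array([0.0]))
        res = RetrievalResult(np.array([550.0]), np.array([0.3]), "m94")
        pct = bottom_contribution_m94(res, deep, 0.1, 0.0, single(0.3))
        assert pct[0] == pytest.approx(100.0)

    def test_closed_form_value(self):
        # (0.3 - 0.05) e^{-1} / 0.141970 * 100 = 64.78%
        deep = DeepWaterReference(np.array([550.0]), np.array([0.05 / math.pi]))
        rw = single(0.05 + 0.25 * math.exp(-1.0))
        res = RetrievalResult(np.array([550.0]), np.array([0.3]), "m94")
        pct = bottom_contribution_m94(res, deep, 0.1, 5.0, rw)
        assert pct[0] == pytest.approx(64.78, abs=0.01)

    def test_zero_signal_flagged_undefined(self):
        deep = DeepWaterReference(np.array([550.0]), np.array([0.01]))
        res = RetrievalResult(np.array([550.0]), np.array([0.3]), "m94")
        pct = bottom_contribution_m94(res, deep, 0.1, 5.0, single(0.0))
        assert np.isnan(pct[0])
        assert res.flags["deep_exceeds_signal"][0]


class TestContributionL99:
    def test_exposed_bottom_is_total(self, geom):
        rho = 0.3
        rrs = single(rho / math.pi, kind=Kind.RRS)
        iops = build_iops(WATER_TYPES["water-a"], geom, np.array([550.0]))
        res = RetrievalResult(np.array([550.0]), np.array([rho]), "l99")
        pct = bottom_contribution_l99(res, iops, 0.0, geom, rrs)
        assert pct[0] == pytest.approx(100.0)

    def test_deep_limit_vanishes(self, geom):
        rrs = single(0.002, kind=Kind.RRS)
        iops = build_iops(WATER_TYPES["water-d"], geom, np.array([550.0]))
        res = RetrievalResult(np.array([550.0]), np.array([0.3]), "l99")
        pct = bottom_contribution_l99(res, iops, 100.0, geom, rrs)
        assert pct[0] == pytest.approx(0.0, abs=1e-9)

    def test_frozen_regression_value(self, grid, geom, bottoms, iops_by_water, deep_by_water):
        """water-a, sand, 5 m at 550 nm; value frozen from direct evaluation
        of the path-term formula."""
        iops, deep = iops_by_water["water-a"], deep_by_water["water-a"]
        sc = Scenario(WATER_TYPES["water-a"], bottoms["coral_sand"], 5.0)
        rrs = l99_forward(sc, iops, deep)
        res = l99_invert(rrs, deep, iops, 5.0, geom)
        pct = bottom_contribution_l99(res, iops, 5.0, geom, rrs)
        assert pct[grid == 550.0][0] == pytest.approx(99.02282763426864, rel=1e-9)


class TestValidity:
    def test_low_contribution_masked(self):
        res = RetrievalResult(np.array([550.0]), np.array([0.3]), "m94")
        res.contribution_pct = np.array([0.4])
        apply_validity(res)
        assert res.flags["low_contribution"][0]
        assert not res.valid_mask[0]

    def test_out_of_range_masked(self):
        res = RetrievalResult(np.array([550.0]), np.array([1.2]), "m94")
        apply_validity(res)
        assert res.flags["out_of_range"][0]

    def test_idempotent_when_all_pass(self):
        res = RetrievalResult(np.array([550.0]), np.array([0.3]), "m94")
        res.contribution_pct = np.array([40.0])
        apply_validity(res)
        before = {k: v.copy() for k, v in res.flags.items()}
        apply_validity(res)
        for k in before:
            np.testing.assert_array_equal(res.flags[k], before[k])
        assert res.valid_mask[0]

    def test_custom_thresholds(self):
        res = RetrievalResult(np.array([550.0]), np.array([0.3]), "m94")
        res.contribution_pct = np.array([3.0])
        apply_validity(res, ValidityConfig(min_contribution_pct=5.0))
        assert res.flags["low_contribution"][0]


class TestUncertainty:
    def test_exact_retrieval_zero(self, grid, bottoms):
        truth = bottoms["coral_sand"]
        res = RetrievalResult(grid, truth.values.copy(), "m94")
        np.testing.assert_allclose(retrieval_uncertainty(res, truth), 0.0, atol=1e-12)

    def test_double_retrieval_is_plus_hundred(self, grid, bottoms):
        truth = bottoms["coral_sand"]
        res = RetrievalResult(grid, 2.0 * truth.values, "m94")
        np.testing.assert_allclose(retrieval_uncertainty(res, truth), 100.0)

    def test_zero_truth_excluded(self, grid):
        truth = BottomSpectrum(grid, np.zeros(grid.size))
        res = RetrievalResult(grid, np.full(grid.size, 0.1), "m94")
        unc = retrieval_uncertainty(res, truth)
        assert np.isnan(unc).all()
        assert res.flags["deep_exceeds_signal"].all()


class TestSensitivity:
    def test_zero_perturbation_zero_sensitivity(self, grid, bottoms):
        s = sensitivity_single(
            WATER_TYPES["water-a"], bottoms["coral_sand"], 3.0, "m94", "Kd", 0.0
        )
        np.testing.assert_allclose(s, 0.0, atol=1e-9)

    def test_closed_form_kd_overestimate(self):
        # Eq-7 propagation: rho_b=0.3, R_inf=0.05, Kd=0.1, z=10, +50% ->
        # |(rho_b - R_inf)(e^{2*0.05*10} - 1)| / rho_b * 100 = 143.19%
        expected = 0.25 * (math.e - 1.0) / 0.3 * 100.0
        assert expected == pytest.approx(143.19, abs=0.01)
        wl = np.array([550.0])
        deep = DeepWaterReference(wl, np.array([0.05 / math.pi]))
        rw = Spectrum(wl, [0.05 + 0.25 * math.exp(-2.0)], Kind.R, Side.BELOW)
        base = m94_invert(rw, deep, 0.1, 10.0).rho_b[0]
        pert = m94_invert(rw, deep, 0.15, 10.0).rho_b[0]
        assert 100.0 * abs(base - pert) / base == pytest.approx(expected, rel=1e-9)

    def test_turbid_deep_overestimate_exceeds_300pct(self, bottoms):
        s = sensitivity_single(
            WATER_TYPES["water-d"], bottoms["coral_sand"], 10.0, "m94", "Kd", 0.5
        )
        wl = bottoms["coral_sand"].wavelengths
        assert s[wl == 550.0][0] > 300.0

    def test_deep_reflectance_insensitive_in_shallow_clear_water(self, bottoms):
        s = sensitivity_single(
            WATER_TYPES["water-a"], bottoms["coral_sand"], 3.0, "m94", "R_inf", 0.5
        )
        wl = bottoms["coral_sand"].wavelengths
        assert s[wl == 450.0][0] < 1.0

    def test_perturbation_outside_range_rejected(self, bottoms):
        with pytest.raises(ValueError):
            sensitivity_single(
                WATER_TYPES["water-a"], bottoms["coral_sand"], 3.0, "m94", "Kd", 1.5
            )

    def test_case_validation_and_table_shape(self):
        case = SensitivityCase(water="water-d", bottom="coral_sand", depth=10.0)
        table = sensitivity_analysis(case, method="l99", param="a",
                                     grid=np.arange(400.0, 701.0, 5.0))
        assert list(table.columns) == [450.0, 550.0, 650.0]
        assert table.loc[0.0].max() == pytest.approx(0.0, abs=1e-9)
        with pytest.raises(ValueError):
            SensitivityCase(water="water-b")

    def test_method_param_compatibility(self, bottoms):
        with pytest.raises(ValueError):
            sensitivity_single(
                WATER_TYPES["water-a"], bottoms["coral_sand"], 3.0, "m94", "a", 0.1
            )


class TestDetectableRange:
    def test_near_surface_interval_is_widest_and_reaches_red(self, grid):
        """At negligible depth the detectable interval is the widest the
        water type allows and extends to 700 nm.  It need not start at
        400 nm: the contribution accounting subtracts the deep-water
        reflectance, and in clear water the blue R_inf can exceed a dark
        mixed bottom, so the bluest wavelengths carry no bottom excess
        even at the surface."""
        b = standard_bottom(grid)
        out = detectable_wavelength_range(WATER_TYPES["water-a"], b, [0.01, 5.0])
        lo, hi = out[0.01]
        assert hi == grid[-1]
        assert lo < 500.0
        deeper = out[5.0]
        assert deeper is not None
        assert deeper[0] >= lo and deeper[1] <= hi

    def test_intervals_nested_across_depth(self, grid):
        b = standard_bottom(grid)
        out = detectable_wavelength_range(WATER_TYPES["water-b"], b, np.arange(1.0, 29.0))
        prev = None
        for z in sorted(out):
            cur = out[z]
            if prev is not None and prev is not None and cur is not None:
                assert cur[0] >= prev[0] and cur[1] <= prev[1]
            if cur is None and prev is None:
                pass
            prev = cur

    def test_turbid_deep_interval_empty_or_narrow(self, grid):
        b = standard_bottom(grid)
        out = detectable_wavelength_range(WATER_TYPES["water-d"], b, [1.0, 40.0])
        shallow, deep = out[1.0], out[40.0]
        assert shallow is not None
        assert deep is None or (deep[1] - deep[0]) < (shallow[1] - shallow[0])


class TestConfusionMatrix:
    def test_row_sums_and_accuracy(self):
        cm = ConfusionMatrix(np.array([[15, 0, 1], [1, 14, 1], [1, 2, 13]]))
        np.testing.assert_array_equal(cm.row_sums, [16, 16, 16])
        acc = cm.accuracy_by_class()
        assert acc["coral_sand"] == pytest.approx(100 * 15 / 16)

    def test_add_accumulates(self):
        cm = ConfusionMatrix()
        cm.add("coral_sand", "green_algae")
        cm.add("coral_sand", "green_algae")
        assert cm.counts[0, 1] == 2

    def test_rejects_negative_counts(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(np.array([[1, -1, 0], [0, 0, 0], [0, 0, 0]]))
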