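"""Standard curves, oxygen profiling, ddCt expression and clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from neuroenergetics.assays import (
    ExpressionMatrix,
    O2Profile,
    calibrate_o2,
    calibration_drift,
    concentration_from_signal,
    ddct_expression,
    depth_axis,
    dilution_series,
    fit_standard_curve,
    locate_slice_core,
    normalize_to_control,
    row_ratio,
    zscore_cluster,
)
from neuroenergetics.synth import CtDesign, O2ProfileSpec, gen_ct_table, \
    gen_o2_profile


class TestDilutionSeries:
    @pytest.mark.parametrize("top,factor,n,expected_first,expected_last", [
        (8000.0, 2.0, 8, 8000.0, 62.5),      # IL-6 ELISA series
        (80.0, 2.0, 9, 80.0, 0.3125),        # nitrite series
        (1000.0, 2.0, 6, 1000.0, 31.25),     # lactate series
    ])
    def test_printed_series(self, top, factor, n, expected_first,
                            expected_last):
        series = dilution_series(top, factor, n)
        assert len(series) == n
        assert series[0] == expected_first
        assert series[-1] == expected_last
        np.testing.assert_allclose(series[:-1] / series[1:], factor)

    def test_unit_factor_rejected(self):
        with pytest.raises(ValueError, match="factor"):
            dilution_series(100.0, 1.0, 5)


class TestStandardCurves:
    def test_linear_noiseless_recovery(self):
        conc = dilution_series(1000.0, 2.0, 6)
        sig = 0.04 + 3e-4 * conc
        curve = fit_standard_curve(list(zip(conc, sig)), "linear")
        np.testing.assert_allclose(curve.coefficients, [0.04, 3e-4],
                                   rtol=1e-9)
        assert curve.fit_stats["r2"] == pytest.approx(1.0)

    def test_quadratic_noiseless_recovery(self):
        conc = dilution_series(8000.0, 2.0, 8)
        truth = np.array([0.05, 2.5e-4, -1e-8])
        sig = truth[0] + truth[1] * conc + truth[2] * conc ** 2
        curve = fit_standard_curve(list(zip(conc, sig)), "quadratic")
        np.testing.assert_allclose(curve.coefficients, truth, rtol=1e-7)

    def test_underdetermined_quadratic_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            fit_standard_curve([(1, 1), (2, 2)], "quadratic")

    def test_non_monotone_curve_rejected(self):
        conc = np.linspace(0, 10, 8)
        sig = (conc - 5.0) ** 2  # U-shaped over the domain
        with pytest.raises(ValueError, match="monotone"):
            fit_standard_curve(list(zip(conc, sig)), "quadratic")

    def test_round_trip_inversion(self):
        """Noiseless signals invert back to their concentrations."""
        for model, truth in (("linear", (0.05, 2.5e-4)),
                             ("quadratic", (0.05, 2.5e-4, -1.2e-8))):
            conc = dilution_series(8000.0, 2.0, 8)
            sig = np.polyval(np.asarray(truth)[::-1], conc)
            curve = fit_standard_curve(list(zip(conc, sig)), model)
            for c, s in zip(conc, sig):
                assert concentration_from_signal(curve, s) == pytest.approx(
                    c, rel=1e-6)

    def test_dilution_factor_multiplies(self):
        conc = dilution_series(1000.0, 2.0, 6)
        curve = fit_standard_curve(
            [(c, 0.1 + 1e-3 * c) for c in conc], "linear")
        s = 0.1 + 1e-3 * 100.0
        assert concentration_from_signal(curve, s, dilution_factor=5) == \
            pytest.approx(500.0, rel=1e-9)

    def test_intercept_signal_maps_to_zero(self):
        conc = np.linspace(0.0, 100.0, 5)
        curve = fit_standard_curve(
            [(c, 0.2 + 2e-3 * c) for c in conc], "linear")
        assert concentration_from_signal(curve, 0.2) == pytest.approx(
            0.0, abs=1e-9)

    def test_out_of_range_signal_rejected(self):
        conc = np.linspace(1.0, 100.0, 5)
        curve = fit_standard_curve(
            [(c, 1e-3 * c) for c in conc], "linear")
        with pytest.raises(ValueError, match="refusing to extrapolate"):
            concentration_from_signal(curve, 1.0)

    def test_noise_scaling_of_recovered_unknowns(self):
        """Median inversion error grows with plate noise (20 seeds per
        level)."""
        from neuroenergetics.synth import PlateSpec, gen_plate
        levels = (0.001, 0.01, 0.05)
        med_errs = []
        for noise in levels:
            errs = []
            for seed in range(20):
                plate = gen_plate(PlateSpec(
                    noise_sd=noise, unknowns_truth=(500.0, 2000.0),
                    seed=seed))
                stds = plate.standards()
                curve = fit_standard_curve(
                    list(zip(stds["conc"], stds["signal"])), "linear")
                for _, row in plate.unknowns().iterrows():
                    try:
                        est = concentration_from_signal(curve, row["signal"])
                    except ValueError:
                        continue
                    errs.append(abs(est - row["conc"]))
            med_errs.append(np.median(errs))
        assert med_errs[0] < med_errs[1] < med_errs[2]


class TestOxygen:
    def test_perfect_sensor_calibration(self):
        cal = calibrate_o2([(0.0, 10.0), (20.0, 110.0), (95.0, 485.0)])
        assert cal.r2 == pytest.approx(1.0)
        assert cal.slope * 10.0 + cal.intercept == pytest.approx(0.0,
                                                                 abs=1e-9)

    def test_nonlinear_sensor_warns(self):
        with pytest.warns(UserWarning, match="r2"):
            calibrate_o2([(0.0, 10.0), (20.0, 300.0), (95.0, 330.0)])

    def test_duplicate_levels_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            calibrate_o2([(0.0, 10.0), (0.0, 12.0), (95.0, 485.0)])

    def test_drift_flag(self):
        pre = calibrate_o2([(0.0, 10.0), (20.0, 110.0), (95.0, 485.0)])
        post_ok = calibrate_o2([(0.0, 10.5), (20.0, 112.0), (95.0, 492.0)])
        post_bad = calibrate_o2([(0.0, 10.0), (20.0, 90.0), (95.0, 390.0)])
        assert not calibration_drift(pre, post_ok)
        assert calibration_drift(pre, post_bad)

    def test_printed_step_geometry(self):
        assert depth_axis(1)[0] == pytest.approx(16.38, abs=0.01)
        assert depth_axis(1, angle_deg=90.0)[0] == pytest.approx(20.0)
        assert depth_axis(6)[-1] == pytest.approx(98.3, abs=0.1)

    def test_bad_angle_rejected(self):
        with pytest.raises(ValueError, match="angle"):
            depth_axis(5, angle_deg=120.0)

    def test_core_at_planted_minimum(self):
        profile = O2Profile(step_index=np.arange(5),
                            depth_um=depth_axis(5),
                            concentration=np.array(
                                [150.0, 120.0, 100.0, 90.0, 95.0]))
        loc = locate_slice_core(profile)
        assert loc.index == 3 and not loc.degenerate

    def test_monotone_profile_flagged(self):
        profile = O2Profile(step_index=np.arange(4), depth_um=depth_axis(4),
                            concentration=np.array([150.0, 120.0, 100.0,
                                                    90.0]))
        loc = locate_slice_core(profile)
        assert loc.index == 3 and loc.degenerate

    def test_flat_profile_degenerate_at_first_index(self):
        profile = O2Profile(step_index=np.arange(4), depth_um=depth_axis(4),
                            concentration=np.full(4, 100.0))
        loc = locate_slice_core(profile)
        assert loc.index == 0 and loc.degenerate

    def test_generator_round_trip(self):
        spec = O2ProfileSpec(noise_sd=0.0, core_step_index=5)
        assert locate_slice_core(gen_o2_profile(spec)).index == 5


class TestDdct:
    def test_null_design_gives_unit_expression(self):
        ct = gen_ct_table(CtDesign(ct_noise_sd=0.0))
        em = ddct_expression(ct)
        np.testing.assert_allclose(em.values.to_numpy(), 1.0)

    def test_one_cycle_is_a_two_fold_change(self):
        ct = gen_ct_table(CtDesign(
            effect_logfc={"TNF": {"LPS": 1.0}}, ct_noise_sd=0.0))
        em = ddct_expression(ct)
        lps = em.groups.index[em.groups == "LPS"]
        np.testing.assert_allclose(em.values.loc["TNF", lps], 2.0)

    def test_round_trip_of_planted_fold_changes(self):
        effects = {"IL6": {"LPS": 3.0, "RES24": 1.5},
                   "TNF": {"LPS": 2.0, "RES48": -1.0}}
        ct = gen_ct_table(CtDesign(effect_logfc=effects, ct_noise_sd=0.0))
        em = ddct_expression(ct)
        for gene, by_group in effects.items():
            for group, logfc in by_group.items():
                cols = em.groups.index[em.groups == group]
                np.testing.assert_allclose(em.values.loc[gene, cols],
                                           2.0 ** logfc, rtol=1e-12)

    def test_loading_offsets_cancel(self):
        """A per-sample Ct shift (loading) leaves relative expression
        unchanged: the reference gene absorbs it."""
        effects = {"IL6": {"LPS": 3.0}}
        a = ddct_expression(gen_ct_table(CtDesign(
            effect_logfc=effects, ct_noise_sd=0.0, loading_offset_sd=0.0)))
        b = ddct_expression(gen_ct_table(CtDesign(
            effect_logfc=effects, ct_noise_sd=0.0, loading_offset_sd=1.0)))
        np.testing.assert_allclose(a.values.to_numpy(),
                                   b.values.to_numpy(), rtol=1e-10)

    def test_missing_reference_gene_rejected(self):
        ct = gen_ct_table(CtDesign())
        with pytest.raises(ValueError, match="reference gene"):
            ddct_expression(ct[ct["gene"] != "ACTB"])

    def test_sample_without_reference_dropped_with_warning(self):
        ct = gen_ct_table(CtDesign())
        drop = (ct["sample"] == "LPS_1") & (ct["gene"] == "ACTB")
        with pytest.warns(UserWarning, match="LPS_1"):
            em = ddct_expression(ct[~drop])
        assert "LPS_1" not in em.values.columns


class TestNormalization:
    @pytest.fixture()
    def matrix(self):
        values = pd.DataFrame(
            {"CTL_1": [10.0, 4.0], "CTL_2": [14.0, 4.0],
             "LPS_1": [36.0, 2.0]},
            index=["akg", "citrate"])
        groups = pd.Series({"CTL_1": "CTL", "CTL_2": "CTL",
                            "LPS_1": "LPS"})
        return ExpressionMatrix(values=values, groups=groups)

    def test_control_mean_becomes_one(self, matrix):
        normed = normalize_to_control(matrix)
        ctl = normed.values[["CTL_1", "CTL_2"]]
        np.testing.assert_allclose(ctl.mean(axis=1), 1.0)
        assert normed.values.loc["akg", "LPS_1"] == pytest.approx(3.0)

    def test_row_scale_invariance(self, matrix):
        doubled = ExpressionMatrix(values=matrix.values * 2.0,
                                   groups=matrix.groups)
        np.testing.assert_allclose(
            normalize_to_control(matrix).values.to_numpy(),
            normalize_to_control(doubled).values.to_numpy())

    def test_zero_control_mean_rejected(self, matrix):
        matrix.values.loc["akg", ["CTL_1", "CTL_2"]] = 0.0
        with pytest.raises(ValueError, match="control mean"):
            normalize_to_control(matrix)

    def test_row_ratio(self, matrix):
        ratio = row_ratio(matrix, "akg", "citrate")
        assert ratio["LPS_1"] == pytest.approx(18.0)
        assert row_ratio(matrix, "akg", "akg").eq(1.0).all()


class TestZscoreCluster:
    @pytest.fixture()
    def matrix(self, rng):
        values = pd.DataFrame(rng.normal(5, 2, size=(6, 8)),
                              index=[f"g{i}" for i in range(6)],
                              columns=[f"s{i}" for i in range(8)])
        groups = pd.Series({f"s{i}": "CTL" if i < 4 else "LPS"
                            for i in range(8)})
        return ExpressionMatrix(values=values, groups=groups)

    def test_rows_standardized(self, matrix):
        zm, _, _ = zscore_cluster(matrix)
        np.testing.assert_allclose(zm.values.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(zm.values.std(axis=1, ddof=1), 1.0,
                                   rtol=1e-12)

    def test_constant_row_zeroed_and_flagged(self, matrix):
        matrix.values.loc["g0"] = 7.0
        zm, _, _ = zscore_cluster(matrix)
        assert (zm.values.loc["g0"] == 0.0).all()
        assert "g0" in zm.flags["constant_rows"]

    @given(a=st.floats(0.5, 3.0), b=st.floats(-5.0, 5.0))
    def test_affine_invariance_per_row(self, a, b):
        rng = np.random.default_rng(42)
        values = pd.DataFrame(rng.normal(size=(3, 5)))
        groups = pd.Series({c: "CTL" for c in values.columns})
        em1 = ExpressionMatrix(values=values, groups=groups)
        em2 = ExpressionMatrix(values=values * a + b, groups=groups)
        z1, _, _ = zscore_cluster(em1)
        z2, _, _ = zscore_cluster(em2)
        np.testing.assert_allclose(z1.values.to_numpy(),
                                   z2.values.to_numpy(), atol=1e-9)

    def test_identical_columns_merge_first_at_height_zero(self, matrix):
        from neuroenergetics.assays import _ward_d_linkage
        x = matrix.values.to_numpy().T.copy()
        x[1] = x[0]
        z = _ward_d_linkage(x)
        assert {int(z[0, 0]), int(z[0, 1])} == {0, 1}
        assert z[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_too_small_matrix_rejected(self):
        em = ExpressionMatrix(
            values=pd.DataFrame({"s1": [1.0], "s2": [2.0]}, index=["g"]),
            groups=pd.Series({"s1": "CTL", "s2": "CTL"}))
        with pytest.raises(ValueError, match=">= 2"):
            zscore_cluster(em)
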