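"""Pressure-step protocols, autoregulatory curve, deviation grading and
sensitivity analysis."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from renoreg.protocols import (ProtocolSpec, StepResult, autoregulatory_curve,
                               deviation_vs_reference, drive_map,
                               grade_deviation, radius_change_from_resistance,
                               run_pressure_step, sensitivity_analysis)

MEAN_FRAC = 0.6 + 0.4 / 3.0     # mean/systolic ratio of the clamp waveform


class TestRadiusConversion:
    @pytest.mark.parametrize("r, r_ref, expected", [
        (1234.5, 1234.5, 0.0),
        (100.0, 1600.0, 100.0),          # R/16 -> radius doubles
        (2441.40625, 1000.0, -20.0),     # 0.8**-4 = 2.4414
    ])
    def test_examples(self, r, r_ref, expected):
        assert radius_change_from_resistance(r, r_ref) \
            == pytest.approx(expected, abs=1e-4)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            radius_change_from_resistance(-1.0, 100.0)

    @given(st.floats(min_value=0.1, max_value=10.0))
    def test_round_trip_fourth_power(self, ratio):
        # a radius change of x% implies a resistance ratio of (1+x/100)**-4
        pct = radius_change_from_resistance(ratio, 1.0)
        assert (1.0 + pct / 100.0) ** -4 == pytest.approx(ratio, rel=1e-9)


class TestProtocolSpec:
    def test_needs_two_levels(self):
        with pytest.raises(ValueError):
            ProtocolSpec(levels=[100.0])

    def test_unknown_clamp_rejected(self):
        with pytest.raises(ValueError):
            ProtocolSpec(levels=[100, 148], clamp="petri-dish")


class TestPressureStep:
    def test_zero_step_yields_zero_percent_changes(self, model):
        res = run_pressure_step(model, ProtocolSpec(
            levels=[100, 100], mode="mr", hold_s=60))
        assert res.pct_rbf[0] == 0.0
        assert res.pct_rbf[1] == pytest.approx(0.0, abs=1e-3)
        assert res.pct_radius[1] == pytest.approx(0.0, abs=1e-3)
        assert res.pct_rvr[1] == pytest.approx(0.0, abs=1e-3)

    def test_uncontrolled_step_matches_ohmic_oracle(self, model, vc_pressure):
        # mode none: flow scales with the perfusion gradient of the clamp
        res = run_pressure_step(model, ProtocolSpec(
            levels=[100, 148], mode="none", hold_s=15))
        oracle = 100.0 * ((MEAN_FRAC * 148 - vc_pressure)
                          / (MEAN_FRAC * 100 - vc_pressure) - 1.0)
        assert res.pct_rbf[1] == pytest.approx(oracle, abs=1.0)
        assert res.pct_rbf[1] == pytest.approx(48.0, abs=6.0)

    def test_control_strength_ordering(self, model):
        # each added controller further buffers the flow response
        pct = {}
        for mode in ("none", "mr", "mr+tgf"):
            res = run_pressure_step(model, ProtocolSpec(
                levels=[100, 148], mode=mode, hold_s=60))
            pct[mode] = abs(res.pct_rbf[1])
        assert pct["mr+tgf"] <= pct["mr"] <= pct["none"]
        assert pct["mr"] < 0.75 * pct["none"]    # MR buffers substantially

    def test_flow_ratio_over_full_band_follows_plateau_slope(self, model):
        # 80 -> 180 with MR only: steady flow ratio approaches the
        # autoregulatory band ratio 1 + k*(p1-p0)/p0 = 1.625 corrected for
        # the clamp's mean pressure and caval offset
        res = run_pressure_step(model, ProtocolSpec(
            levels=[80, 180], mode="mr", hold_s=60))
        ratio = res.rbf_l_min[1] / res.rbf_l_min[0]
        mr = model.config.autoregulation.mr
        pvc = model.baseline_summary()["p_vc_mmhg"]
        # target-flow ratio rescaled by actual vs nominal gradients
        expected = 1.625 * ((MEAN_FRAC * 180 - pvc) / (180 - pvc)) \
            / ((MEAN_FRAC * 80 - pvc) / (80 - pvc))
        assert ratio == pytest.approx(expected, rel=0.05)

    def test_stability_across_autoregulatory_band(self, model):
        # closed-loop clamp runs settle (no growing oscillation) at the
        # band edges with both controllers active
        res = run_pressure_step(model, ProtocolSpec(
            levels=[80, 180], mode="mr+tgf", hold_s=60))
        assert all(res.converged)

    def test_clamp_and_whole_body_agree_at_matched_perfusion(self, model):
        # same achieved renal-artery pressures, mode none: the two step
        # realisations give %dRBF within 5 pp
        wb = run_pressure_step(model, ProtocolSpec(
            levels=[100, 148], mode="none", clamp="whole-body", hold_s=30))
        # recover the achieved mean AR pressures to set matched clamp levels
        traces = [drive_map(model, lv, mode="none")[0] for lv in (100, 148)]
        p_ar = [t.beat_average("P:AR", 5) for t in traces]
        clamp = run_pressure_step(model, ProtocolSpec(
            levels=[p / MEAN_FRAC for p in p_ar], mode="none", hold_s=15))
        assert clamp.pct_rbf[1] == pytest.approx(wb.pct_rbf[1], abs=5.0)

    def test_step_result_frame_shape(self, model):
        res = run_pressure_step(model, ProtocolSpec(
            levels=[100, 120], mode="mr", hold_s=10))
        frame = res.to_frame()
        assert len(frame) == 2
        assert frame.loc[0, "pct_rbf"] == 0.0


class TestAutoregulatoryCurve:
    def test_reference_and_k_calibration_points(self, model):
        curve = autoregulatory_curve(model, pressures=[80.0, 180.0])
        assert curve.pct_radius.iloc[0] == pytest.approx(0.0, abs=1e-9)
        assert curve.pct_radius.iloc[1] == pytest.approx(-20.0, abs=2.0)

    def test_radius_monotone_nonincreasing_on_band(self, model):
        curve = autoregulatory_curve(model,
                                     pressures=np.arange(80.0, 181.0, 5.0))
        dr = np.diff(curve.pct_radius.to_numpy())
        assert np.all(dr <= 1e-9)

    def test_flat_below_p0(self, model):
        curve = autoregulatory_curve(model, pressures=[60.0, 70.0, 80.0])
        assert curve.r_t_mmhg_s_per_l.nunique() == 1


class TestDeviationScoring:
    @pytest.mark.parametrize("dev, grade", [
        (0.0, "very good"), (9.9, "very good"), (15.0, "good"),
        (25.0, "fair"), (35.0, "poor")])
    def test_grade_bands(self, dev, grade):
        assert grade_deviation(dev) == grade

    def _result(self):
        return StepResult(levels=[100, 148], mode="mr",
                          rbf_l_min=[1.0, 1.25], gfr_ml_min=[149.0, 170.0],
                          r_afferent=[1500.0, 2100.0], rvr=[4700.0, 5500.0],
                          converged=[True, True])

    def test_exact_match_scores_zero_very_good(self):
        res = self._result()
        dev = deviation_vs_reference(res, {"pct_rbf": res.pct_rbf[1:]})
        assert dev.deviation_pp.iloc[0] == pytest.approx(0.0)
        assert dev.grade.iloc[0] == "very good"

    def test_mismatched_quantities_rejected(self):
        res = self._result()
        with pytest.raises(KeyError):
            deviation_vs_reference(res, {"pct_gfr": [10.0]})
        with pytest.raises(ValueError):
            deviation_vs_reference(res, {"pct_rbf": [10.0, 20.0]})


class TestSensitivity:
    def test_zero_perturbation_gives_zero_deltas(self, model):
        table, max_delta = sensitivity_analysis(
            model, "k", ProtocolSpec(levels=[100, 123], mode="mr", hold_s=15),
            perturbations=(0.0,))
        assert max_delta == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(table.delta_pp, 0.0)

    def test_unknown_parameter_rejected(self, model):
        with pytest.raises(ValueError):
            sensitivity_analysis(model, "heart_rate", ProtocolSpec(
                levels=[100, 123], mode="mr", hold_s=10))
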