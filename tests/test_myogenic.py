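"""Unit tests for the myogenic response (sensing, target curve, filter)."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from renoreg.myogenic import (MRParams, MyogenicResponse,
                              afferent_target_resistance, mr_update,
                              sensed_pressure, target_conductance)
from renoreg.waveforms import generate_waveform

DT = 1e-3


def make_params(**over) -> MRParams:
    base = dict(p0=80.0, p1=180.0, q0=0.018, k=0.5, delta1=0.3, delta2=1.2,
                tau1=4.0, tau2=5.3, gain=1.0, r_base=1500.0,
                r_gl_vr=400.0, r_gl_tu=300.0, r_tu_vr=100.0, r_vr_vc=50.0)
    base.update(over)
    return MRParams(**base)


class TestSensedPressure:
    def test_constant_history(self):
        _, y = generate_waveform("constant", 5.0, DT, value=100.0)
        assert sensed_pressure(y, DT, 0.3, 1.2) == 100.0

    def test_pulsatile_window_spanning_a_beat_returns_systolic(self):
        # 80-120 mmHg pulse at 69 bpm (period 0.87 s): the 0.3-1.2 s
        # look-back window covers a full beat, so the max is systolic
        _, y = generate_waveform("pulse", 5.0, DT, systolic=120.0,
                                 diastolic=80.0, heart_rate=69.0)
        got = sensed_pressure(y, DT, 0.3, 1.2)
        # brute-force oracle over the discretised window
        lag1, lag2 = round(0.3 / DT), round(1.2 / DT)
        oracle = np.max(y[len(y) - 1 - lag2:len(y) - lag1])
        assert got == oracle
        assert got == pytest.approx(120.0, abs=1e-3)   # discretised peak

    def test_step_first_sensed_after_delta1(self):
        # step 100 -> 150 at t0: the window max first sees 150 delta1 later
        params = make_params()
        mr = MyogenicResponse(params, DT, p_init=100.0)
        t0, onset = 2.0, None
        n = int(4.0 / DT)
        for i in range(n):
            t = i * DT
            mr.push(100.0 if t < t0 else 150.0)
            if onset is None and mr.sensed() > 100.0:
                onset = t
        assert onset == pytest.approx(t0 + params.delta1, abs=2 * DT)

    def test_insufficient_history_rejected(self):
        with pytest.raises(ValueError, match="history"):
            sensed_pressure(np.ones(100), DT, 0.3, 1.2)


class TestTargetConductance:
    def test_value_below_p0(self):
        # sub-p0 branch: q0/(p0 - P_VC)
        p = make_params()
        assert target_conductance(70.0, 0.0, p) == pytest.approx(0.018 / 80.0)

    def test_continuity_at_breakpoints(self):
        p = make_params()
        for bp in (p.p0, p.p1):
            below = target_conductance(bp - 1e-9, 5.0, p)
            at = target_conductance(bp, 5.0, p)
            above = target_conductance(bp + 1e-9, 5.0, p)
            assert below == pytest.approx(at, rel=1e-6)
            assert above == pytest.approx(at, rel=1e-6)

    def test_target_flow_identity_at_p1(self):
        # implied target flow at p1 is q0 * (1 + k*(p1-p0)/p0) = 1.625*q0
        p = make_params()
        c = target_conductance(180.0, 7.0, p)
        assert c * (180.0 - 7.0) == pytest.approx(1.625 * p.q0, rel=1e-12)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            target_conductance(5.0, 10.0, make_params())

    @given(st.floats(min_value=20.0, max_value=249.0),
           st.floats(min_value=0.0, max_value=12.0))
    def test_target_flow_nondecreasing_and_bounded(self, p_ar, p_vc):
        p = make_params()
        if p_ar <= p_vc + 1.0:
            return
        flow = target_conductance(p_ar, p_vc, p) * (p_ar - p_vc)
        flow_up = target_conductance(p_ar + 1.0, p_vc, p) * (p_ar + 1.0 - p_vc)
        assert flow_up >= flow * (1.0 - 1e-12)
        if p.p0 <= p_ar <= p.p1:   # on the plateau the flow band is [q0, 1.625*q0]
            assert p.q0 * (1.0 - 1e-9) <= flow <= 1.625 * p.q0 * (1.0 + 1e-9)


class TestAfferentTargetResistance:
    def test_hand_example(self):
        # downstream: (1/400 + 1/(300+100))^-1 = 200, series 50 -> 250
        p = make_params()
        assert afferent_target_resistance(1e-3, p) == pytest.approx(750.0)

    def test_whole_path_when_downstream_vanishes(self):
        # with a negligible post-afferent network the afferent limb is the
        # whole renal path: R_T -> c_T**-1
        p = make_params(r_gl_vr=1e-9, r_gl_tu=1e-9, r_tu_vr=1e-9, r_vr_vc=1e-12)
        assert afferent_target_resistance(1e-3, p) == pytest.approx(1000.0, rel=1e-6)

    def test_round_trip_total_resistance(self):
        # placing R_T as the afferent limb restores total = c_T**-1
        p = make_params()
        c_t = 1.0 / 1234.5
        r_t = afferent_target_resistance(c_t, p)
        total = r_t + 1.0 / (1.0 / p.r_gl_vr
                             + 1.0 / (p.r_gl_tu + p.r_tu_vr)) + p.r_vr_vc
        assert total == pytest.approx(1.0 / c_t, rel=1e-12)

    def test_floor_clamp(self, caplog):
        p = make_params()
        with caplog.at_level("WARNING", logger="renoreg"):
            r = afferent_target_resistance(1.0 / 200.0, p)   # below downstream
        assert r == pytest.approx(p.resistance_floor)
        assert "floor" in caplog.text


class TestMRUpdate:
    def test_fixed_point(self):
        p = make_params()
        dr = mr_update(100.0, p.r_base + 100.0, p.r_base + 100.0, DT, p)
        assert dr == pytest.approx(100.0)

    @pytest.mark.parametrize("dt", [2e-3, 1e-3])
    def test_exponential_relaxation(self, dt):
        p = make_params()
        target = p.r_base + 300.0          # constant constriction demand
        n = int(round(3 * p.tau1 / dt))
        dr, errs = 0.0, []
        for i in range(1, n + 1):
            dr = mr_update(dr, target, p.r_base + dr, dt, p)
            expected = 300.0 * (1.0 - np.exp(-i * dt / p.tau1))
            errs.append(abs(dr - expected))
        assert max(errs) / 300.0 < 1e-3
        self.__class__._err = getattr(self.__class__, "_err", {})
        self.__class__._err[dt] = max(errs)

    def test_error_scales_linearly_with_dt(self):
        errs = self.__class__._err
        assert errs[2e-3] / errs[1e-3] == pytest.approx(2.0, rel=0.2)

    def test_converges_within_five_tau(self):
        p = make_params()
        dr = 0.0
        for _ in range(int(5 * p.tau1 / DT)):
            dr = mr_update(dr, p.r_base + 200.0, p.r_base + dr, DT, p)
        assert abs(dr - 200.0) < 0.01 * 200.0

    def test_constriction_faster_than_dilation(self):
        # 90% response time after an upward step (tau1) is shorter than
        # after the mirrored downward step (tau2)
        p = make_params()

        def t90(start, target):
            dr, i = start, 0
            span = target - start
            while abs(dr - start) < 0.9 * abs(span):
                dr = mr_update(dr, p.r_base + target, p.r_base + dr, DT, p)
                i += 1
            return i * DT

        up = t90(0.0, 300.0)
        down = t90(300.0, 0.0)
        assert up < down
        assert up == pytest.approx(np.log(10) * p.tau1, rel=0.05)
        assert down == pytest.approx(np.log(10) * p.tau2, rel=0.05)

    def test_literal_convention_swaps_time_constants(self):
        p = make_params(tau_convention="literal")
        # upward step now uses tau2 under the literal branch reading
        dr = mr_update(0.0, p.r_base + 300.0, p.r_base, DT, p)
        assert dr == pytest.approx(DT * 300.0 / p.tau2)
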