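"""Unit tests for the compartment/connector integrator."""

import numpy as np
import pytest

from renoreg.core import (Compartment, ConfigurationError, Connector,
                          LumpedCircuit, NumericalError, TimeVaryingElastance,
                          elastic_pressure, net_volume_derivative,
                          resistive_flow)


class TestElementaryOperations:
    @pytest.mark.parametrize("e, v, v0, expected", [
        (123.0, 0.05, 0.05, 0.0),           # zero stressed volume
        (500.0, 0.10, 0.09, 5.0),           # hand arithmetic
        (100.0, 0.02, 0.05, -3.0),          # under-filled: negative allowed
    ])
    def test_elastic_pressure(self, e, v, v0, expected):
        assert elastic_pressure(e, v, v0) == pytest.approx(expected)

    def test_elastic_pressure_rejects_nonpositive_elastance(self):
        with pytest.raises(ConfigurationError):
            elastic_pressure(0.0, 0.1, 0.05)

    @pytest.mark.parametrize("p1, p2, r, valve, expected", [
        (100.0, 100.0, 50.0, False, 0.0),
        (100.0, 0.0, 50.0, False, 2.0),
        (5.0, 20.0, 50.0, True, 0.0),       # valve blocks backflow
        (5.0, 20.0, 50.0, False, -0.3),
    ])
    def test_resistive_flow(self, p1, p2, r, valve, expected):
        assert resistive_flow(p1, p2, r, valve) == pytest.approx(expected)

    def test_resistive_flow_rejects_nonpositive_resistance(self):
        with pytest.raises(ConfigurationError):
            resistive_flow(1.0, 0.0, 0.0)

    @pytest.mark.parametrize("inflows, outflows, expected", [
        ([0.02], [0.02], 0.0),
        ([0.03], [0.01, 0.01], 0.01),
    ])
    def test_net_volume_derivative(self, inflows, outflows, expected):
        assert net_volume_derivative(inflows, outflows) == pytest.approx(expected)


class TestTimeVaryingElastance:
    def test_activation_normalised_and_bounded(self):
        tve = TimeVaryingElastance(ees=3000.0, ed=60.0)
        ph = np.linspace(0, 1, 5000, endpoint=False)
        a = tve.activation(ph)
        assert np.all(a >= 0.0) and np.all(a <= 1.0 + 1e-12)
        assert a.max() == pytest.approx(1.0, abs=1e-4)
        # periodic
        assert np.allclose(tve.activation(ph), tve.activation(ph + 3.0))

    def test_elastance_between_ed_and_ees(self):
        tve = TimeVaryingElastance(ees=3000.0, ed=60.0)
        ph = np.linspace(0, 1, 2000, endpoint=False)
        e = tve.elastance(ph)
        assert e.min() >= 60.0 - 1e-9
        assert e.max() <= 3000.0 + 1e-9
        assert e.max() == pytest.approx(3000.0, rel=1e-3)

    def test_systole_diastole_pressure_ratio(self):
        # same stressed volume at peak activation vs none: P ratio = Ees/Ed
        tve = TimeVaryingElastance(ees=2000.0, ed=100.0)
        ph = np.linspace(0, 1, 5000, endpoint=False)
        e = tve.elastance(ph)
        v, v0 = 0.12, 0.04
        p_sys = e.max() * (v - v0)
        p_dia = e.min() * (v - v0)
        assert p_sys / p_dia == pytest.approx(2000.0 / 100.0, rel=1e-3)


def _rc_pair(r=500.0, e1=1000.0, e2=2000.0, dt=1e-3):
    comps = [Compartment("A", e1, 0.0, 0.10),
             Compartment("B", e2, 0.0, 0.02)]
    conns = [Connector("A_B", "A", "B", r)]
    # heart rate only sets the beat bookkeeping; use 60 bpm for a 1 s beat
    return LumpedCircuit(comps, conns, heart_rate=60.0, dt=dt)


class TestIntegrator:
    def test_single_compartment_state_unchanged(self):
        c = LumpedCircuit([Compartment("A", 1000.0, 0.01, 0.05)], [],
                          heart_rate=60.0, dt=1e-3)
        v0 = c.V.copy()
        c.step(1000)
        assert np.array_equal(c.V, v0)

    def test_rc_relaxation_matches_closed_form(self):
        # two elastic compartments through one resistance: the pressure
        # difference decays as exp(-t/tau) with tau = R/(E1+E2)
        r, e1, e2 = 500.0, 1000.0, 2000.0
        tau = r / (e1 + e2)

        def max_error(dt):
            c = _rc_pair(r, e1, e2, dt)
            trace = c.simulate(duration=5 * tau)
            dp = trace.pressures[:, 0] - trace.pressures[:, 1]
            dp0 = e1 * 0.10 - e2 * 0.02
            expected = dp0 * np.exp(-trace.time / tau)
            return np.max(np.abs(dp - expected)) / dp0

        err1 = max_error(2e-3)
        err2 = max_error(1e-3)
        assert err1 < 0.02
        # explicit Euler is first order: halving dt halves the error
        assert err1 / err2 == pytest.approx(2.0, rel=0.2)

    def test_rc_total_volume_exact(self):
        c = _rc_pair()
        total0 = c.total_volume()
        c.step(20_000)
        assert abs(c.total_volume() - total0) <= 1e-12

    @pytest.mark.filterwarnings("ignore::RuntimeWarning")
    def test_numerical_failure_names_compartment(self):
        # grossly unstable: dt far beyond the 2*tau Euler limit
        c = _rc_pair(r=0.01, e1=1e6, e2=1e6, dt=1e-3)
        with pytest.raises(NumericalError, match="A|B"):
            c.step(5000)

    def test_unknown_endpoint_rejected(self):
        with pytest.raises(ConfigurationError, match="unknown endpoint"):
            LumpedCircuit([Compartment("A", 100.0, 0.0, 0.1)],
                          [Connector("A_X", "A", "X", 10.0)],
                          heart_rate=60.0)


class TestFullModel:
    def test_volume_conserved_over_10s(self, model):
        circuit, _ = model.build_circuit(mode="mr+tgf")
        trace = circuit.simulate(duration=10.0)
        tv = trace.total_volume()
        assert np.max(np.abs(tv - tv[0])) <= 1e-6

    def test_valve_flows_nonnegative(self, model):
        circuit, _ = model.build_circuit(mode="none")
        trace = circuit.simulate(duration=5.0)
        for name in ("LA_LV", "LV_AA", "RA_RV", "RV_PA"):
            assert np.all(trace.signal(f"q:{name}") >= 0.0)

    def test_steady_state_flags_and_periodicity(self, model):
        trace, info = model.run_to_steady_state(mode="none")
        assert info["converged"]
        spb = trace.steps_per_beat
        last, prev = trace.pressures[-spb:], trace.pressures[-2 * spb:-spb]
        scale = np.maximum(np.abs(prev), 1.0)
        assert np.max(np.abs(last - prev) / scale) < 1e-3

    def test_one_beat_cannot_converge(self, model):
        _, info = model.run_to_steady_state(mode="none", max_beats=1)
        assert not info["converged"]

    def test_cardiac_output_equals_stroke_volume_times_rate(self, model):
        trace, _ = model.run_to_steady_state(mode="none")
        co = trace.beat_average("q:LV_AA", 5) * 60.0          # L/min
        lv = trace.signal("V:LV")[-5 * trace.steps_per_beat:]
        sv = (lv.max() - lv.min())                             # L/beat
        assert co == pytest.approx(sv * trace.heart_rate, rel=5e-3)


class TestBeatAverage:
    def test_constant_signal(self, model):
        trace = model.simulate(2.0, mode="none")
        trace.pressures[:, 0] = 7.5
        assert trace.beat_average("P:PV", 2) == pytest.approx(7.5)

    def test_sinusoid_at_heart_frequency_averages_to_zero(self, model):
        trace = model.simulate(3.0, mode="none")
        spb = trace.steps_per_beat
        n = len(trace)
        trace.pressures[:, 0] = np.sin(2 * np.pi * np.arange(n) / spb)
        assert abs(trace.beat_average("P:PV", 3)) < 1e-10

    def test_window_longer_than_trace_rejected(self, model):
        trace = model.simulate(1.0, mode="none")
        with pytest.raises(ValueError, match="longer than"):
            trace.beat_average("P:AA", 50)
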