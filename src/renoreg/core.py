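"""Fixed-step integrator for lumped compartment/connector circulations.

The circulation is a network of elastic *compartments* (nodes holding
volume) joined by volumeless resistive *connectors* (edges), integrated
with an explicit Euler scheme at a fixed step.  The constitutive laws are

    P(t)   = E(t) * (V(t) - V0)          elastic compartment pressure
    q(t)   = (P_src - P_tgt) / R         connector flow (>= 0 for valves)
    dV/dt  = sum(q_in) - sum(q_out)      volume balance

Heart chambers use a periodic time-varying elastance E(t) built from a
double-Hill activation waveform.  Controllers (renal autoregulation) are
attached as per-step hooks that may rewrite connector resistances; the new
resistance takes effect on the following step.

Units: mmHg, L, s throughout (resistance mmHg*s/L, elastance mmHg/L,
flow L/s).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TimeVaryingElastance",
    "Compartment",
    "Connector",
    "PressureBoundary",
    "SimulationTrace",
    "LumpedCircuit",
    "NumericalError",
    "ConfigurationError",
    "elastic_pressure",
    "resistive_flow",
    "net_volume_derivative",
]


class ConfigurationError(ValueError):
    """Invalid model definition (bad resistance, dangling endpoint, ...)."""


class NumericalError(RuntimeError):
    """Non-finite state encountered during integration."""


# ---------------------------------------------------------------------------
# elementary operations (scalar forms of the model equations)
# ---------------------------------------------------------------------------

def elastic_pressure(elastance: float, volume: float, unstressed_volume: float) -> float:
    """Pressure of an elastic compartment, E*(V - V0).

    May be negative when V < V0, signalling an under-filled compartment;
    no collapse model is applied.
    """
    if elastance <= 0:
        raise ConfigurationError(f"elastance must be positive, got {elastance}")
    return elastance * (volume - unstressed_volume)


def resistive_flow(p_source: float, p_target: float, resistance: float,
                   valve: bool = False) -> float:
    """Flow through a resistive connector, (P1 - P2)/R.

    A valve has infinite backward resistance: flow is exactly zero whenever
    the gradient would drive it backwards.
    """
    if resistance <= 0:
        raise ConfigurationError(f"resistance must be positive, got {resistance}")
    q = (p_source - p_target) / resistance
    if valve and q < 0.0:
        return 0.0
    return q


def net_volume_derivative(inflows: Sequence[float], outflows: Sequence[float]) -> float:
    """dV/dt of a compartment: total inflow minus total outflow."""
    return float(sum(inflows) - sum(outflows))


# ---------------------------------------------------------------------------
# model elements
# ---------------------------------------------------------------------------

@dataclass
class TimeVaryingElastance:
    """Periodic chamber elastance E(t) = Ed + a(t)*(Ees - Ed).

    The activation a(t) is a double-Hill pulse normalised to peak 1,
    parameterised by rise/decay time fractions of the cycle and Hill
    exponents; ``offset_frac`` shifts the pulse within the cycle (used to
    place atrial contraction late in the cycle).
    """

    ees: float                      # end-systolic elastance, mmHg/L
    ed: float                       # end-diastolic elastance, mmHg/L
    rise_frac: float = 0.269        # rise time constant / cycle period
    decay_frac: float = 0.452       # decay time constant / cycle period
    m1: float = 1.32                # rise Hill exponent
    m2: float = 21.9                # decay Hill exponent
    offset_frac: float = 0.0        # activation onset shift / cycle period

    def __post_init__(self) -> None:
        if self.ees <= 0 or self.ed <= 0:
            raise ConfigurationError("elastances must be positive")
        if self.ees < self.ed:
            raise ConfigurationError("end-systolic elastance below end-diastolic")

    def _raw(self, ph: np.ndarray) -> np.ndarray:
        g1 = (ph / self.rise_frac) ** self.m1
        g2 = (ph / self.decay_frac) ** self.m2
        return (g1 / (1.0 + g1)) * (1.0 / (1.0 + g2))

    @property
    def _peak(self) -> float:
        # normalisation constant over a fine grid, cached on first use
        if not hasattr(self, "_peak_cache"):
            fine = np.linspace(0.0, 1.0, 200_001)
            object.__setattr__(self, "_peak_cache", float(np.max(self._raw(fine))))
        return self._peak_cache

    def activation(self, phase: np.ndarray) -> np.ndarray:
        """Normalised activation a in [0, 1] for cycle phase in [0, 1)."""
        ph = np.mod(np.asarray(phase, dtype=float) - self.offset_frac, 1.0)
        return np.minimum(self._raw(ph) / self._peak, 1.0)

    def elastance(self, phase: np.ndarray) -> np.ndarray:
        return self.ed + self.activation(phase) * (self.ees - self.ed)


@dataclass
class Compartment:
    """Elastic volume-holding node."""

    name: str
    elastance: float | TimeVaryingElastance
    unstressed_volume: float        # L
    volume: float                   # starting volume, L

    def __post_init__(self) -> None:
        if self.volume < 0 or self.unstressed_volume < 0:
            raise ConfigurationError(f"{self.name}: volumes must be non-negative")
        if isinstance(self.elastance, (int, float)) and self.elastance <= 0:
            raise ConfigurationError(f"{self.name}: elastance must be positive")


@dataclass
class PressureBoundary:
    """Node with a prescribed periodic pressure waveform.

    Used by the renal perfusion clamp: the node supplies/absorbs whatever
    volume the flows require, so global conservation holds only for fully
    elastic (closed-loop) circuits.  ``waveform`` maps cycle phase in
    [0, 1) to pressure in mmHg; a float prescribes a constant pressure.
    """

    name: str
    waveform: float | Callable[[np.ndarray], np.ndarray]

    def pressure(self, phase: np.ndarray) -> np.ndarray:
        if callable(self.waveform):
            return np.asarray(self.waveform(phase), dtype=float)
        return np.full_like(np.asarray(phase, dtype=float), float(self.waveform))


@dataclass
class Connector:
    """Volumeless resistive edge, optionally a one-way valve."""

    name: str
    source: str
    target: str
    resistance: float               # mmHg*s/L
    valve: bool = False

    def __post_init__(self) -> None:
        if self.resistance <= 0:
            raise ConfigurationError(
                f"connector {self.name}: resistance must be positive, "
                f"got {self.resistance}")


# ---------------------------------------------------------------------------
# simulation trace
# ---------------------------------------------------------------------------

@dataclass
class SimulationTrace:
    """Time-indexed record of compartment pressures/volumes and flows."""

    time: np.ndarray                # s, shape (n,)
    pressures: np.ndarray           # mmHg, shape (n, n_comp)
    volumes: np.ndarray             # L, shape (n, n_comp)
    flows: np.ndarray               # L/s, shape (n, n_conn)
    compartments: list[str]
    connectors: list[str]
    heart_rate: float               # bpm
    dt: float                       # s
    steps_per_beat: int

    def __len__(self) -> int:
        return len(self.time)

    def signal(self, name: str) -> np.ndarray:
        """Return a recorded signal: 'P:LV', 'V:LV' or 'q:LV_AA'."""
        kind, _, label = name.partition(":")
        if kind == "P":
            return self.pressures[:, self.compartments.index(label)]
        if kind == "V":
            return self.volumes[:, self.compartments.index(label)]
        if kind == "q":
            return self.flows[:, self.connectors.index(label)]
        raise KeyError(f"unknown signal {name!r}; use 'P:NAME', 'V:NAME' or 'q:NAME'")

    def beat_average(self, name: str, window_beats: int = 5) -> float:
        """Time-average of a signal over the final integer cardiac cycles."""
        y = self.signal(name)
        n = window_beats * self.steps_per_beat
        if n > len(y):
            raise ValueError(
                f"window of {window_beats} beats ({n} samples) longer than "
                f"trace ({len(y)} samples)")
        return float(np.mean(y[-n:]))

    def total_volume(self) -> np.ndarray:
        return self.volumes.sum(axis=1)

    def to_wide_frame(self) -> pd.DataFrame:
        data: dict[str, np.ndarray] = {"time_s": self.time}
        for j, c in enumerate(self.compartments):
            data[f"P:{c}"] = self.pressures[:, j]
        for j, c in enumerate(self.compartments):
            data[f"V:{c}"] = self.volumes[:, j]
        for j, c in enumerate(self.connectors):
            data[f"q:{c}"] = self.flows[:, j]
        return pd.DataFrame(data)

    def to_tidy_frame(self) -> pd.DataFrame:
        wide = self.to_wide_frame()
        tidy = wide.melt(id_vars="time_s", var_name="variable", value_name="value")
        units = {"P": "mmHg", "V": "L", "q": "L/s"}
        tidy["units"] = tidy["variable"].str.partition(":")[0].map(units)
        return tidy

    def plot(self, signals: Sequence[str], ax=None):
        """Quick line plot of selected signals (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for s in signals:
            ax.plot(self.time, self.signal(s), label=s)
        ax.set_xlabel("time (s)")
        ax.legend()
        return ax


# ---------------------------------------------------------------------------
# circuit
# ---------------------------------------------------------------------------

# hook signature: hook(step_index, time, pressures, flows) -> None
Hook = Callable[[int, float, np.ndarray, np.ndarray], None]


class LumpedCircuit:
    """Executable compartment/connector network with explicit Euler stepping.

    The cycle period is snapped to an integer number of solver steps so
    that beats align exactly with the time grid (the effective heart rate
    differs from the nominal one by < 0.1% at dt = 1 ms).
    """

    def __init__(self,
                 compartments: Sequence[Compartment | PressureBoundary],
                 connectors: Sequence[Connector],
                 heart_rate: float,
                 dt: float = 1e-3):
        if dt <= 0:
            raise ConfigurationError("dt must be positive")
        if heart_rate <= 0:
            raise ConfigurationError("heart rate must be positive")
        names = [c.name for c in compartments]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate compartment names")
        self.comp_names: list[str] = names
        self.conn_names: list[str] = [c.name for c in connectors]
        self.compartments = list(compartments)
        self.connectors = list(connectors)
        self.heart_rate = float(heart_rate)

        period = 60.0 / heart_rate
        self.steps_per_beat = max(1, round(period / dt))
        self.dt = period / self.steps_per_beat

        n = len(compartments)
        idx = {c.name: i for i, c in enumerate(compartments)}
        for conn in connectors:
            for end in (conn.source, conn.target):
                if end not in idx:
                    raise ConfigurationError(
                        f"connector {conn.name}: unknown endpoint {end!r}")

        self._src = np.array([idx[c.source] for c in connectors], dtype=np.intp)
        self._tgt = np.array([idx[c.target] for c in connectors], dtype=np.intp)
        self._valve = np.array([c.valve for c in connectors], dtype=bool)
        self.R = np.array([c.resistance for c in connectors], dtype=float)
        self._invR = 1.0 / self.R

        # incidence matrix: dV = M @ q
        self._M = np.zeros((n, len(connectors)))
        for j in range(len(connectors)):
            self._M[self._src[j], j] -= 1.0
            self._M[self._tgt[j], j] += 1.0

        self.V0 = np.zeros(n)
        self.V = np.zeros(n)
        self._boundary = np.zeros(n, dtype=bool)
        for i, c in enumerate(compartments):
            if isinstance(c, PressureBoundary):
                self._boundary[i] = True
            else:
                self.V0[i] = c.unstressed_volume
                self.V[i] = c.volume
        self._elastic = ~self._boundary

        self._build_phase_tables()
        self._step_index = 0
        self.hooks: list[Hook] = []

    # -- tables -------------------------------------------------------------

    def _build_phase_tables(self) -> None:
        """Precompute per-phase elastance and boundary-pressure tables."""
        spb = self.steps_per_beat
        phase = np.arange(spb) / spb
        n = len(self.compartments)
        self._E = np.zeros((spb, n))
        self._Pbound = np.zeros((spb, n))
        for i, c in enumerate(self.compartments):
            if isinstance(c, PressureBoundary):
                self._Pbound[:, i] = c.pressure(phase)
            elif isinstance(c.elastance, TimeVaryingElastance):
                self._E[:, i] = c.elastance.elastance(phase)
            else:
                self._E[:, i] = float(c.elastance)

    def set_boundary_waveform(self, name: str,
                              waveform: float | Callable[[np.ndarray], np.ndarray]) -> None:
        """Replace the prescribed waveform of a boundary node mid-run."""
        i = self.comp_names.index(name)
        if not self._boundary[i]:
            raise ConfigurationError(f"{name} is not a pressure boundary")
        node = self.compartments[i]
        assert isinstance(node, PressureBoundary)
        node.waveform = waveform
        phase = np.arange(self.steps_per_beat) / self.steps_per_beat
        self._Pbound[:, i] = node.pressure(phase)

    def set_resistance(self, name: str, value: float) -> None:
        if value <= 0:
            raise ConfigurationError(
                f"connector {name}: resistance must be positive, got {value}")
        j = self.conn_names.index(name)
        self.R[j] = value
        self._invR[j] = 1.0 / value

    # -- state --------------------------------------------------------------

    @property
    def time(self) -> float:
        return self._step_index * self.dt

    def pressures(self) -> np.ndarray:
        ph = self._step_index % self.steps_per_beat
        P = self._E[ph] * (self.V - self.V0)
        P[self._boundary] = self._Pbound[ph][self._boundary]
        return P

    def flows(self, P: np.ndarray | None = None) -> np.ndarray:
        if P is None:
            P = self.pressures()
        q = (P[self._src] - P[self._tgt]) * self._invR
        np.clip(q, 0.0, None, out=q, where=self._valve)
        return q

    def total_volume(self) -> float:
        return float(self.V[self._elastic].sum())

    def _check_finite(self) -> None:
        if not np.all(np.isfinite(self.V)):
            bad = [self.comp_names[i] for i in np.flatnonzero(~np.isfinite(self.V))]
            raise NumericalError(
                f"non-finite volume in compartment(s) {', '.join(bad)} "
                f"at t = {self.time:.3f} s")

    # -- integration ----------------------------------------------------------

    def add_hook(self, hook: Hook) -> None:
        self.hooks.append(hook)

    def step(self, n_steps: int = 1,
             record: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, int] | None = None,
             accumulate: tuple[np.ndarray, np.ndarray] | None = None) -> None:
        """Advance ``n_steps`` explicit Euler steps.

        ``record``: optional (time, P, V, q, offset) output buffers.
        ``accumulate``: optional (P_sum, q_sum) running-sum buffers used by
        the beat-convergence loop (cheaper than full recording).
        """
        dt = self.dt
        spb = self.steps_per_beat
        V, V0 = self.V, self.V0
        E_tab, Pb_tab = self._E, self._Pbound
        src, tgt, invR, valve = self._src, self._tgt, self._invR, self._valve
        boundary, elastic, M = self._boundary, self._elastic, self._M
        hooks = self.hooks
        i0 = self._step_index

        for s in range(n_steps):
            i = i0 + s
            ph = i % spb
            P = E_tab[ph] * (V - V0)
            P[boundary] = Pb_tab[ph][boundary]
            q = (P[src] - P[tgt]) * invR
            np.clip(q, 0.0, None, out=q, where=valve)
            dV = M @ q
            V[elastic] += dt * dV[elastic]
            for hook in hooks:
                hook(i, i * dt, P, q)
            if record is not None:
                t_out, p_out, v_out, q_out, off = record
                t_out[off + s] = i * dt
                p_out[off + s] = P
                v_out[off + s] = V
                q_out[off + s] = q
            if accumulate is not None:
                np.add(accumulate[0], P, out=accumulate[0])
                np.add(accumulate[1], q, out=accumulate[1])

        self._step_index = i0 + n_steps
        self._check_finite()

    def simulate(self, duration: float | None = None,
                 n_beats: int | None = None) -> SimulationTrace:
        """Integrate and record every step over a duration or beat count."""
        if (duration is None) == (n_beats is None):
            raise ValueError("specify exactly one of duration or n_beats")
        if n_beats is not None:
            n = n_beats * self.steps_per_beat
        else:
            n = int(round(duration / self.dt))
        t = np.empty(n)
        P = np.empty((n, len(self.comp_names)))
        V = np.empty((n, len(self.comp_names)))
        q = np.empty((n, len(self.conn_names)))
        self.step(n, record=(t, P, V, q, 0))
        return SimulationTrace(t, P, V, q, list(self.comp_names),
                               list(self.conn_names), self.heart_rate,
                               self.dt, self.steps_per_beat)

    def run_to_steady_state(self, max_beats: int = 200,
                            rtol: float = 1e-3,
                            consecutive: int = 3,
                            record_beats: int = 5,
                            min_beats: int = 5) -> tuple[SimulationTrace, dict]:
        """Integrate beat by beat until beat-averaged pressures and flows
        settle (relative change < ``rtol`` for ``consecutive`` beats), then
        record a final window of ``record_beats`` full beats.

        Returns (trace, info); ``info['converged']`` is False if
        ``max_beats`` was exhausted first.
        """
        spb = self.steps_per_beat
        nC, nQ = len(self.comp_names), len(self.conn_names)
        prev = None
        ok_run = 0
        converged = False
        beats_done = 0
        for b in range(max_beats):
            acc = (np.zeros(nC), np.zeros(nQ))
            self.step(spb, accumulate=acc)
            beats_done = b + 1
            mean = np.concatenate(acc) / spb
            if prev is not None:
                scale = np.maximum(np.abs(prev),
                                   np.concatenate([np.full(nC, 1.0),     # 1 mmHg floor
                                                   np.full(nQ, 1e-4)]))  # 0.1 ml/s floor
                rel = np.max(np.abs(mean - prev) / scale)
                ok_run = ok_run + 1 if rel < rtol else 0
                if ok_run >= consecutive and beats_done >= min_beats:
                    converged = True
                    break
            prev = mean
        trace = self.simulate(n_beats=record_beats)
        return trace, {"converged": converged, "beats": beats_done + record_beats}
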