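"""Validation protocols: pressure steps, autoregulatory curves, deviation
scoring and one-at-a-time sensitivity analysis.

The central experiment mirrors the isolated-kidney preparations the
renal controllers were validated against: a *renal perfusion clamp*
drives the renal arterial compartment with a prescribed pulsatile
pressure whose systolic value steps between protocol levels, while the
kidney (GL, TU, VR and the controlled afferent arteriole) responds
dynamically and the caval outlet is held at its baseline pressure.
A *whole-body* variant instead loads the closed-loop model with stressed
volume until the mean arterial pressure reaches each level.

Reported per level: beat-averaged renal blood flow, GFR, afferent
resistance, renal vascular resistance, and percent changes versus the
first level (afferent radius changes via R ~ r**-4).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .circulation import GestationalCirculation
from .controller import AutoregulationController, ControllerMode
from .core import LumpedCircuit, PressureBoundary, SimulationTrace
from .myogenic import afferent_target_resistance, target_conductance
from .tgf import TGFParams
from .waveforms import pulse_waveform

log = logging.getLogger("renoreg")

__all__ = ["ProtocolSpec", "StepResult", "radius_change_from_resistance",
           "run_pressure_step", "autoregulatory_curve",
           "deviation_vs_reference", "grade_deviation",
           "sensitivity_analysis", "drive_map"]

SECONDS_PER_MINUTE = 60.0
RENAL_COMPARTMENTS = ["GL", "TU", "VR"]
RENAL_CONNECTORS = ["AR_GL", "GL_VR", "GL_TU", "TU_VR", "VR_VC"]


def radius_change_from_resistance(r: float, r_ref: float) -> float:
    """Percent change in vessel radius implied by a resistance change.

    Poiseuille resistance scales with radius to the inverse fourth power,
    so r/r_ref -> 100 * ((R/R_ref)**(-1/4) - 1).
    """
    if r <= 0 or r_ref <= 0:
        raise ValueError("resistances must be positive")
    return 100.0 * ((r / r_ref) ** -0.25 - 1.0)


@dataclass
class ProtocolSpec:
    """Declarative description of a perfusion-pressure step experiment."""

    levels: Sequence[float]                 # mmHg (systolic for the clamp,
                                            # MAP for whole-body)
    mode: str = "mr"                        # none | mr | mr+tgf
    hold_s: float = 120.0                   # simulated hold per level
    clamp: str = "renal"                    # renal | whole-body
    pulse_fraction: float = 0.4             # clamp pulse pressure / systolic
    record_beats: int = 5

    def __post_init__(self) -> None:
        if len(self.levels) < 2:
            raise ValueError("a step protocol needs at least two levels")
        if self.hold_s <= 0:
            raise ValueError("hold duration must be positive")
        if self.clamp not in ("renal", "whole-body"):
            raise ValueError(f"unknown clamp type {self.clamp!r}")
        ControllerMode.from_string(self.mode)   # validates


@dataclass
class StepResult:
    """Beat-averaged outputs of a pressure-step protocol, per level."""

    levels: list[float]
    mode: str
    rbf_l_min: list[float]
    gfr_ml_min: list[float]
    r_afferent: list[float]                 # mmHg*s/L
    rvr: list[float]                        # AR -> VC total, mmHg*s/L
    converged: list[bool]
    pct_rbf: list[float] = field(default_factory=list)
    pct_radius: list[float] = field(default_factory=list)
    pct_rvr: list[float] = field(default_factory=list)
    pct_rvr_afferent: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.pct_rbf:
            self.pct_rbf = [100.0 * (x / self.rbf_l_min[0] - 1.0)
                            for x in self.rbf_l_min]
            self.pct_radius = [radius_change_from_resistance(
                r, self.r_afferent[0]) for r in self.r_afferent]
            self.pct_rvr = [100.0 * (x / self.rvr[0] - 1.0) for x in self.rvr]
            self.pct_rvr_afferent = [100.0 * (x / self.r_afferent[0] - 1.0)
                                     for x in self.r_afferent]

    def outputs(self) -> dict[str, list[float]]:
        """The reported percent-change outputs (levels beyond the first)."""
        return {"pct_rbf": self.pct_rbf[1:],
                "pct_radius": self.pct_radius[1:],
                "pct_rvr": self.pct_rvr[1:]}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "level_mmhg": self.levels, "mode": self.mode,
            "rbf_l_min": self.rbf_l_min, "gfr_ml_min": self.gfr_ml_min,
            "r_afferent_mmhg_s_per_l": self.r_afferent,
            "rvr_mmhg_s_per_l": self.rvr, "converged": self.converged,
            "pct_rbf": self.pct_rbf, "pct_radius": self.pct_radius,
            "pct_rvr": self.pct_rvr,
            "pct_rvr_afferent": self.pct_rvr_afferent,
        })


# ---------------------------------------------------------------------------
# renal perfusion clamp
# ---------------------------------------------------------------------------

def build_clamp_circuit(model: GestationalCirculation, level: float,
                        vc_pressure: float, mode: str,
                        pulse_fraction: float = 0.4
                        ) -> tuple[LumpedCircuit, Optional[AutoregulationController]]:
    """Isolated renal submodel driven by a prescribed AR pressure.

    The renal-artery compartment becomes a pulsatile pressure boundary
    (systolic = ``level``, diastolic = (1 - pulse_fraction) * level) and
    the caval vein a constant-pressure sink; GL, TU and VR stay elastic.
    """
    cfg = model.config
    comps: list = [PressureBoundary(
        "AR", pulse_waveform(level, (1.0 - pulse_fraction) * level))]
    for name in RENAL_COMPARTMENTS:
        comps.append(cfg.compartment(name).build())
    comps.append(PressureBoundary("VC", vc_pressure))
    conns = [cfg.connector(n).build() for n in RENAL_CONNECTORS]
    circuit = LumpedCircuit(comps, conns, cfg.heart_rate_bpm, cfg.dt_s)
    cmode = ControllerMode.from_string(mode)
    controller = None
    if cmode.mr_active or cmode.tgf_active:
        controller = AutoregulationController(
            circuit, cmode, model.mr_params(),
            TGFParams.from_config(cfg.autoregulation.tgf))
    return circuit, controller


def _measure_level(circuit: LumpedCircuit, record_beats: int,
                   afferent: str = "AR_GL", inlet: str = "AR",
                   rbf_connector: str = "AR_GL") -> dict:
    """Record ``record_beats`` beats and reduce them to level metrics."""
    j_aff = circuit.conn_names.index(afferent)
    r_samples: list[float] = []
    capture = lambda i, t, P, q: r_samples.append(circuit.R[j_aff])
    circuit.add_hook(capture)
    trace = circuit.simulate(n_beats=record_beats)
    circuit.hooks.remove(capture)

    ba = lambda s: trace.beat_average(s, record_beats)
    rbf = ba(f"q:{rbf_connector}")
    p_in = ba(f"P:{inlet}")
    p_out = ba("P:VC")
    # convergence: compare first vs last recorded beat
    spb = circuit.steps_per_beat
    q = trace.signal(f"q:{rbf_connector}")
    b_first = float(np.mean(q[:spb]))
    b_last = float(np.mean(q[-spb:]))
    converged = abs(b_last - b_first) <= 1e-3 * max(abs(b_first), 1e-4)
    return {
        "rbf_l_min": rbf * SECONDS_PER_MINUTE,
        "gfr_ml_min": ba("q:GL_TU") * SECONDS_PER_MINUTE * 1000.0,
        "r_afferent": float(np.mean(r_samples)),
        "rvr": (p_in - p_out) / rbf,
        "converged": converged,
        "trace": trace,
    }


def run_pressure_step(model: GestationalCirculation, protocol: ProtocolSpec,
                      vc_pressure: float | None = None) -> StepResult:
    """Execute a pressure-step protocol and report per-level metrics.

    For the renal clamp the controller state carries over between levels
    (as in the source preparations, where each step starts from the
    previous hold); for the whole-body variant each level is an
    independent volume-driven steady state.
    """
    cmode = ControllerMode.from_string(protocol.mode)
    if cmode.tgf_active:
        tgf = model.config.autoregulation.tgf
        needed = 5.0 * max(tgf.tau3_s, tgf.tau4_s) + tgf.delta3_s
        if protocol.hold_s < needed:
            log.info("hold %.0f s is below 5*tau+delta3 = %.0f s; residual "
                     "TGF drift will be small but nonzero", protocol.hold_s,
                     needed)

    if protocol.clamp == "whole-body":
        return _run_whole_body_step(model, protocol)

    if vc_pressure is None:
        vc_pressure = model.baseline_summary()["p_vc_mmhg"]
    circuit, _ = build_clamp_circuit(model, protocol.levels[0], vc_pressure,
                                     protocol.mode, protocol.pulse_fraction)
    hold_steps = int(round(protocol.hold_s / circuit.dt))
    rows = []
    for level in protocol.levels:
        circuit.set_boundary_waveform(
            "AR", pulse_waveform(level,
                                 (1.0 - protocol.pulse_fraction) * level))
        circuit.step(hold_steps)
        rows.append(_measure_level(circuit, protocol.record_beats))
    return StepResult(
        levels=list(protocol.levels), mode=protocol.mode,
        rbf_l_min=[r["rbf_l_min"] for r in rows],
        gfr_ml_min=[r["gfr_ml_min"] for r in rows],
        r_afferent=[r["r_afferent"] for r in rows],
        rvr=[r["rvr"] for r in rows],
        converged=[r["converged"] for r in rows])


# ---------------------------------------------------------------------------
# whole-body drive
# ---------------------------------------------------------------------------

def drive_map(model: GestationalCirculation, map_target: float,
              mode: str = "none", rtol: float = 2e-5,
              max_beats: int = 500, ytol: float = 0.08
              ) -> tuple[SimulationTrace, dict]:
    """Scale stressed volume (via VC) until beat-averaged MAP hits target.

    Returns the steady-state trace at the solved volume and an info dict
    with the volume increment and achieved MAP.
    """
    from .circulation import _solve_scalar

    cfg = model.config.model_copy(deep=True)
    vc = cfg.compartment("VC")
    warm: dict = {"V": None}
    last: dict = {}

    def map_of_volume(v: float) -> float:
        vc.volume_l = v
        m = GestationalCirculation(cfg)
        circuit, _ = m.build_circuit(mode=mode)
        if warm["V"] is not None:
            V = warm["V"].copy()
            vc_idx = circuit.comp_names.index("VC")
            V[vc_idx] += circuit.V.sum() - V.sum()
            if V[vc_idx] > 0:
                circuit.V[:] = V
        trace, info = circuit.run_to_steady_state(max_beats=max_beats,
                                                  rtol=rtol)
        warm["V"] = circuit.V.copy()
        last["trace"], last["info"], last["circuit"] = trace, info, circuit
        return trace.beat_average("P:AA", 3)

    v0 = vc.volume_l
    # bracket guess from total systemic conductance: dMAP/dV is of order
    # 40-80 mmHg/L for these compliances
    v1 = v0 + (map_target - map_of_volume(v0)) / 60.0
    _solve_scalar(lambda v: map_of_volume(v) - map_target, v0, v1,
                  ytol=ytol, lo=0.05, hi=v0 + 6.0, max_iter=15)
    info = {"vc_volume_l": vc.volume_l, "dv_l": vc.volume_l - v0,
            "achieved_map": last["trace"].beat_average("P:AA", 3),
            "converged": last["info"]["converged"],
            "beats": last["info"]["beats"]}
    return last["trace"], info


def _run_whole_body_step(model: GestationalCirculation,
                         protocol: ProtocolSpec) -> StepResult:
    rows = []
    for level in protocol.levels:
        trace, info = drive_map(model, level, mode=protocol.mode)
        ba = lambda s: trace.beat_average(s, protocol.record_beats)
        rbf = ba("q:AD_AR")
        # effective beat-averaged afferent resistance from the pressure drop
        r_aff = (ba("P:AR") - ba("P:GL")) / ba("q:AR_GL")
        rows.append({
            "rbf_l_min": rbf * SECONDS_PER_MINUTE,
            "gfr_ml_min": ba("q:GL_TU") * SECONDS_PER_MINUTE * 1000.0,
            "r_afferent": r_aff,
            "rvr": (ba("P:AR") - ba("P:VC")) / rbf,
            "converged": info["converged"],
        })
    return StepResult(
        levels=list(protocol.levels), mode=protocol.mode,
        rbf_l_min=[r["rbf_l_min"] for r in rows],
        gfr_ml_min=[r["gfr_ml_min"] for r in rows],
        r_afferent=[r["r_afferent"] for r in rows],
        rvr=[r["rvr"] for r in rows],
        converged=[r["converged"] for r in rows])


# ---------------------------------------------------------------------------
# autoregulatory curve
# ---------------------------------------------------------------------------

def autoregulatory_curve(model: GestationalCirculation,
                         pressures: Sequence[float] | None = None,
                         vc_pressure: float | None = None,
                         reference_pressure: float = 80.0) -> pd.DataFrame:
    """Steady-state myogenic curve over a renal-pressure grid.

    Evaluates the target conductance/resistance closed forms at each
    (steady, non-pulsatile) sensed pressure and converts the afferent
    resistance to a percent radius change relative to the maximally
    dilated reference (0% at 80 mmHg by convention).
    """
    if pressures is None:
        pressures = np.arange(60.0, 201.0, 5.0)
    if vc_pressure is None:
        vc_pressure = model.baseline_summary()["p_vc_mmhg"]
    mr = model.mr_params()
    r_ref = afferent_target_resistance(
        target_conductance(reference_pressure, vc_pressure, mr), mr)
    rows = []
    for p in pressures:
        c_t = target_conductance(float(p), vc_pressure, mr)
        r_t = afferent_target_resistance(c_t, mr)
        rows.append({
            "p_ar_mmhg": float(p),
            "c_t_l_per_s_mmhg": c_t,
            "r_t_mmhg_s_per_l": r_t,
            "rbf_l_min": c_t * (p - vc_pressure) * SECONDS_PER_MINUTE,
            "pct_radius": radius_change_from_resistance(r_t, r_ref),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# deviation scoring
# ---------------------------------------------------------------------------

def grade_deviation(deviation_pp: float) -> str:
    """Grade an absolute deviation in percentage points.

    Bands: < 10 very good, 10-20 good, 20-30 fair, > 30 poor.
    """
    d = abs(deviation_pp)
    if d < 10.0:
        return "very good"
    if d <= 20.0:
        return "good"
    if d <= 30.0:
        return "fair"
    return "poor"


def deviation_vs_reference(result: StepResult,
                           reference: dict[str, Sequence[float]]
                           ) -> pd.DataFrame:
    """Score the protocol's percent-change outputs against user-supplied
    reference values (e.g. digitised animal observations).

    ``reference`` maps output names ('pct_rbf', 'pct_radius', 'pct_rvr')
    to per-level values for the levels beyond the first.
    """
    outputs = result.outputs()
    rows = []
    for name, ref_vals in reference.items():
        if name not in outputs:
            raise KeyError(f"unknown output {name!r}; "
                           f"expected one of {sorted(outputs)}")
        model_vals = outputs[name]
        if len(ref_vals) != len(model_vals):
            raise ValueError(
                f"{name}: reference has {len(ref_vals)} values for "
                f"{len(model_vals)} step levels")
        for lvl, mv, rv in zip(result.levels[1:], model_vals, ref_vals):
            dev = abs(mv - rv)
            rows.append({"quantity": name, "level_mmhg": lvl,
                         "model_pct": mv, "reference_pct": rv,
                         "deviation_pp": dev, "grade": grade_deviation(dev)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# sensitivity analysis
# ---------------------------------------------------------------------------

_SENSITIVITY_PARAMS = {"k", "g_tgf"}


def _perturbed_model(model: GestationalCirculation, parameter: str,
                     factor: float) -> GestationalCirculation:
    cfg = model.config.model_copy(deep=True)
    if parameter == "k":
        cfg.autoregulation.mr.k *= factor
    elif parameter == "g_tgf":
        cfg.autoregulation.tgf.gain_mmhg_s_per_l_per_l_min *= factor
    else:
        raise ValueError(f"unknown sensitivity parameter {parameter!r}; "
                         f"use one of {sorted(_SENSITIVITY_PARAMS)}")
    return GestationalCirculation(cfg)


def sensitivity_analysis(model: GestationalCirculation, parameter: str,
                         protocol: ProtocolSpec,
                         perturbations: Sequence[float] = (-0.2, -0.1, 0.1, 0.2),
                         ) -> tuple[pd.DataFrame, float]:
    """One-at-a-time sensitivity of the protocol's percent-change outputs.

    Re-runs ``protocol`` with ``parameter`` scaled by (1 + p) for each
    perturbation p and reports, per output and level, the change versus
    the unperturbed run.  Returns (table, max |delta|).
    """
    vc_pressure = (model.baseline_summary()["p_vc_mmhg"]
                   if protocol.clamp == "renal" else None)
    base = run_pressure_step(model, protocol, vc_pressure=vc_pressure)
    base_out = base.outputs()
    rows = []
    max_delta = 0.0
    for pert in perturbations:
        pm = _perturbed_model(model, parameter, 1.0 + pert)
        res = run_pressure_step(pm, protocol, vc_pressure=vc_pressure)
        for name, vals in res.outputs().items():
            for lvl, v, v0 in zip(res.levels[1:], vals, base_out[name]):
                delta = v - v0
                max_delta = max(max_delta, abs(delta))
                rows.append({"parameter": parameter, "perturbation": pert,
                             "output": name, "level_mmhg": lvl,
                             "value_pct": v, "baseline_pct": v0,
                             "delta_pp": delta})
    return pd.DataFrame(rows), max_delta
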