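"""First-trimester gestational circulation: topology, baseline design and
calibration.

The circulation has 19 compartments — a four-chamber heart with
time-varying elastances, a pulmonary loop (PA, PV), the systemic arteries
(AA, AD), upper/lower body beds (UB, LB), a lumped single-nephron kidney
(AR -> GL -> {efferent || filtrate} -> VR) and a four-compartment uterine
circuit (UA, SA, PL, UV) — closed through the caval vein (VC).

Because the source parameter tables are defined by their hemodynamic
*targets* rather than fixed values, this module regenerates the parameter
set: ``design_baseline`` lays out a physiologically reasoned starting
point in closed form and ``GestationalCirculation.fit`` runs the staged
calibration (systemic -> renal -> operating-point quiescence -> refine)
until the targets are met:

    heart rate 69 bpm, cardiac output 5.8 L/min, mean arterial pressure
    ~82.5 mmHg, renal blood flow 1.0 L/min, GFR 0.149 L/min.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .config import (AutoregulationConfig, CalibrationTargetsConfig,
                     CompartmentConfig, ConnectorConfig, ElastanceProfile,
                     ModelConfig, load_config)
from .controller import AutoregulationController, ControllerMode
from .core import ConfigurationError, LumpedCircuit, SimulationTrace
from .myogenic import MRParams, sensed_pressure, target_conductance
from .tgf import TGFParams

log = logging.getLogger("renoreg")

__all__ = ["COMPARTMENTS", "CONNECTORS", "RENAL_RESISTANCES",
           "SYSTEMIC_BED_RESISTANCES", "design_baseline",
           "GestationalCirculation", "CalibrationResults",
           "hemodynamic_summary"]

# Figure-1 topology ----------------------------------------------------------

COMPARTMENTS = ["PV", "LA", "LV", "AA", "AD", "UB", "LB", "AR", "GL", "TU",
                "VR", "UA", "SA", "PL", "UV", "VC", "RA", "RV", "PA"]

# (name, source, target, valve)
CONNECTORS = [
    ("PV_LA", "PV", "LA", False),
    ("LA_LV", "LA", "LV", True),      # mitral valve
    ("LV_AA", "LV", "AA", True),      # aortic valve
    ("AA_AD", "AA", "AD", False),
    ("AA_UB", "AA", "UB", False),
    ("AD_LB", "AD", "LB", False),
    ("AD_AR", "AD", "AR", False),
    ("AR_GL", "AR", "GL", False),     # afferent arteriole (controlled)
    ("GL_VR", "GL", "VR", False),     # efferent arteriole
    ("GL_TU", "GL", "TU", False),     # glomerular filtration (GFR)
    ("TU_VR", "TU", "VR", False),
    ("VR_VC", "VR", "VC", False),
    ("AD_UA", "AD", "UA", False),
    ("UA_SA", "UA", "SA", False),
    ("SA_PL", "SA", "PL", False),
    ("PL_UV", "PL", "UV", False),
    ("UV_VC", "UV", "VC", False),
    ("UB_VC", "UB", "VC", False),
    ("LB_VC", "LB", "VC", False),
    ("VC_RA", "VC", "RA", False),
    ("RA_RV", "RA", "RV", True),      # tricuspid valve
    ("RV_PA", "RV", "PA", True),      # pulmonary valve
    ("PA_PV", "PA", "PV", False),
]

RENAL_RESISTANCES = ["AD_AR", "AR_GL", "GL_VR", "GL_TU", "TU_VR", "VR_VC"]
SYSTEMIC_BED_RESISTANCES = ["AA_UB", "AD_LB", "UB_VC", "LB_VC"]
HEART_VALVES = ["LA_LV", "LV_AA", "RA_RV", "RV_PA"]

SECONDS_PER_MINUTE = 60.0


# ---------------------------------------------------------------------------
# baseline design
# ---------------------------------------------------------------------------

def _renal_design(p_ad: float, p_vc: float, p_ar: float, p_vr: float,
                  p_tu: float, rbf_l_min: float, gfr_l_min: float,
                  q0: float = 0.018, k: float = 0.5,
                  p0: float = 80.0, p1: float = 180.0,
                  dilated_radius_drop: float = 0.20) -> dict[str, float]:
    """Closed-form renal resistance split.

    The post-afferent lumped resistance is pinned by the maximal-dilation
    anchor: with the myogenic curve at k, the afferent target resistance
    at a sensed pressure of p1 must sit ``dilated_radius_drop`` below the
    maximally dilated (p0) radius via R ~ r**-4.  The remaining drop is
    distributed over the individual connectors using the target renal
    compartment pressures.
    """
    rbf = rbf_l_min / SECONDS_PER_MINUTE
    gfr = gfr_l_min / SECONDS_PER_MINUTE
    cinv_lo = (p0 - p_vc) / q0
    cinv_hi = (p1 - p_vc) / (q0 * (1.0 + k * (p1 - p0) / p0))
    rho = (1.0 - dilated_radius_drop) ** -4
    r_down = (cinv_hi - rho * cinv_lo) / (1.0 - rho)
    if r_down <= 0:
        raise ConfigurationError("renal design infeasible: negative "
                                 "downstream resistance")

    r_vr_vc = (p_vr - p_vc) / rbf
    r_parallel = r_down - r_vr_vc
    p_gl = p_vr + r_parallel * rbf
    r_gl_vr = (p_gl - p_vr) / (rbf - gfr)
    r_gl_tu = (p_gl - p_tu) / gfr
    r_tu_vr = (p_tu - p_vr) / gfr
    r_total = (p_ad - p_vc) / rbf
    r_ad_ar = (p_ad - p_ar) / rbf
    r_ar_gl = r_total - r_down - r_ad_ar
    if min(r_ar_gl, r_gl_vr, r_gl_tu, r_tu_vr, r_vr_vc, r_ad_ar) <= 0:
        raise ConfigurationError("renal design infeasible: non-positive "
                                 "resistance in split")
    return {"AD_AR": r_ad_ar, "AR_GL": r_ar_gl, "GL_VR": r_gl_vr,
            "GL_TU": r_gl_tu, "TU_VR": r_tu_vr, "VR_VC": r_vr_vc}


def design_baseline(heart_rate: float = 69.0, dt: float = 1e-3) -> ModelConfig:
    """Construct the shipped pre-calibration parameter set in closed form.

    Mean-pressure and flow targets (mmHg, L/min) for an 8-week pregnant
    condition are laid out per compartment; resistances follow from Ohm's
    law, elastances from typical compliances, and starting volumes put
    every compartment at its design pressure.  ``fit`` then trims the
    free parameters until the simulated targets are met.
    """
    # design mean pressures, mmHg
    P = {"AA": 82.5, "AD": 82.2, "UB": 40.0, "LB": 40.0,
         "AR": 78.0, "GL": 53.6, "TU": 14.0, "VR": 7.0,
         "UA": 70.0, "SA": 40.0, "PL": 15.0, "UV": 6.0,
         "VC": 3.8, "PA": 15.0, "PV": 8.0,
         "LA": 6.5, "RA": 3.2, "LV": 8.0, "RV": 4.0}
    # design branch flows, L/min
    q_ub, q_lb, q_ut, q_renal, co = 2.2, 2.5, 0.1, 1.0, 5.8
    gfr = 0.149

    def R(dp: float, q_l_min: float) -> float:
        return dp / (q_l_min / SECONDS_PER_MINUTE)

    resist = {
        "PV_LA": R(P["PV"] - P["LA"], co),
        "LA_LV": 12.0, "LV_AA": 12.0,
        "AA_AD": R(P["AA"] - P["AD"], co - q_ub),
        "AA_UB": R(P["AA"] - P["UB"], q_ub),
        "UB_VC": R(P["UB"] - P["VC"], q_ub),
        "AD_LB": R(P["AD"] - P["LB"], q_lb),
        "LB_VC": R(P["LB"] - P["VC"], q_lb),
        "AD_UA": R(P["AD"] - P["UA"], q_ut),
        "UA_SA": R(P["UA"] - P["SA"], q_ut),
        "SA_PL": R(P["SA"] - P["PL"], q_ut),
        "PL_UV": R(P["PL"] - P["UV"], q_ut),
        "UV_VC": R(P["UV"] - P["VC"], q_ut),
        "VC_RA": 6.0, "RA_RV": 10.0, "RV_PA": 10.0,
        "PA_PV": R(P["PA"] - P["PV"], co),
    }
    resist.update(_renal_design(p_ad=P["AD"], p_vc=P["VC"], p_ar=P["AR"],
                                p_vr=P["VR"], p_tu=P["TU"],
                                rbf_l_min=q_renal, gfr_l_min=gfr))

    # vascular elastances, mmHg/L (inverse compliances)
    E = {"AA": 1667.0, "AD": 1000.0, "UB": 50.0, "LB": 50.0,
         "AR": 10000.0, "GL": 20000.0, "TU": 20000.0, "VR": 5000.0,
         "UA": 20000.0, "SA": 20000.0, "PL": 3333.0, "UV": 5000.0,
         "VC": 8.0, "PA": 250.0, "PV": 125.0}
    V0 = {"AA": 0.05, "AD": 0.12, "UB": 0.40, "LB": 0.40,
          "AR": 0.015, "GL": 0.01, "TU": 0.01, "VR": 0.05,
          "UA": 0.01, "SA": 0.01, "PL": 0.15, "UV": 0.05,
          "VC": 1.80, "PA": 0.08, "PV": 0.30,
          "LA": 0.03, "LV": 0.04, "RA": 0.03, "RV": 0.04}

    # heart chambers: double-Hill time-varying elastance; atrial activation
    # is placed late in the cycle (offset 0.75) so atrial systole precedes
    # ventricular ejection
    ventricle_shape = dict(rise_frac=0.269, decay_frac=0.452, m1=1.32, m2=21.9,
                           offset_frac=0.0)
    atrium_shape = dict(rise_frac=0.11, decay_frac=0.18, m1=1.9, m2=13.0,
                        offset_frac=0.75)
    heart = {
        "LV": ElastanceProfile(ees_mmhg_per_l=3000.0, ed_mmhg_per_l=60.0,
                               **ventricle_shape),
        "RV": ElastanceProfile(ees_mmhg_per_l=600.0, ed_mmhg_per_l=35.0,
                               **ventricle_shape),
        "LA": ElastanceProfile(ees_mmhg_per_l=300.0, ed_mmhg_per_l=150.0,
                               **atrium_shape),
        "RA": ElastanceProfile(ees_mmhg_per_l=150.0, ed_mmhg_per_l=80.0,
                               **atrium_shape),
    }

    comps = []
    for name in COMPARTMENTS:
        if name in heart:
            prof = heart[name]
            vol = V0[name] + P[name] / prof.ed_mmhg_per_l
            comps.append(CompartmentConfig(
                name=name, elastance_profile=prof,
                unstressed_volume_l=V0[name], volume_l=round(vol, 6)))
        else:
            vol = V0[name] + P[name] / E[name]
            comps.append(CompartmentConfig(
                name=name, elastance_mmhg_per_l=E[name],
                unstressed_volume_l=V0[name], volume_l=round(vol, 6)))

    conns = [ConnectorConfig(name=n, source=s, target=t,
                             resistance_mmhg_s_per_l=round(resist[n], 4),
                             valve=v)
             for n, s, t, v in CONNECTORS]

    return ModelConfig(
        heart_rate_bpm=heart_rate, dt_s=dt,
        compartments=comps, connectors=conns,
        autoregulation=AutoregulationConfig(mode="mr+tgf"),
        calibration=CalibrationTargetsConfig())


# ---------------------------------------------------------------------------
# measurements
# ---------------------------------------------------------------------------

def hemodynamic_summary(trace: SimulationTrace, window_beats: int = 5) -> dict:
    """Beat-averaged headline quantities from a steady-state trace."""
    ba = lambda s: trace.beat_average(s, window_beats)
    co = ba("q:LV_AA") * SECONDS_PER_MINUTE
    out = {
        "map_mmhg": ba("P:AA"),
        "p_ad_mmhg": ba("P:AD"),
        "co_l_min": co,
        "sv_ml": co / trace.heart_rate * 1000.0,
        "rbf_l_min": ba("q:AD_AR") * SECONDS_PER_MINUTE,
        "gfr_l_min": ba("q:GL_TU") * SECONDS_PER_MINUTE,
        "p_vc_mmhg": ba("P:VC"),
        "p_ar_mmhg": ba("P:AR"),
        "p_gl_mmhg": ba("P:GL"),
        "p_tu_mmhg": ba("P:TU"),
        "p_vr_mmhg": ba("P:VR"),
    }
    return out


def _solve_scalar(f, x0: float, x1: float, ytol: float,
                  max_iter: int = 12, lo: float | None = None,
                  hi: float | None = None) -> tuple[float, float]:
    """Secant iteration for smooth monotone 1-D calibration maps.

    Returns (x, f(x)) with |f(x)| <= ytol or after max_iter evaluations.
    """
    y0 = f(x0)
    if abs(y0) <= ytol:
        return x0, y0
    y1 = f(x1)
    for _ in range(max_iter):
        if abs(y1) <= ytol:
            return x1, y1
        if y1 == y0:
            break
        x2 = x1 - y1 * (x1 - x0) / (y1 - y0)
        if lo is not None:
            x2 = max(lo, x2)
        if hi is not None:
            x2 = min(hi, x2)
        x0, y0, x1, y1 = x1, y1, x2, f(x2)
    log.warning("scalar solve stopped at residual %.4g (tol %.4g)", y1, ytol)
    return x1, y1


# ---------------------------------------------------------------------------
# model object
# ---------------------------------------------------------------------------

class GestationalCirculation:
    """Closed-loop first-trimester circulation model.

    Parameters
    ----------
    config : ModelConfig
        Validated model definition (compartments, connectors, heart rate,
        autoregulation block, calibration targets).

    Typical use::

        model = GestationalCirculation.from_packaged("baseline")
        res = model.fit()          # staged calibration to the targets
        print(res.summary())
        trace, info = res.model.run_to_steady_state()
    """

    def __init__(self, config: ModelConfig):
        self.config = config
        self.validate_topology()
        self._baseline_cache: dict | None = None

    # constructors ---------------------------------------------------------

    @classmethod
    def from_file(cls, path) -> "GestationalCirculation":
        return cls(load_config(path))

    @classmethod
    def from_packaged(cls, name: str = "calibrated") -> "GestationalCirculation":
        from .config import packaged_config
        return cls(packaged_config(name))

    @classmethod
    def from_design(cls, heart_rate: float = 69.0) -> "GestationalCirculation":
        return cls(design_baseline(heart_rate=heart_rate))

    # validation -----------------------------------------------------------

    def validate_topology(self) -> None:
        cfg = self.config
        names = {c.name for c in cfg.compartments}
        missing = set(COMPARTMENTS) - names
        if missing:
            raise ConfigurationError(
                f"missing compartment(s): {', '.join(sorted(missing))}")
        conn_names = {c.name for c in cfg.connectors}
        missing_conn = {n for n, *_ in CONNECTORS} - conn_names
        if missing_conn:
            raise ConfigurationError(
                f"missing connector(s): {', '.join(sorted(missing_conn))}")
        for n, s, t, v in CONNECTORS:
            c = cfg.connector(n)
            if (c.source, c.target) != (s, t):
                raise ConfigurationError(
                    f"connector {n} must join {s} -> {t}")
            if v and not c.valve:
                raise ConfigurationError(f"connector {n} must be a valve")
        # closed loop: every compartment reachable following flow direction
        adj: dict[str, list[str]] = {n: [] for n in names}
        for c in cfg.connectors:
            adj[c.source].append(c.target)
        seen = set()
        stack = ["LV"]
        while stack:
            n = stack.pop()
            if n in seen:
                continue
            seen.add(n)
            stack.extend(adj[n])
        unreachable = names - seen
        if unreachable:
            raise ConfigurationError(
                f"compartment(s) unreachable from LV: "
                f"{', '.join(sorted(unreachable))}")

    # circuit construction ---------------------------------------------------

    def build_circuit(self, mode: str | None = None,
                      dt: float | None = None
                      ) -> tuple[LumpedCircuit, Optional[AutoregulationController]]:
        """Instantiate the executable circuit, optionally with controllers.

        ``mode`` overrides the config's autoregulation mode.
        """
        cfg = self.config
        comps = [c.build() for c in cfg.compartments]
        conns = [c.build() for c in cfg.connectors]
        circuit = LumpedCircuit(comps, conns, cfg.heart_rate_bpm,
                                dt or cfg.dt_s)
        mode_str = mode if mode is not None else cfg.autoregulation.mode
        cmode = ControllerMode.from_string(mode_str)
        controller = None
        if cmode.mr_active or cmode.tgf_active:
            controller = AutoregulationController(
                circuit, cmode,
                self.mr_params(), TGFParams.from_config(cfg.autoregulation.tgf))
        return circuit, controller

    def mr_params(self) -> MRParams:
        cfg = self.config
        return MRParams.from_config(
            cfg.autoregulation.mr,
            r_base=cfg.resistance("AR_GL"),
            r_gl_vr=cfg.resistance("GL_VR"),
            r_gl_tu=cfg.resistance("GL_TU"),
            r_tu_vr=cfg.resistance("TU_VR"),
            r_vr_vc=cfg.resistance("VR_VC"))

    # simulation -------------------------------------------------------------

    def simulate(self, duration: float, mode: str | None = None) -> SimulationTrace:
        circuit, _ = self.build_circuit(mode=mode)
        return circuit.simulate(duration=duration)

    def run_to_steady_state(self, mode: str | None = None, max_beats: int = 200,
                            **kw) -> tuple[SimulationTrace, dict]:
        circuit, _ = self.build_circuit(mode=mode)
        return circuit.run_to_steady_state(max_beats=max_beats, **kw)

    def baseline_summary(self, refresh: bool = False) -> dict:
        """Cached steady-state summary of the uncontrolled model."""
        if self._baseline_cache is None or refresh:
            trace, info = self.run_to_steady_state(mode="none")
            s = hemodynamic_summary(trace)
            s["converged"] = info["converged"]
            self._baseline_cache = s
        return self._baseline_cache

    # calibration -----------------------------------------------------------

    def fit(self, targets: CalibrationTargetsConfig | None = None,
            refine: int = 1, quiescence: bool = True,
            max_beats: int = 500, rtol: float = 2e-5) -> "CalibrationResults":
        """Run the staged calibration and return the results object.

        Stages: (A) systemic — stressed volume sets the mean arterial
        pressure, the four body-bed resistances (scaled jointly) set the
        cardiac output; (B) renal — all six renal resistances scaled at
        fixed ratios for renal blood flow, then the filtration resistance
        GL_TU alone for GFR; (C) operating-point quiescence — the
        renal-artery compartment elastance is tuned so the myogenic target
        resistance at the sensed (systolic) pressure equals the calibrated
        afferent resistance (dR_MR = 0 at baseline); plus ``refine``
        repeat passes.  The model's config is left calibrated in place.
        """
        cfg = self.config
        tg = targets or cfg.calibration
        history: list[dict] = []
        steady = self._steady_evaluator(max_beats, rtol)

        for cycle in range(refine + 1):
            self._calibrate_systemic(cfg, tg, steady, history)
            self._calibrate_renal(cfg, tg, steady, history)
            if quiescence:
                # inside the loop: the renal-artery elastance it adjusts
                # feeds back (weakly) on CO/MAP via pulse rectification, so
                # the next cycle re-trims the systemic side
                self._tune_quiescence(cfg, steady, history)

        final = steady(cfg)
        trace = final.pop("_trace")
        warm = final.pop("_warm")
        # freeze the converged volume distribution into the config so any
        # fresh run starts at (periodic) steady state
        for i, name in enumerate(c.name for c in cfg.compartments):
            cfg.compartment(name).volume_l = float(warm["V"][i])
        achieved = {
            "map_mmhg": final["map_mmhg"],
            "co_l_min": final["co_l_min"],
            "sv_ml": final["sv_ml"],
            "rbf_l_min": final["rbf_l_min"],
            "gfr_l_min": final["gfr_l_min"],
        }
        wanted = {
            "map_mmhg": tg.map_mmhg,
            "co_l_min": tg.co_l_min,
            "sv_ml": tg.co_l_min / cfg.heart_rate_bpm * 1000.0,
            "rbf_l_min": tg.rbf_l_min,
            "gfr_l_min": tg.gfr_l_min,
        }
        self._baseline_cache = None
        return CalibrationResults(model=self, targets=wanted,
                                  achieved=achieved, history=history,
                                  steady_info=final, trace=trace)

    def _steady_evaluator(self, max_beats: int = 500, rtol: float = 2e-5):
        """Steady-state summary evaluator with volume warm-starting.

        Successive evaluations start from the previous converged volume
        distribution (shifted through VC so the config's total volume is
        honoured): the slowest transient is whole-body volume
        redistribution, so this cuts each evaluation from hundreds of
        beats to a few dozen.
        """
        warm: dict = {"V": None}

        def steady(c: ModelConfig) -> dict:
            m = GestationalCirculation(c)
            circuit, _ = m.build_circuit(mode="none")
            if warm["V"] is not None:
                V = warm["V"].copy()
                vc_idx = circuit.comp_names.index("VC")
                V[vc_idx] += circuit.V.sum() - V.sum()
                if V[vc_idx] > 0:
                    circuit.V[:] = V
            trace, info = circuit.run_to_steady_state(max_beats=max_beats,
                                                      rtol=rtol)
            warm["V"] = circuit.V.copy()      # state at a beat boundary
            s = hemodynamic_summary(trace)
            s["converged"] = info["converged"]
            s["_trace"] = trace
            s["_warm"] = warm
            return s

        return steady

    def calibrate_systemic(self, targets: CalibrationTargetsConfig | None = None
                           ) -> "GestationalCirculation":
        """Run only the systemic stage (CO and MAP) on this model's config."""
        history: list[dict] = []
        self._calibrate_systemic(self.config, targets or self.config.calibration,
                                 self._steady_evaluator(), history)
        self._baseline_cache = None
        return self

    def calibrate_renal_branch(self, targets: CalibrationTargetsConfig | None = None
                               ) -> "GestationalCirculation":
        """Run only the renal stage (split, RBF, GFR) on this model's config."""
        history: list[dict] = []
        self._calibrate_renal(self.config, targets or self.config.calibration,
                              self._steady_evaluator(), history)
        self._baseline_cache = None
        return self

    # -- stage A: systemic ----------------------------------------------------

    def _calibrate_systemic(self, cfg, tg, steady, history) -> None:
        # nested solve: for each joint scale of the four body-bed
        # resistances, the stressed volume is first re-solved so the mean
        # arterial pressure sits on target, then the cardiac output at
        # that pressure is reported.  This decouples the two knobs (CO is
        # (MAP - CVP)/SVR, so at fixed MAP it responds monotonically to
        # the bed scale).
        vc = cfg.compartment("VC")
        base_r = {n: cfg.resistance(n) for n in SYSTEMIC_BED_RESISTANCES}

        def map_of_volume(v: float) -> float:
            vc.volume_l = v
            return steady(cfg)["map_mmhg"]

        def solve_map() -> None:
            v0 = vc.volume_l
            _solve_scalar(lambda x: map_of_volume(x) - tg.map_mmhg,
                          v0, v0 + 0.05, ytol=0.08,
                          lo=max(0.1, v0 - 1.5), hi=v0 + 2.5)

        def co_at_map(s: float) -> float:
            for name in SYSTEMIC_BED_RESISTANCES:
                cfg.set_resistance(name, base_r[name] * s)
            solve_map()
            return steady(cfg)["co_l_min"]

        s, res = _solve_scalar(lambda x: co_at_map(x) - tg.co_l_min,
                               1.0, 1.06, ytol=0.01, lo=0.2, hi=5.0)
        history.append({"stage": "systemic", "bed_scale": s,
                        "vc_volume_l": vc.volume_l, "co_residual": res})

    # -- stage B: renal ---------------------------------------------------------

    def _calibrate_renal(self, cfg, tg, steady, history) -> None:
        # re-derive the renal split from the *measured* perfusion and caval
        # pressures so the maximal-dilation anchor (0% radius change at p0,
        # -20% at p1) stays exact at the achieved operating point; relative
        # pressure offsets within the kidney are kept from the design
        s = steady(cfg)
        p_ad, p_vc = s["p_ad_mmhg"], s["p_vc_mmhg"]
        mr = cfg.autoregulation.mr
        try:
            split = _renal_design(
                p_ad=p_ad, p_vc=p_vc, p_ar=p_ad - 4.2,
                p_vr=p_vc + 3.2, p_tu=p_vc + 10.2,
                rbf_l_min=tg.rbf_l_min, gfr_l_min=tg.gfr_l_min,
                q0=mr.q0_l_per_s, k=mr.k, p0=mr.p0_mmhg, p1=mr.p1_mmhg)
            shift = max(abs(r / cfg.resistance(n) - 1.0)
                        for n, r in split.items())
            if shift > 3e-3:     # keep calibration idempotent: skip no-ops
                for name, r in split.items():
                    cfg.set_resistance(name, r)
            history.append({"stage": "renal/split", "p_ad": p_ad,
                            "p_vc": p_vc, "applied": shift > 3e-3, **split})
        except ConfigurationError as exc:
            log.warning("renal re-split skipped (%s); keeping prior split", exc)

        for _ in range(2):
            base_r = {n: cfg.resistance(n) for n in RENAL_RESISTANCES}

            def rbf_of_scale(s: float) -> float:
                for name in RENAL_RESISTANCES:
                    cfg.set_resistance(name, base_r[name] * s)
                return steady(cfg)["rbf_l_min"]

            s, res = _solve_scalar(lambda x: rbf_of_scale(x) - tg.rbf_l_min,
                                   1.0, 1.05, ytol=0.002, lo=0.2, hi=5.0)
            history.append({"stage": "renal/rbf", "scale": s, "residual": res})

            r_gl_tu0 = cfg.resistance("GL_TU")

            def gfr_of_r(r: float) -> float:
                cfg.set_resistance("GL_TU", r)
                return steady(cfg)["gfr_l_min"]

            r, res = _solve_scalar(lambda x: gfr_of_r(x) - tg.gfr_l_min,
                                   r_gl_tu0, r_gl_tu0 * 1.05, ytol=5e-4,
                                   lo=r_gl_tu0 * 0.2, hi=r_gl_tu0 * 5.0)
            history.append({"stage": "renal/gfr", "r_gl_tu": r,
                            "residual": res})
            if abs(res) <= 5e-4 and abs(s - 1.0) < 0.02:
                break

    # -- stage C: myogenic quiescence at the operating point ----------------

    def _quiescence_residual(self, summary_trace: SimulationTrace) -> float:
        """R_T(sensed systolic AR pressure) minus the baseline afferent
        resistance; zero means dR_MR = 0 at the operating point."""
        mr = self.mr_params()
        p_ar = summary_trace.signal("P:AR")
        p_vc = summary_trace.beat_average("P:VC", 3)
        sensed = sensed_pressure(p_ar, summary_trace.dt, mr.delta1, mr.delta2)
        cinv = 1.0 / target_conductance(sensed, p_vc, mr)
        r_total = self.config.resistance("AR_GL") + mr.downstream_resistance
        return cinv - r_total

    def _tune_quiescence(self, cfg, steady, history) -> None:
        ar = cfg.compartment("AR")

        def residual(e: float) -> float:
            ar.elastance_mmhg_per_l = e
            s = steady(cfg)
            return self._quiescence_residual(s["_trace"])

        e0 = ar.elastance_mmhg_per_l
        e, res = _solve_scalar(residual, e0, e0 * 1.4, ytol=3.0,
                               lo=1500.0, hi=3e5)
        history.append({"stage": "quiescence/e_ar", "e_ar": e,
                        "residual_mmhg_s_per_l": res})


# ---------------------------------------------------------------------------
# results object
# ---------------------------------------------------------------------------

@dataclass
class CalibrationResults:
    """Outcome of ``GestationalCirculation.fit``.

    Carries the calibrated model, target/achieved values and the stage
    history; ``summary()`` renders the calibration report.
    """

    model: GestationalCirculation
    targets: dict[str, float]
    achieved: dict[str, float]
    history: list[dict] = field(default_factory=list)
    steady_info: dict = field(default_factory=dict)
    trace: SimulationTrace | None = None

    @property
    def config(self) -> ModelConfig:
        return self.model.config

    @property
    def relative_errors(self) -> dict[str, float]:
        return {k: (self.achieved[k] - v) / v for k, v in self.targets.items()}

    @property
    def converged(self) -> bool:
        ok = bool(self.steady_info.get("converged", False))
        return ok and all(abs(e) < 0.02 for e in self.relative_errors.values())

    def report_frame(self) -> pd.DataFrame:
        rows = [{"quantity": k, "target": self.targets[k],
                 "achieved": self.achieved[k],
                 "relative_error": self.relative_errors[k]}
                for k in self.targets]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = ["Gestational circulation calibration",
                 "=" * 51,
                 f"{'quantity':<12}{'target':>12}{'achieved':>12}{'rel.err':>10}",
                 "-" * 51]
        for k in self.targets:
            lines.append(f"{k:<12}{self.targets[k]:>12.4g}"
                         f"{self.achieved[k]:>12.4g}"
                         f"{self.relative_errors[k]:>10.2%}")
        lines.append("-" * 51)
        lines.append(f"converged: {self.converged}")
        return "\n".join(lines)
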