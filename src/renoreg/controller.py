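"""Combination of the myogenic and TGF outputs into the afferent resistance.

Each solver step the controller pushes the current renal-artery pressure
and GFR into the delay buffers, advances both first-order filters, and
writes the combined afferent resistance

    R_AR_GL = R_base + g_MR * dR_MR + g_TGF * dR_TGF      (floored)

into the circuit for the *next* step (explicit one-step lag, O(dt)).
Controller activation modes reproduce the three study arms: no control,
myogenic response only ("TGF independent"), and both mechanisms intact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .core import LumpedCircuit
from .myogenic import MyogenicResponse, MRParams
from .tgf import TGFParams, TubuloglomerularFeedback

log = logging.getLogger("renoreg")

__all__ = ["ControllerMode", "combined_resistance", "AutoregulationController"]


@dataclass(frozen=True)
class ControllerMode:
    mr_active: bool
    tgf_active: bool

    @classmethod
    def from_string(cls, mode: str) -> "ControllerMode":
        table = {"none": (False, False), "mr": (True, False),
                 "mr+tgf": (True, True)}
        try:
            return cls(*table[mode])
        except KeyError:
            raise ValueError(f"unknown mode {mode!r}; use none|mr|mr+tgf") from None

    def __str__(self) -> str:
        return {(False, False): "none", (True, False): "mr",
                (True, True): "mr+tgf", (False, True): "tgf"}[
                    (self.mr_active, self.tgf_active)]


def combined_resistance(r_base: float, dr_mr: float, dr_tgf: float,
                        g_mr: float, g_tgf: float, mode: ControllerMode,
                        floor_frac: float = 0.05) -> float:
    """Afferent resistance from the two controller increments, floored.

    ``dr_tgf`` is the pre-gain TGF state (L/min of GFR deviation);
    ``dr_mr`` is already in mmHg*s/L.
    """
    r = r_base
    if mode.mr_active:
        r += g_mr * dr_mr
    if mode.tgf_active:
        r += g_tgf * dr_tgf
    floor = floor_frac * r_base
    if r < floor:
        log.warning("combined afferent resistance %.3g below floor %.3g; "
                    "clamping", r, floor)
        return floor
    return r


class AutoregulationController:
    """Per-step hook wiring the MR and TGF filters to a circuit.

    Signals: renal-artery pressure (compartment AR), instantaneous caval
    pressure (VC), GFR as the GL -> TU connector flow.  Actuator: the
    AR_GL connector resistance.  Delay buffers are filled every step even
    when a mechanism is inactive, so toggling one on mid-run sees the
    true (delayed) history; the resistance is only written when at least
    one mechanism is active, which keeps mode 'none' bit-identical to the
    uncontrolled model.
    """

    def __init__(self, circuit: LumpedCircuit, mode: ControllerMode,
                 mr_params: MRParams, tgf_params: TGFParams,
                 ar: str = "AR", vc: str = "VC",
                 afferent: str = "AR_GL", gfr_connector: str = "GL_TU"):
        self.circuit = circuit
        self.mode = mode
        self._i_ar = circuit.comp_names.index(ar)
        self._i_vc = circuit.comp_names.index(vc)
        self._j_aff = circuit.conn_names.index(afferent)
        self._j_gfr = circuit.conn_names.index(gfr_connector)

        p0 = circuit.pressures()
        q0 = circuit.flows(p0)
        self.mr = MyogenicResponse(mr_params, circuit.dt, p0[self._i_ar])
        self.tgf = TubuloglomerularFeedback(tgf_params, circuit.dt,
                                            q0[self._j_gfr])
        self.r_base = mr_params.r_base
        self.floor_frac = mr_params.floor_frac
        circuit.add_hook(self)

    # hook interface ---------------------------------------------------------

    def __call__(self, i: int, t: float, P, q) -> None:
        self.mr.push(P[self._i_ar])
        self.tgf.push(q[self._j_gfr])
        mode = self.mode
        if mode.mr_active:
            self.mr.update(P[self._i_vc], self.circuit.R[self._j_aff])
        if mode.tgf_active:
            self.tgf.update()
        if mode.mr_active or mode.tgf_active:
            r = combined_resistance(self.r_base, self.mr.dr_mr,
                                    self.tgf.dr_tgf, self.mr.params.gain,
                                    self.tgf.params.gain, mode,
                                    self.floor_frac)
            self.circuit.R[self._j_aff] = r
            self.circuit._invR[self._j_aff] = 1.0 / r

    # conveniences -------------------------------------------------------

    @property
    def afferent_resistance(self) -> float:
        return float(self.circuit.R[self._j_aff])
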