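"""Myogenic response: pressure-driven control of afferent arteriolar tone.

The myogenic mechanism senses the systolic (windowed-maximum) pressure in
the renal artery compartment and adjusts the afferent arteriolar
resistance so that renal flow follows a shallow autoregulatory curve
instead of the steep Ohmic line:

* sensed pressure   P_AR = max P(tau) over tau in [t - d2, t - d1]
* target conductance c_T: piecewise in P_AR with plateau slope set by k
  between the autoregulatory limits p0 and p1, referenced to the caval
  pressure so the gradient over the kidney drives the target flow
* target afferent resistance R_T: the total renal target resistance
  c_T**-1 minus the fixed post-afferent network (efferent in parallel
  with the filtrate path, plus the renal-venous outflow)
* first-order relaxation of the resistance increment dR_MR toward
  R_T - R_base, with separate constriction/dilation time constants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .config import MRConfig

log = logging.getLogger("renoreg")

__all__ = ["MRParams", "sensed_pressure", "target_conductance",
           "afferent_target_resistance", "mr_update", "MyogenicResponse"]


@dataclass
class MRParams:
    """Myogenic constants plus the fixed downstream renal resistances."""

    p0: float                   # lower autoregulatory pressure limit, mmHg
    p1: float                   # upper autoregulatory pressure limit, mmHg
    q0: float                   # desired renal blood flow, L/s
    k: float                    # fractional flow change across [p0, p1]
    delta1: float               # constriction onset delay, s
    delta2: float               # dilation onset delay, s
    tau1: float                 # vasoconstriction time constant, s
    tau2: float                 # vasodilation time constant, s
    gain: float                 # g_MR, dimensionless
    r_base: float               # calibrated baseline afferent resistance
    r_gl_vr: float              # efferent arteriole, mmHg*s/L
    r_gl_tu: float              # glomerular filtration path, mmHg*s/L
    r_tu_vr: float              # tubular outflow path, mmHg*s/L
    r_vr_vc: float              # renal venous outflow, mmHg*s/L
    tau_convention: str = "physiological"
    floor_frac: float = 0.05

    def __post_init__(self) -> None:
        if self.p0 >= self.p1:
            raise ValueError("p0 must be below p1")
        if self.delta1 >= self.delta2:
            raise ValueError("delta1 must be below delta2")
        if min(self.tau1, self.tau2) <= 0 or self.q0 <= 0 or self.k < 0:
            raise ValueError("invalid myogenic constants")

    @classmethod
    def from_config(cls, cfg: MRConfig, r_base: float,
                    r_gl_vr: float, r_gl_tu: float,
                    r_tu_vr: float, r_vr_vc: float) -> "MRParams":
        return cls(p0=cfg.p0_mmhg, p1=cfg.p1_mmhg, q0=cfg.q0_l_per_s, k=cfg.k,
                   delta1=cfg.delta1_s, delta2=cfg.delta2_s,
                   tau1=cfg.tau1_s, tau2=cfg.tau2_s, gain=cfg.gain,
                   r_base=r_base, r_gl_vr=r_gl_vr, r_gl_tu=r_gl_tu,
                   r_tu_vr=r_tu_vr, r_vr_vc=r_vr_vc,
                   tau_convention=cfg.tau_convention,
                   floor_frac=cfg.resistance_floor_frac)

    @property
    def downstream_resistance(self) -> float:
        """Post-afferent lumped resistance: GL_VR || (GL_TU + TU_VR), + VR_VC."""
        par = 1.0 / (1.0 / self.r_gl_vr + 1.0 / (self.r_gl_tu + self.r_tu_vr))
        return par + self.r_vr_vc

    @property
    def resistance_floor(self) -> float:
        return self.floor_frac * self.r_base


def sensed_pressure(history: np.ndarray, dt: float,
                    delta1: float, delta2: float) -> float:
    """Windowed systolic pressure: max over [t - delta2, t - delta1].

    ``history`` is the sampled pressure up to and including the current
    time t at spacing dt; it must cover at least delta2.
    """
    lag1 = int(round(delta1 / dt))
    lag2 = int(round(delta2 / dt))
    if lag2 >= len(history):
        raise ValueError("history shorter than delta2")
    last = len(history) - 1
    return float(np.max(history[last - lag2:last - lag1 + 1]))


def target_conductance(p_ar: float, p_vc: float, params: MRParams) -> float:
    """Myogenic target conductance of the whole renal path, L/(s*mmHg).

    Below p0 the target flow is q0, between p0 and p1 it rises with
    fractional slope k, above p1 it saturates; all referenced to the
    arteriovenous gradient P_AR - P_VC.
    """
    if p_ar <= p_vc:
        raise ValueError(f"P_AR ({p_ar}) must exceed P_VC ({p_vc})")
    p0, p1, q0, k = params.p0, params.p1, params.q0, params.k
    if p_ar < p0:
        return q0 / (p0 - p_vc)
    if p_ar <= p1:
        return q0 * (1.0 + k * (p_ar - p0) / p0) / (p_ar - p_vc)
    return q0 * (1.0 + k * (p1 - p0) / p0) / (p1 - p_vc)


def afferent_target_resistance(c_t: float, params: MRParams) -> float:
    """Invert the target conductance to the afferent-only resistance.

    Subtracts the fixed downstream network from the total target
    resistance; results at or below the floor are clamped (with a
    warning) rather than allowed to go non-physical.
    """
    if c_t <= 0:
        raise ValueError("target conductance must be positive")
    r_t = 1.0 / c_t - params.downstream_resistance
    floor = params.resistance_floor
    if r_t <= floor:
        log.warning("afferent target resistance %.3g at/below floor %.3g; "
                    "clamping", r_t, floor)
        return floor
    return r_t


def mr_update(dr_mr: float, r_target: float, r_current: float,
              dt: float, params: MRParams) -> float:
    """One explicit Euler step of the myogenic resistance increment.

    dR_MR relaxes toward Delta_R = R_T - R_base with the constriction
    constant tau1 when constriction is required and the dilation constant
    tau2 otherwise.  The published branch condition is typeset the other
    way around; ``tau_convention='literal'`` reproduces that reading.
    """
    delta_r = r_target - params.r_base
    constricting = r_target > r_current
    if params.tau_convention == "literal":
        use_tau1 = r_current > r_target
    else:
        use_tau1 = constricting
    tau = params.tau1 if use_tau1 else params.tau2
    return dr_mr + dt * (delta_r - dr_mr) / tau


class MyogenicResponse:
    """Stateful myogenic controller with a pressure-history ring buffer.

    The buffer is pre-filled with the initial pressure so the controller
    is quiescent at t = 0 (warm-up convention).
    """

    def __init__(self, params: MRParams, dt: float, p_init: float):
        self.params = params
        self.dt = dt
        self._lag1 = int(round(params.delta1 / dt))
        self._lag2 = int(round(params.delta2 / dt))
        self._buf = np.full(self._lag2 + 1, float(p_init))
        self._pos = 0           # next write position
        self.dr_mr = 0.0

    def push(self, p_ar: float) -> None:
        self._buf[self._pos] = p_ar
        self._pos = (self._pos + 1) % len(self._buf)

    def sensed(self) -> float:
        """Max of the buffered pressure over lags [delta1, delta2]."""
        L = len(self._buf)
        newest = self._pos - 1          # may be negative; python mod below
        hi = (newest - self._lag1) % L  # most recent sample in the window
        lo = (newest - self._lag2) % L  # oldest sample in the window
        if lo <= hi:
            return float(np.max(self._buf[lo:hi + 1]))
        return float(max(np.max(self._buf[lo:]), np.max(self._buf[:hi + 1])))

    def target_resistance(self, p_vc: float) -> float:
        c_t = target_conductance(self.sensed(), p_vc, self.params)
        return afferent_target_resistance(c_t, self.params)

    def update(self, p_vc: float, r_current: float) -> float:
        """Advance one step; returns the new dR_MR (mmHg*s/L, pre-gain)."""
        r_t = self.target_resistance(p_vc)
        self.dr_mr = mr_update(self.dr_mr, r_t, r_current, self.dt, self.params)
        return self.dr_mr
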