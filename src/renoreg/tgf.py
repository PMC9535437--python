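"""Tubuloglomerular feedback: delayed GFR control of afferent tone.

The macula densa is represented by a pure transport delay delta3 on the
glomerular filtration rate (the GL -> TU connector flow), a clamped
linear activation around the operating point, and a first-order
relaxation with separate constriction/dilation time constants:

    a_TGF(t)  = clamp(GFR(t - delta3), th, sa) - op
    d(dR_TGF)/dt = (a_TGF - dR_TGF)/tau3   if a_TGF > 0   (constriction)
                 = (a_TGF - dR_TGF)/tau4   otherwise      (dilation)

The activation and the filtered state dR_TGF are carried in L/min of GFR
deviation; the contribution to the afferent resistance is
g_TGF * dR_TGF with g_TGF in (mmHg*s/L)/(L/min).  ``recalibrate_gain``
re-fits g_TGF so the closed-loop renal-flow response to a pressure step
matches a user-supplied reference, mirroring how the gain was originally
anchored to isolated-nephron observations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import TGFConfig

__all__ = ["TGFParams", "delayed_gfr", "tgf_activation", "tgf_update",
           "TubuloglomerularFeedback", "recalibrate_gain"]

L_PER_S_TO_ML_PER_MIN = 60_000.0


@dataclass
class TGFParams:
    op_gfr: float               # operating point, ml/min
    th_gfr: float               # threshold (lower clamp), ml/min
    sa_gfr: float               # saturation (upper clamp), ml/min
    delta3: float               # macula densa sensing delay, s
    tau3: float                 # constriction time constant, s
    tau4: float                 # dilation time constant, s
    gain: float                 # g_TGF, (mmHg*s/L) per (L/min) of deviation

    def __post_init__(self) -> None:
        if not (self.th_gfr < self.op_gfr < self.sa_gfr):
            raise ValueError("need th_GFR < op_GFR < sa_GFR")
        if min(self.delta3, self.tau3, self.tau4) <= 0:
            raise ValueError("delays and time constants must be positive")

    @classmethod
    def from_config(cls, cfg: TGFConfig) -> "TGFParams":
        return cls(op_gfr=cfg.op_gfr_ml_min, th_gfr=cfg.th_gfr_ml_min,
                   sa_gfr=cfg.sa_gfr_ml_min, delta3=cfg.delta3_s,
                   tau3=cfg.tau3_s, tau4=cfg.tau4_s,
                   gain=cfg.gain_mmhg_s_per_l_per_l_min)


def delayed_gfr(history: np.ndarray, dt: float, delta3: float) -> float:
    """GFR value delta3 seconds before the end of the sampled history.

    Nearest-sample lookup (delta3 >> dt, so interpolation is pointless).
    During warm-up — history shorter than the delay — the oldest (initial)
    sample is returned.
    """
    lag = int(round(delta3 / dt))
    if lag >= len(history):
        return float(history[0])
    return float(history[len(history) - 1 - lag])


def tgf_activation(gfr_delayed_ml_min: float, params: TGFParams) -> float:
    """Clamped linear activation, ml/min of GFR deviation."""
    g = min(max(gfr_delayed_ml_min, params.th_gfr), params.sa_gfr)
    return g - params.op_gfr


def tgf_update(dr_tgf: float, a_tgf: float, dt: float,
               params: TGFParams) -> float:
    """First-order relaxation of dR_TGF toward the activation.

    Both arguments are in the same GFR-deviation units; the caller picks
    them (this module uses L/min internally).
    """
    tau = params.tau3 if a_tgf > 0 else params.tau4
    return dr_tgf + dt * (a_tgf - dr_tgf) / tau


class TubuloglomerularFeedback:
    """Stateful TGF controller with a GFR-history ring buffer."""

    def __init__(self, params: TGFParams, dt: float, gfr_init_l_per_s: float):
        self.params = params
        self.dt = dt
        self._lag = int(round(params.delta3 / dt))
        init_ml_min = gfr_init_l_per_s * L_PER_S_TO_ML_PER_MIN
        self._buf = np.full(self._lag + 1, init_ml_min)
        self._pos = 0
        self.dr_tgf = 0.0       # filtered deviation, L/min

    def push(self, gfr_l_per_s: float) -> None:
        self._buf[self._pos] = gfr_l_per_s * L_PER_S_TO_ML_PER_MIN
        self._pos = (self._pos + 1) % len(self._buf)

    def sensed(self) -> float:
        """Delayed GFR in ml/min (oldest sample in the ring buffer)."""
        # after push, the sample at _pos is exactly delta3 old
        return float(self._buf[self._pos % len(self._buf)])

    def update(self) -> float:
        """Advance one step; returns the new dR_TGF (L/min of deviation)."""
        a_ml_min = tgf_activation(self.sensed(), self.params)
        self.dr_tgf = tgf_update(self.dr_tgf, a_ml_min / 1000.0, self.dt,
                                 self.params)
        return self.dr_tgf

    @property
    def resistance_contribution(self) -> float:
        """g_TGF * dR_TGF, mmHg*s/L."""
        return self.params.gain * self.dr_tgf


def recalibrate_gain(model, protocol, reference_pct_rbf: float,
                     bounds: tuple[float, float] = (0.0, 5e4),
                     xtol: float = 1.0) -> float:
    """Re-fit g_TGF so the protocol's %ΔRBF at the last level matches a
    user-supplied reference value (percent).

    ``model`` is a GestationalCirculation, ``protocol`` a ProtocolSpec with
    TGF active.  Returns the fitted gain and leaves it set on the model's
    configuration.  Raises if the reference is not bracketed by the gain
    bounds (larger gains buffer flow more, so %ΔRBF is decreasing in gain).
    """
    from scipy.optimize import brentq

    from .protocols import run_pressure_step

    def pct_rbf(gain: float) -> float:
        cfg = model.config.model_copy(deep=True)
        cfg.autoregulation.tgf.gain_mmhg_s_per_l_per_l_min = gain
        m = type(model)(cfg)
        res = run_pressure_step(m, protocol)
        return res.pct_rbf[-1]

    lo, hi = bounds
    f = lambda g: pct_rbf(g) - reference_pct_rbf
    gain = float(brentq(f, lo, hi, xtol=xtol))
    model.config.autoregulation.tgf.gain_mmhg_s_per_l_per_l_min = gain
    return gain
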