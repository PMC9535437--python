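"""Deterministic test/drive waveform generators.

These serve two roles: unit-test fixtures for exercising the controllers
in isolation (constant / pulse / step / ramp signals sampled at solver
resolution) and the pulsatile pressure waveform used by the renal
perfusion clamp.
"""

from __future__ import annotations

import numpy as np

__all__ = ["pulse_phase_shape", "pulse_waveform", "generate_waveform"]

# fraction of the cycle occupied by the systolic hump of the generic pulse;
# a sin^2 hump over 2/3 of the cycle has mean 1/3, so the mean pressure of
# the pulse equals diastolic + pulse_pressure/3 (the standard MAP estimate)
SYSTOLE_FRAC = 2.0 / 3.0


def pulse_phase_shape(phase: np.ndarray) -> np.ndarray:
    """Normalised pulse shape w(phase) in [0, 1] with mean 1/3."""
    ph = np.mod(np.asarray(phase, dtype=float), 1.0)
    w = np.zeros_like(ph)
    mask = ph < SYSTOLE_FRAC
    w[mask] = np.sin(np.pi * ph[mask] / SYSTOLE_FRAC) ** 2
    return w


def pulse_waveform(systolic: float, diastolic: float):
    """Return phase -> pressure callable: diastolic + PP * w(phase)."""
    if systolic < diastolic:
        raise ValueError("systolic below diastolic")

    def wave(phase: np.ndarray) -> np.ndarray:
        return diastolic + (systolic - diastolic) * pulse_phase_shape(phase)

    return wave


def generate_waveform(kind: str, duration: float, dt: float = 1e-3,
                      **params) -> tuple[np.ndarray, np.ndarray]:
    """Sample a named deterministic signal at solver resolution.

    kinds:
      constant: value
      pulse:    systolic, diastolic, heart_rate (bpm)
      step:     before, after, at (s)
      ramp:     start, slope (per s)
    """
    n = int(round(duration / dt))
    t = np.arange(n) * dt
    if kind == "constant":
        y = np.full(n, float(params["value"]))
    elif kind == "pulse":
        period = 60.0 / float(params["heart_rate"])
        y = pulse_waveform(params["systolic"], params["diastolic"])(t / period)
    elif kind == "step":
        y = np.where(t < float(params["at"]), float(params["before"]),
                     float(params["after"]))
    elif kind == "ramp":
        y = float(params.get("start", 0.0)) + float(params["slope"]) * t
    else:
        raise ValueError(f"unknown waveform kind {kind!r}")
    return t, y
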