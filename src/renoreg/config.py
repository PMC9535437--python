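"""Configuration schema, validation and (de)serialisation.

The canonical configuration format is JSON.  Units are encoded in the
field names (``_mmhg``, ``_l``, ``_s``, ``_l_per_s`` ...) and converted
once at load time into the internal mmHg/L/s convention.
"""

from __future__ import annotations

import json
import logging
from importlib import resources
from pathlib import Path
from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .core import (Compartment, ConfigurationError, Connector,
                   TimeVaryingElastance)

log = logging.getLogger("renoreg")

__all__ = [
    "ElastanceProfile", "CompartmentConfig", "ConnectorConfig",
    "MRConfig", "TGFConfig", "AutoregulationConfig",
    "CalibrationTargetsConfig", "ModelConfig",
    "load_config", "save_config", "packaged_config",
]


class _Base(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ElastanceProfile(_Base):
    """Double-Hill time-varying elastance parameters for a heart chamber."""

    ees_mmhg_per_l: float = Field(gt=0)
    ed_mmhg_per_l: float = Field(gt=0)
    rise_frac: float = Field(default=0.269, gt=0, lt=1)
    decay_frac: float = Field(default=0.452, gt=0, lt=1)
    m1: float = Field(default=1.32, gt=0)
    m2: float = Field(default=21.9, gt=0)
    offset_frac: float = Field(default=0.0, ge=-1.0, le=1.0)

    @model_validator(mode="after")
    def _check(self) -> "ElastanceProfile":
        if self.ees_mmhg_per_l < self.ed_mmhg_per_l:
            raise ValueError("ees must be >= ed")
        return self

    def build(self) -> TimeVaryingElastance:
        return TimeVaryingElastance(
            ees=self.ees_mmhg_per_l, ed=self.ed_mmhg_per_l,
            rise_frac=self.rise_frac, decay_frac=self.decay_frac,
            m1=self.m1, m2=self.m2, offset_frac=self.offset_frac)


class CompartmentConfig(_Base):
    name: str
    elastance_mmhg_per_l: Optional[float] = None
    elastance_profile: Optional[ElastanceProfile] = None
    unstressed_volume_l: float = Field(ge=0)
    volume_l: float = Field(ge=0)

    @model_validator(mode="after")
    def _check(self) -> "CompartmentConfig":
        if (self.elastance_mmhg_per_l is None) == (self.elastance_profile is None):
            raise ValueError(
                f"compartment {self.name}: give exactly one of "
                f"elastance_mmhg_per_l or elastance_profile")
        if self.elastance_mmhg_per_l is not None and self.elastance_mmhg_per_l <= 0:
            raise ValueError(f"compartment {self.name}: elastance must be positive")
        return self

    def build(self) -> Compartment:
        e = (self.elastance_profile.build() if self.elastance_profile is not None
             else float(self.elastance_mmhg_per_l))
        return Compartment(self.name, e, self.unstressed_volume_l, self.volume_l)


class ConnectorConfig(_Base):
    name: str
    source: str
    target: str
    resistance_mmhg_s_per_l: float
    valve: bool = False

    @model_validator(mode="after")
    def _check(self) -> "ConnectorConfig":
        if self.resistance_mmhg_s_per_l <= 0:
            raise ValueError(
                f"connector {self.name}: resistance must be positive, "
                f"got {self.resistance_mmhg_s_per_l}")
        return self

    def build(self) -> Connector:
        return Connector(self.name, self.source, self.target,
                         self.resistance_mmhg_s_per_l, self.valve)


class MRConfig(_Base):
    """Myogenic response constants (defaults: published renal values)."""

    p0_mmhg: float = 80.0
    p1_mmhg: float = 180.0
    q0_l_per_s: float = 0.018
    k: float = Field(default=0.5, ge=0)
    delta1_s: float = Field(default=0.3, gt=0)
    delta2_s: float = Field(default=1.2, gt=0)
    tau1_s: float = Field(default=4.0, gt=0)
    tau2_s: float = Field(default=5.3, gt=0)
    gain: float = 1.0
    tau_convention: Literal["physiological", "literal"] = "physiological"
    resistance_floor_frac: float = Field(default=0.05, gt=0, lt=1)

    @model_validator(mode="after")
    def _check(self) -> "MRConfig":
        if self.p0_mmhg >= self.p1_mmhg:
            raise ValueError("p0 must be below p1")
        if self.q0_l_per_s <= 0:
            raise ValueError("q0 must be positive")
        if self.delta1_s >= self.delta2_s:
            raise ValueError("delta1 must be below delta2")
        return self


class TGFConfig(_Base):
    """Tubuloglomerular feedback constants.

    The activation is carried in L/min of GFR deviation, so the gain has
    units (mmHg*s/L)/(L/min); see docs/methods.md for the unit convention
    and ``renoreg.tgf.recalibrate_gain`` for re-fitting it to a reference.
    """

    op_gfr_ml_min: float = 149.0
    th_gfr_ml_min: float = 144.0
    sa_gfr_ml_min: float = 333.0
    delta3_s: float = Field(default=18.0, gt=0)
    tau3_s: float = Field(default=15.0, gt=0)
    tau4_s: float = Field(default=33.0, gt=0)
    gain_mmhg_s_per_l_per_l_min: float = 200.0

    @model_validator(mode="after")
    def _check(self) -> "TGFConfig":
        if not (self.th_gfr_ml_min < self.op_gfr_ml_min < self.sa_gfr_ml_min):
            raise ValueError("need th_GFR < op_GFR < sa_GFR")
        return self


class AutoregulationConfig(_Base):
    mode: Literal["none", "mr", "mr+tgf"] = "none"
    mr: MRConfig = Field(default_factory=MRConfig)
    tgf: TGFConfig = Field(default_factory=TGFConfig)


class CalibrationTargetsConfig(_Base):
    """Hemodynamic targets the calibration procedure regenerates."""

    map_mmhg: float = Field(default=82.5, gt=0)
    co_l_min: float = Field(default=5.8, gt=0)
    co_range_l_min: tuple[float, float] = (5.7, 6.0)
    rbf_l_min: float = Field(default=1.0, gt=0)
    gfr_l_min: float = Field(default=0.149, gt=0)
    # optional soft targets for the renal compartment pressures, mmHg
    renal_pressures_mmhg: Optional[dict[str, float]] = None

    @model_validator(mode="after")
    def _check(self) -> "CalibrationTargetsConfig":
        lo, hi = self.co_range_l_min
        if not lo < hi:
            raise ValueError("CO range low must be below high")
        return self


class ModelConfig(_Base):
    heart_rate_bpm: float = Field(gt=0)
    dt_s: float = Field(default=1e-3, gt=0)
    compartments: list[CompartmentConfig]
    connectors: list[ConnectorConfig]
    autoregulation: AutoregulationConfig = Field(default_factory=AutoregulationConfig)
    calibration: CalibrationTargetsConfig = Field(
        default_factory=CalibrationTargetsConfig)

    @model_validator(mode="after")
    def _check(self) -> "ModelConfig":
        names = [c.name for c in self.compartments]
        if len(set(names)) != len(names):
            raise ValueError("duplicate compartment names")
        known = set(names)
        for conn in self.connectors:
            for end in (conn.source, conn.target):
                if end not in known:
                    raise ValueError(
                        f"connector {conn.name}: unknown endpoint {end!r}")
        return self

    # convenience accessors ------------------------------------------------

    def compartment(self, name: str) -> CompartmentConfig:
        for c in self.compartments:
            if c.name == name:
                return c
        raise KeyError(name)

    def connector(self, name: str) -> ConnectorConfig:
        for c in self.connectors:
            if c.name == name:
                return c
        raise KeyError(name)

    def resistance(self, name: str) -> float:
        return self.connector(name).resistance_mmhg_s_per_l

    def set_resistance(self, name: str, value: float) -> None:
        self.connector(name).resistance_mmhg_s_per_l = value


def load_config(path: str | Path) -> ModelConfig:
    """Load and validate a model configuration from JSON."""
    raw = json.loads(Path(path).read_text())
    if "autoregulation" not in raw:
        log.info("config %s has no autoregulation block; controllers default "
                 "to mode 'none'", path)
    try:
        return ModelConfig.model_validate(raw)
    except Exception as exc:  # re-raise with file context
        raise ConfigurationError(f"invalid config {path}: {exc}") from exc


def save_config(cfg: ModelConfig, path: str | Path) -> None:
    Path(path).write_text(json.dumps(cfg.model_dump(), indent=1) + "\n")


def packaged_config(name: str = "calibrated") -> ModelConfig:
    """Load one of the shipped configurations ('baseline' or 'calibrated')."""
    ref = resources.files("renoreg").joinpath(f"configs/{name}.json")
    return ModelConfig.model_validate(json.loads(ref.read_text()))
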