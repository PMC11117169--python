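"""Validated configuration schema for the simulation pipeline.

Pydantic models mirror the module structure (network build, heart,
periphery, vessel elements, solver, tracking, scenarios); validation
errors carry field paths. `PipelineConfig.digest()` hashes the canonical
JSON form so reports can assert reproducibility.
"""
from __future__ import annotations

import hashlib
import json
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, field_validator

from . import hemodynamics as hd


class NetworkConfig(BaseModel):
    seed: int = 0
    n_shunts: int = Field(10, ge=0)
    n_equivalent: int = Field(15, ge=0)
    thebesian_order_limit: int = Field(3, ge=0)
    thebesian_chamber: Literal["LA", "LV"] = "LA"
    shunt_resistance: Optional[float] = Field(
        None, description="Pa.s/m3; default 5x order -1 venule resistance")
    order_table: Optional[str] = Field(
        None, description="CSV path; default reduced table when omitted")


class ChamberConfig(BaseModel):
    E_max: float = Field(gt=0)
    E_min: float = Field(gt=0)
    V0: float
    onset: float = 0.0
    duration: float = Field(0.45, gt=0, le=1)

    def build(self) -> hd.ChamberParams:
        return hd.ChamberParams(self.E_max, self.E_min, self.V0,
                                self.onset, self.duration)


class HeartConfig(BaseModel):
    period: float = Field(0.6, gt=0)
    lv: ChamberConfig = ChamberConfig(E_max=2.0, E_min=0.06, V0=10.0,
                                      onset=0.0, duration=0.45)
    la: ChamberConfig = ChamberConfig(E_max=0.25, E_min=0.12, V0=5.0,
                                      onset=0.80, duration=0.35)

    def build(self) -> hd.HeartModel:
        return hd.HeartModel(self.period, self.lv.build(), self.la.build())


class PeripheryConfig(BaseModel):
    R_av: float = Field(0.010, gt=0)
    R_mv: float = Field(0.008, gt=0)
    R_sys: float = Field(1.2, gt=0)
    R_ven: float = Field(0.05, gt=0)
    C_as: float = Field(1.5, gt=0)
    C_vs: float = Field(60.0, gt=0)
    V_as0: float = 300.0
    V_vs0: float = 2500.0

    def build(self) -> hd.PeripheralModel:
        return hd.PeripheralModel(
            R_av=self.R_av, R_mv=self.R_mv, R_sys=self.R_sys, R_ven=self.R_ven,
            C_as=self.C_as, C_vs=self.C_vs, V_as0=self.V_as0, V_vs0=self.V_vs0)


class ElementsConfig(BaseModel):
    viscosity: float = Field(3.0e-3, gt=0, description="Pa.s")
    beta: float = Field(0.2, ge=0)
    pref_mmhg: float = Field(45.0, gt=0)
    c_total_order0_ml_per_mmhg: float = Field(5.0e-8, gt=0)
    imp_peak: float = Field(0.75, ge=0, le=1)
    imp_zero_order: int = Field(7, ge=1)


class SolverConfig(BaseModel):
    n_beats: int = Field(8, ge=2)
    output_dt: float = Field(2e-3, gt=0)
    rtol: float = Field(1e-7, gt=0)
    atol_rel: float = Field(1e-9, gt=0)


class TrackingConfig(BaseModel):
    n_indicators: int = Field(1000, ge=1)
    n_retro: int = Field(1000, ge=1)
    replicates: int = Field(5, ge=1)
    duration_s: float = Field(600.0, gt=0)
    mode: Literal["steady", "instantaneous"] = "steady"
    release_orders: list[int] = [1, 0, -1]
    region_only: bool = True
    micro_volume_scale: float = Field(30.0, gt=0)
    release_mode: Literal["bolus", "continuous"] = "bolus"
    release_window_s: float = Field(0.0, ge=0)


class ScenariosConfig(BaseModel):
    names: list[str] = ["baseline", "occlusion_only", "sarp_nb", "sarp_b"]
    sarp_b_mean_mmhg: float = 63.9   # measured retroperfusion pressure, balloon inflated
    sarp_nb_mean_mmhg: float = 39.2  # balloon deflated
    pulse_mmhg: float = 30.0

    @field_validator("names")
    @classmethod
    def _known(cls, v):
        allowed = {"baseline", "occlusion_only", "sarp_b", "sarp_nb"}
        bad = [n for n in v if n not in allowed]
        if bad:
            raise ValueError(f"unknown scenario name(s) {bad}; allowed {sorted(allowed)}")
        if not v:
            raise ValueError("scenario list must not be empty")
        return v

    def build(self, name: str) -> hd.Scenario:
        if name == "sarp_b":
            return hd.Scenario.sarp_b(self.sarp_b_mean_mmhg, self.pulse_mmhg)
        if name == "sarp_nb":
            return hd.Scenario.sarp_nb(self.sarp_nb_mean_mmhg, self.pulse_mmhg)
        return hd.Scenario.by_name(name)


class PipelineConfig(BaseModel):
    seed: int = 0
    network: NetworkConfig = NetworkConfig()
    heart: HeartConfig = HeartConfig()
    periphery: PeripheryConfig = PeripheryConfig()
    elements: ElementsConfig = ElementsConfig()
    solver: SolverConfig = SolverConfig()
    tracking: TrackingConfig = TrackingConfig()
    scenarios: ScenariosConfig = ScenariosConfig()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(self.model_dump_json()), fh,
                           sort_keys=True)

    def canonical_json(self) -> str:
        return json.dumps(json.loads(self.model_dump_json()), sort_keys=True,
                          separators=(",", ":"))

    def digest(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()
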