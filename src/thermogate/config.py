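"""Configuration models (pydantic, schema-validated, unknown keys rejected).

Physical constants shared by every module live here too: the gas constant and
the Celsius/Kelvin offset. All user-facing temperatures are degrees Celsius;
thermodynamic arithmetic is done in Kelvin internally.
"""
from __future__ import annotations

import hashlib
import json
from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

#: Gas constant, J/(mol K)
R_GAS = 8.314462618
#: Gas constant, kJ/(mol K) — gating/unfolding enthalpies are kept in kJ/mol
R_GAS_KJ = R_GAS / 1000.0
#: Celsius -> Kelvin offset
KELVIN_OFFSET = 273.15


def celsius_to_kelvin(t_c):
    return t_c + KELVIN_OFFSET


def kelvin_to_celsius(t_k):
    return t_k - KELVIN_OFFSET


class DetectionConfig(BaseModel):
    """Settings for Arrhenius threshold detection and downstream summaries.

    ``min_points`` is the sliding-window length used to locate the steepest
    component; ``r2_min`` the minimum coefficient of determination a window
    must reach to count as linear; ``guard_gap`` the number of samples left
    out between the steep window and the baseline region; ``t_max_C`` caps
    the analysed temperature range (40 degC for oocyte-style ramps).
    """

    model_config = ConfigDict(extra="forbid")

    min_points: int = Field(10, ge=3)
    r2_min: float = Field(0.90, gt=0.0, le=1.0)
    guard_gap: int = Field(2, ge=0)
    baseline_min_points: int = Field(3, ge=2)
    t_max_C: float = 40.0
    parallel_tol: float = Field(1e-9, gt=0.0)
    probe_C: float = 40.0
    #: reference temperature for Q10; None -> midpoint of the steep segment
    q10_t_ref_C: Optional[float] = None
    #: subtract the extrapolated baseline (leak) before the half-max search
    subtract_leak: bool = True


class SimulatedConstruct(BaseModel):
    """One synthetic channel construct in a pipeline run."""

    model_config = ConfigDict(extra="forbid")

    name: str
    t_half_C: float = Field(..., gt=0.0, lt=100.0)
    dH: float = Field(250.0, gt=0.0)
    i_max: float = Field(4000.0, gt=0.0)
    leak_ref: float = Field(150.0, ge=0.0)
    q10_leak: float = Field(1.3, ge=1.0)
    noise_sd: float = Field(0.03, ge=0.0)
    n_traces: int = Field(24, ge=1)


class RampProtocolConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    t_start_C: float = 10.0
    t_stop_C: float = 40.0
    rate_C_per_s: float = Field(0.5, gt=0.0)
    sample_hz: float = Field(2.0, gt=0.0)

    @model_validator(mode="after")
    def _ordered(self):
        if not self.t_start_C < self.t_stop_C:
            raise ValueError("t_start_C must be below t_stop_C")
        return self


class PipelineConfig(BaseModel):
    """Full pipeline configuration; unknown keys are rejected at load time."""

    model_config = ConfigDict(extra="forbid")

    seed: int = Field(0, ge=0, lt=2**31)
    detection: DetectionConfig = Field(default_factory=DetectionConfig)
    protocol: RampProtocolConfig = Field(default_factory=RampProtocolConfig)
    tm_method: Literal["boltzmann_fit", "half_max_interp", "derivative_max"] = (
        "boltzmann_fit"
    )
    hill_n_bounds: tuple[float, float] = (0.3, 10.0)
    #: synthetic cohort to generate; mutually compatible with file inputs
    simulate: Optional[list[SimulatedConstruct]] = None
    traces_csv: Optional[str] = None
    traces_ref_json: Optional[str] = None
    dose_csv: Optional[str] = None
    melt_csv: Optional[str] = None
    panel_tsv: Optional[str] = None
    out_dir: Optional[str] = None

    @model_validator(mode="after")
    def _bounds_ok(self):
        lo, hi = self.hill_n_bounds
        if not (0 < lo < hi):
            raise ValueError("hill_n_bounds must be positive and increasing")
        return self

    def config_hash(self) -> str:
        """Reproducible SHA-256 over the canonical JSON form of the config."""
        canon = json.dumps(self.model_dump(mode="json"), sort_keys=True,
                           separators=(",", ":"))
        return hashlib.sha256(canon.encode()).hexdigest()

    @classmethod
    def from_json_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.model_validate(json.load(fh))
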