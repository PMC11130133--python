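"""Validated pipeline configuration (pydantic schema + YAML loading)."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = ["PipelineConfig", "SimConfig", "DetectConfig", "OptotagConfig", "PSDConfig"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimConfig(_Strict):
    duration_s: float = Field(120.0, gt=0)
    noise_sd: float = Field(1.0, ge=0)
    n_d1: int = Field(2, ge=0)
    n_d2: int = Field(3, ge=0)
    n_other: int = Field(1, ge=0)
    d1_modulation: float = -0.5
    d2_modulation: float = 0.5
    opto_latency_ms: float = Field(3.0, ge=0)
    template_snr: float = Field(6.0, gt=0)
    pulse_rate_hz: float = Field(10.0, gt=0)
    pulse_width_ms: float = Field(20.0, gt=0)
    stim_onset_s: float = Field(60.0, ge=0)
    stim_duration_s: float = Field(50.0, gt=0)
    beta_amplitude: dict[str, float] = Field(
        default_factory=lambda: {"C": 0.5, "CE": 0.5, "PD": 1.5, "PE": 1.0}
    )
    groups: list[str] = Field(default_factory=lambda: ["C", "CE", "PD", "PE"])
    subjects_per_group: int = Field(3, ge=1)


class DetectConfig(_Strict):
    snr_threshold: float = Field(3.0, gt=0)
    n_pcs: int = Field(3, ge=1)
    k_max: int = Field(8, ge=1)
    min_unit_snr: float = Field(3.0, gt=0)
    rate_max_hz: float = Field(10.0, gt=0)
    width_min_us: float = Field(300.0, gt=0)


class OptotagConfig(_Strict):
    latency_max_ms: float = Field(5.0, gt=0)
    mod_threshold: float = Field(0.2, gt=0)
    baseline_s: float = Field(60.0, gt=0)
    latency_window_ms: float = Field(10.0, gt=0)


class PSDConfig(_Strict):
    segment_s: float = Field(2.0, gt=0)
    overlap_frac: float = Field(0.5, ge=0, lt=1)
    band: tuple[float, float] = (12.0, 30.0)

    @model_validator(mode="after")
    def _band_order(self) -> "PSDConfig":
        if self.band[0] >= self.band[1]:
            raise ValueError(f"band must be (lo, hi) with lo < hi, got {self.band}")
        return self


class PipelineConfig(_Strict):
    seed: int = Field(0, ge=0, lt=2**31)
    alpha: float = Field(0.05, gt=0, lt=1)
    sim: SimConfig = Field(default_factory=SimConfig)
    detect: DetectConfig = Field(default_factory=DetectConfig)
    optotag: OptotagConfig = Field(default_factory=OptotagConfig)
    psd: PSDConfig = Field(default_factory=PSDConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(data)

    def config_hash(self) -> str:
        """Stable short hash of the full configuration, stamped on outputs."""
        blob = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]
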