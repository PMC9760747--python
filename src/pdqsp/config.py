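"""Pipeline configuration: schema, loading and validation.

A single YAML/JSON file configures the whole pipeline: the model
parameter block, the study designs, the fit configuration, the
sensitivity and expression-sweep settings, and the mandatory global seed
for every stochastic command. Unknown keys are rejected.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .cohort import ArmSpec, StudyDesign, default_designs, recovery_designs
from .errors import ConfigError
from .params import ModelParameters

__all__ = ["PipelineConfig", "load_config", "config_hash", "seed_streams"]


class ArmConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    arm: str
    dose_mg_per_kg: float = 0.0
    schedule: str = ""
    route: str = "IV"


class StudyConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    study: int
    site: int
    n_per_group: int = Field(gt=0)
    arms: list[ArmConfig]
    inoculum: float = Field(gt=0)
    treatment_start: float = Field(ge=0)
    duration: float = Field(gt=0)

    def to_design(self) -> StudyDesign:
        return StudyDesign(
            study=self.study, site=self.site, n_per_group=self.n_per_group,
            arms=tuple(ArmSpec(a.arm, a.dose_mg_per_kg, a.schedule, a.route)
                       for a in self.arms),
            inoculum=self.inoculum, treatment_start=self.treatment_start,
            duration=self.duration,
        )


class FitSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    free_fixed: list[str] = ["kpfr_T", "klimit_T", "beta_kpfr_site2",
                             "beta_klimit_site2", "Emax_ADCC", "kapop"]
    free_omegas: list[str] = ["omega_kpfr", "omega_klimit"]
    free_error: bool = True
    max_outer: int = 12
    polish_cycles: int = 1
    compute_rse: bool = False


class SensitivitySection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    fraction: float = Field(default=0.3, gt=0, lt=1)
    dose_mg_per_kg: float = 10.0
    schedule: str = "Q3Dx3"
    treatment_start: float = 7.0
    t_end: float = 30.0


class SweepSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    receptor: str = "R_PDL1"
    levels_relative: list[float] = [0.1, 0.3, 1.0, 3.0, 10.0]
    readout_day: float = 12.0


class PipelineConfig(BaseModel):
    """Validated configuration of the end-to-end pipeline."""

    model_config = ConfigDict(extra="forbid")

    parameters: ModelParameters = Field(default_factory=ModelParameters)
    designs: list[StudyConfig] | str = "default"   # or "recovery"
    horizon: float = Field(default=40.0, gt=0)
    eta_balance: str = "match_moments"
    calibration_burden: float = Field(default=8.0e6, gt=0)
    fit: FitSection = Field(default_factory=FitSection)
    sensitivity: SensitivitySection = Field(default_factory=SensitivitySection)
    sweep: SweepSection = Field(default_factory=SweepSection)
    seed: int | None = None
    outdir: str = "qsp_out"

    def study_designs(self) -> tuple[StudyDesign, ...]:
        if self.designs == "default":
            return default_designs()
        if self.designs == "recovery":
            return recovery_designs()
        return tuple(s.to_design() for s in self.designs)

    def require_seed(self) -> int:
        if self.seed is None:
            raise ConfigError(
                "a seed is required for stochastic commands; set `seed` in "
                "the config or pass --seed")
        return int(self.seed)


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML or JSON pipeline configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if data is None:
        data = {}
    try:
        return PipelineConfig.model_validate(data)
    except ValidationError as exc:
        first = exc.errors()[0]
        loc = ".".join(str(x) for x in first["loc"])
        raise ConfigError(f"invalid config field {loc!r}: {first['msg']}") from exc


def config_hash(cfg: PipelineConfig) -> str:
    """Stable hash of the serialized configuration (manifest record)."""
    blob = json.dumps(cfg.model_dump(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def seed_streams(seed: int, names: tuple[str, ...] = (
        "generate", "fit", "sensitivity", "analyze")) -> dict[str, int]:
    """Expand one global seed into independent per-stage integer seeds."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(names))
    return {name: int(c.generate_state(1)[0] % (2**31 - 1))
            for name, c in zip(names, children)}
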