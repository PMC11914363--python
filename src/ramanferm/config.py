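"""Structured experiment configuration (YAML) with strict key validation."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .dataset import ANALYTES


def _from_dict(cls, data: dict, context: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys in {context}: {sorted(unknown)}")
    return cls(**data)


@dataclass
class SimulationConfig:
    n_batches: int = 3
    initial_glucose_mM: float = 111.0
    inoculum_gL: float = 0.10
    sampling_interval_h: float = 1.0
    n_feeds: int = 3
    bolus_mM: float = 75.0
    kinetics: dict = field(default_factory=dict)    # overrides of KineticParams fields
    noise: dict = field(default_factory=dict)       # overrides of NoiseModel fields
    titration: dict = field(default_factory=dict)   # per-analyte overrides of TITRATION_DESIGNS


@dataclass
class PreprocessingConfig:
    crop_low: float = 450.0
    crop_high: float = 1800.0


@dataclass
class ModelingConfig:
    max_lv: int = 10
    n_folds: int = 7
    elbow_tau: float = 0.05
    lv_overrides: dict = field(default_factory=dict)   # analyte -> forced LV count


@dataclass
class SupplementationConfig:
    targets: list = field(default_factory=lambda: list(ANALYTES))


@dataclass
class ExperimentConfig:
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    preprocessing: PreprocessingConfig = field(default_factory=PreprocessingConfig)
    modeling: ModelingConfig = field(default_factory=ModelingConfig)
    supplementation: SupplementationConfig = field(default_factory=SupplementationConfig)

    @classmethod
    def from_dict(cls, data: dict) -> "ExperimentConfig":
        data = dict(data or {})
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
        return cls(
            seed=int(data.get("seed", 0)),
            simulation=_from_dict(SimulationConfig, data.get("simulation", {}) or {}, "simulation"),
            preprocessing=_from_dict(PreprocessingConfig, data.get("preprocessing", {}) or {}, "preprocessing"),
            modeling=_from_dict(ModelingConfig, data.get("modeling", {}) or {}, "modeling"),
            supplementation=_from_dict(SupplementationConfig, data.get("supplementation", {}) or {}, "supplementation"),
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def default_config() -> ExperimentConfig:
    """The shipped default study layout: 3 calibration batches, 1 validation
    batch, a three-bolus fed-batch, and one titration per analyte."""
    return ExperimentConfig()
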