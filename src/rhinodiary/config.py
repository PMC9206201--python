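"""Analysis configuration: defaults, YAML loading, CLI overrides."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from .quality import IndexConfig


@dataclass(frozen=True)
class AnalysisConfig:
    """Options steering the full analysis pipeline.

    Defaults reproduce the reference choices: 80% adherence threshold,
    (max - min)/S variation range, calendar-adjacent pairing, trend
    changes as sign transitions, sample SD in the CV.
    """

    adherence_threshold: float = 80.0
    pairing: str = "calendar"
    rvar_plus_one: bool = False
    trend_mode: str = "sign_transition"
    cv_ddof: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.adherence_threshold <= 100.0:
            raise ValueError("adherence_threshold must be in (0, 100]")
        # delegate option validation
        self.index_config

    @property
    def index_config(self) -> IndexConfig:
        return IndexConfig(
            pairing=self.pairing,
            rvar_plus_one=self.rvar_plus_one,
            trend_mode=self.trend_mode,
            cv_ddof=self.cv_ddof,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_mapping(cls, mapping: dict) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**mapping)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls.from_mapping(data)

    def with_overrides(self, **overrides) -> "AnalysisConfig":
        """New config with the given non-None fields replaced."""
        updates = {k: v for k, v in overrides.items() if v is not None}
        return dataclasses.replace(self, **updates)
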