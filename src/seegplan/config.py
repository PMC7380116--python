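"""Run configuration: schema-validated settings for reproducible runs."""

from __future__ import annotations

import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .metrics import ConstraintSettings
from .phantom import PhantomParams


class ConstraintsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    max_length: float = 90.0
    max_angle: float = 30.0
    margin: float = 3.0
    risk_threshold: float = 1.0
    min_electrode_spacing: float = 10.0
    d_max: float = 10.0

    def to_settings(self) -> ConstraintSettings:
        return ConstraintSettings(**self.model_dump())


class PhantomConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    outer_radius: float = 80.0
    gm_inner_radius: float = 70.0
    gm_outer_radius: float = 78.0
    n_vessel_segments: int = 40
    vessel_radius_min: float = 0.5
    vessel_radius_max: float = 2.0
    n_regions: int = 6
    mesh_subdivisions: int = 3

    def to_params(self) -> PhantomParams:
        d = self.model_dump()
        lo = d.pop("vessel_radius_min")
        hi = d.pop("vessel_radius_max")
        return PhantomParams(vessel_radius_range=(lo, hi), **d)


class PriorConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    min_count: int = 5
    membership_tolerance: float = 2.0
    point_radius: float = 5.0
    exclusions: list[str] = Field(default_factory=list)
    entry_wcss_max: float | None = None
    target_wcss_max: float | None = None


class KnnConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    k: int = 5
    n_folds: int = 5


class RunConfig(BaseModel):
    """Top-level configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    constraints: ConstraintsConfig = Field(default_factory=ConstraintsConfig)
    phantom: PhantomConfig = Field(default_factory=PhantomConfig)
    priors: PriorConfig = Field(default_factory=PriorConfig)
    knn: KnnConfig = Field(default_factory=KnnConfig)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(data)

    def write_resolved(self, directory: str | Path) -> None:
        """Write the fully resolved config next to a run's outputs."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        (d / "resolved_config.yaml").write_text(
            yaml.safe_dump(self.model_dump(), sort_keys=False)
        )
        (d / "seed_manifest.json").write_text(json.dumps({"seed": self.seed}))
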