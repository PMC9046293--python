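"""Validated pipeline configuration.

Defaults mirror the classical analysis settings: 16 µm GLI measuring field,
101-point depth-normalized profiles, sliding-window block sizes 10–24,
Hotelling/Bonferroni threshold alpha = 0.001, the three-adjacent-sections
consistency rule, and one million permutation iterations.
"""

from __future__ import annotations

import json
from pathlib import Path

from pydantic import BaseModel, Field, model_validator


class SimulateConfig(BaseModel):
    n_sections: int = Field(3, ge=1)
    pixel_size_um: float = Field(2.0, gt=0)
    outer_radius_um: float = Field(1200.0, gt=0)
    thickness_um: float = Field(400.0, gt=0)
    arc_deg: float = Field(92.0, gt=0, le=350)
    traverse_spacing_um: float = Field(16.0, gt=0)
    border_drift_traverses: int = Field(0, ge=0)


class GliConfig(BaseModel):
    field_size_um: float = Field(16.0, gt=0)


class ProfilesConfig(BaseModel):
    spacing_um: float = Field(16.0, gt=0)
    n_depth: int = Field(101, ge=3)


class BordersConfig(BaseModel):
    block_min: int = Field(10, ge=6)
    block_max: int = Field(24, ge=6)
    alpha: float = Field(0.001, gt=0, le=1)
    match_tol: int = Field(2, ge=0)
    min_sections: int = Field(3, ge=1)
    # cross-section matching tolerance: position estimates in adjacent
    # sections carry independent noise of a few traverses; 6 traverses at the
    # default 16 µm spacing is ~0.1 mm, far below the extent of any area
    tol_positions: int = Field(6, ge=0)

    @model_validator(mode="after")
    def _check_range(self):
        if self.block_max < self.block_min:
            raise ValueError("block_max must be >= block_min")
        return self


class PermtestConfig(BaseModel):
    n_iter: int = Field(1_000_000, ge=1)
    paired: bool = True


class PipelineConfig(BaseModel):
    """Full pipeline configuration; every field has the classical default."""

    seed: int = 0
    simulate: SimulateConfig = SimulateConfig()
    gli: GliConfig = GliConfig()
    profiles: ProfilesConfig = ProfilesConfig()
    borders: BordersConfig = BordersConfig()
    permtest: PermtestConfig = PermtestConfig()
    output_dir: str = "cytoparcel_out"

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load a JSON or YAML config file."""
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            return cls.model_validate(yaml.safe_load(text))
        return cls.model_validate(json.loads(text))

    def to_json(self) -> str:
        return self.model_dump_json(indent=2)
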