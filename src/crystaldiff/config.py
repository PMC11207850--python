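"""Schema-validated run configuration (YAML or JSON).

A :class:`RunConfig` describes one simulated experiment end to end: crystal
geometry, diffusion parameters, optics, the sampling schedule and a mandatory
seed.  The config is echoed into every output directory so a run can always
be reproduced from its artefacts.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator

from .optics import OpticsModel
from .sim import FACES, CrystalGeometry, DiffusionParams


class GeometryConfig(BaseModel):
    extents_um: tuple[float, float, float] = (100.0, 100.0, 100.0)
    voxel_pitch_um: float = 2.0
    exposed_faces: list[str] = Field(default_factory=lambda: list(FACES))
    defects: list[tuple[int, int, int]] = Field(default_factory=list)

    @field_validator("exposed_faces")
    @classmethod
    def _known_faces(cls, v):
        bad = set(v) - set(FACES)
        if bad:
            raise ValueError(f"unknown faces {sorted(bad)}")
        return v

    def build(self) -> CrystalGeometry:
        return CrystalGeometry(
            extents=tuple(self.extents_um),
            voxel_pitch=self.voxel_pitch_um,
            exposed_faces=tuple(self.exposed_faces),
            defects=tuple(tuple(d) for d in self.defects),
        )


class DiffusionConfig(BaseModel):
    D_m2_per_s: "float | dict[str, float]" = 1.5e-15
    boundary_occupancy: float | None = None
    dt_s: float | None = None

    def build(self) -> DiffusionParams:
        return DiffusionParams(
            D=self.D_m2_per_s,
            boundary_occupancy=self.boundary_occupancy,
            dt_s=self.dt_s,
        )


class OpticsConfig(BaseModel):
    view_axis: str = "z"
    extinction_per_um: float = 0.039
    extinction_rgb: tuple[float, float, float] = (0.2, 1.0, 1.0)
    background_rgb: tuple[float, float, float] = (200.0, 200.0, 200.0)
    noise_sd: float = 2.0
    pad_px: int = 4

    def build(self, seed: int | None) -> OpticsModel:
        return OpticsModel(
            view_axis=self.view_axis,
            extinction=self.extinction_per_um,
            extinction_rgb=tuple(self.extinction_rgb),
            background_rgb=tuple(self.background_rgb),
            noise_sd=self.noise_sd,
            pad_px=self.pad_px,
            seed=seed,
        )


class RunConfig(BaseModel):
    """One simulated infusion/release experiment."""

    mode: str = "release"
    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    diffusion: DiffusionConfig = Field(default_factory=DiffusionConfig)
    optics: OpticsConfig = Field(default_factory=OpticsConfig)
    sample_times_min: list[float]
    seed: int
    frame_format: str = "png"

    @field_validator("mode")
    @classmethod
    def _mode_known(cls, v):
        if v not in ("uptake", "release"):
            raise ValueError("mode must be 'uptake' or 'release'")
        return v

    @field_validator("sample_times_min")
    @classmethod
    def _times_increasing(cls, v):
        if len(v) == 0 or any(b <= a for a, b in zip(v, v[1:])):
            raise ValueError("sample_times_min must be strictly increasing")
        return v


def load_config(path: "str | Path") -> RunConfig:
    """Load and validate a YAML or JSON run configuration."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return RunConfig.model_validate(data)


def dump_config(config: RunConfig, path: "str | Path") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(config.model_dump(), sort_keys=False))
    return path
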