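"""Validated pipeline configuration (YAML-serializable, unknown keys rejected)."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .optics import CameraModel, OpticalSystem
from .simulator import ScintillatorStack


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeometryConfig(_Section):
    slab_thickness_um: float = 100.0
    gap_bottom_um: float = 5.0
    gap_top_um: float | None = 5.0
    lateral_extent_um: float = 20000.0
    light_yield_per_kev: float = 20.0
    range_scale_um: float | None = None

    def build(self) -> ScintillatorStack:
        return ScintillatorStack(**self.model_dump())


class OpticsConfig(_Section):
    wavelength_nm: float = 475.0
    refractive_index: float = 1.0
    numerical_aperture: float = 0.75
    effective_magnification: float = 3.6
    focal_plane_z_um: float = -5.0
    system_blur_um: float = 10.0
    dual_plate_blur_um: float = 18.0

    def build(self) -> OpticalSystem:
        return OpticalSystem(**self.model_dump())


class CameraConfig(_Section):
    pixel_size_um: float = 16.0
    binning: int = 4
    em_gain: float = 1060.0
    exposure_s: float = 0.030
    read_noise_e: float = 30.0
    dark_rate_e_per_s: float = 0.001
    quantum_efficiency: float = 0.01
    bias_offset_adu: float = 200.0

    def build(self) -> CameraModel:
        return CameraModel(**self.model_dump())


class ReconstructionConfig(_Section):
    k_sigma: float = 5.0
    min_pixels: int = 2
    close_radius: int = 1


class QuantificationConfig(_Section):
    roi_diameter_um: float = 90.0
    half_life_min: float = 110.0
    n_background_rois: int = 66
    decay_correct_double: bool = True


class ScenarioConfig(_Section):
    """Synthetic single-then-double experiment emulating the cell study."""

    n_cells: int = 66
    frame_shape: tuple[int, int] = (128, 128)
    n_frames: int = 10000
    dark_frames: int = 1000
    exposure_s: float = 0.030
    delta_t_min: float = 21.0
    mean_n0: float = 2.0e4
    dispersion: float = 0.5
    cell_radius_um: float = 20.0
    min_separation_um: float = 120.0
    efflux_rate_per_min: float = 0.0
    focus_depth_um: float = 24.5
    threshold_kev: float = 10.0


class PipelineConfig(_Section):
    version: str = Field(default=__version__)
    seed: int = 0
    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    optics: OpticsConfig = Field(default_factory=OpticsConfig)
    camera: CameraConfig = Field(default_factory=CameraConfig)
    reconstruction: ReconstructionConfig = Field(default_factory=ReconstructionConfig)
    quantification: QuantificationConfig = Field(default_factory=QuantificationConfig)
    scenario: ScenarioConfig = Field(default_factory=ScenarioConfig)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(json.loads(self.model_dump_json()), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "PipelineConfig":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        return cls.model_validate(yaml.safe_load(text) or {})

    def config_hash(self) -> str:
        return hashlib.sha256(self.model_dump_json().encode()).hexdigest()[:16]


SCENARIO_PRESETS: dict[str, dict] = {
    # the cell experiment at full scale: ~66 analyzable cells, 10,000 frames
    # per configuration, 21-minute delay
    "paper_default": {},
    # same physics at reduced problem size for quick runs; per-cell molecule
    # load raised so per-frame event density matches the full-length run
    "paper_scaled": {
        "n_cells": 20,
        "n_frames": 1000,
        "dark_frames": 200,
        "mean_n0": 5.0e4,
    },
}


def preset_config(name: str, seed: int = 0, efflux: bool = False) -> PipelineConfig:
    """A ready-made configuration for a named scenario preset."""
    if name not in SCENARIO_PRESETS:
        raise KeyError(f"unknown scenario preset {name!r}; "
                       f"choose from {sorted(SCENARIO_PRESETS)}")
    kwargs = dict(SCENARIO_PRESETS[name])
    if efflux:
        kwargs["efflux_rate_per_min"] = 0.02
    return PipelineConfig(seed=seed, scenario=ScenarioConfig(**kwargs))
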