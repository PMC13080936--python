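"""Pipeline configuration schema and validation.

The YAML config mirrors the pipeline stages; unknown keys are rejected so
typos fail loudly, and every value is echoed into the run metadata.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class InputConfig(_Strict):
    movie: Optional[str] = None
    axis_order: Literal["TCYX", "TYXC", "CTYX"] = "TCYX"
    n_channels: Optional[int] = None
    pixel_size_um: float = Field(1.0, gt=0)
    frame_interval_s: float = Field(1.0, gt=0)


class SimulateConfig(_Strict):
    enabled: bool = False
    ki: float = Field(0.04, ge=0)
    ke: float = Field(5.0, gt=0)
    l_total: int = Field(2000, gt=0)
    n_spots: int = Field(80, gt=0)
    n_frames: int = Field(360, gt=0)
    frame_interval_s: float = Field(5.0, gt=0)
    fov: tuple[int, int] = (512, 512)
    psf_sigma_px: float = Field(1.3, gt=0)
    spot_amplitude: float = Field(150.0, gt=0)
    background_level: float = Field(100.0, ge=0)
    read_noise_sd: float = Field(2.0, ge=0)
    bleach_rate: tuple[float, float] = (0.001, 0.001)
    diffusion_px2s: float = Field(0.02, ge=0)


class BleachConfig(_Strict):
    enabled: bool = False
    # channel index, or "all" to fit and correct every channel independently
    channel: Union[int, Literal["all"]] = "all"


class SegmentConfig(_Strict):
    enabled: bool = False
    method: Literal["watershed", "polygon-file", "import"] = "watershed"
    channel: int = 0
    intensity_threshold: float = Field(0.0, ge=0)
    min_area_px: int = Field(50, ge=0)
    min_peak_separation_px: int = Field(10, ge=1)
    smoothing_sigma_px: float = Field(2.0, gt=0)
    mask_path: Optional[str] = None
    polygon_path: Optional[str] = None


class DetectConfig(_Strict):
    enabled: bool = True
    channel: int = 0
    sigma_px: float = Field(1.3, gt=0)
    threshold: Optional[float] = None  # None = AUTO
    min_separation_px: int = Field(3, ge=1)
    cluster_multiplier: float = Field(3.0, gt=1)
    drop_clusters: bool = False


class TrackConfig(_Strict):
    enabled: bool = True
    max_disp_px: float = Field(5.0, ge=0)
    memory: int = Field(1, ge=0)
    min_track_len: int = Field(10, ge=0)
    method: Literal["assignment", "greedy"] = "assignment"


class IntensityConfig(_Strict):
    enabled: bool = True
    method: Literal["total", "bg_sub", "gauss"] = "bg_sub"
    gap_policy: Literal["skip", "interp"] = "skip"
    disk_radius_px: Optional[float] = None
    ring_width_px: float = Field(3.0, gt=0)


class ColocalizeConfig(_Strict):
    enabled: bool = False
    channel_a: int = 0
    channel_b: int = 1
    d_max_px: float = Field(2.0, gt=0)
    min_fraction: float = Field(0.5, ge=0, le=1)


class CorrelateConfig(_Strict):
    enabled: bool = False
    channel: int = 1
    mode: Literal["acf", "ccf"] = "acf"
    max_lag_s: Optional[float] = None
    l_eff_codons: Optional[float] = None
    g0_choice: Literal["raw", "extrap"] = "extrap"


class PipelineConfig(_Strict):
    input: InputConfig = InputConfig()
    output_dir: str = "livespot_out"
    seed: int = 0
    log_level: Literal["DEBUG", "INFO", "WARNING", "ERROR"] = "INFO"
    simulate: SimulateConfig = SimulateConfig()
    bleach: BleachConfig = BleachConfig()
    segment: SegmentConfig = SegmentConfig()
    detect: DetectConfig = DetectConfig()
    track: TrackConfig = TrackConfig()
    intensity: IntensityConfig = IntensityConfig()
    colocalize: ColocalizeConfig = ColocalizeConfig()
    correlate: CorrelateConfig = CorrelateConfig()

    @model_validator(mode="after")
    def _cross_checks(self) -> "PipelineConfig":
        if not self.simulate.enabled and self.input.movie is None:
            raise ValueError("input.movie is required when the simulate stage is disabled")
        if self.intensity.disk_radius_px is not None and self.intensity.disk_radius_px <= 0:
            raise ValueError("intensity.disk_radius_px must be > 0")
        if self.correlate.enabled and self.correlate.l_eff_codons is not None \
                and self.correlate.l_eff_codons <= 0:
            raise ValueError("correlate.l_eff_codons must be > 0")
        return self

    def flat_parameters(self) -> dict:
        flat = {}

        def walk(prefix: str, obj) -> None:
            for key, value in obj.items():
                name = f"{prefix}.{key}" if prefix else key
                if isinstance(value, dict):
                    walk(name, value)
                else:
                    flat[name] = value

        walk("", self.model_dump(mode="json"))
        return flat


def validate_config(path: str | Path) -> PipelineConfig:
    """Parse and validate a YAML pipeline config, filling defaults."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    return PipelineConfig.model_validate(raw)


def serialize_config(config: PipelineConfig, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(config.model_dump(mode="json"), sort_keys=True))
    return path
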