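"""Schema-validated run configuration (YAML).

All lengths are nm except scene geometry, which is µm (pixel sizes stay nm).
Every stochastic element has an explicit seed so runs are reproducible from
the config alone.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Literal, Optional, Tuple, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .control import DEFAULT_KII, DEFAULT_KP, DEFAULT_KI, ControllerGains
from .estimation import AXES, AxisStackConfig
from .simulator import DriftModel, NoiseModel, VirtualMicroscope, VirtualScene

__all__ = [
    "RunConfig",
    "ConfigError",
    "load_config",
    "build_microscope",
]


class ConfigError(Exception):
    """Configuration failed schema validation; message names the field."""


class StackCfg(BaseModel):
    model_config = ConfigDict(extra="forbid")
    range_nm: float = 200.0
    step_nm: float = 20.0
    settle_buffer_ms: float = 100.0


class GainsCfg(BaseModel):
    model_config = ConfigDict(extra="forbid")
    kp: float = DEFAULT_KP
    ki: float = DEFAULT_KI
    kii: float = DEFAULT_KII
    output_limit_nm: float = 200.0
    stage_limit_nm: float = 50000.0


class SceneCfg(BaseModel):
    model_config = ConfigDict(extra="forbid")
    pattern: Literal["holey_carbon", "bead_field", "tile_target"] = "holey_carbon"
    fov_px: Tuple[int, int] = (160, 160)
    pixel_size_nm: Tuple[float, float] = (75.0, 75.0)
    hole_diameter_um: float = 2.0
    hole_spacing_um: float = 2.0
    hole_contrast: float = 0.35
    n_beads: int = 25
    bead_sigma_nm: float = 120.0
    tile_pitch_um: float = 10.0
    base_intensity: float = 1.0
    background: float = 0.08
    supersample: int = 4
    margin_px: int = 32
    psf_w0_nm: float = 250.0
    psf_zr_nm: float = 1000.0
    defocus_nm: float = 2000.0  # working z position (axial sensitivity needs defocus)
    seed: int = 0

    @model_validator(mode="after")
    def _roi_size(self) -> "SceneCfg":
        if self.fov_px[0] < 8 or self.fov_px[1] < 8:
            raise ValueError("fov_px must be at least 8×8")
        return self


class DriftCfg(BaseModel):
    model_config = ConfigDict(extra="forbid")
    kind: Literal["none", "linear", "random_walk", "sinusoidal"] = "none"
    rate_nm: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    sigma_nm: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    amplitude_nm: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    period_iters: float = 1000.0
    seed: int = 0


class NoiseCfg(BaseModel):
    model_config = ConfigDict(extra="forbid")
    enabled: bool = True
    photon_peak: float = 45000.0
    read_sigma: float = 10.0
    offset: float = 100.0
    saturation: float = 65535.0
    seed: int = 0


class RunConfig(BaseModel):
    """Full stabilization run description: stacks, gains, scene, noise, drift."""

    model_config = ConfigDict(extra="forbid")
    stacks: Dict[str, StackCfg] = Field(
        default_factory=lambda: {ax: StackCfg() for ax in AXES}
    )
    gains: GainsCfg = GainsCfg()
    calibration: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    scene: SceneCfg = SceneCfg()
    drift: DriftCfg = DriftCfg()
    noise: NoiseCfg = NoiseCfg()
    seed: int = 0

    @model_validator(mode="after")
    def _axes_complete(self) -> "RunConfig":
        for ax in AXES:
            if ax not in self.stacks:
                raise ValueError(f"stacks must define axis {ax!r}")
        return self

    def stack_configs(self) -> Dict[str, AxisStackConfig]:
        return {
            ax: AxisStackConfig(
                axis=ax,
                range_nm=c.range_nm,
                step_nm=c.step_nm,
                settle_buffer_ms=c.settle_buffer_ms,
            )
            for ax, c in self.stacks.items()
        }

    def controller_gains(self) -> ControllerGains:
        g = self.gains
        return ControllerGains(
            kp=g.kp,
            ki=g.ki,
            kii=g.kii,
            output_limit_nm=g.output_limit_nm,
            stage_limit_nm=g.stage_limit_nm,
        )


def load_config(path: Union[str, Path]) -> RunConfig:
    """Load and validate a YAML run configuration.

    Raises :class:`ConfigError` naming the offending field path.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"invalid YAML in {path}: {exc}") from exc
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        locs = "; ".join(
            ".".join(str(p) for p in err["loc"]) + ": " + err["msg"]
            for err in exc.errors()
        )
        raise ConfigError(f"invalid config {path}: {locs}") from exc


def build_microscope(cfg: RunConfig, seed: Optional[int] = None) -> VirtualMicroscope:
    """Instantiate the virtual microscope a config describes.

    ``seed``, if given, overrides the config seed (and reseeds the noise and
    drift models coherently).
    """
    base_seed = cfg.seed if seed is None else seed
    s = cfg.scene
    scene = VirtualScene(
        pattern=s.pattern,
        fov_px=tuple(s.fov_px),
        pixel_size_nm=tuple(s.pixel_size_nm),
        hole_diameter_um=s.hole_diameter_um,
        hole_spacing_um=s.hole_spacing_um,
        hole_contrast=s.hole_contrast,
        n_beads=s.n_beads,
        bead_sigma_nm=s.bead_sigma_nm,
        tile_pitch_um=s.tile_pitch_um,
        base_intensity=s.base_intensity,
        background=s.background,
        supersample=s.supersample,
        margin_px=s.margin_px,
        psf_w0_nm=s.psf_w0_nm,
        psf_zr_nm=s.psf_zr_nm,
        seed=s.seed,
    )
    noise = None
    if cfg.noise.enabled:
        noise = NoiseModel(
            photon_peak=cfg.noise.photon_peak,
            read_sigma=cfg.noise.read_sigma,
            offset=cfg.noise.offset,
            saturation=cfg.noise.saturation,
            seed=base_seed,
        )
    d = cfg.drift
    drift = DriftModel(
        kind=d.kind,
        rate_nm=d.rate_nm,
        sigma_nm=d.sigma_nm,
        amplitude_nm=d.amplitude_nm,
        period_iters=d.period_iters,
        seed=(base_seed * 7919 + d.seed) % (2**31),
    )
    return VirtualMicroscope(
        scene=scene,
        noise=noise,
        drift=drift,
        start_position_nm=(0.0, 0.0, s.defocus_nm),
        seed=base_seed,
    )
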