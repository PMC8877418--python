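"""Run configuration: one YAML file driving every pipeline stage.

Precedence is CLI flag > config file > built-in default. The fully resolved
parameter set (and a short hash of it) is stamped into the header of every
output CSV so any table can be traced back to the exact geometry and
settings that produced it.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ValidationError
from .kinetics import KineticsParams
from .mechanics import PlatformGeometry
from .tracking import DetectionParams

__all__ = ["RunConfig", "load_config"]


@dataclass
class AcquisitionConfig:
    frame_rate: float = 100.0  # fps
    pixel_size_um: float = 5.0  # µm/px — user must calibrate


@dataclass
class GeometryConfig:
    # L is the platform's 3 mm post; E, R, a are Sylgard-184-typical
    # placeholders the user must calibrate for absolute forces.
    E_pa: float = 2.0e6
    R_m: float = 0.25e-3
    L_m: float = 3.0e-3
    a_m: float = 1.5e-3


@dataclass
class DetectionConfig:
    min_area_px: float = 20.0
    max_area_px: float | None = None
    min_circularity: float = 0.5
    max_gap: int = 5  # frames; 50 ms at 100 fps
    baseline_distance_um: float | None = None  # default: relaxed (max) distance
    per_post_deflection: bool = False


@dataclass
class KineticsConfig:
    pacing_frequency_hz: float | None = 1.0  # None → auto peak detection
    baseline_frac: float = 0.1
    prominence_frac: float = 0.2
    savgol_window: int = 11
    savgol_order: int = 3


@dataclass
class DoseConfig:
    free_bottom: bool = False
    n_starts: int = 16


@dataclass
class RunConfig:
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    kinetics: KineticsConfig = field(default_factory=KineticsConfig)
    dose: DoseConfig = field(default_factory=DoseConfig)
    seeding_area_mm2: float = 11.0
    seed: int = 0

    def platform_geometry(self) -> PlatformGeometry:
        """Validated geometry object (raises early on a > L etc.)."""
        return PlatformGeometry(
            E_pa=self.geometry.E_pa,
            R_m=self.geometry.R_m,
            L_m=self.geometry.L_m,
            a_m=self.geometry.a_m,
            pixel_size_um=self.acquisition.pixel_size_um,
            frame_rate=self.acquisition.frame_rate,
        )

    def detection_params(self) -> DetectionParams:
        return DetectionParams(
            min_area=self.detection.min_area_px,
            max_area=self.detection.max_area_px,
            min_circularity=self.detection.min_circularity,
        )

    def kinetics_params(self) -> KineticsParams:
        return KineticsParams(
            baseline_frac=self.kinetics.baseline_frac,
            prominence_frac=self.kinetics.prominence_frac,
            savgol_window=self.kinetics.savgol_window,
            savgol_order=self.kinetics.savgol_order,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    def config_hash(self) -> str:
        """Short stable digest of the resolved parameter set."""
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        cfg = cls()
        blocks = {
            "acquisition": cfg.acquisition,
            "geometry": cfg.geometry,
            "detection": cfg.detection,
            "kinetics": cfg.kinetics,
            "dose": cfg.dose,
        }
        for name, block in blocks.items():
            for key, value in (data.get(name) or {}).items():
                if not hasattr(block, key):
                    raise ValidationError(f"unknown config key {name}.{key}")
                setattr(block, key, value)
        for key in ("seeding_area_mm2", "seed"):
            if key in data:
                setattr(cfg, key, data[key])
        extra = set(data) - set(blocks) - {"seeding_area_mm2", "seed"}
        if extra:
            raise ValidationError(f"unknown config sections: {sorted(extra)}")
        return cfg


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML config (or defaults when ``path`` is None) and validate it."""
    if path is None:
        cfg = RunConfig()
    else:
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = RunConfig.from_dict(data)
    cfg.platform_geometry()  # fail fast on invalid geometry
    if cfg.acquisition.frame_rate <= 0 or cfg.acquisition.pixel_size_um <= 0:
        raise ValidationError("acquisition frame_rate and pixel_size_um must be positive")
    return cfg
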