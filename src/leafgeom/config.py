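"""Run configuration: plate geometry, preprocessing and detection options.

The pipeline is driven by a single :class:`PipelineConfig` that can be
round-tripped through YAML.  Physical plate geometry must match the plate
that appears in the photographs; everything else has workable defaults.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .errors import InvalidParameterError

#: ITU-R BT.601 luma weights, the conventional "weighted average" greyscale.
BT601_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass
class PreprocessConfig:
    """Greyscale / smoothing / binarisation parameters.

    ``gauss_sigma=0`` disables smoothing entirely (identity filter).
    """

    gray_weights: tuple[float, float, float] = BT601_WEIGHTS
    gauss_sigma: float = 1.0
    threshold_method: str = "otsu"  # "otsu" | "fixed"
    fixed_threshold: float = 128.0

    def __post_init__(self) -> None:
        w = tuple(float(x) for x in self.gray_weights)
        if len(w) != 3 or any(x < 0 for x in w):
            raise InvalidParameterError(f"gray_weights must be 3 non-negative reals, got {w}")
        if abs(sum(w) - 1.0) > 1e-9:
            raise InvalidParameterError(f"gray_weights must sum to 1, got sum={sum(w)!r}")
        self.gray_weights = w
        if self.gauss_sigma < 0:
            raise InvalidParameterError(f"gauss_sigma must be >= 0, got {self.gauss_sigma}")
        if self.threshold_method not in ("otsu", "fixed"):
            raise InvalidParameterError(f"unknown threshold_method {self.threshold_method!r}")


@dataclass
class PlateConfig:
    """Physical geometry of the calibration plate's black frame.

    ``width_mm``/``height_mm`` are the *outer* dimensions of the black
    rectangular frame (the four outer corners are the calibration points).
    1-mm tick marks sit just inside the upper and left frame borders.
    """

    width_mm: float = 160.0
    height_mm: float = 120.0
    thickness_mm: float = 3.0
    tick_spacing_mm: float = 1.0
    px_per_mm: float = 10.0  # rectified-image rendering scale

    def __post_init__(self) -> None:
        for name in ("width_mm", "height_mm", "thickness_mm", "tick_spacing_mm", "px_per_mm"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"plate.{name} must be > 0")


@dataclass
class DetectionConfig:
    """Plate-corner detection options.

    The default detector simplifies the largest dark contour to a
    quadrilateral with a Douglas-Peucker tolerance schedule (fractions of
    the contour perimeter).  A Hough-line detector is available as an
    alternative for images where polygon approximation struggles.
    """

    method: str = "contour"  # "contour" | "hough"
    dp_tol_start: float = 0.01  # fraction of contour perimeter
    dp_tol_factor: float = 1.5
    dp_tol_max: float = 0.10

    def __post_init__(self) -> None:
        if self.method not in ("contour", "hough"):
            raise InvalidParameterError(f"unknown detection method {self.method!r}")
        if not (0 < self.dp_tol_start <= self.dp_tol_max):
            raise InvalidParameterError("require 0 < dp_tol_start <= dp_tol_max")


@dataclass
class TickConfig:
    """Tick-mark recovery options.

    The directional dilation kernel length is calibrated for captures
    ~3264 px wide and rescaled linearly with actual image width.
    Tick positions are read at component centroids.
    """

    kernel_len_ref: int = 49
    ref_image_width: int = 3264
    min_ticks: int = 3
    mode: str = "centroid"  # centroid | inner_end

    def kernel_len(self, image_width: int) -> int:
        return max(3, round(self.kernel_len_ref * image_width / self.ref_image_width))


@dataclass
class PipelineConfig:
    """Complete configuration for the measurement pipeline."""

    plate: PlateConfig = field(default_factory=PlateConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    ticks: TickConfig = field(default_factory=TickConfig)

    # ---- serialisation -------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["preprocess"]["gray_weights"] = list(d["preprocess"]["gray_weights"])
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        kw: dict[str, Any] = {}
        if "plate" in d:
            kw["plate"] = PlateConfig(**d["plate"])
        if "preprocess" in d:
            p = dict(d["preprocess"])
            if "gray_weights" in p:
                p["gray_weights"] = tuple(p["gray_weights"])
            kw["preprocess"] = PreprocessConfig(**p)
        if "detection" in d:
            kw["detection"] = DetectionConfig(**d["detection"])
        if "ticks" in d:
            kw["ticks"] = TickConfig(**d["ticks"])
        return cls(**kw)

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def digest(self) -> str:
        """Short hash of the canonical YAML form, for report headers."""
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]
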