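"""Validated run configuration (YAML/JSON file plus programmatic use)."""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = ["RoiSpec", "FilterSpec", "KinematicSpec", "RunConfig"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class RoiSpec(_Strict):
    type: str  # "circle" | "polygon"
    center: Optional[list[float]] = None
    radius: Optional[float] = None
    vertices: Optional[list[list[float]]] = None

    def build(self):
        from .video import Roi

        if self.type == "circle":
            return Roi("circle", center=tuple(self.center), radius=self.radius)
        return Roi("polygon", vertices=[tuple(v) for v in self.vertices])


class FilterSpec(_Strict):
    min_area: float = 1.0
    max_area: float = float("inf")
    min_length: float = 0.0
    max_length: float = float("inf")
    min_ratio: float = 0.0
    max_ratio: float = float("inf")

    def build(self):
        from .track import ContourFilter

        return ContourFilter(**self.model_dump())


class KinematicSpec(_Strict):
    tl: float = 0.0
    th: float = float("inf")
    ti: float = 0.0
    threshold_unit: str = "px"

    @model_validator(mode="after")
    def _ordered(self):
        if not 0 <= self.tl <= self.th:
            raise ValueError("need 0 <= tl <= th")
        return self

    def build(self, roi=None):
        from .kinematics import KinematicConfig

        return KinematicConfig(tl=self.tl, th=self.th, ti=self.ti,
                               roi=roi, threshold_unit=self.threshold_unit)


class RunConfig(_Strict):
    """Everything one tracking run needs; unknown keys are rejected."""

    video: str
    output_dir: str = "."
    n_individuals: int = Field(ge=1)
    mode: str = "otsu"                  # "otsu" | "manual"
    manual_threshold: Optional[float] = None
    invert: bool = False
    scale: float = Field(default=1.0, gt=0)  # cm per pixel
    median_kernel: int = 3
    cleanup: bool = True
    roi: Optional[RoiSpec] = None
    contour_filter: FilterSpec = Field(default_factory=FilterSpec)
    kinematics: KinematicSpec = Field(default_factory=KinematicSpec)
    seed: int = 0
    verbosity: str = "info"

    @model_validator(mode="after")
    def _mode_ok(self):
        if self.mode not in ("otsu", "manual"):
            raise ValueError("mode must be 'otsu' or 'manual'")
        if self.mode == "manual" and self.manual_threshold is None:
            raise ValueError("manual mode needs manual_threshold")
        return self

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls.model_validate(data)

    def tracker_config(self):
        from .track import TrackerConfig

        return TrackerConfig(
            n_individuals=self.n_individuals,
            mode=self.mode,
            manual_threshold=self.manual_threshold,
            invert=self.invert,
            contour_filter=self.contour_filter.build(),
            median_kernel=self.median_kernel,
            cleanup=self.cleanup,
            roi=self.roi.build() if self.roi else None,
            seed=self.seed,
        )
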