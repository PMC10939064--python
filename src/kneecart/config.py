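"""Run configuration for measurement and grading.

All measurement behaviour that the underlying method leaves open is pinned
here so a run is fully reproducible from (inputs, config).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Optional

import yaml


@dataclass(frozen=True)
class RunConfig:
    """Tunable parameters of the measurement and grading pipeline.

    Parameters
    ----------
    n_lines:
        Number of measurement lines per bone per slice. 36 lines at 5
        degrees sweep half a turn around the femoral origin.
    angle_step:
        Angular increment of the femoral ray sweep, degrees.
    min_component_px:
        Connected components (8-connected, per class) smaller than this are
        removed before measurement.
    ray_sample_step:
        Sub-pixel sampling interval along femoral rays, in pixels.
    grade1_tolerance:
        Fraction of the standard thickness within which a measurement still
        counts as normal (grade 1). Thickness alone cannot detect
        signal-abnormality-only lesions, so "normal" needs a band.
    grade4_epsilon:
        Thickness (mm) below which cartilage counts as absent (grade 4).
        ``None`` resolves to one row spacing of the slice being graded:
        a sub-pixel residual is read as exposed bone.
    anterior_is_left:
        True when the anterior side of the joint is on the image left.
        Controls which measurement-line block maps to the anterior third.
    count_mode:
        "subpixel" (default) samples rays at ``ray_sample_step`` intervals;
        "pixels" counts whole pixel points along the line (1 px steps).
    missing_as_zero:
        When True, lines or regions with no cartilage intersection are
        treated as zero thickness (full-thickness loss) instead of being
        excluded as out-of-field.
    """

    n_lines: int = 36
    angle_step: float = 5.0
    min_component_px: int = 20
    ray_sample_step: float = 0.1
    grade1_tolerance: float = 0.10
    grade4_epsilon: Optional[float] = None
    anterior_is_left: bool = True
    count_mode: str = "subpixel"
    missing_as_zero: bool = False

    def __post_init__(self) -> None:
        if self.n_lines < 1 or self.angle_step <= 0:
            raise ValueError("n_lines and angle_step must be positive")
        if self.n_lines * self.angle_step > 360.0 + 1e-9:
            raise ValueError("n_lines * angle_step must not exceed 360 degrees")
        if self.min_component_px < 1:
            raise ValueError("min_component_px must be >= 1")
        if self.ray_sample_step <= 0:
            raise ValueError("ray_sample_step must be > 0")
        if not 0 <= self.grade1_tolerance < 1:
            raise ValueError("grade1_tolerance must be in [0, 1)")
        if self.grade4_epsilon is not None and self.grade4_epsilon <= 0:
            raise ValueError("grade4_epsilon must be > 0 when given")
        if self.count_mode not in ("subpixel", "pixels"):
            raise ValueError("count_mode must be 'subpixel' or 'pixels'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def with_overrides(self, **kwargs) -> "RunConfig":
        """Return a copy with non-None keyword overrides applied."""
        updates = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **updates) if updates else self

    def to_dict(self) -> dict:
        return asdict(self)
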