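"""Measurement-line geometry: 36 lines per bone, thickness in millimetres.

Femoral cartilage wraps around the condyle, so it is profiled radially:
the midpoint of the segment joining the two arc endpoints is the origin,
and rays are cast from it at fixed angular increments (default 36 rays,
5 degrees apart, covering the half-plane that contains the cartilage).
Tibial cartilage lies flat on the plateau, so it is profiled by vertical
lines at evenly spaced columns between its two side endpoints.

Per line, thickness is the physical length (mm) of the longest contiguous
in-cartilage run along the line. The longest run — not the total
foreground count — is used because a ray can clip a curved arc twice.
All lengths are computed in physical space, so anisotropic pixel spacing
is handled exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .config import RunConfig
from .errors import DegenerateGeometryError, EmptyMaskError
from .preprocessing import BoneMask
from .types import Bone

Spacing = Tuple[float, float]  # (row mm/px, col mm/px)


@dataclass(frozen=True)
class MeasurementLine:
    """One measurement line: 1-based index, pixel-space origin, physical-space
    unit direction, and thickness in mm (None = no cartilage intersection)."""

    index: int
    origin: Tuple[float, float]
    direction: Tuple[float, float]
    thickness_mm: Optional[float]

    def __post_init__(self) -> None:
        if self.thickness_mm is not None and self.thickness_mm < 0:
            raise ValueError("thickness must be non-negative")


@dataclass(frozen=True)
class ThicknessProfile:
    """Ordered per-line thickness for one bone on one slice."""

    bone: Bone
    lines: List[MeasurementLine]
    spacing: Spacing

    def __post_init__(self) -> None:
        indices = [ln.index for ln in self.lines]
        if indices != list(range(1, len(self.lines) + 1)):
            raise ValueError("line indices must be 1..n in order")

    @property
    def thicknesses(self) -> List[Optional[float]]:
        return [ln.thickness_mm for ln in self.lines]


def _longest_run(hits: np.ndarray) -> int:
    """Length of the longest run of True in a 1D boolean array."""
    if not hits.any():
        return 0
    padded = np.concatenate(([False], hits, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]
    return int((ends - starts).max())


def line_thickness(
    origin: Tuple[float, float],
    direction: Tuple[float, float],
    mask: np.ndarray,
    spacing: Spacing,
    sample_step: float = 0.1,
) -> float:
    """Thickness (mm) along one ray through a binary mask.

    The ray starts at ``origin`` (pixel coordinates, pixel centres at
    integers) and marches in ``direction`` (unit vector in physical mm
    space, (d_row, d_col)) at ``sample_step``-pixel intervals until it
    leaves the image. Each sample is classified by the pixel containing
    it; the result is the physical length of the longest contiguous
    in-cartilage run of samples, 0 when the ray misses the cartilage.
    """
    if sample_step <= 0:
        raise ValueError("sample_step must be > 0")
    row_sp, col_sp = spacing
    h, w = mask.shape
    step_mm = sample_step * min(row_sp, col_sp)
    # physical start and the maximal useful path length (image diagonal)
    oy, ox = origin[0] * row_sp, origin[1] * col_sp
    diag_mm = math.hypot(h * row_sp, w * col_sp)
    n_steps = int(diag_mm / step_mm) + 2
    t = np.arange(n_steps) * step_mm
    py = oy + t * direction[0]
    px = ox + t * direction[1]
    # pixel r owns [r-0.5, r+0.5): floor(x+0.5), not rint, whose half-even
    # tie-break would let boundary samples be claimed by both neighbours
    rows = np.floor(py / row_sp + 0.5).astype(np.int64)
    cols = np.floor(px / col_sp + 0.5).astype(np.int64)
    inside = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
    # keep only the initial in-bounds stretch: once the ray exits it never returns
    exit_idx = np.argmin(inside) if not inside.all() else inside.size
    if exit_idx == 0:
        return 0.0
    hits = mask[rows[:exit_idx], cols[:exit_idx]]
    return _longest_run(hits) * step_mm


def femoral_profile(bone_mask: BoneMask, spacing: Spacing, config: RunConfig) -> ThicknessProfile:
    """Radial thickness profile of the femoral cartilage arc.

    The origin is the midpoint of the segment connecting the two arc
    endpoints. ``config.n_lines`` rays are cast at ``config.angle_step``
    increments, offset by half a step so no ray is parallel to the
    endpoint line, sweeping the half-plane on the cartilage-centroid side.
    The sweep starts at the image-left (min-column) endpoint, so line 1 is
    on the image-left side — matching the tibial column ordering.
    """
    if bone_mask.bone is not Bone.FEMUR:
        raise ValueError("femoral_profile requires a FEMUR mask")
    if not bone_mask.pixels.any():
        raise EmptyMaskError("femoral mask is empty")
    row_sp, col_sp = spacing
    (r1, c1), (r2, c2) = bone_mask.endpoints
    p1 = np.array([r1 * row_sp, c1 * col_sp])
    p2 = np.array([r2 * row_sp, c2 * col_sp])
    base = p2 - p1
    norm = float(np.hypot(*base))
    if norm == 0.0:
        raise DegenerateGeometryError("femoral endpoints coincide")
    u_base = base / norm
    origin_px = ((r1 + r2) / 2.0, (c1 + c2) / 2.0)
    origin_mm = (p1 + p2) / 2.0

    rr, cc = np.nonzero(bone_mask.pixels)
    centroid_mm = np.array([rr.mean() * row_sp, cc.mean() * col_sp])
    normal = np.array([-u_base[1], u_base[0]])
    if float(np.dot(centroid_mm - origin_mm, normal)) < 0:
        normal = -normal

    sample_step = 1.0 if config.count_mode == "pixels" else config.ray_sample_step
    lines: List[MeasurementLine] = []
    for i in range(1, config.n_lines + 1):
        theta = math.radians((i - 0.5) * config.angle_step)
        # rotate from the origin->left-endpoint direction towards the normal
        d = math.cos(theta) * (-u_base) + math.sin(theta) * normal
        thick = line_thickness(origin_px, (d[0], d[1]), bone_mask.pixels, spacing, sample_step)
        lines.append(
            MeasurementLine(
                index=i,
                origin=origin_px,
                direction=(float(d[0]), float(d[1])),
                thickness_mm=thick if thick > 0 else None,
            )
        )
    return ThicknessProfile(bone=Bone.FEMUR, lines=lines, spacing=spacing)


def tibial_profile(bone_mask: BoneMask, spacing: Spacing, config: RunConfig) -> ThicknessProfile:
    """Vertical-line thickness profile of the tibial cartilage slab.

    ``config.n_lines`` image columns are placed evenly (inclusive) between
    the two side endpoints; per column the thickness is the longest
    contiguous vertical foreground run times the row spacing (exact pixel
    counting — vertical lines need no sub-pixel sampling).
    """
    if bone_mask.bone is not Bone.TIBIA:
        raise ValueError("tibial_profile requires a TIBIA mask")
    if not bone_mask.pixels.any():
        raise EmptyMaskError("tibial mask is empty")
    row_sp, _ = spacing
    (r1, c1), (r2, c2) = bone_mask.endpoints
    cmin, cmax = min(c1, c2), max(c1, c2)
    if cmin == cmax:
        raise DegenerateGeometryError("tibial mask spans a single column")
    cols = np.rint(cmin + np.arange(config.n_lines) * (cmax - cmin) / (config.n_lines - 1))
    lines: List[MeasurementLine] = []
    for i, col in enumerate(cols.astype(int), start=1):
        run_px = _longest_run(bone_mask.pixels[:, col])
        column = bone_mask.pixels[:, col]
        first_row = int(np.argmax(column)) if column.any() else 0
        lines.append(
            MeasurementLine(
                index=i,
                origin=(float(first_row), float(col)),
                direction=(1.0, 0.0),
                thickness_mm=run_px * row_sp if run_px > 0 else None,
            )
        )
    return ThicknessProfile(bone=Bone.TIBIA, lines=lines, spacing=spacing)
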