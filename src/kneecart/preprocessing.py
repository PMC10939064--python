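"""Segmentation cleanup and per-bone mask extraction.

Network output contains speckle: small isolated components that are not
cartilage. These are removed per class before measurement, then each bone
class is lifted into a binary mask with its two end points, which anchor
the measurement geometry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import ndimage

from .errors import EmptyMaskError
from .io_formats import FEMORAL_CLASS, TIBIAL_CLASS, LabelMask
from .types import Bone

# 8-connectivity: thin oblique cartilage rims break apart under 4-connectivity
_STRUCTURE_8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class BoneMask:
    """Binary mask of one bone's cartilage plus its two extreme end points.

    Endpoints are the extreme foreground pixels along the column axis
    (min-col and max-col; ties broken by smaller row) — the two ends of a
    sagittal cartilage arc.
    """

    pixels: np.ndarray
    bone: Bone
    endpoints: Tuple[Tuple[int, int], Tuple[int, int]]

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=bool)
        object.__setattr__(self, "pixels", px)
        for r, c in self.endpoints:
            if not px[r, c]:
                raise ValueError("endpoints must be foreground pixels")

    @property
    def n_pixels(self) -> int:
        return int(self.pixels.sum())


def remove_small_components(mask: LabelMask, min_component_px: int = 20) -> LabelMask:
    """Remove, per class, 8-connected components smaller than the threshold.

    Classes are cleaned independently so a small speck of one class cannot
    be rescued by touching a large component of the other. Idempotent, and
    never adds foreground.
    """
    if min_component_px < 1:
        raise ValueError("min_component_px must be >= 1")
    out = mask.pixels.copy()
    for cls in (FEMORAL_CLASS, TIBIAL_CLASS):
        binary = mask.pixels == cls
        labels, n = ndimage.label(binary, structure=_STRUCTURE_8)
        if n == 0:
            continue
        sizes = np.bincount(labels.ravel())[1:]  # component 0 is background
        small = np.flatnonzero(sizes < min_component_px) + 1
        if small.size:
            out[np.isin(labels, small)] = 0
    cleaned = LabelMask(out)
    if mask.pixels.any() and not cleaned.pixels.any():
        warnings.warn(
            "all components fell below the size threshold; mask is empty", stacklevel=2
        )
    return cleaned


def find_endpoints(binary: np.ndarray) -> Tuple[Tuple[int, int], Tuple[int, int]]:
    """Extreme-column foreground pixels; ties broken by the smaller row."""
    rows, cols = np.nonzero(binary)
    if rows.size == 0:
        raise EmptyMaskError("mask has no foreground pixels")
    cmin, cmax = cols.min(), cols.max()
    left_row = rows[cols == cmin].min()
    right_row = rows[cols == cmax].min()
    return (int(left_row), int(cmin)), (int(right_row), int(cmax))


def extract_bone(mask: LabelMask, bone: Bone) -> BoneMask:
    """Lift one class out of a (cleaned) label mask into a BoneMask."""
    cls = FEMORAL_CLASS if bone is Bone.FEMUR else TIBIAL_CLASS
    binary = mask.class_mask(cls)
    if not binary.any():
        raise EmptyMaskError(f"no {bone.name.lower()} cartilage pixels in mask")
    return BoneMask(pixels=binary, bone=bone, endpoints=find_endpoints(binary))
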