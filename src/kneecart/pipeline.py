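"""End-to-end measurement of one slice: cleanup -> bones -> profiles ->
thirds -> regional report."""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

from .config import RunConfig
from .errors import EmptyMaskError
from .geometry import ThicknessProfile, femoral_profile, tibial_profile
from .io_formats import DicomMeta, LabelMask, effective_spacing
from .preprocessing import extract_bone, remove_small_components
from .regions import (
    RegionThicknessReport,
    average_thirds,
    infer_compartment,
    map_regions,
    merge_reports,
)
from .types import Bone, Compartment


@dataclass(frozen=True)
class SliceResult:
    report: RegionThicknessReport
    spacing: Tuple[float, float]
    profiles: dict  # Bone -> ThicknessProfile for bones present
    warnings: List[str]


def measure_slice(
    mask: LabelMask,
    meta: DicomMeta,
    config: RunConfig = RunConfig(),
    compartment: Optional[Compartment] = None,
) -> SliceResult:
    """Measure regional cartilage thickness on one labelled slice.

    A bone class that is empty after cleanup is skipped with a warning;
    if both are empty the slice is unmeasurable.
    """
    spacing = effective_spacing(meta, mask)
    cleaned = remove_small_components(mask, config.min_component_px)
    comp = infer_compartment(meta, compartment)
    anterior_first = config.anterior_is_left

    reports = []
    profiles = {}
    notes: List[str] = []
    for bone, profiler in ((Bone.FEMUR, femoral_profile), (Bone.TIBIA, tibial_profile)):
        try:
            bone_mask = extract_bone(cleaned, bone)
        except EmptyMaskError:
            notes.append(f"{bone.name.lower()} cartilage absent after cleanup; skipped")
            continue
        profile = profiler(bone_mask, spacing, config)
        profiles[bone] = profile
        thirds = average_thirds(profile, missing_as_zero=config.missing_as_zero)
        reports.append(map_regions(thirds, bone, comp, anterior_first))
    if not reports:
        raise EmptyMaskError("no cartilage left in mask after cleanup")
    return SliceResult(
        report=merge_reports(reports), spacing=spacing, profiles=profiles, warnings=notes
    )
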