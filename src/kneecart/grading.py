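"""Four-level cartilage damage grading against a standard-thickness table.

The clinical Recht/ICRS scales grade lesion depth; from a cartilage-only
segmentation the observable quantity is the remaining thickness m relative
to the regional standard S, so the scale is operationalised as:

    grade 4  m < epsilon            (full-thickness loss; sub-pixel residual
                                     is read as exposed subchondral bone)
    grade 3  epsilon <= m <= S/2    (less than half the standard remains)
    grade 2  S/2 < m < (1 - tau) S  (damaged, more than half remains)
    grade 1  m >= (1 - tau) S       (normal thickness, within tolerance tau)

Thresholds are checked in this order, so the four intervals always
partition [0, inf) and the grade is non-increasing in m.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

from .config import RunConfig
from .errors import ReferenceError_
from .regions import ReferenceTable, RegionThicknessReport
from .types import RegionCode, Sex, Side

#: entry status values
STATUS_OK = "OK"
STATUS_UNGRADED = "UNGRADED"  # no reference cell for the region
STATUS_WITHHELD = "WITHHELD"  # measurement missing and missing_as_zero unset


@dataclass(frozen=True)
class GradeEntry:
    grade: Optional[int]
    measured_mm: Optional[float]
    standard_mm: Optional[float]
    loss_fraction: Optional[float]
    status: str = STATUS_OK


@dataclass(frozen=True)
class GradeReport:
    entries: Dict[RegionCode, GradeEntry]


def _resolve_epsilon(config: RunConfig, row_spacing: Optional[float]) -> float:
    if config.grade4_epsilon is not None:
        return config.grade4_epsilon
    if row_spacing is None or row_spacing <= 0:
        raise ValueError(
            "grade4_epsilon unset: pass the slice row_spacing so the default "
            "(one row spacing) can be resolved"
        )
    return row_spacing


def assign_grade(
    measured: Optional[float],
    standard: float,
    config: RunConfig = RunConfig(),
    row_spacing: Optional[float] = None,
) -> Optional[int]:
    """Grade one region's measured thickness against its standard.

    ``measured`` of None means the region had no usable measurement: with
    ``config.missing_as_zero`` it grades 4, otherwise the grade is
    withheld (None returned; callers flag the region).
    """
    if standard <= 0:
        raise ReferenceError_("standard thickness must be positive")
    if measured is None:
        if config.missing_as_zero:
            return 4
        return None
    if measured < 0:
        raise ValueError("measured thickness must be non-negative")
    eps = _resolve_epsilon(config, row_spacing)
    tau = config.grade1_tolerance
    if measured < eps:
        return 4
    if measured <= 0.5 * standard:
        return 3
    if measured < (1.0 - tau) * standard:
        return 2
    return 1


def grade_report(
    report: RegionThicknessReport,
    table: ReferenceTable,
    sex: Sex,
    side: Side,
    config: RunConfig = RunConfig(),
    row_spacing: Optional[float] = None,
) -> GradeReport:
    """Grade every measured region with its (sex, side, region) standard.

    Regions whose reference cell is unpopulated are reported UNGRADED;
    regions with no measurement (and missing_as_zero unset) are WITHHELD.
    """
    entries: Dict[RegionCode, GradeEntry] = {}
    for code, entry in report.entries.items():
        cell = table.get(sex, side, code)
        if cell is None:
            entries[code] = GradeEntry(
                grade=None,
                measured_mm=entry.mean_mm,
                standard_mm=None,
                loss_fraction=None,
                status=STATUS_UNGRADED,
            )
            continue
        grade = assign_grade(entry.mean_mm, cell.mean_mm, config, row_spacing)
        measured_eff = entry.mean_mm
        if measured_eff is None and config.missing_as_zero:
            measured_eff = 0.0
        loss = None if measured_eff is None else 1.0 - measured_eff / cell.mean_mm
        entries[code] = GradeEntry(
            grade=grade,
            measured_mm=entry.mean_mm,
            standard_mm=cell.mean_mm,
            loss_fraction=loss,
            status=STATUS_OK if grade is not None else STATUS_WITHHELD,
        )
    return GradeReport(entries=entries)
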