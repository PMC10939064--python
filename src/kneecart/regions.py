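"""Regional averaging and the standard-thickness reference table.

Measurement lines are averaged in index thirds (lines 1-12, 13-24, 25-36)
and mapped to the anatomical subregions of one compartment. Reference
standards — population mean +/- SD of regional thickness in healthy knees
— are keyed by (sex, side, region) and aggregated over per-case means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import AmbiguousCompartmentError, ReferenceError_
from .geometry import ThicknessProfile
from .io_formats import DicomMeta
from .types import Bone, Compartment, RegionCode, Sex, Side, Third, region_code


@dataclass(frozen=True)
class RegionEntry:
    mean_mm: Optional[float]
    n_lines_used: int


@dataclass(frozen=True)
class RegionThicknessReport:
    """Thickness per anatomical subregion for one slice (one compartment)."""

    entries: Dict[RegionCode, RegionEntry]
    compartment: Optional[Compartment]

    def mean_for(self, code: RegionCode) -> Optional[float]:
        entry = self.entries.get(code)
        return None if entry is None else entry.mean_mm


@dataclass(frozen=True)
class RefCell:
    mean_mm: float
    sd_mm: float

    def __post_init__(self) -> None:
        if self.mean_mm <= 0 or self.sd_mm < 0:
            raise ReferenceError_("reference cells need mean > 0 and sd >= 0")


CellKey = Tuple[Sex, Side, RegionCode]


@dataclass
class ReferenceTable:
    """Standard thickness mean +/- SD (mm) keyed by (sex, side, region)."""

    cells: Dict[CellKey, RefCell] = field(default_factory=dict)

    def get(self, sex: Sex, side: Side, region: RegionCode) -> Optional[RefCell]:
        return self.cells.get((sex, side, region))

    @classmethod
    def from_csv(cls, path: str | Path) -> "ReferenceTable":
        df = pd.read_csv(path, comment="#")
        table = cls()
        for _, row in df.iterrows():
            if pd.isna(row["mean_mm"]) or pd.isna(row["sd_mm"]):
                continue
            key = (Sex(row["sex"]), Side[str(row["side"]).upper()], RegionCode(row["region"]))
            table.cells[key] = RefCell(float(row["mean_mm"]), float(row["sd_mm"]))
        return table

    def to_csv(self, path: str | Path) -> None:
        records = [
            {
                "sex": sex.value,
                "side": side.value,
                "region": region.value,
                "mean_mm": round(cell.mean_mm, 2),
                "sd_mm": round(cell.sd_mm, 2),
            }
            for (sex, side, region), cell in sorted(
                self.cells.items(), key=lambda kv: (kv[0][0].value, kv[0][1].value, kv[0][2].value)
            )
        ]
        pd.DataFrame(records, columns=["sex", "side", "region", "mean_mm", "sd_mm"]).to_csv(
            path, index=False
        )


def load_default_reference() -> ReferenceTable:
    """Packaged reference standards.

    Femoral cells ship with the package; the tibial file is an explicitly
    empty placeholder that users must populate from their own cohort —
    tibial regions stay ungradable until then.
    """
    table = ReferenceTable()
    pkg = resources.files("kneecart.data")
    for name in ("reference_femoral.csv", "reference_tibial_placeholder.csv"):
        with resources.as_file(pkg / name) as path:
            table.cells.update(ReferenceTable.from_csv(path).cells)
    return table


def average_thirds(
    profile: ThicknessProfile, missing_as_zero: bool = False
) -> List[Tuple[Optional[float], int]]:
    """Average line thickness over the three index blocks of a profile.

    For 36 lines the blocks are [1, 12], [13, 24], [25, 36]. Lines without
    a cartilage intersection are excluded from the mean (out-of-field, not
    zero thickness) unless ``missing_as_zero`` counts them as 0. A block
    with no usable line yields (None, 0).
    """
    n = len(profile.lines)
    if n % 3 != 0:
        raise ValueError("profile length must be divisible by 3")
    block = n // 3
    out: List[Tuple[Optional[float], int]] = []
    for b in range(3):
        values = [ln.thickness_mm for ln in profile.lines[b * block : (b + 1) * block]]
        if missing_as_zero:
            values = [0.0 if v is None else v for v in values]
        usable = [v for v in values if v is not None]
        if usable:
            out.append((float(np.mean(usable)), len(usable)))
        else:
            out.append((None, 0))
    return out


def map_regions(
    thirds: Sequence[Tuple[Optional[float], int]],
    bone: Bone,
    compartment: Compartment,
    anterior_first: bool = True,
) -> RegionThicknessReport:
    """Assign the three block averages to anterior / central / posterior codes.

    ``anterior_first`` states that the first line block sits on the anterior
    side; when False the anterior/posterior assignment is reversed.
    """
    if len(thirds) != 3:
        raise ValueError("expected exactly three block averages")
    order = (Third.ANTERIOR, Third.CENTRAL, Third.POSTERIOR)
    if not anterior_first:
        order = (Third.POSTERIOR, Third.CENTRAL, Third.ANTERIOR)
    entries = {
        region_code(bone, compartment, third): RegionEntry(mean_mm=value, n_lines_used=count)
        for third, (value, count) in zip(order, thirds)
    }
    return RegionThicknessReport(entries=entries, compartment=compartment)


def merge_reports(reports: Iterable[RegionThicknessReport]) -> RegionThicknessReport:
    """Combine per-bone reports of the same compartment into one."""
    entries: Dict[RegionCode, RegionEntry] = {}
    compartment = None
    for rep in reports:
        entries.update(rep.entries)
        compartment = rep.compartment if compartment is None else compartment
    return RegionThicknessReport(entries=entries, compartment=compartment)


#: Compartment shown by the quarter-stack slice positions, by laterality.
#: Sagittal stacks sweep across the joint; the two annotated positions sit
#: at ~1/4 and ~3/4 of the stack and show opposite compartments depending on
#: which knee is imaged. This convention is a package decision — confirm it
#: against your acquisition protocol or pass an explicit override.
_COMPARTMENT_CONVENTION: Dict[Tuple[Side, str], Compartment] = {
    (Side.RIGHT, "q1"): Compartment.LATERAL,
    (Side.RIGHT, "q2"): Compartment.MEDIAL,
    (Side.LEFT, "q1"): Compartment.MEDIAL,
    (Side.LEFT, "q2"): Compartment.LATERAL,
}


def infer_compartment(
    meta: DicomMeta, override: Optional[Compartment] = None
) -> Compartment:
    """Resolve which compartment a slice shows from its stack position.

    Slices in the first quarter of the stack (fraction <= 0.375) map to one
    compartment and slices in the last quarter (>= 0.625) to the other,
    with the assignment switched by laterality. Slices in the central half
    are ambiguous and require an override.
    """
    if override is not None:
        return override
    frac = meta.slice_index / (meta.n_slices - 1) if meta.n_slices > 1 else 0.5
    if frac <= 0.375:
        quarter = "q1"
    elif frac >= 0.625:
        quarter = "q2"
    else:
        raise AmbiguousCompartmentError(
            f"slice {meta.slice_index} of {meta.n_slices} is in the central half "
            "of the stack; pass an explicit compartment"
        )
    return _COMPARTMENT_CONVENTION[(meta.laterality, quarter)]


@dataclass(frozen=True)
class CohortCase:
    """One subject's regional thickness means plus demographics."""

    regions: Mapping[RegionCode, float]
    sex: Sex
    side: Side


def build_reference(cohort: Iterable[CohortCase], min_cases: int = 2) -> ReferenceTable:
    """Aggregate a healthy cohort into a reference table.

    Per (sex, side, region) cell: mean and sample SD (n-1 denominator) of
    the per-case region means — subjects, not lines, are the unit of
    aggregation. Cells with fewer than ``min_cases`` cases are left
    unpopulated with a warning.
    """
    pooled: Dict[CellKey, List[float]] = {}
    for case in cohort:
        for region, value in case.regions.items():
            pooled.setdefault((case.sex, case.side, region), []).append(float(value))
    table = ReferenceTable()
    for key, values in pooled.items():
        if len(values) < min_cases:
            sex, side, region = key
            warnings.warn(
                f"reference cell ({sex.value}, {side.value}, {region.value}) has "
                f"{len(values)} case(s); left unpopulated",
                stacklevel=2,
            )
            continue
        arr = np.asarray(values)
        table.cells[key] = RefCell(float(arr.mean()), float(arr.std(ddof=1)))
    return table


def reference_mean(table: ReferenceTable, bone: Bone) -> float:
    """Unweighted mean of all reference cell means for one bone, 2 dp.

    Cell means are exact 2-dp decimals, so the average is computed in
    decimal arithmetic and rounded half-up — float rounding can misprint
    values that land exactly on a half (e.g. a true mean of 1.9775).
    """
    expected = [
        (sex, side, region)
        for sex in Sex
        for side in Side
        for region in RegionCode
        if region.bone is bone
    ]
    missing = [key for key in expected if key not in table.cells]
    if missing:
        names = ", ".join(f"({s.value},{d.value},{r.value})" for s, d, r in missing)
        raise ReferenceError_(f"reference table missing cells for {bone.name}: {names}")
    total = sum(
        (Decimal(repr(table.cells[key].mean_mm)) for key in expected), Decimal(0)
    )
    mean = (total / len(expected)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)
    return float(mean)
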