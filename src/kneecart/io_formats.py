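"""Reading label masks and DICOM metadata; writing measurement reports.

Label masks are RGB rasters where femoral cartilage is pure red (255, 0, 0)
and tibial cartilage pure blue (0, 0, 255) on black background. They are
decoded to integer class rasters {0 background, 1 femur, 2 tibia}. DICOM
files supply the physical calibration (PixelSpacing) and the demographic
tags (laterality, patient sex) that select the reference standard.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Tuple

import numpy as np
import pandas as pd
import pydicom
import yaml
from PIL import Image

from .errors import FormatError, InputError, MetadataError
from .types import Compartment, RegionCode, Sex, Side

#: Default colour -> class mapping for label images.
DEFAULT_PALETTE: Mapping[Tuple[int, int, int], int] = {
    (255, 0, 0): 1,  # femoral cartilage
    (0, 0, 255): 2,  # tibial cartilage
}

FEMORAL_CLASS = 1
TIBIAL_CLASS = 2


@dataclass(frozen=True)
class LabelMask:
    """2D class-labelled raster: 0 background, 1 femoral, 2 tibial cartilage."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise FormatError("label mask must be a non-empty 2D raster")
        if not np.isin(px, (0, 1, 2)).all():
            raise FormatError("label mask values must be in {0, 1, 2}")
        object.__setattr__(self, "pixels", px.astype(np.uint8))

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def class_mask(self, cls: int) -> np.ndarray:
        """Binary mask of one class."""
        return self.pixels == cls

    def to_rgb(self, palette: Mapping[Tuple[int, int, int], int] = DEFAULT_PALETTE) -> np.ndarray:
        rgb = np.zeros(self.pixels.shape + (3,), dtype=np.uint8)
        for colour, cls in palette.items():
            rgb[self.pixels == cls] = colour
        return rgb

    def save_png(self, path: str | Path) -> None:
        Image.fromarray(self.to_rgb()).save(path, format="PNG")


@dataclass(frozen=True)
class DicomMeta:
    """Acquisition metadata needed for calibration and reference lookup."""

    row_spacing: float
    col_spacing: float
    rows: int
    cols: int
    laterality: Side
    sex: Sex
    slice_index: int = 0
    n_slices: int = 1

    def __post_init__(self) -> None:
        if self.row_spacing <= 0 or self.col_spacing <= 0:
            raise MetadataError("pixel spacing must be positive")
        if not 0 <= self.slice_index < self.n_slices:
            raise MetadataError("slice_index must satisfy 0 <= index < n_slices")


def read_label_mask(
    path: str | Path,
    palette: Mapping[Tuple[int, int, int], int] = DEFAULT_PALETTE,
    tolerance: int = 0,
) -> LabelMask:
    """Decode a raster label image into a :class:`LabelMask`.

    Colour matching is exact by default; ``tolerance`` allows a per-channel
    absolute deviation to absorb lossy re-encodes. Any colour not matching
    the palette maps to background.
    """
    try:
        img = Image.open(path)
    except (OSError, ValueError) as exc:
        raise InputError(f"cannot read label image {path}: {exc}") from exc
    rgb = np.asarray(img.convert("RGB"), dtype=np.int16)
    if rgb.size == 0:
        raise FormatError(f"label image {path} has zero area")
    out = np.zeros(rgb.shape[:2], dtype=np.uint8)
    for colour, cls in palette.items():
        hit = (np.abs(rgb - np.asarray(colour, dtype=np.int16)) <= tolerance).all(axis=-1)
        out[hit] = cls
    return LabelMask(out)


def _parse_laterality(raw: str) -> Optional[Side]:
    token = str(raw).strip().upper()
    if not token:
        return None
    if token.startswith("L"):
        return Side.LEFT
    if token.startswith("R"):
        return Side.RIGHT
    if "LEFT" in token:
        return Side.LEFT
    if "RIGHT" in token:
        return Side.RIGHT
    return None


def _parse_sex(raw: str) -> Optional[Sex]:
    token = str(raw).strip().upper()
    if token == "M":
        return Sex.M
    if token in ("F", "W"):
        return Sex.W
    return None


def read_sidecar(path: str | Path) -> dict:
    """Read a YAML sidecar overriding laterality / sex / compartment."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    out: dict = {}
    if "laterality" in data:
        side = _parse_laterality(data["laterality"])
        if side is None:
            raise MetadataError(f"sidecar laterality {data['laterality']!r} not understood")
        out["laterality"] = side
    if "sex" in data:
        sex = _parse_sex(data["sex"])
        if sex is None:
            raise MetadataError(f"sidecar sex {data['sex']!r} not understood")
        out["sex"] = sex
    if "compartment" in data:
        out["compartment"] = Compartment[str(data["compartment"]).upper()]
    return out


def read_dicom_meta(
    path: str | Path,
    laterality: Optional[Side] = None,
    sex: Optional[Sex] = None,
) -> DicomMeta:
    """Extract measurement-relevant tags from a DICOM file.

    Laterality resolution order: Laterality tag, Image Laterality,
    BodyPartExamined string match, then the ``laterality`` override.
    Missing PixelSpacing, or unresolvable laterality / sex, raise
    :class:`MetadataError` rather than guessing.
    """
    try:
        ds = pydicom.dcmread(str(path), force=False, stop_before_pixels=True)
    except Exception as exc:
        raise InputError(f"cannot parse DICOM file {path}: {exc}") from exc

    spacing = getattr(ds, "PixelSpacing", None)
    if spacing is None or len(spacing) < 2:
        raise MetadataError(f"{path}: PixelSpacing tag missing")
    row_spacing, col_spacing = float(spacing[0]), float(spacing[1])

    rows = int(getattr(ds, "Rows", 0) or 0)
    cols = int(getattr(ds, "Columns", 0) or 0)
    if rows <= 0 or cols <= 0:
        raise MetadataError(f"{path}: Rows/Columns tags missing")

    side: Optional[Side] = None
    for tag in ("Laterality", "ImageLaterality", "BodyPartExamined"):
        raw = getattr(ds, tag, None)
        if raw:
            side = _parse_laterality(raw)
            if side is not None:
                break
    if side is None:
        side = laterality
    if side is None:
        raise MetadataError(f"{path}: laterality not found in tags and no override given")

    sex_val = _parse_sex(getattr(ds, "PatientSex", "") or "")
    if sex_val is None:
        sex_val = sex
    if sex_val is None:
        raise MetadataError(f"{path}: patient sex not found in tags and no override given")

    instance = getattr(ds, "InstanceNumber", None)
    slice_index = int(instance) - 1 if instance is not None else 0
    n_slices = int(getattr(ds, "ImagesInAcquisition", 0) or 0)
    if n_slices <= 0:
        n_slices = slice_index + 1

    return DicomMeta(
        row_spacing=row_spacing,
        col_spacing=col_spacing,
        rows=rows,
        cols=cols,
        laterality=side,
        sex=sex_val,
        slice_index=slice_index,
        n_slices=n_slices,
    )


def effective_spacing(meta: DicomMeta, mask: LabelMask) -> Tuple[float, float]:
    """Physical mm/px of the mask raster, rescaled from the native DICOM grid.

    Masks may have been produced at a working resolution different from the
    acquisition matrix; the class raster is never resampled — instead the
    spacing is rescaled so physical sizes are preserved. Identity when the
    dimensions match.
    """
    return (
        meta.row_spacing * meta.rows / mask.height,
        meta.col_spacing * meta.cols / mask.width,
    )


# ---------------------------------------------------------------------------
# Report serialization


def _report_records(report, grades=None) -> list[dict]:
    """Flatten a RegionThicknessReport (+ optional GradeReport) to records."""
    records = []
    grade_entries = grades.entries if grades is not None else {}
    for code, entry in report.entries.items():
        rec: dict = {
            "region": code.value,
            "mean_mm": None if entry.mean_mm is None else round(entry.mean_mm, 2),
            "n_lines_used": entry.n_lines_used,
        }
        g = grade_entries.get(code)
        if g is not None:
            rec.update(
                grade=g.grade,
                standard_mm=None if g.standard_mm is None else round(g.standard_mm, 2),
                loss_fraction=None if g.loss_fraction is None else round(g.loss_fraction, 4),
                status=g.status,
            )
        records.append(rec)
    return records


def write_report(
    report, path: str | Path, format: str = "json", grades=None, extra: Optional[dict] = None
) -> None:
    """Write a regional thickness report (JSON or flat CSV), mm at 2 dp.

    ``extra`` (JSON only) merges additional provenance fields — e.g. the
    slice spacing and demographics — into the top-level payload.
    """
    path = Path(path)
    records = _report_records(report, grades)
    if not records:
        warnings.warn(f"writing empty report to {path}", stacklevel=2)
    if format == "json":
        payload = {
            "compartment": report.compartment.name if report.compartment else None,
            "regions": {r["region"]: {k: v for k, v in r.items() if k != "region"} for r in records},
        }
        if extra:
            payload.update(extra)
        path.write_text(json.dumps(payload, indent=2) + "\n")
    elif format == "csv":
        columns = ["region", "mean_mm", "n_lines_used"]
        if grades is not None:
            columns += ["grade", "standard_mm", "loss_fraction", "status"]
        pd.DataFrame(records, columns=columns).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_report(path: str | Path):
    """Read a JSON report written by :func:`write_report`."""
    from .regions import RegionEntry, RegionThicknessReport

    data = json.loads(Path(path).read_text())
    entries = {}
    for name, rec in data.get("regions", {}).items():
        entries[RegionCode(name)] = RegionEntry(
            mean_mm=rec.get("mean_mm"), n_lines_used=int(rec.get("n_lines_used", 0))
        )
    compartment = Compartment[data["compartment"]] if data.get("compartment") else None
    return RegionThicknessReport(entries=entries, compartment=compartment)
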