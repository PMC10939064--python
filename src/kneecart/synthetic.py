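"""Synthetic phantoms with analytically known thickness.

The generator emulates single-slice cartilage segmentations: a half-annulus
arc stands in for femoral cartilage wrapping a condyle, and a flat slab for
tibial cartilage on the plateau. Truth is defined analytically from the
spec (ring width or slab height times spacing), never measured from the
raster, so it is an independent oracle for the measurement pipeline.
Optional boundary jitter emulates segmentation wear; optional speckles
emulate the small spurious components that cleanup must remove.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple, Union

import numpy as np
import pandas as pd
import pydicom
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .errors import InputError
from .io_formats import DicomMeta, LabelMask
from .regions import CohortCase, ReferenceTable
from .types import Bone, Compartment, RegionCode, Sex, Side, Third, region_code

KIND_HALF_ANNULUS = "half_annulus"
KIND_SLAB = "slab"
KIND_COMPOSITE = "composite"


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic slice.

    Annulus radii are in pixels and are converted to millimetres through
    the row spacing, so the rasterised ring is circular in physical space
    (elliptical in pixels under anisotropic spacing) and its physical
    width is exactly ``(outer_radius - inner_radius) * row_spacing``.
    """

    kind: str = KIND_COMPOSITE
    height: int = 256
    width: int = 256
    centre: Tuple[int, int] = (100, 128)  # annulus centre (row, col), px
    inner_radius: float = 40.0  # px
    outer_radius: float = 50.0  # px
    slab_top: int = 190  # first slab row
    slab_height: int = 10  # px
    slab_cols: Tuple[int, int] = (40, 215)  # inclusive column range
    row_spacing: float = 0.4  # mm/px
    col_spacing: float = 0.4  # mm/px
    noise_px: float = 0.0  # boundary jitter amplitude, px
    n_speckles: int = 0
    speckle_px: int = 4  # pixels per spurious component
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in (KIND_HALF_ANNULUS, KIND_SLAB, KIND_COMPOSITE):
            raise InputError(f"unknown phantom kind {self.kind!r}")
        if not 0 < self.inner_radius < self.outer_radius:
            raise InputError("need outer_radius > inner_radius > 0")
        if self.slab_height < 1:
            raise InputError("slab height must be >= 1 px")
        if self.row_spacing <= 0 or self.col_spacing <= 0:
            raise InputError("pixel spacing must be positive")
        margin = math.ceil(self.noise_px)
        if self.kind in (KIND_HALF_ANNULUS, KIND_COMPOSITE):
            r0, c0 = self.centre
            reach = self.outer_radius * self.row_spacing
            reach_rows = reach / self.row_spacing + margin
            reach_cols = reach / self.col_spacing + margin
            if (
                r0 + reach_rows >= self.height
                or c0 - reach_cols < 0
                or c0 + reach_cols >= self.width
                or r0 < 0
            ):
                raise InputError("annulus exceeds the image")
        if self.kind in (KIND_SLAB, KIND_COMPOSITE):
            if (
                self.slab_top < 0
                or self.slab_top + self.slab_height + margin > self.height
                or self.slab_cols[0] < 0
                or self.slab_cols[1] >= self.width
                or self.slab_cols[0] >= self.slab_cols[1]
            ):
                raise InputError("slab exceeds the image")


@dataclass(frozen=True)
class PhantomTruth:
    """Analytic ground truth for a phantom slice."""

    femoral_mm: Optional[float]
    tibial_mm: Optional[float]
    femoral_lines: Optional[np.ndarray]
    tibial_lines: Optional[np.ndarray]
    region_mm: Dict[RegionCode, float]
    compartment: Compartment


def _rasterize_annulus(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    r0, c0 = spec.centre
    rows = (np.arange(spec.height) - r0)[:, None] * spec.row_spacing
    cols = (np.arange(spec.width) - c0)[None, :] * spec.col_spacing
    dist = np.hypot(rows, cols)
    inner_mm = spec.inner_radius * spec.row_spacing
    outer_mm = spec.outer_radius * spec.row_spacing
    if spec.noise_px > 0:
        # per-angle radius perturbation: reproducible "wear" of the outer edge
        n_bins = 72
        jitter = rng.uniform(-spec.noise_px, spec.noise_px, n_bins) * spec.row_spacing
        angle = np.arctan2(rows, cols)  # [-pi, pi]
        bins = ((angle + np.pi) / (2 * np.pi) * n_bins).astype(int) % n_bins
        outer = outer_mm + jitter[bins]
    else:
        outer = outer_mm
    lower_half = np.arange(spec.height)[:, None] >= r0
    return (dist >= inner_mm) & (dist <= outer) & lower_half


def _rasterize_slab(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    out = np.zeros((spec.height, spec.width), dtype=bool)
    c0, c1 = spec.slab_cols
    if spec.noise_px > 0:
        jitter = np.rint(rng.uniform(-spec.noise_px, spec.noise_px, c1 - c0 + 1)).astype(int)
    else:
        jitter = np.zeros(c1 - c0 + 1, dtype=int)
    for offset, j in enumerate(jitter):
        bottom = spec.slab_top + max(1, spec.slab_height + j)
        out[spec.slab_top : bottom, c0 + offset] = True
    return out


def _place_speckles(
    pixels: np.ndarray, spec: PhantomSpec, rng: np.random.Generator
) -> None:
    """Scatter small spurious components (below typical cleanup thresholds)."""
    side = max(1, math.ceil(math.sqrt(spec.speckle_px)))
    h, w = pixels.shape
    for _ in range(spec.n_speckles):
        cls = int(rng.integers(1, 3))
        for _attempt in range(200):
            r = int(rng.integers(1, h - side - 1))
            c = int(rng.integers(1, w - side - 1))
            window = pixels[r - 1 : r + side + 1, c - 1 : c + side + 1]
            if (window == 0).all():
                block = np.zeros(side * side, dtype=np.uint8)
                block[: spec.speckle_px] = cls
                pixels[r : r + side, c : c + side] = block.reshape(side, side)
                break


def phantom_meta(spec: PhantomSpec) -> DicomMeta:
    """Metadata fixture consistent with the phantom raster.

    Slice 9 of a 36-slice right-knee stack sits in the first quarter of
    the stack, which the compartment convention maps to LATERAL.
    """
    return DicomMeta(
        row_spacing=spec.row_spacing,
        col_spacing=spec.col_spacing,
        rows=spec.height,
        cols=spec.width,
        laterality=Side.RIGHT,
        sex=Sex.M,
        slice_index=9,
        n_slices=36,
    )


def make_phantom(
    spec: PhantomSpec, n_lines: int = 36
) -> Tuple[LabelMask, DicomMeta, PhantomTruth]:
    """Rasterize a phantom slice and return it with metadata and truth."""
    rng = np.random.default_rng(spec.seed)
    pixels = np.zeros((spec.height, spec.width), dtype=np.uint8)
    femoral_mm: Optional[float] = None
    tibial_mm: Optional[float] = None
    if spec.kind in (KIND_HALF_ANNULUS, KIND_COMPOSITE):
        pixels[_rasterize_annulus(spec, rng)] = 1
        femoral_mm = (spec.outer_radius - spec.inner_radius) * spec.row_spacing
    if spec.kind in (KIND_SLAB, KIND_COMPOSITE):
        slab = _rasterize_slab(spec, rng)
        if (pixels[slab] != 0).any():
            raise InputError("slab overlaps the annulus; adjust the geometry")
        pixels[slab] = 2
        tibial_mm = spec.slab_height * spec.row_spacing
    if spec.n_speckles > 0:
        _place_speckles(pixels, spec, rng)

    meta = phantom_meta(spec)
    compartment = Compartment.LATERAL  # per phantom_meta stack position
    region_mm: Dict[RegionCode, float] = {}
    thirds = (Third.ANTERIOR, Third.CENTRAL, Third.POSTERIOR)
    if femoral_mm is not None:
        region_mm.update({region_code(Bone.FEMUR, compartment, t): femoral_mm for t in thirds})
    if tibial_mm is not None:
        region_mm.update({region_code(Bone.TIBIA, compartment, t): tibial_mm for t in thirds})
    truth = PhantomTruth(
        femoral_mm=femoral_mm,
        tibial_mm=tibial_mm,
        femoral_lines=None if femoral_mm is None else np.full(n_lines, femoral_mm),
        tibial_lines=None if tibial_mm is None else np.full(n_lines, tibial_mm),
        region_mm=region_mm,
        compartment=compartment,
    )
    return LabelMask(pixels), meta, truth


def write_dicom_fixture(meta: DicomMeta, path: str | Path, seed: int = 0) -> None:
    """Write a minimal metadata-only DICOM Part-10 file for the given meta."""
    file_meta = FileMetaDataset()
    file_meta.MediaStorageSOPClassUID = pydicom.uid.SecondaryCaptureImageStorage
    file_meta.MediaStorageSOPInstanceUID = generate_uid(entropy_srcs=[f"kneecart-{seed}"])
    file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=file_meta, preamble=b"\0" * 128)
    ds.SOPClassUID = file_meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = file_meta.MediaStorageSOPInstanceUID
    ds.Modality = "MR"
    ds.Rows = meta.rows
    ds.Columns = meta.cols
    ds.PixelSpacing = [meta.row_spacing, meta.col_spacing]
    ds.Laterality = "L" if meta.laterality is Side.LEFT else "R"
    ds.PatientSex = "M" if meta.sex is Sex.M else "F"
    ds.InstanceNumber = meta.slice_index + 1
    ds.ImagesInAcquisition = meta.n_slices
    ds.BodyPartExamined = "KNEE"
    ds.save_as(str(path), enforce_file_format=True)


def write_phantom(spec: PhantomSpec, out_dir: str | Path, stem: str = "phantom") -> Dict[str, Path]:
    """Write mask PNG + DICOM fixture + truth CSV for one phantom."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mask, meta, truth = make_phantom(spec)
    paths = {
        "mask": out_dir / f"{stem}.png",
        "dicom": out_dir / f"{stem}.dcm",
        "truth": out_dir / f"{stem}.truth.csv",
    }
    mask.save_png(paths["mask"])
    write_dicom_fixture(meta, paths["dicom"], seed=spec.seed)
    records = [
        {"region": code.value, "true_mm": round(value, 4)}
        for code, value in sorted(truth.region_mm.items(), key=lambda kv: kv[0].value)
    ]
    pd.DataFrame(records, columns=["region", "true_mm"]).to_csv(paths["truth"], index=False)
    return paths


CellSpec = Union[ReferenceTable, Mapping[Tuple[Sex, Side, RegionCode], Tuple[float, float]]]

#: round-robin demographic assignment order for synthetic cohorts
_GROUPS = [
    (Sex.M, Side.LEFT),
    (Sex.W, Side.LEFT),
    (Sex.M, Side.RIGHT),
    (Sex.W, Side.RIGHT),
]


def _normalize_cells(cells: CellSpec) -> Dict[Tuple[Sex, Side, RegionCode], Tuple[float, float]]:
    if isinstance(cells, ReferenceTable):
        return {key: (cell.mean_mm, cell.sd_mm) for key, cell in cells.cells.items()}
    return {key: (float(m), float(s)) for key, (m, s) in cells.items()}


def make_cohort(n: int, cells: CellSpec, seed: int = 0) -> List[CohortCase]:
    """Draw a synthetic healthy cohort of ``n`` cases.

    Per case, regional thickness is drawn from the stated per-cell normal
    distributions truncated at 0; sex/side are assigned round-robin over
    the four (sex, side) groups, so each group receives ~n/4 cases.
    """
    if n < 2:
        raise ValueError("cohort needs at least 2 cases")
    table = _normalize_cells(cells)
    rng = np.random.default_rng(seed)
    cases: List[CohortCase] = []
    for i in range(n):
        sex, side = _GROUPS[i % len(_GROUPS)]
        regions: Dict[RegionCode, float] = {}
        for (cell_sex, cell_side, region), (mean, sd) in table.items():
            if cell_sex is not sex or cell_side is not side:
                continue
            value = rng.normal(mean, sd)
            attempts = 0
            while value <= 0 and attempts < 100:  # truncate at 0
                value = rng.normal(mean, sd)
                attempts += 1
            regions[region] = max(value, 1e-6)
        cases.append(CohortCase(regions=regions, sex=sex, side=side))
    return cases
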