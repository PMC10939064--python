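# kneecart

Automated knee-cartilage thickness measurement and damage grading from
segmentation masks.

Loss of articular cartilage is the central feature of knee osteoarthritis,
and thickness measured on sagittal MRI is the quantity clinicians track —
but measuring it by hand, region by region, is slow. `kneecart` takes the
*output* of a cartilage segmentation (one RGB label image per slice:
femoral cartilage pure red, tibial cartilage pure blue) together with the
DICOM metadata of the original acquisition, and produces per-region
thickness in millimetres plus a 4-level damage grade. It is aimed at
researchers validating segmentation/morphometry pipelines and at anyone
who needs a transparent, testable reference implementation of line-based
cartilage morphometry.

## Method

For each slice the pipeline:

1. **Cleans** the label mask: 8-connected components smaller than
   `min_component_px` (default 20 px) are removed per class.
2. **Profiles** each bone with 36 measurement lines.
   *Femur*: the two arc endpoints (extreme-column foreground pixels) are
   joined; from the midpoint of that segment, 36 rays are cast at 5°
   steps (offset half a step) sweeping the half-plane containing the
   cartilage. *Tibia*: 36 vertical lines at evenly spaced columns between
   the two side endpoints. Per line, thickness is the physical length of
   the longest contiguous in-cartilage run,
   `t_i = |run_i| · Δs` with Δs from the DICOM `PixelSpacing`
   (anisotropy-aware; sub-pixel ray sampling at 0.1 px).
3. **Averages** lines 1–12, 13–24 and 25–36 into the anterior, central
   and posterior thirds, yielding up to 6 of the 12 WORMS-style
   subregions per slice ({F,T} × {M,L} × {A,C,P}, e.g. FMA = anterior
   medial femur).
4. **Grades** each region against a sex- and side-specific standard
   thickness S (remaining thickness m): grade 4 if m < ε (≈ one pixel:
   bone exposed), grade 3 if m ≤ S/2, grade 2 if m < (1−τ)·S, else
   grade 1 (normal, tolerance τ = 10 %).

A packaged reference table provides the femoral standards (mean ± SD per
sex/side/region from a healthy cohort aged 20–45); tibial cells ship as an
explicitly empty placeholder to be filled from your own cohort with
`build_reference`. Evaluation utilities implement DSC, IoU, MAPE, grading
accuracy and Bland–Altman agreement, and a synthetic phantom generator
(half-annulus arcs, flat slabs, boundary jitter, speckle) provides
analytically known ground truth so the whole pipeline is testable without
clinical data.

## Worked example

Measure and grade a synthetic worn femoral arc (true thickness
4 px × 0.4 mm/px = 1.6 mm, roughly 20 % below the packaged standards):

```python
from kneecart import (PhantomSpec, RunConfig, grade_report,
                      load_default_reference, make_phantom, measure_slice)

spec = PhantomSpec(kind="half_annulus", inner_radius=46, outer_radius=50,
                   row_spacing=0.4, col_spacing=0.4)
mask, meta, truth = make_phantom(spec)
result = measure_slice(mask, meta)
grades = grade_report(result.report, load_default_reference(),
                      meta.sex, meta.laterality, RunConfig(),
                      row_spacing=result.spacing[0])
for code, entry in sorted(result.report.entries.items()):
    g = grades.entries[code]
    print(f"{code.value}: measured {entry.mean_mm:.2f} mm "
          f"(true {truth.region_mm[code]:.2f}), "
          f"standard {g.standard_mm:.2f}, grade {g.grade}")
```

prints

```
FLA: measured 1.70 mm (true 1.60), standard 2.30, grade 2
FLC: measured 1.68 mm (true 1.60), standard 2.06, grade 2
FLP: measured 1.70 mm (true 1.60), standard 1.98, grade 2
```

The slice (number 10 of a 36-slice right-knee stack) maps to the lateral
compartment; the measured means sit within one pixel spacing (0.4 mm) of
the analytic truth, and each region grades 2 — damaged, but more than
half of the standard thickness remains.

The same pipeline is available from the shell:

```sh
kneecart simulate --out fixtures --n 2
kneecart measure --masks fixtures --dicom fixtures --out reports
kneecart grade   --report reports/phantom_000.thickness.json --out graded.json
kneecart evaluate --pred fixtures --ref fixtures --out metrics.json
```

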