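# Methods

## Model and assumptions

`kneecart` measures articular cartilage thickness on single sagittal
slices from class-labelled rasters (background / femoral cartilage /
tibial cartilage). It assumes:

- cartilage has been segmented upstream; labels are pure colours
  (femur (255,0,0), tibia (0,0,255)), decoded by exact colour match with
  an optional per-channel tolerance for lossy re-encodes;
- thickness runs from the articular surface to the tidemark, i.e. the
  full labelled band is cartilage;
- one sagittal slice shows one compartment (medial or lateral);
- physical calibration comes from the DICOM `PixelSpacing` of the source
  acquisition. When the mask was produced at a different working
  resolution than the acquisition matrix, the class raster is **never**
  resampled (interpolating labels corrupts them); instead the spacing is
  rescaled by `rows/mask_height` and `cols/mask_width`
  (`effective_spacing`).

## Measurement geometry

**Cleanup.** Per class, 8-connected components under `min_component_px`
are deleted. 8-connectivity is used because thin oblique cartilage rims
fragment under 4-connectivity. The threshold (default 20 px) is a package
choice — small enough to keep genuine thin cartilage at 0.3–0.5 mm/px
spacings, large enough to remove segmentation speckle — and is exposed in
the configuration. Classes are cleaned independently so a speck of one
class cannot survive by touching a large component of the other. The
operation is idempotent and never adds foreground.

**Endpoints.** A bone's two endpoints are its extreme-column foreground
pixels (ties broken by the smaller row). For a sagittal cartilage arc or
slab these are its two anatomical ends. This definition ties the
measurement frame to the image column axis; acquisitions rotated by 90°
are out of scope.

**Femoral profile.** The origin is the midpoint of the segment joining
the endpoints. 36 rays at 5° increments sweep the half-plane on the side
of the endpoint line containing the foreground centroid. Angles are
offset by half a step (2.5°, 7.5°, …, 177.5°) so no ray is parallel to
the endpoint line, where a tangent ray would report an arbitrarily long
chord. The sweep starts at the image-left endpoint, so line 1 is on the
image-left side for both bones. Rays are marched in physical (mm) space
at `ray_sample_step` (default 0.1 px, converted through the smaller
spacing); each sample is assigned to the pixel containing it under the
half-open convention `pixel r owns [r−0.5, r+0.5)` (implemented as
`floor(x+0.5)`; round-half-even would let boundary samples be claimed by
both neighbours). Thickness is the physical length of the **longest
contiguous** in-cartilage run — not the total foreground count, because a
ray can clip a curved arc twice and total counting would double-count.
Sub-pixel sampling converges to the true chord length on oblique rays and
reduces to pixel counting on axis-aligned lines (agreement within one
sample step, property-tested); a strict integer pixel-point mode remains
available (`count_mode: "pixels"`). Note that rays measure *along-ray*
length; for the femur the rays are radial and hence approximately
boundary-normal, which is the intended regime.

**Tibial profile.** 36 vertical lines at columns
`c_i = c_min + (i−1)(c_max − c_min)/35`, rounded to the nearest integer
column (inclusive spacing between the two side endpoints). Vertical lines
need no sub-pixel sampling: thickness is the longest vertical pixel run ×
row spacing, exact by construction.

**Missing lines.** A line that intersects no cartilage is recorded as
MISSING and excluded from region averages — out-of-field geometry is not
evidence of full-thickness loss. A region whose every line is MISSING is
itself MISSING. The `missing_as_zero` flag restores the alternative
reading (absent = worn to zero), which also makes missing regions grade 4.

## Regional mapping

Line blocks 1–12 / 13–24 / 25–36 average into the anterior / central /
posterior thirds, mapped to codes {F,T}{M,L}{A,C,P}. Which end of the
sweep is anterior depends on acquisition orientation, not on knee side,
so `anterior_is_left` is a single configuration flag (default true,
per-file overridable); when false, A and P swap.

Which compartment a slice shows is inferred from its stack position: with
fraction `f = slice_index/(n_slices−1)`, `f ≤ 0.375` is the quarter-1
position and `f ≥ 0.625` the quarter-2 position; a right knee maps
quarter-1 → lateral and quarter-2 → medial, a left knee the reverse.
Slices in the central half are ambiguous and require an explicit
compartment. This convention table is a package decision — acquisition
protocols differ in sweep direction — and should be confirmed once per
site; the override always wins.

## Reference table and grading

`build_reference` aggregates per-case regional means into per-(sex, side,
region) cells as mean and sample SD (n−1); subjects, not individual
lines, are the unit of aggregation, matching how normative cohorts are
reported. Cells with fewer than 2 cases are left unpopulated. The
packaged femoral table covers all 24 femoral cells; the tibial file is an
explicitly empty placeholder — fabricating standards would silently
corrupt grading, so tibial regions report UNGRADED until the user
supplies a cohort.

`reference_mean` (the per-bone average of cell means, unweighted across
cells) is computed in decimal arithmetic with half-up rounding at 2 dp:
the cells are exact 2-dp decimals, and float rounding can misprint means
that land exactly on a half (the packaged femoral mean is exactly
1.9775 → 1.98).

Grading maps remaining thickness m against the regional standard S with
two auxiliary parameters the underlying clinical scales leave
unobservable from a cartilage-only mask:

- **τ = `grade1_tolerance`** (default 0.10): thickness alone cannot see
  grade-1 signal abnormality, so "normal thickness" is a band
  m ≥ (1−τ)·S. τ = 0 makes grades 1 and 2 meet exactly at m = S.
- **ε = `grade4_epsilon`** (default: one row spacing, resolved per
  slice): "exposed subchondral bone" is proxied by a sub-pixel residual,
  m < ε.

Thresholds are applied in the order 4 → 3 → 2 → 1
(`m < ε`, `m ≤ S/2`, `m < (1−τ)·S`, else 1), so the four intervals
partition [0, ∞) for every parameter combination — including degenerate
ones such as ε > S/2, where the grade-3 band is simply empty — and the
grade is non-increasing in m. "Less than half of normal thickness" is
read as *remaining* thickness ≤ S/2 (boundary → grade 3), the monotone
reading of the lesion-depth semantics.

## Synthetic phantoms

`make_phantom` rasterises a half-annulus (femoral class) whose flat side
lies on the endpoint line, and/or a rectangular slab (tibial class).
Truth is **analytic** — ring width or slab height × row spacing — never
measured from the raster, so it stays independent of the code under
test. Annulus radii are given in pixels and converted to mm through the
row spacing; the raster is drawn in physical space, so under anisotropic
spacing the ring is elliptical in pixels but its physical width is exact.
Boundary "wear" is a seeded per-angle (annulus) or per-column (slab)
jitter of the outer edge; speckle components are placed with a 1-px
clearance from real structures and sized below the cleanup threshold.
The metadata fixture places the slice at position 10 of a 36-slice
right-knee stack (lateral compartment under the convention above).

What the phantoms do **not** emulate: MRI intensities and artefacts,
realistic condyle shape, partial-volume boundaries, inter-slice context,
or correlated segmentation error. Passing the recovery tests therefore
demonstrates the *measurement* chain is correct given a segmentation, not
that any segmentation is accurate.

`make_cohort(n, cells, seed)` draws per-case regional thickness from
per-cell normal distributions truncated at 0, with sex/side assigned
round-robin (n total cases → n/4 per demographic group), fully seeded.

## Numerical choices and problem sizes

- Ray sampling 0.1 px: quantisation error one sample step per run,
  bounded by the property tests.
- Endpoint ties and the centroid side-test break ties deterministically
  (smaller row; positive-normal side), so identical inputs give
  byte-identical reports.
- Default test and validation sizes: 256×256 phantoms, 100-mask oracle
  sweeps, 1000-tuple grading scans, 800-case cohorts (200 per cell) —
  sizes at which the statistical tolerances (0.05 mm on recovered cell
  means ≈ 2.4 SE) are meaningful while the whole suite runs in seconds.

## Known limitations

- Measurement is 2D per slice; no 3D thickness mapping across the stack.
- Along-ray length slightly overestimates normal thickness where rays are
  not boundary-normal (documented 45° example: 10-px slab reads √2×
  taller along the diagonal).
- The compartment convention and the anterior-side flag encode
  acquisition conventions the data format does not carry; both are
  overridable and should be validated per protocol.
- True grade-1 lesions (signal change at preserved thickness) and actual
  subchondral bone state are not observable from a cartilage-only mask.
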