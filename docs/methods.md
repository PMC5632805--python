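# Methods

This note documents the models, conventions and numerical choices behind
`phenowell`, in the order data flows through the package.

## Coordinate conventions and plate geometry

Plate coordinates are physical millimetres, origin at the top-left plate
corner, x right, y down; image pixels are 0-based, row-major, origin
top-left, with points written (x, y) = (column, row).  Wells are numbered
**column-wise** starting at the top-left well (`linear_index =
(col − 1)·n_rows + row`), numbering down each column with columns left to
right.  The anchoring of well #1 at the top-left corner is a package
convention: well-plate vendors and plate readers disagree on the origin
corner, and nothing in per-well summary outputs disambiguates it, so it is
fixed here once and exposed through the layout API rather than hidden.

Built-in layouts use the ANSI/SLAS microplate footprint (127.76 mm ×
85.48 mm) with typical vendor well pitches and radii for the 6- (2×3), 12-
(3×4) and 24-well (4×6) formats.  All geometry is overridable through a
YAML layout file; the invariants (wells disjoint, wells inside the plate
rectangle) are enforced at construction.

## Fiducial template

Four blue tray marks anchor registration: three just outside the plate
corners (top-left, top-right, bottom-right) and one at mid-height on the
left edge, each a disc of radius 2.5 mm centred 6 mm outside the plate
rectangle.  The asymmetry is deliberate: with marks at all four corners the
mark set is invariant under a 180° rotation, so a flipped registration
would fit the marks perfectly *and* pass the green-outside-wells check
(the well grid also maps onto itself), silently permuting every well label.
Breaking the symmetry makes the wrong orientation geometrically poor and
therefore rankable.

## Lens distortion

Radial distortion uses the single-coefficient division model about the
image centre: an observed point at radius `r_d` maps to the undistorted
point `p_u = c + (p_d − c)/(1 + k·r_d²)`, `k` in px⁻².  The model was
chosen because its forward map has a closed algebraic form (solving
`k·r_u·r_d² − r_d + r_u = 0` for the root continuous at k = 0), so the
synthetic generator can apply exactly the distortion the corrector inverts
and round-trip accuracy is testable analytically.  Correction resamples
bilinearly; `k` is a camera property supplied through configuration (no
published value exists for the original optics), with k = 0 an exact
identity.  Invertibility requires `1 − 4k·r² ≥ 0` over the raster; the
corrector rejects larger k.

## Registration with ranked candidates and validated retry

Blue marks are segmented by the same HSV band logic as plants (hue band
around blue, minimum saturation), connected components below 40 px are
discarded, and up to the 8 largest centroids enter the correspondence
search.  Every assignment of min(n, 4) detected marks to template positions
is fitted with a least-squares similarity transform; candidates are scored
by normalised inverse RMS residual, near-duplicates (within ~1 px/10⁻³ rad
in parameters) are merged, and the list is returned sorted.  "Plausibility"
is thus an explicit residual-based score, not a calibrated probability — no
probabilistic model of mark detection is available to justify more.

The measurement loop tries candidates in rank order: correct → register →
crop → segment → validate.  Validation accepts a candidate only if at most
`outside_tolerance` plant pixels (default 0, counted after the
component-size filter) lie outside the union of well discs — the
self-check that a registration mistake almost always throws green area
outside the wells.  If every candidate fails, the best-scoring croppable
candidate is returned flagged invalid for manual review rather than raising,
since a production run must not stop on one bad image.

The crop covers exactly the plate rectangle at a configurable resolution
(`crop_px_per_mm`).  Its default is the *nominal* scale at which the plate
plus a 12 mm fiducial margin fills the input raster; the synthetic renderer
uses the same convention, so measured pixel counts are directly comparable
to generated ground truth without a calibration step.  On real data this
scale is arbitrary but consistent across images of one run, which is all
that ratio- and rank-based downstream statistics require.

## Segmentation

Plant pixels satisfy H ∈ [35, 90] (0–179 half-degree scale), S ≥ 60 and
V ∈ [40, 255] (0–255), combined with logical AND — a standard
green-vegetation band against a white background, where sophistication is
unnecessary.  The only post-processing is removal of connected components
smaller than 5 px: raw sensor noise occasionally produces isolated
in-band pixels, and a literal zero-tolerance outside-wells check would
otherwise reject sound registrations.  All cut-offs are configuration,
not constants; the defaults are exercised against the generator's colour
model, which deliberately samples hues wide enough (green 120° ± jitter,
blue ≈ 240°) that misconfigured bands fail the tests.

## Synthetic plates

The renderer builds an ideal raster (near-white background with slight
texture, grey well rims, blue fiducial discs, green rosette blobs), then
resamples it **once** by nearest neighbour through the composed inverse of
the applied similarity pose and distortion, and finally adds clipped
Gaussian sensor noise (default sd 3 intensity levels).  Rosettes are
star-shaped blobs — a disc modulated by 4–8 angular lobes with random
phase and amplitude — whose pixels are admitted in order of increasing
normalised radius, so the per-well pixel count is *exact* and monotone in
the requested area.  Ground-truth areas are therefore defined in the
undistorted, untransformed frame, and a measured area differs from truth
only through the resampling chain, which is what an end-to-end accuracy
figure should include.

Random plate poses draw scale 0.88–0.97 of nominal, rotation ±3°,
translation ±1% of the short image side, and dimensionless distortion
k·r²_max ∈ [0, 0.03] — magnitudes representative of a fixed overhead camera
with mild barrel distortion while keeping all fiducials on the raster (the
renderer verifies this and refuses poses that clip a mark).  The default
raster is 2500 × 2000 px, the native camera resolution of the platform
this emulates; tests and the acceptance sweep render at 1000 × 800 with
areas scaled accordingly, a choice of problem size for the suite, with
full-resolution conformance checked separately.

The generator does **not** emulate: leaf-level morphology, shadows, foil
condensation and specular highlights, chlorosis/senescence colour shifts,
plants overhanging well boundaries, or agar discolouration.  Passing the
end-to-end suite therefore demonstrates correctness of the geometry,
segmentation and accounting chain under controlled nuisance, not
robustness to every artefact of real imagery; on real data the HSV bands
and mark thresholds are expected to need per-setup tuning.

## Growth simulation

Each plant follows `A(t) = A₀·exp(r_eff·t)·exp(ε_t)`, with `A₀ ~
N(300, 60²)` px truncated at 50 px, `ε_t ~ N(0, 0.1²)` per observation, and
`r_eff = baseline_rgr × factor(treatment)`.  The baseline RGR of
0.40 day⁻¹ and the starting area reproduce control rosettes growing from a
few hundred to several thousand pixels over nine days of daily imaging, the
regime of the assay this package targets.  Treatment factors (1.0, 0.85,
0.70, 0.44, 0.16 for control through 150 mM NaCl) mirror a salt
dose-response in which severe stress cuts the growth rate by more than
half within days; mortality is a per-day Bernoulli hazard (0.07 day⁻¹ at
the highest dose, giving ≈50% survival by day nine), and death is
absorbing with area 0 thereafter — matching how a dead, fully chlorotic
rosette disappears from the green mask.  These defaults are the simulated
study conditions and are fixed; anything else is configurable per
experiment.

## Growth statistics

* **RGR** is the classical `(ln A₂ − ln A₁)/(t₂ − t₁)` per sampling
  interval.  Intervals touching a zero area yield NaN (a dead plant has no
  growth rate) rather than raising, so population summaries degrade
  gracefully.
* **Exponential fits** are OLS of ln A on t over strictly positive areas
  (≥3 points required); reported are A₀, r, Pearson's r of the linearised
  pairs, and the regression F-test p-value.  In simple regression the
  F-test and the slope t-test coincide, which is how "significance after
  linearisation" is interpreted here.
* Group curves report the arithmetic mean ± SE (sd/√n, ddof = 1) on a
  shared time grid; heterogeneous grids are an error rather than silently
  interpolated.
* **Survival** counts a plant dead from the first time-point its area is at
  or below `death_threshold` (default 0 px — strictly positive area means
  alive), and keeps it dead regardless of later segmentation flicker.
* **Quartiles** use linear interpolation between order statistics (the
  default convention of mainstream numeric stacks); this is stated because
  published per-day quartile tables depend on the convention.  SE of a
  single observation is reported as 0.
* Where a per-group RGR curve is needed, per-plant RGR values are averaged
  (rather than taking the RGR of the group mean curve); both orders agree
  exactly for noiseless exponentials and the per-plant route keeps dead
  plants from biasing the group value.

## Group inference

Kruskal–Wallis is implemented directly — mid-ranks for ties, the standard
tie-correction factor on H, p from χ²(k − 1) — rather than delegated, so
the degenerate all-tied case can return H = 0, p = 1 (no evidence of
difference) instead of an undefined ratio.  The implementation is
cross-checked against an independent library routine on non-degenerate
data in the tests.

The Conover–Iman post-hoc uses rank means with the pooled rank variance
`S² = (ΣR² − N(N+1)²/4)/(N−1)`, the factor `(N−1−H)/(N−k)`, and two-sided
p-values from Student's t on N − k df.  P-values are **unadjusted by
default** with Holm correction available by option: per-day letter tables
in this assay tradition are typically drawn from unadjusted pairwise
tests, and the safer choice is exposed rather than imposed.  Each day is
tested separately; no across-day multiplicity control is attempted.

Letter displays use insert-and-absorb: one letter column initially holds
all groups; each significant pair splits every column containing both
members; subset columns are absorbed; columns are lettered in
descending-median order so the largest-median group always carries "a".
The algorithm guarantees the defining property — two groups share a letter
iff their pairwise p ≥ α — which the tests verify exhaustively over all
significance patterns for up to five groups.

## Tabular conventions

Image filenames encode acquisition time and camera position as
`<YYYYMMDD>T<HHMMSS>_x<int>_y<int>.png`; parsing and formatting round-trip
exactly.  Results tables (XLSX and CSV twins) carry exactly filename,
date, x, y, area_1…area_n with wells column-wise.  Plate identity is
recovered from the camera (x, y) through an explicit position→plate map in
the design file — the platform database that originally served this role
is replaced by configuration.  `time_from_start` is fractional days since
the earliest acquisition of the experiment, so a "day d" of daily imaging
corresponds to offset d − 1.

## Known limitations

* A similarity transform cannot absorb perspective or anisotropic scale;
  strongly off-axis cameras would need a homography.
* Well areas are counted in whole pixels inside hard disc boundaries;
  rosettes overhanging a well rim are truncated.
* The empty-well / dead-plant distinction does not exist at image level —
  both yield area 0; the design file is the only source of occupancy.
* Segmentation thresholds are global per run; strong illumination
  gradients across the table are not modelled or corrected.
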