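# Methods

This note documents the models, conventions, parameters and design
choices behind `dxarfa`, and what the synthetic experiments do and do not
demonstrate.

## Coordinate conventions

Rasters are `(row, column)` arrays, 0-based, row 0 proximal; physical
coordinates are millimetres with pixel centres at half-integer offsets
(`x = (c + 0.5)·pixel_width`, `y = (r + 0.5)·pixel_height`).  The
canonical orientation is a right hip with the lateral aspect (greater
trochanter) at small x; left-hip scans are mirrored into this frame before
landmarking and registration, so a single rotation-only Procrustes
alignment suffices.  Anisotropic pixel spacing is carried in metadata, but
the generator emits isotropic 0.56 mm pixels, the mean pixel size of the
scans the method was developed for.

## Synthetic phantom and cohorts

The phantom is a geometric stand-in for a post-operative proximal-femur
DXA scan, not an X-ray physics simulation.  Its silhouette (shaft, greater
and lesser trochanter, neck-resection cut) holds ≈14,000 pixels in
bone ∪ prosthesis at 0.56 mm spacing.  Value ranges follow typical
post-operative baseline scans: cancellous 0.5–1 g/cm², cortical shaft 2–3 g/cm²,
stem/cement up to 4 g/cm², soft tissue near zero.  Values are smoothed
within the bone compartment (Gaussian, σ = 1.3 mm) to emulate
partial-volume transitions between cortical and cancellous bone; the
nominal ranges therefore hold per pixel on interior "core" masks
(`Phantom.tissue_cores`) outside the transition bands, while compartment
boundaries stay sharp.

Subject anatomy is a random smooth deformation of the phantom, constant
across visits.  The deformation is affine-dominated — rotation
U(±1.5°), per-axis log-scale sd 2%, shear sd 1%, translation sd 1 mm per
axis — plus a low-amplitude smooth residual sampled on a ~15 mm control
grid (node sd 5% of `shape_jitter_mm`) and upsampled with a cubic spline.
All components scale with `shape_jitter_mm` (default 2 mm, giving typical
displacements of a couple of mm).  The affine dominance is deliberate:
subject-to-subject femoral variation is mostly size/aspect/orientation,
and a 16-landmark TPS can only capture deformations of roughly that
complexity; planting large non-affine variation would test the generator,
not the method.

Lesions act multiplicatively: inside the footprint, BMD is scaled by
`1 + magnitude_pct/100 · time_profile(visit)` (profile linear in months by
default).  The footprint starts from a named template zone (or polygon)
and is grown/shrunk by signed Euclidean distance until it holds exactly
`round(target_area_fraction · n_bone)` pixels, so ground truth is exact
before noise.  Pixel noise is i.i.d. Gaussian, sd 0.05 g/cm² (default),
added per visit in scan space and clipped at zero; pixel-level
precision figures are not available for this scan mode, so this default was chosen to put
single-pixel longitudinal SD on the order of reported DXA precision and
is configurable.  Repositioning pairs apply two independent rigid motions
(rotation ≤ 2°, translation ≤ 2 mm) and noise draws to one subject's
anatomy; their true change field is identically zero.

Everything is driven by one `numpy` Generator seeded from the spec, so
identical specs give bitwise-identical cohorts.

## Segmentation

Fixed operator order: Gaussian-smoothed gradient-magnitude edge map
(σ = 1.5 px) refines threshold boundaries (pixels on strong edges — above
0.15 of the maximum edge magnitude — are classified by their raw value,
elsewhere by the smoothed value, which suppresses isolated noise);
threshold 3.5 g/cm² → prosthesis candidates; threshold 0.25 g/cm² on the
rest → bone; morphological opening then closing (disk radius 2 px);
components under 50 px dropped; prosthesis holes filled.  All five numbers
are package defaults exposed in configuration; on the coarse 0.94 mm
validation grid the morphology scales down (radius 1 px, minimum 20 px) so
the ~3 mm cortical band survives opening.  Cement is assigned to the
prosthesis compartment; this affects baseline maps only, never the
longitudinal statistics, which live on bone pixels.  Scans with an empty
bone compartment after cleanup are excluded and logged, never imputed.

## Landmarks and registration

Sixteen points per scan, ordering = correspondence: prosthesis tip,
prosthesis shoulder, greater-trochanter apex, lesser-trochanter apex, and
medial + lateral bone-boundary points at six evenly spaced heights between
the greater-trochanter apex and the prosthesis tip.  The anatomical
definitions are a package convention (declared precisely for
reproducibility) with three stabilisations against pixel quantisation:
detection runs in a prosthesis-aligned frame (the stem's principal axis is
rotated to vertical first), extreme points are centroids of a ~2 mm cap at
the extremum rather than single pixels, and boundary columns are refined
to subpixel precision by interpolating the intensity crossing of the bone
threshold, averaged over a ±1.5 mm row band.  A control band that would
collide with an anatomic landmark (e.g. the lesser-trochanter apex) is
shifted by a row.

GPA iterates similarity alignment (translation, rotation, uniform scale;
least squares, proper rotations) against a consensus renormalised to unit
centroid size each round; tol 1e-6, max 100 iterations, warning and last
iterate on non-convergence.  The template grid uses the cohort's mean
centroid size with a 15% margin, plus a 50% distal margin in y: the
landmarks span only trochanter-to-tip while the scanned field continues
~2.5 cm of shaft distal to the tip, and the template must cover it (this
also makes the area denominator match the full periprosthetic bone area).
The template bone mask is the ≥50% majority vote of registered baseline
bone masks.

Warping is backward: a TPS (kernel U(r) = r²·log r², exact interpolation,
no regularisation, affine part) fitted from template landmarks to scan
landmarks carries each template pixel centre into the scan, where BMD is
interpolated with bone-masked bilinear weights (normalised convolution).
Masked interpolation never mixes soft-tissue or prosthesis values into
bone and preserves constants over bone exactly.  A pixel is available only
if it lands inside the scan, on the bone compartment (nearest-neighbour
label), with bone support > 0.25.  Values are treated as intensities — no
Jacobian (mass-preserving) correction is applied, matching a direct
reading of how percent change against baseline is reported.

### Registration accuracy

With 16 landmarks on a 0.56 mm grid, the end-to-end warp of a deformed
subject back onto the template carries ≈0.3–0.9 mm of residual
correspondence drift (extreme- and row-based landmark definitions are not
exactly affine-equivariant, and a double resampling alone contributes
≈0.02 g/cm² mean absolute error).  The measured mean absolute BMD
discrepancy at the default 2 mm jitter is ≈0.06–0.10 g/cm², concentrated
in the cortico-cancellous transition band; the regression test bounds it
at 0.12 g/cm².  This absolute error is largely irrelevant to the
longitudinal statistics: within a subject, baseline and follow-up warp
through nearly identical maps, so warp errors cancel in the paired
differences — which is why null calibration and lesion recovery are
unaffected.

## Pixel inference

Paired t-test per template bone pixel with at least
`min_subjects_per_pixel` (default 5) subjects available at both visits;
pixels below the minimum, or with zero-variance differences, are excluded
from the multiple-testing count N (and logged).  Two-sided p-values
throughout — gains and losses are read from the same map.  Percent change
is the mean over subjects of the subject-level relative change (not the
percent change of the mean), a documented choice where the table
convention is ambiguous.  BH q-values are `p(i)·N/i` along the increasing
sort with a downward cumulative minimum (both raw and monotone q are
retained; selection uses the monotone q, which equals the step-up set and
gives tied p-values identical q).  Summaries divide by the template bone
mask pixel count; empty significant subsets report 0.0 area and 0.0 mean
change, mirroring the usual "no change" row convention.  The
chi-squared areal comparison treats pixels as independent counts, as is
conventional in this framework; pixels are in truth spatially correlated, so its p-values
inherit that caveat and no spatial correction is attempted.

## Validation experiments and problem sizes

* **FDR control (repositioning null).** 29 same-day pairs per replicate,
  200 replicates, full pipeline, on a 0.94 mm grid (~5,000 template bone
  pixels; ~4,300 tested) so the study runs in minutes; the statistical
  behaviour under test does not depend on grid scale.  Observed: 1–2% of
  replicates contain any q ≤ 0.05 pixel (bound: 5% plus Monte-Carlo
  margin), mean false-discovery proportion ≪ α.
* **Null p-uniformity.** A no-lesion, noise-only cohort of 35 subjects at
  full resolution gives ~11,800 tested pixels with KS distance from
  uniform < 0.02.  At much smaller n (≈10–20) the per-subject variance
  heterogeneity induced by interpolation makes the one-sample t slightly
  non-exact (a Behrens–Fisher-type effect) and the KS distance grows to
  ~0.03–0.04; trial-sized cohorts are the intended regime.
* **Parameter recovery.** A −12% lesion over 15% of bone area, n = 35,
  default noise: recovered area within ±3 percentage points and mean
  change within ±2.  Registration scatter smears the lesion rim by ~1–2
  pixels; the BH selection picks up part of that rim, which is the main
  residual bias in recovered area.

What passing these experiments shows: the statistical chain (pairing,
t-test, BH, areal summary) is calibrated and powerful on data whose
deformations are within TPS capture and whose noise is Gaussian and
independent.  What they do not show: robustness to metal artefacts,
scanner drift, bone-map extraction errors, grossly non-affine anatomy, or
correlated noise — none of which the generator emulates.

## Degenerate inputs and numerical choices

TPS refuses collinear source landmarks (rank check) and needs ≥3 points;
GPA needs ≥2 configurations of equal cardinality; duplicate subject/visit
pairs and follow-up = baseline are input errors; subjects missing the
baseline visit are dropped and logged.  Ties in p use a stable sort.  The
chi-squared comparison returns exactly (0, 1) for identical groups and
logs a warning when an expected cell is below 1.  Stacks store BMD as
float32; statistics are computed in float64.
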