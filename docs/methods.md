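# Methods

## Geometric model

The tibiofemoral joint is modelled as two single-valued height fields over
a shared mediolateral/anteroposterior grid: the tibial superior bone
surface `z_t(x, y)` and the femoral inferior bone surface `z_f(x, y)`,
each with a cartilage thickness map (`c_t`, `c_f`, mm). The femoral surface
is constructed as the tibial surface offset by the cartilage stack plus a
residual (non-contact) gap, with an optional spherical condylar sagitta —
so a zero-curvature phantom is a pair of parallel plates with
`gap = c_t + c_f + residual gap` everywhere, and a curved phantom widens
away from each condyle apex by `R - sqrt(R² - r²)`. Compartments are
assigned by mediolateral thirds (medial | intercondylar | lateral), with
the medial side at low x.

Height fields were chosen over meshes deliberately: they make perpendicular
ray casting, silhouette projection and closed-form oracles tractable, and
they suffice for tibiofemoral JSW. Overhanging anatomy, ligaments and the
patellofemoral compartment are out of scope.

## Weight bearing

Loading a phantom does two things:

1. **Contact closure** — the femur settles rigidly by the largest amount
   that keeps the bone-to-bone gap at least the (compressed) cartilage
   stack everywhere; at the contact point the residual gap collapses to
   zero. Bone *shape* never changes.
2. **Cartilage compression** — both thickness maps shrink multiplicatively
   by `1 − δ · load · (1 − meniscal load share)`, where δ is the subject's
   deformability coefficient (fractional compression under full standard
   load, 0 ≤ δ < 1) and the meniscal load share is the fraction of load
   bypassing the cartilage (defaults 0.4/0.3/0.2/0.1 for extrusion grades
   0–3 — a more extruded meniscus carries less).

At zero load the phantom is returned unchanged (only flagged loaded): the
contact closure is treated as binary with any standing load, while
compression scales continuously with δ·load. The plates worked example
(1 + 1 mm cartilage, zero gap, δ = 0.2, full load, no meniscus) gives a
loaded bone-to-bone distance of 2·1·(1 − 0.2) = 1.6 mm.

## Measurements

**3D perpendicular median JSW.** From every defined tibial grid point a ray
is marched along the local unit normal (central-difference gradients) with
step 0.25 mm up to 15 mm; the first crossing of the femoral surface is
refined by bisection to ~1e-4 mm, ties resolved toward the smaller
distance. A sample is *reflected* iff a ray cast from its femoral hit point
along the femoral inward normal intersects the defined tibial surface
anywhere within the same range — a point-return criterion would exclude
almost everything on curved surfaces, so intersection anywhere is the
operative reading. The statistic is the median (mean also reported) over
samples that are hits, reflected, and inside the compartment region; at
least 10 included samples are required for a valid result.

**Compartment regions.** For total joint width W, each side's measurement
region is exactly (3/20)·W wide with its outer border (2/15)·W inside the
joint border (stored as exact fractions). The intercondylar area is
excluded implicitly. Since 2/15 + 3/20 ≈ 0.283 < 0.5 the regions can never
overlap.

**Projection and 2D JSW.** Pose standardization fits a least-squares plane
to the tibial superior surface (rotation 1: plane normal → +z), then
levels the femoral points, keeps the distal 40 % (avoiding shaft and rim
interference), splits them at the median x and takes the posterior-most
point of each half as the condylar landmarks (rotation 2 about z: condylar
line → x-axis). One rigid transform is applied to the whole volume; the
tibia–femur relation is never changed. The projection collapses the
repositioned volume along the anteroposterior axis — maximum intensity by
default, which for bright bone on a radiolucent background realizes the
silhouette identity (apparent gap at x = minimum gap over y); a `sum` mode
exists for attenuation-style experiments. A step wedge with 10 mm physical
steps is embedded in an appended bottom margin; pixel size is recovered as
step length / median detected step span, robust to a single corrupted
step. Edges are detected per column at sub-pixel precision by linear
interpolation of the intensity across the threshold; the framework places
two vertical joint borders (outermost defined columns) and two horizontal
reference lines, and the compartment mean JSW averages the tibia–femur
distance at four locations per region, at fractions {1/8, 3/8, 5/8, 7/8}
of the region width. The four-location rule follows the digital
radiographic analysis observable; the upstream software's exact positions
are not published, so the equally spaced fractions are this package's
choice, overridable by explicit coordinates.

**Cartilage thickness.** The MRI-style observable is per-point truth plus
i.i.d. Gaussian noise clipped at zero, measured only on unloaded phantoms
(a loaded phantom raises — thickness is a non-weight-bearing measurement).
The compartment mean pools tibial and femoral per-point values into one
average, so a phantom with 2 mm on each plate reads 2 mm thickness against
a ~4.4 mm bone-to-bone JSW; the average of plate means is reported
alongside since the two aggregations differ when plate coverage differs.
A mask-based path (`thickness_from_mask`) measures normal-direction ray
lengths through a binary cartilage mask for realism tests.

## Cohort simulation

Per subject: baseline MAC pooled thickness ~ N(2.0, 0.9²) truncated at
0.3 mm (Table-level magnitudes of an end-stage cohort), the lateral
compartment 1.0 mm thicker per plate (the contrast that makes the
most-affected-compartment rule stable under measurement noise);
deformability δ ~ N(0.15, 0.08²) clipped to [0, 0.5); meniscal extrusion
grade uniform in {0..3}, constant over time. The 2-year effect adds
e ~ N(0.2, 0.1²) mm to *both* plates, so the pooled mean thickness changes
by e and the bone-to-bone distance by 2e. δ drifts by N(0, 0.08²) over the
two years, independently of e — the hypothesized mechanism by which
weight-bearing change decouples from thickness change. All draws flow from
one seed; identical seeds give bit-identical cohorts.

Per-modality measurement noise (1 sd, mm): X-ray 0.4 (repositioning and
beam geometry dominate), 2D CT 0.25, 3D CT 0.15, MRI 0.1. These were fixed
by error-propagation before running the cohort studies: they keep every
cross-sectional correlation above 0.9 (between-subject spread ~0.9 mm
dwarfs the noise) while the longitudinal weight-bearing vs MRI correlation
(~0.2 expected) falls clearly below the 3D CT vs MRI correlation (~0.4
expected), reproducing the direction of the weight-bearing decoupling.

**Two measurement paths.** The *imaging* path runs render → segment →
extract surfaces → perpendicular field → reflect → median (3D) and
standardize → project → wedge → four-location mean (2D) exactly as a real
volume would be processed; it is used for end-to-end validation at small
n. The *fast* path applies the identical region geometry and estimators
directly to the phantom's analytic height fields (silhouette minimum per
column for 2D; gap-map median over the region for 3D, where the flat-ish
plateau makes perpendicular ≈ vertical). Cohort-scale studies (100 cohorts
× 100 subjects × 2 timepoints) use the fast path; full imaging at that
scale would be thousands of volume renders for no extra validity, since
the paths agree within a voxel on the geometries the cohort generator
produces (asserted in the test suite).

## Statistics

Pearson correlations for all six technique pairs, cross-sectionally
(both timepoints pooled, n = 2 × subjects) and longitudinally (per-subject
follow-up − baseline deltas, n = subjects); complete-case only, no
imputation, no multiplicity correction. p-values use the exact transform
t = R√(n−2)/√(1−R²) with n−2 df. Strength labels use the Evans bands on
|R| as half-open intervals [0, 0.2), [0.2, 0.4), [0.4, 0.6), [0.6, 0.8),
[0.8, 1] — the printed scale leaves 0.39–0.40 and 0.79–0.80 ambiguous;
0.40 → moderate and 0.80 → very strong here. Achieved power is estimated
by Monte Carlo (default 100,000 seeded bivariate-normal replicates of size
n, fraction with p < α) or a bias-corrected Fisher-z approximation
(mean z shifted by ρ/(2(n−1))); the two agree to ~0.005 at the study's
operating points. The most affected compartment is the side with the
smaller baseline weight-bearing JSW, ties to medial (logged) — the upstream
criterion is unstated, so this operationalization is documented rather than
claimed. The exclusion cascade counts each subject once, in the first
applicable category (treatment conversion, then missing CT, then motion
artefact).

`JswAgreementModel(table).fit()` wraps the analysis statsmodels-style: the
results object carries both matrices, `summary()`, `to_frame()`,
`achieved_power(pair)` and a scatterplot-matrix plot.

## Numerical choices and degenerate inputs

* Ray marching: coarse step then 30 bisection iterations (tolerance far
  below 1e-4 mm for any sane step); rays leaving the defined femoral
  domain or exceeding the range are misses; a ray starting at or through
  the opposing surface is an immediate hit at distance 0.
* Surface extraction takes the first bone crossing per column (top of
  tibia, bottom of femur), ignoring internal cavities; sub-voxel
  refinement interpolates the rendered partial-volume intensity profile
  across the threshold and is exact when both bracketing voxels are
  partial. A surface lying exactly on a voxel-centre plane makes the
  boundary layer's occupancy exactly 0.5 — no threshold classifies it
  stably, so validation fixtures keep surfaces off that degenerate
  alignment.
* Segmentation is global threshold (default 500 on the synthetic scale) +
  small-object removal + two-largest-components + closing (radius 1);
  tibia is the component with the lower z centroid, and an ambiguous
  ordering (< 1 voxel apart) demands a seed-label image — the stand-in for
  the protocol's manual interaction, not a reconstruction of it.
* Wedge step width is rounded to whole pixels, so recovered pixel size is
  exact when the 10 mm step divides the pixel size evenly and within half
  a pixel otherwise.
* Compartment fractions are `fractions.Fraction` constants; region
  arithmetic is exact up to float multiplication.

## What the phantoms do and do not show

The generator emulates: paired bone surfaces with mm-scale cartilage,
load-dependent compression with subject-specific deformability, a small
2-year treatment effect, per-modality noise, and the resulting
cross-sectional vs longitudinal correlation structure. It does not
emulate: real CT physics (beam divergence, scatter, Hounsfield
calibration), knee flexion (deliberately, matching the 2D rendering
limitation of the protocol it mirrors; a config knob can tilt the femur),
osteophytes, menisci as imaged structures, focal cartilage lesions, or
segmentation failure modes of clinical data. Passing tests therefore
validate the *measurement mathematics* and the *mechanistic explanation*
of the correlation pattern, not clinical performance on patient images.

Problem sizes used by the test and acceptance suites — 70 × 50 mm grids at
0.5–1 mm steps, cohorts up to 100 subjects, 100 cohort replicates, 100,000
power replicates — were chosen as the smallest sizes at which the checked
quantities are stable to well within their tolerances.
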