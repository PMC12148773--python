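# Methods

`oartmotion` quantifies how much the bladder changes during the on-couch
interval of CBCT-guided online adaptive radiotherapy (oART) — between the
planning CBCT (pCBCT) used to re-optimize the daily plan and the verification
CBCT (vCBCT) acquired just before delivery — and what those changes do to the
delivered dose. This note describes the models, conventions and numerical
choices, and what the synthetic phantom does and does not establish.

## Coordinate and field conventions

All geometry lives in the DICOM LPS patient frame (x = left, y = posterior,
z = superior/cranial), millimetres. Grids are regular, voxel-centered,
0-based, with an orthonormal direction matrix; the index→physical map is
affine (`origin + direction · (spacing ⊙ index)`).

Displacement fields use one convention everywhere: they are defined on the
**fixed** image's grid with pull-back semantics, `out(x) = moving(x + d(x))`.
With fixed = vCBCT and moving = pCBCT, `x + d(x)` is the planning-frame
(pre-motion) position of the tissue found at verification point `x`. File
importers/exporters carry a metadata note naming this convention; fields
pointing the other way can be inverted by fixed-point iteration
(`registration.invert_field`, tolerance 0.05 voxel, ≤ 50 iterations).
This single-convention rule exists because mixed push-forward/pull-back
bookkeeping is the dominant source of silent sign errors in DVF pipelines.

## Contour metrics

- Volume = foreground voxel count × voxel volume; expansion rate =
  (V_v − V_p)/Δt in cc/min, where Δt comes from the acquisition timestamps
  (negative values mean the bladder shrank).
- The Hausdorff distance is **directed** (planning → verification) by
  default, following the asymmetric clinical definition; a symmetric pooled
  variant is available. Distances are Euclidean in mm between face-connected
  boundary voxel centers. `slice2d` mode (default) restricts the
  nearest-point search to the same axial slice — the plane in which such
  contours are drawn and reviewed — with a 3-D fallback for slices present
  in only one mask; `full3d` searches in 3-D. The per-slice reading of an
  "in-plane" boundary distance is one of two defensible interpretations;
  both are implemented, and results from the two modes should not be mixed.
- HD95% (95th percentile of the pooled point distances, linear-interpolation
  order statistics) is the robust summary; the maximum is also reported.
- DSC = 2|A∩B| / (|A| + |B|).

## Registration

A rigid stage (SimpleITK, Mattes mutual information or mean squares, dense
sampling so results are deterministic) is followed by a Gaussian-regularized
symmetric-forces demons registration run coarse-to-fine over 5 levels
(shrink factors 16…1), with per-level iteration counts (100, 80, 60, 30, 10)
and field smoothing of 1.5 voxels per level unless configured in mm.
Structure guidance, when bladder masks accompany the images, adds a smoothed
mask-contrast channel (Gaussian σ = 2 mm, weight relative to the image's
1–99 percentile range) to both images, sharpening the similarity gradient at
the guided organ. Diffeomorphic-quality is asserted by checking Jacobian
positivity rather than guaranteed by construction; divergence (similarity
worsening across the final full-resolution level) sets a non-convergence
flag instead of raising.

Validation follows clinical DIR practice: the warped planning bladder is
compared with the verification bladder by DSC, and a result is considered
acceptable at DSC ≥ 0.9.

`warp_mask` anti-aliases the binary indicator (Gaussian, 0.7 voxel) and
samples it trilinearly, thresholding at 0.5. This sub-voxel surface recovery
is deliberate: with 2 mm voxels and an ~80 cc organ, plain nearest-neighbour
pull-back loses ~2–4 DSC points to pure voxel quantization, which would
swamp the registration error the validation is meant to measure.
Nearest-neighbour sampling remains available (`interpolation="nearest"`).

## Deformation analysis

Per fraction: exceedance fractions (share of bladder volume whose
displacement along the left–right, anterior–posterior or cranial–caudal axis,
or in magnitude, exceeds 3/5/7 mm — absolute components by default, since the
margin question is sign-agnostic; signed variants available), cumulative
(survival) deformation histograms, and the Jacobian determinant of the warp
`x + d(x)` by central differences in physical mm (one-sided at borders):
1 = volume preserving, 2 = local doubling. Per course: voxelwise mean and SD
(sample, n−1 convention; configurable) of |d| across fractions in a common
reference frame, with a boundary-sampled point cloud export for surface
rendering. Per-fraction fields are brought to a common frame by field
composition `d(x) = d_in(x) + d_out(x + d_in(x))` with trilinear sampling.

## Dosimetry

The vCBCT cannot support dose recomputation (uncalibrated intensities), so
the "treated" dose is estimated by pulling the intended dose through the
registration field: `treated(x) = intended(x + d(x))`, trilinear, with
out-of-extent voxels set to 0 Gy and flagged. Whether dose warping should use
the motion field or its inverse is a genuinely open bookkeeping question in
this kind of analysis; here the contract is explicit — the field passed must
map verification-frame points to planning-frame points, which is exactly
what registering fixed = vCBCT against moving = pCBCT produces — and the
inversion helper covers the other case.

DVHs are cumulative (volume fraction receiving ≥ dose), volume-weighted,
with a 0.05 Gy default bin — fine enough for tail metrics like D0.03cc.
Metrics: Vx% (of prescription), V in Gy, Dy% (hottest y% of volume), Dc cc
(hottest c cm³), linear interpolation within bins. A relative tolerance of
1e-9 is applied when testing dose ≥ threshold so that interpolation round-off
(a warped uniform dose at Rx·(1 − 1e-16)) cannot drop a voxel out of its bin.
Intended metrics are evaluated on planning-frame structures and treated
metrics on verification-frame structures (fresh verification masks when
available, warped planning masks otherwise). All doses are per fraction
(Gy/fx); course dose is a plain sum with no radiobiological conversion.

## Cohort statistics

Group mean/SD pool all fractions. Intra-patient SD = unweighted mean over
patients of each patient's within-course SD (a pooled-variance alternative
is reported alongside, since the phrasing "the SD for each patient" admits
both); inter-patient SD = SD of patient means. Time trends use pooled OLS of
a metric against the on-couch interval with the classical two-sided slope
t-test — within-patient correlation is deliberately ignored, matching the
simple analysis this mirrors, and p-values are reported raw with no
multiple-testing correction; treat them descriptively. Weekly box statistics
use type-7 (linear interpolation) quartiles and whiskers at the most extreme
datum within 1.5·IQR; "week" = blocks of 5 fractions when no calendar exists.

## The synthetic phantom

The phantom emulates the study conditions the analysis chain needs, with
analytic ground truth for every quantity downstream code estimates:

- **Anatomy**: a superellipsoid bladder (exponent 2.5) with a smooth random
  low-order surface perturbation (±5%), inside a textured soft-tissue
  background (sum of fixed random cosines, SD 30 HU-like units) bounded by a
  body outline; bladder contrast −100; additive noise SD 5. Defaults:
  128×128×96 voxels at 2 mm — desk-scale, yet fine enough that 3–7 mm
  thresholds span more than a voxel.
- **Filling protocols**: full ≈ 200 cc baseline filling at 3.4 ± 1.5 cc/min;
  empty ≈ 80 cc at 0.8 ± 0.3 cc/min; on-couch interval drawn from a
  truncated normal 19.7 ± 3.3 min (min 5). Baseline volumes per protocol are
  assumptions (plausible anatomy; only the rates and the interval are
  externally anchored). Day-to-day planning-volume variability is lognormal:
  25% CV between patients, 10% CV between fractions.
- **Motion**: an anisotropic radial map about the bladder centroid. The
  stored (pull-back) truth field is
  `d(x) = −s · w(n̂) · g(ρ(x)) · (x − c)` with direction weights
  `w = 1 + 2·max(n_z,0)² + 1·max(−n_y,0)² + 0.2·n_x²` emphasizing cranial
  and anterior surface motion (the physiological filling pattern), and a
  cosine taper `g` from 1 at the bladder surface (shape radius ρ = 1) to 0
  at ρ = 2, keeping the map local and diffeomorphic. The scale `s` is
  calibrated per fraction by bisection so the voxelized verification volume
  equals planning volume + rate × interval (≤ 3% voxelization error).
- **Dose**: PTV = bladder dilated isotropically by the margin (default 7 mm,
  the adaptive-margin setting this emulates), prescription (default
  5 Gy/fx) flat inside the PTV with a Gaussian penumbra (σ = 5 mm) outside.
- **Determinism**: all randomness flows from a single seeded generator;
  identical specs give bit-identical cohorts.

What the phantom does *not* reproduce: CBCT physics (scatter, rings, beam
hardening), segmentation error (masks are exact up to voxelization),
non-bladder anatomy (no rectum/bowel beyond what DVH tests need), sliding
interfaces, or peristaltic/irregular motion. Tests passing on the phantom
therefore establish the correctness of the analysis chain — registration
recovery, exceedance accounting, dose-warping bookkeeping, statistics — not
the clinical accuracy of demons registration on real CBCT pairs.

## Problem sizes and numerical choices

End-to-end checks run a 2-patient × 10-fraction cohort at the default
128×128×96 grid (registration recovery, exceedance chain, dosimetric margin
properties) and a 10-patient × 20-fraction masks-only cohort on a 64×64×48
grid for the variance-component recovery, where only volume statistics are
exercised. The t-test calibration uses 2000 null replicates at n = 183
fractions. Volume-calibration bisection runs 18 iterations on the bladder's
bounding subbox. Degenerate inputs raise typed errors (empty masks →
undefined-metric; reversed timestamps → chronology; zero predictor variance
→ degenerate design) rather than returning NaNs silently.

## Known limitations

- The demons stage assumes consistent intensities between the two scans;
  genuine cross-protocol CBCT pairs may need the mutual-information rigid
  stage plus externally computed deformable fields (the field importer
  accepts any 3-component NIfTI/MetaImage in the package convention).
- Pooled OLS understates uncertainty in the presence of within-patient
  correlation; the variance decomposition quantifies, but the trend test
  does not absorb, that structure.
- Exceedance on recovered fields inherits registration error in low-gradient
  organ interiors; the phantom bounds this at ≤ 1 voxel mean error, real
  data may be worse.
- No anisotropic-margin recipe is computed; the exceedance table is the
  input a margin designer would use, not the margin itself.
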