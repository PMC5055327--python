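# Methods notes

## Pipeline

One global quantization feeds both metrics. For a volume `V` (any MR signal
units) the level of voxel `v` is

    level(v) = floor(255 * (v - min V) / (max V - min V) + 0.5),  clamped to [0, 255]

i.e. equal-width bins with round-half-up, so the image minimum maps exactly
to 0 and the maximum to 255. The extremes are taken over the *whole image*,
background included: on T2-weighted images the minimum is anchored near
zero (air/bone) and the maximum by cerebrospinal fluid, which is what makes
levels — and therefore entropies and gradient magnitudes — comparable
across cases. A constant image quantizes to all zeros with a logged warning
(its entropy is 0 by construction). No percentile clipping, winsorization
or per-slice normalization is applied. The mapping is invariant to affine
intensity rescaling `v -> a*v + b` (a > 0) and monotone in `v`.

**Entropy.** The histogram of the 256 predefined levels is taken over the
VOI voxels and summarized as `S = -sum p_i log2 p_i` bits, with
`0*log2(0) = 0`. Bins are never adaptive; the unit is bits (max 8). The
implementation is the direct vectorized sum over occupied bins and is
tested against a per-voxel log-sum oracle at 1e-12 relative tolerance.

**Edge statistics.** The quantized volume is filtered slice-by-slice with
the unnormalized 3×3 Prewitt kernels (weights ±1) and the per-pixel
magnitude `G = sqrt(Gx^2 + Gy^2)` is formed. Filtering is strictly 2D —
the kernels are 2D operators and clinical slices are usually anisotropic —
with the slice axis configurable (default: third array axis, axial
convention). Image borders use replicate padding, which contributes no
spurious frame gradient. The VOI rim is `mask AND NOT erode2D(mask)` with
the full 3×3 (8-connected) structuring element applied per slice; erosion
never crosses slices, so rim voxels in the first/last slice are retained,
and a mask touching the image frame is rim there. Edge mean and Edge
median are the arithmetic mean and median (even counts: midpoint of the
two central order statistics) of `G` over rim voxels. On 0..255 data these
land in roughly the 10–90 range for realistic lesions, matching the
published per-case values.

## Statistics

Group comparisons use the classic pooled-variance (Student) unpaired
t-test: it is the textbook reading of "Student's t-test" and the default
of the commercial software of the study's era. The 95% CI of the mean
difference uses the t(n1+n2-2) quantile. Zero pooled variance degenerates
explicitly (equal means: p = 1, CI (0,0)).

ROC analysis sweeps thresholds over all observed score values (plus the
+inf endpoint, so the curve always spans (0,0) to (1,1)). The AUC is the
midrank Mann–Whitney statistic — a positive/negative tie counts half —
which equals the trapezoidal area under that curve exactly. The standard
error is the DeLong placement-value (structural component) estimator:

    var = var(V10)/m + var(V01)/n

with `V10`/`V01` the per-positive/per-negative placement values. The 95%
CI is `auc ± 1.96*se` clamped to [0, 1], and the p-value against the
chance line is a two-sided normal test of `(auc - 0.5)/se`. DeLong was
chosen over the older Hanley–McNeil SE because it reproduces all four
published AUC confidence intervals at 2-decimal rounding (Hanley–McNeil
reproduces only the two tie-free ones); the two estimators differ by well
under one CI width on this cohort. The implementation is cross-checked in
the tests against exhaustive pair counting, scikit-learn's AUC, and R
pROC's DeLong CI.

One reproduction caveat: the cohort's entropy column contains three values
(6.40, 5.74, 6.34) shared by one homogeneous and one heterogeneous case.
Under the midrank convention the entropy~heterogeneity AUC is 0.7245,
which rounds to 0.72 where the original report prints 0.73; the original
software's tie handling is undocumented, and no standard convention
reproduces both of its tie-affected AUCs simultaneously. Everything else —
all mean differences, t-test CIs, the other three AUCs and all four AUC
CIs — matches the published values at 2-decimal rounding.

## Cohort fixture

The 50-case table (demographics, diagnosis, WHO grade, IDH1 status, the
two blinded readings, and the three per-case metrics) ships as a plain TSV
guarded by a SHA-256 checksum; loading verifies the row count and the
22/28 grade split. Direction conventions are (hetero − homo),
(well defined − vague), (mutant − wild type), with the same class positive
in each ROC and higher metric predicting it. The per-case *image* metrics
cannot be re-derived — the MRIs themselves were never deposited — so the
image pipeline is validated by invariants and phantoms instead.

## Phantom generator

Each phantom is an ellipsoidal hyperintense lesion (default semi-axes
20×20×6 voxels on a 64×64×16 grid) on a darker background (level 30), with:

- **heterogeneity dial**: `k` intensity components; each lesion voxel
  draws a component (categorical by weight) and optional Gaussian noise
  (default sd 5). With equal weights, separated means and no noise the VOI
  entropy is ~log2 k bits (a small multinomial-sampling deficit, well
  inside 0.1 bit at the default lesion size of ~10^4 voxels);
- **sharpness dial**: the whole image is smoothed with a Gaussian of width
  `border_blur_sigma` voxels (default 1). Rim gradients fall monotonically
  with sigma;
- a small fixed-intensity blob (level 255, radius 2.5, far from the
  lesion) stamped *after* the blur, playing cerebrospinal fluid's role of
  pinning the global maximum so the 256-level rescale is anchored
  identically across specs. The background pins the minimum.

The VOI mask is the exact pre-blur ellipsoid — the analogue of manually
segmenting the visible lesion — and depends only on geometry, so the
sharpness and heterogeneity dials can be tested independently. One
`numpy.random.Generator` seeded per phantom makes generation bit-exact
reproducible; no global random state is touched.

Defaults were chosen to caricature a lower-grade glioma on T2WI: lesion
well inside the field of view, contrast ~150 levels above background, mild
noise and mild blur. What the phantoms do **not** emulate: Rician noise
statistics, bias fields, anisotropic voxel spacing, multiple lesions,
partial-volume CSF inside the VOI. Passing phantom tests therefore shows
the pipeline measures what it claims on controlled geometry, not that the
metrics are robust to scanner physics.

## Numerical and degenerate-input choices

- Quantization rounding: floor(x + 0.5) (round half up), endpoints exact.
- Entropy convention 0·log 0 = 0; result clipped only by construction.
- Median over an even rim count: average of the two central values.
- Gradient at image borders: replicate padding.
- Empty masks, single-class labels, groups smaller than 2, and grid
  mismatches raise `ValidationError`/`GridMismatchError` rather than
  returning NaNs; the CLI maps these to exit code 2 (I/O 3, fixture
  integrity 4).
- p-values are floored at the smallest positive normal double so they stay
  in (0, 1].
- Native-grid computation throughout: voxel anisotropy is not resampled,
  and the NIfTI affine is carried through I/O but never interpreted.

## Problem sizes

Tests and the acceptance script use the default 64×64×16 phantom grid and
ten seeds per condition for the dose-response checks; the cohort analyses
are closed-form on 50 cases. The full suite runs in a few seconds.

## Known limitations

- Segmentation is out of scope: a VOI mask must be supplied (or generated
  synthetically).
- Slice-wise 2D filtering means the rim of a one-slice lesion is scored
  entirely in-plane; 3D gradient operators are deliberately not offered.
- The AUC p-value is a large-sample normal test; exact/permutation
  p-values are not implemented.
- DICOM must be converted to NIfTI upstream.
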