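# Methods

## The pipeline

`fastil` scores tumor-infiltrating lymphocyte (TIL) density on H&E
whole-slide images in three stages, followed by aggregation, visualization,
and prognostic evaluation.

**Stage 1 — patch extraction.** The slide is downsampled by
`mask_downsample` (default 32), converted to grayscale with ITU-R BT.601
luma (0.299 R + 0.587 G + 0.114 B), and thresholded: a pixel is tissue iff
its luma is strictly below 170 (H&E tissue is darker than glass; a pixel at
exactly 170 is background). Connected components smaller than
`min_object_area_px` (64 mask-scale pixels) are removed as debris. A
non-overlapping grid of `patch_size` (768 px) squares anchored at the
level-0 origin is intersected with the mask; a patch becomes a candidate
when at least `tissue_fraction_min` (10%) of its footprint is tissue —
deliberately permissive so boundary tumor is not lost; content filtering is
the next step's job. Each candidate patch is then read at full resolution,
deconvolved into the Hematoxylin–Eosin–DAB space with the standard
Ruifrok–Johnston stain matrix on decadic optical densities (scikit-image's
convention), and kept iff its mean hematoxylin OD is at least `h_threshold`
(default 0.017, with `>=` so the boundary keeps the patch). The numeric
scale of this threshold is tied to the HED normalization used here; other
deconvolution conventions require recalibration.

**Stage 2 — classification.** Every candidate receives one of four labels
(tumor, stroma, necrosis, normal) from a pluggable classifier; only tumor
and stroma patches — the compartments that carry the infiltrate — are kept.
The classifier is a contract (`classify(patch_rgb, *, x0=0, y0=0)`), so a
trained CNN can be plugged in through a thin adapter; the keyword-only
`x0`/`y0` origin exists so ground-truth oracles can locate the patch, and
pixel-based classifiers ignore it. Shipped implementations: an *oracle*
(majority ground-truth class under the patch, ties broken by the fixed
priority tumor > stroma > necrosis > normal; an all-background patch
defaults to normal), a *heuristic* reference (below), and a constant
classifier for degenerate tests. `balance_test_set` implements the
evaluation convention of clipping every class to the rarest class's count,
with seed-controlled subsampling.

**Stage 3 — quantification and scoring.** A pluggable quantifier returns
per-patch nucleus detections with a lymphocyte/other call. The per-patch
TIL count c_i (lymphocytes only) is normalized by physical patch area,

    d_i = c_i / (patch_size · mpp)² · 10⁶   [cells/mm²],

the slide score is the mean of d_i over retained patches, and the patient
score is the mean of slide means over the patient's k slides — a mean of
means, so each slide contributes equally regardless of patch count; for
k = 1 it reduces to the slide score. A nucleus straddling a patch border
belongs to the patch containing its center, which makes counts
partition-exact over the half-open grid squares. A slide with no retained
tumor/stroma patches yields *no score* (`til_score = None`): an
unevaluable slide must not masquerade as "no TILs".

**Randomized sampling.** Between stages 1 and 2 the candidate set can be
subsampled uniformly without replacement to m = max(1, round(ratio · N))
patches (round half to even). Because the slide score is a mean, simple
random sampling leaves it unbiased; the `monte_carlo_stability` harness
replicates the downstream pipeline over a ratio grid and reports the
replicate mean ± sd of the cohort-mean score and of the concordance index.
Replicate r uses seed `base_seed + r`; within a replicate each slide gets
an independent stream spawned from (replicate seed, slide index), so the
whole table is reproducible byte-for-byte from `base_seed`.

**Visualization.** Per-patch densities are painted over a thumbnail
(`overlay_downsample`, default 32) through a colormap scaled to
[0, `clip_max`] with `clip_max` = 10,000 cells/mm² — densities above that
are clipped so outlier patches do not wash out the scale — and
alpha-blended at 0.5; pixels outside retained patch footprints are left
untouched, and the saved figure carries a 0–10,000 colorbar.

**Prognostic evaluation.** Harrell's concordance index is implemented by
explicit pair enumeration with pinned conventions: a pair is comparable
when the shorter observed time is an event; equal times with both events
are not comparable; an event tied with a censored time counts the censored
subject as the survivor; tied risk scores contribute 1/2. TILs are
protective, so `direction="higher_score_lower_risk"` negates scores.
Quartile groups use linearly interpolated empirical percentiles (NumPy
default, "type 7") with right-closed intervals, and explicit cutoffs can
be supplied to score new patients against a fixed reference cohort. The
Kaplan–Meier estimator is the standard product-limit computation (one row
per distinct observed time; censored-only times reduce the risk set
without moving survival). The log-rank statistic is delegated to
lifelines (`multivariate_logrank_test`); tests validate it against a hand
O−E/V tabulation and a permutation null. Multivariable Cox modeling is
deliberately out of scope — established survival tooling already does it.

## The synthetic slide generator

The generator renders what the pipeline's assumptions require of real H&E,
with full ground truth (region map, tissue mask at a stated downsample with
majority-rule blocks, and the exact planted nucleus list):

- glass background at gray 245 (above the 170 mask threshold);
- tissue regions (rectangles or polygons, disjoint) filled eosin-pink
  (228, 120, 150): BT.601 luma 155.7 (below 170, so it masks as tissue) and
  hematoxylin OD exactly 0 (so nucleus-free eosin fails the 0.017 filter);
- nuclei as disks clipped at region borders: lymphocytes (60, 30, 100),
  radius 3 px, H ≈ 0.146; other cells (90, 60, 130), radius 5 px,
  H ≈ 0.105 — at the default densities this keeps tissue-patch H means
  above 0.017;
- necrosis filled with a dusky low-contrast smeared texture around
  (170, 145, 125) (H ≈ 0.021, just above the filter so sparse-nucleus
  necrotic tissue survives stage 1 and is removed by the classifier, as in
  real pipelines) and fewer than 5% of tumor's nuclei.

Default densities (lymphocyte, other) per mm²: tumor (1500, 4000), stroma
(800, 2500), normal (100, 2800), necrosis (20, 150). The stroma/normal
other-cell densities are set so their nuclear coverage keeps retained
tissue above the hematoxylin threshold. Fixtures are rendered at
1 µm/pixel, where the disk radii approximate real nuclear sizes.

Counts are deterministic — `round(density × region_area_mm²)` per region
and cell kind — so density-recovery tests carry no planting noise
(`poisson_counts=True` restores stochastic counts); positions are uniform
over the region's pixels under the spec seed, and identical specs render
byte-identical images.

What the generator does *not* emulate: stain variation, scanner artifacts
(folds, pen marks, blur), nuclear pleomorphism and texture, overlapping
tissue layers, or tertiary lymphoid structures. Passing tests therefore
demonstrate the pipeline's arithmetic, geometry, determinism, and
statistical behavior — not classifier or detector accuracy on real
histology, which is the job of the pluggable trained models.

Survival cohorts draw exponential event times with

    hazard_i = baseline_hazard · exp(log_hr_per_1000 · (d_i − 1500)/1000),

d_i uniform over `density_grid` (default 200–3000 cells/mm²), independent
uniform censoring on (0, 12] years. The default `log_hr_per_1000 = −0.5`
gives a moderate protective effect (true-density c-index ≈ 0.62 at
n = 200), typical of a prognostic biomarker. The prognostic-recovery
experiment (tests and acceptance script) instead uses a strong link of −2
per 1000: a power calculation shows that demonstrating c > 0.5 at five
bootstrap standard errors with 200 patients (SE ≈ 0.03–0.04) requires
c ≳ 0.70, which a moderate effect cannot reach at any sampling ratio. The
standard cohort slide is 2304² px at 1 µm/pixel with a grid-aligned
2×2-patch tumor block and a 1×2-patch stroma column whose infiltrate
tracks the tumor's at 60%.

## Reference models

The shipped *reference detector* is a classical stand-in for a deep
nucleus model: hematoxylin OD thresholded at 0.06, 8-connected components,
area gate [min_area, max_area], lymphocyte call for components with area
≤ `lymph_area_max` and circularity 4πA/P² ≥ 0.7. Defaults (20/600/250 px)
are quoted for 0.25 µm/px material and rescale by (0.25/mpp)² via
`DetectorParams.scaled`; they are stand-in values, not biological claims.
On 1 µm/px fixtures the tests use (10/200/50 px, circularity 0.6).

The *heuristic classifier* uses three per-patch features — density of
hematoxylin-positive blobs per mm², mean hematoxylin OD, and the fraction
of small (lymphocyte-sized) blobs — with thresholds calibrated once on the
generator's default palette: blob density < 600/mm² → necrosis; H mean
≥ 0.027 → tumor; small-blob fraction ≥ 0.13 → stroma; else normal. It
exists so the pipeline can run end to end without ground truth; it makes
no claim to CNN-level accuracy on real tissue.

## Numerical and design choices

- Coordinates are 0-based level-0 pixels; a patch is the half-open square
  [x, x+P) × [y, y+P). Flat images are 1-level pyramids; mpp is stored
  once per slide and assumed isotropic. Patches are read from level 0.
- Grid stride equals the patch size (no overlap), origin (0, 0); partial
  edge patches are dropped.
- mpp comes from TIFF resolution tags (pixels/cm or pixels/inch); an
  explicit `mpp_override` always wins, and opening fails loudly when
  neither exists.
- Patch tables serialize reals at 17 significant digits, so round-trips
  are exact for doubles; absent fields are empty cells.
- The hematoxylin mean is computed on the full-resolution patch.
- Quartile cut-offs may be computed on the evaluated cohort or supplied
  from a reference cohort; both modes are first-class because the
  reference-cohort question is study-specific.
- Problem sizes in the test suite and acceptance script are desk-scale by
  construction: slides of 4–36 patches, mask-fidelity checks on 3072² px
  slides, a 36-patch homogeneous slide with 200 sampling replicates, and
  120–200-patient cohorts.

## Known limitations

- The tissue threshold (170), hematoxylin threshold (0.017), and heuristic
  thresholds are dataset-dependent; on differently stained material they
  must be recalibrated.
- The reference detector merges touching nuclei (connected components), so
  it undercounts dense infiltrates; the oracle quantifier exists precisely
  to separate pipeline arithmetic from detector error.
- No artifact handling (pen marks, folds) — real deployments need slide QC
  upstream.
- The log-rank delegation inherits lifelines' handling of tied event
  times (the standard hypergeometric variance).
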