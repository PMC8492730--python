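# Methods

This note documents the models, algorithms, parameters and design choices
behind `octa3d`, and what the synthetic-data tests do and do not establish
about real scans.

## Scan model and conventions

A scan is an 8-bit grayscale cube in canonical (z, y, x) order, z
increasing from vitreous to choroid; voxel indices are 0-based and all slab
and substack ranges are half-open `[z0, z1)`.  `ScanGeometry` carries the
physical extents; the default is a 3 × 3-mm macular cube of 300 × 300
A-scans and 1536 axial pixels over 3 mm depth, giving a 10 µm lateral and
1.95 µm axial pitch.  Raw exports carry a JSON sidecar declaring shape,
on-disk axis order and dtype, because vendor raw dumps do not document
either; 16-bit inputs are reduced by an integer right-shift (warned).

## 3D quantification

**Axial rescaling.**  `z_scale_factor` is the axial-to-lateral pitch ratio
(0.1953… ≈ 0.195 for the default geometry).  Resampling z by this factor
(linear interpolation by default; nearest available for exactness checks)
makes voxels isotropic at the lateral pitch; the effective axial pitch after
resampling is tracked explicitly (`old_pitch · nz / round(nz · factor)`)
rather than assumed exactly isotropic.

**Thresholding.**  The stack threshold is iterative intermeans (IsoData
family): starting from the midpoint of the occupied gray range, iterate
`t ← floor((mean(≤t) + mean(>t)) / 2)` to a fixed point (a floor-induced
cycle terminates at the first revisited level).  Binarization keeps voxels
*strictly above* the level.  The threshold is computed on the rescaled
retina substack with masked-out (extraretinal) voxels excluded from the
histogram — including the zero spike introduced by masking would drag the
low-class mean toward 0 and depress the threshold; the inclusive behaviour
remains available (`histogram_excludes_masked=False`).  An exhaustive
fixed-point oracle in the test suite checks the implementation on random
histograms.

**Metrics.**  3D vascular volume = suprathreshold voxel count × effective
voxel volume (mm³).  Neuroretinal volume is defined as the area-weighted
mean thickness integrated over the full scan area, so
`volume = mean_thickness · area / 1000` holds exactly by construction; this
convention is self-consistent with published clinical means (321.5 µm over
9 mm² = 2.89 mm³).  3D perfusion density = 100 × vascular / neuroretinal
volume.  The stage order — artifact removal → substack → rescale →
threshold → count — is part of the contract; thresholding before rescaling
produces different counts and is rejected by a regression test.

## Retina segmentation

Boundary detection runs per A-scan on an axially smoothed copy (5-sample
uniform filter; speckle otherwise punches sub-threshold holes into the
band).  The edge threshold is the midpoint of the two robust class levels
(medians of the voxels on either side of the global intermeans split) — the
intermeans level itself sits above the band's half-rise when the speckled
band distribution is skewed, which would bias both boundaries inward.  The
ILM is the start of the contiguous suprathreshold run containing the first
run of ≥3 consecutive samples; the outer boundary is one past the end of
the last such run.
Columns with no detectable band are filled from their nearest detected
neighbour; more than 20 % undetected columns is a hard failure.  Surfaces
are median-filtered laterally (5 × 5, up to three passes) against a
configurable maximum inter-column jump (20 px default).  The substack crop
zeroes voxels outside each column's `[ilm, outer)` — stricter than a plain
axial crop, so a curved retina cannot admit choroidal signal into the
count.

## Projection-artifact removal

Superficial flow casts decorrelation tails down the beam.  The default
`axial_peak` mode works per column:

* noise floor = column median + 2 MAD (robust, parameter-light);
* contiguous runs above the floor shorter than 3 samples are ignored
  (isolated noise exceedances are left untouched, which keeps the
  algorithm near-transparent on vessel-free columns);
* within a run, vessel peaks are the run's global maximum plus every local
  maximum with topographic prominence ≥ 4 MAD — a genuine deep vessel
  rising from under a tail qualifies, noise wiggles riding the tail do
  not;
* each peak retains the contiguous region where intensity stays ≥ 60 % of
  the peak (`keep_fraction`); a vessel cross-section is a compact bump,
  whereas a tail hangs below its source at a strictly smaller fraction and
  decays, so it falls outside the retained region;
* remaining run voxels are attenuated to the column median.

The mode never increases a voxel, is approximately idempotent, and leaves a
pure-noise volume essentially unchanged.  A `subtraction` baseline
(`v(z) − α · max(v(z' < z))`, α = 0.3 default) is provided for comparison.
Both operate on the stored 8-bit values; whether a clinical device's
removal operates on linear or log-scaled decorrelation is generally
undocumented, and no attempt is made to reproduce any proprietary
implementation voxel-for-voxel.

## 2D quantification

SCP = `[ilm, ilm + 110 µm)`, DVC = the next 60 µm, clipped at the outer
boundary; the depths approximate instrument defaults and are fully
configurable (the phantom generator places its plexuses at the same
offsets, so 2D recovery tests are self-consistent).  Slabs are collapsed by
per-column max projection (preserves thin capillaries better than mean;
mean available), binarized with a global Otsu threshold by default
(intermeans and mean + k·SD alternatives behind the same flag — all are
standard en-face OCTA binarizations, and the tests score ground-truth
recovery rather than a specific dialect), and the 2D perfusion density is
the white-pixel percentage.

## Synthetic phantom

The generator emulates the acquisition the pipeline targets, with exact
ground truth:

* **Surfaces** — ILM depth 200 µm and thickness 320 µm with smooth
  low-frequency undulations (±15 / ±10 µm).
* **Vessels** — persistent random-walk centerlines (mostly lateral, slight
  axial drift) stamped with anisotropic ellipsoids of radius 10–16 µm,
  grown until each plexus slab (SCP 0–110 µm, DVC 110–170 µm below ILM)
  reaches its target volume fraction (defaults 0.06 / 0.10).  Dilated
  random walks realize an exactly countable fraction with tube-like
  morphology; no attempt at fractal branching realism.
* **Structural volume** — bright retina band (160) over dark background
  (8) with multiplicative gamma speckle (shape 4, i.e. ~50 % relative SD).
* **OCTA volume** — additive gamma background noise (mean 12) plus vessel
  voxels at an SSI-dependent level: mean intensity 40 + 19.5·SSI with a
  per-voxel SD of 30 (capillary decorrelation is heterogeneous; the spread
  also makes strong tails overlap the dim end of the vessel distribution,
  as in real scans).  SSI enters only ordinally (the clinical use is an
  exclusion gate at 7), so a linear contrast map suffices.
* **Projection tails** — deterministic given the noisy volume and the
  vessel mask: a voxel at distance d below a vessel voxel of intensity V
  gains `strength · V · exp(−d / τ)` (τ = 100 µm default), taking the
  strongest decayed overlying contribution where several vessels stack — a
  tail tracks its source's intensity but does not accumulate without
  bound, which keeps the artifact below vessel level as in real
  decorrelation data.  Noise is added before tails, so removal efficacy is
  measurable against an exact oracle.

**Cohorts.**  Two groups (default 35 + 35, one eye per subject, the
clinical design size).  Per-eye slab fractions are drawn normally: SCP
(0.06, 0.003) identical in both groups, DVC (0.10, 0.015) in controls with
the diabetic mean lowered by `effect_dvc_fraction` (default 0.010 —
calibrated analytically, including the pipeline's measurement noise at the
desk-scale grid, so that the *measured* DVC-density effect size is Cohen's
d ≈ 0.6, matching the standardized group difference reported clinically).
Eye-level thickness is drawn at (320.5, 8) µm — modest between-eye spread,
so that perfusion-density variance is vessel-dominated.  Covariates follow
the cohort summary statistics of the target study population: age
27.2 ± 10.2 (diabetic) / 31.0 ± 11.4 (control) years, HbA1c 7.5 ± 0.7 %,
diabetes duration 13.2 ± 6.0 years (diabetics only); SSI is uniform on
[7, 10], the post-exclusion range.  Per-subject seeds are spawned from the
master seed via `SeedSequence`, so cohorts are reproducible eye-by-eye.

**What the phantom does not model** — optically realistic speckle physics,
eye motion and bulk-motion line artifacts, vessel branching hierarchies,
the foveal avascular zone, partial-volume blur at vessel walls, and
intraretinal layer contrast.  Passing recovery tests therefore show that
the *quantification* is faithful when its assumptions hold (clear band
contrast, tube-like vessels, exponential tails); they do not certify
segmentation or thresholding performance on pathological clinical scans.

Because the synthetic vasculature is confined to two discrete plexus bands
within a 320 µm retina, the whole-retina 3D perfusion density of a default
phantom (~4 %) is lower than typical clinical values (~10 %), while the 2D
slab densities (~27–33 %) are near clinical magnitudes.  The fractions are
free parameters; the tests measure recovery of whatever fraction was
constructed, not absolute clinical levels.

## Statistics

Group comparison uses the independent-samples pooled-variance Student's
t-test (the clinical analysis names it; Welch available by flag), raw
two-sided p-values with no multiple-testing correction, and mean ± SD
summaries rounded to printed clinical precision (volumes 2 dp, densities
and thickness 1 dp, p 3 dp).  Shapiro–Wilk p-values per metric and group
are reported in the numeric comparison table for screening but never gate
the t-test.  Metric–covariate association in the diabetic
group uses Pearson correlation.  Elementary tests are delegated to
`scipy.stats` behind validated wrappers.

## Problem sizes used in the test suite

Simulation-based tests run on reduced geometries that preserve the
full-size pitch anisotropy: 80 × 80 × 192 (12 µm / 3 µm) for single-eye
checks, 64 × 64 × 160 for cohort replicates, and 150 × 150 × 512 for the
parameter-recovery study.  These sizes keep the Monte-Carlo suites
practical on a laptop-class machine while leaving every algorithmic path
identical to the full 300 × 300 × 1536 case.

## Known limitations

* The per-column peak-retention removal assumes tails are weaker than
  ~60 % of their source vessel's peak; saturated or near-saturated tails
  (clipped at 255 together with their source) cannot be separated by any
  intensity criterion.
* Surface segmentation assumes a single bright band; it is not an
  intraretinal layer segmenter and will fail on volumes without clear
  band contrast (by design, with an error, rather than silently).
* `EyeMetrics.vascular_volume_mm3 ≤ macular_volume_mm3` holds only when
  retina masking was applied upstream (the pipeline always applies it).
* The intermeans fixed point is not always unique on pathological
  histograms; the implementation's midpoint-start iteration is the
  documented tie-break, and the oracle test checks that convention.
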