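# octa3d

Volume-rendered 3D quantification of macular perfusion from optical
coherence tomography angiography (OCTA), for retinal imaging researchers
studying early microvascular change — e.g. diabetic eyes before any visible
retinopathy — where conventional 2D en-face metrics are limited by slab
segmentation artifacts.

## What it computes

Conventional OCTA analysis flattens the angiographic cube into en-face slab
images and reports a 2D perfusion density per plexus.  The volume-rendered
approach instead quantifies the vasculature in 3D.  Given a co-registered
structural OCT volume and an OCTA decorrelation volume (8-bit, 3 × 3-mm
macular cube), the pipeline runs:

1. **Projection-artifact removal** — superficial vessels cast decorrelation
   "tails" down the beam axis; a per-A-scan peak-retention algorithm
   attenuates them (a scaled-subtraction baseline is also available).
2. **Retina segmentation** — ILM and outer retinal boundary located on the
   structural volume; the OCTA cube is cropped to the retina and
   extraretinal voxels are zeroed.
3. **Axial rescaling** — OCTA cubes are heavily anisotropic; the z-axis is
   resampled by the pitch ratio

   ```
   Z scale = (depth extent / axial pixels) / (lateral extent / A-scans)
           = (3 × 300) / (1536 × 3) = 0.195     (default geometry)
   ```

   so voxels become isotropic before counting.
4. **Global thresholding** — a single iterative-intermeans (IsoData-style)
   threshold from the stack histogram separates flow signal from background.
5. **3D metrics** —

   ```
   3D vascular volume [mm³]  = (# suprathreshold voxels) × voxel volume
   3D perfusion density [%]  = 100 × vascular volume / neuroretinal volume
   ```

   with the neuroretinal volume integrated from the segmented thickness map.
6. **2D metrics** — SCP and DVC slabs are max-projected, binarized (Otsu by
   default) and reported as 2D perfusion densities, so the plexus-specific
   contribution to any 3D deficit can be weighed.

Because no clinical volumes ship with the package, a **synthetic phantom
generator** (`octa3d.synthetic`) produces structural/OCTA pairs with exactly
known ground truth — tube-like vessels grown to target volume fractions in
two plexus slabs, speckle, projection tails, per-eye signal-strength index
(SSI) — plus two-group cohorts with clinical covariates and a deficit
confined to the deep vascular complex.  A statistics layer applies the
SSI < 7 exclusion and emits the clinical-style report tables
(mean ± SD + Student's t per metric; Pearson correlations with HbA1c and
diabetes duration).

## Worked example

`examples/02_quantify_eye.py` simulates one desk-scale eye (80 × 80 × 192
voxels, 12 µm lateral / 3 µm axial pitch) and quantifies it:

```
axial rescale factor for this geometry: 0.250
(default full-size geometry: 0.195)
3D vascular volume:     0.0113 mm^3
3D perfusion density:   3.87 %
SCP 2D perfusion density: 29.5 %
DVC 2D perfusion density: 26.9 %
mean macular thickness: 317.8 um
macular volume:         0.2929 mm^3
ground-truth whole-retina vessel fraction: 3.90 %
```

The estimated 3D perfusion density (3.87 %) recovers the constructed
ground-truth vessel fraction (3.90 %) to within 0.03 percentage points.
The other examples demonstrate the phantom generator
(`01_simulate_eye.py`), the effect of projection-artifact removal on the
DVC density (`03_projection_removal.py`), and a full cohort report with
both tables (`04_cohort_report.py`).

A thin CLI wraps the same functions for shell use:

```bash
octa3d simulate --n-per-group 5 --seed 0 --out-dir scans/
octa3d process --octa scans/dia-000_octa.tif \
               --structural scans/dia-000_structural.tif --out metrics.json
octa3d cohort --n-per-group 10 --seed 0 --out report/
```

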