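# octava — automatic visual-acuity estimation from OCTA images

Visual acuity (VA) is normally measured with manual eye charts — a slow,
subjective procedure.  In retinal vascular disease (e.g. retinal vein
occlusion), vision loss tracks measurable changes in the macular
microvasculature that OCT angiography (OCTA) images directly.  `octava`
implements a fully automatic estimator of decimal VA from four en-face
OCTA scans of a consultation (3 mm and 6 mm fields of view, superficial
and deep capillary plexus):

1. **FAZ area.**  The foveal avascular zone is segmented on the 3 mm SCP
   scan (white top-hat → hysteresis edge detection → morphological
   closing/opening → complement → largest-and-centered candidate →
   region-growing contour refinement) and its area is converted to mm²:

   `Area_FAZ = p · mm² / (H · W)`

   for a `p`-pixel mask on an `H × W` image covering `mm × mm` of retina.

2. **Vessel density.**  Each scan is binarised with the adaptive (Otsu)
   threshold minimising the within-class variance
   `σ²_w(t) = ω₀(t)σ₀²(t) + ω₁(t)σ₁²(t)`, thinned to one-pixel
   centerlines by iterated hit-or-miss thinning
   `Thinning(I, e) = I ∩ ¬HitOrMiss(I, e)`, and summarised as
   `VD = 100 · p / (height · width)` — globally and per sector of an
   ETDRS-style circular grid (central / temporal / nasal / superior /
   inferior, with laterality-aware nasal–temporal assignment).

3. **Regression.**  The 21 biomarkers per consultation (FAZ area + 5
   sector densities × 4 scans) feed an ε-SVR on standardised features.
   VA is regressed on the logMAR-style scale `−log₁₀(VA)`;
   hyperparameters come from an exhaustive grid search under 5-fold CV on
   an 80/20 split, scored by mean absolute error.  Reported metrics are
   MAE, RMSE and the *increment* `100 · (RMSE − MAE) / RMSE`, a summary
   of how heavy-tailed the errors are.

Clinical OCTA data are private, so the package ships a first-class
synthetic-angiogram generator (`octava.synthetic_octa`) producing
branching capillary networks with controllable per-sector density, a FAZ
bounded by a perifoveal arcade, speckle and background drift — with exact
ground truth, and cohorts with a known linear feature→VA link, so every
stage is testable end to end.

## Worked example

```python
import numpy as np
from octava import (SyntheticParams, generate_vessel_image, segment_faz,
                    AngioImage, vd_proposed, build_grid, quadrant_densities,
                    generate_cohort, VisualAcuityModel, SearchConfig)

sample = generate_vessel_image(SyntheticParams(faz_radius_mm=0.35, seed=7))
img = AngioImage(pixels=sample.image, fov_mm=3, plexus="SCP", laterality="OD")
faz = segment_faz(img)
print("FAZ area: %.4f mm^2" % faz.area_mm2)

mask, skel, vd = vd_proposed(sample.image)
grid = build_grid(sample.image.shape, 3, "OD")
qd = quadrant_densities(skel.grid, grid)

cohort = generate_cohort(n=200, seed=42, noise_sigma_va=0.05)
X = np.array([c.features_true for c in cohort.samples])
va = np.array(cohort.va_true)
print(VisualAcuityModel(X, va).fit(SearchConfig(seed=0)).summary())
```

prints (abridged):

```
FAZ area: 0.3908 mm^2                   # generating truth: 0.3839 mm^2
Otsu threshold 118; global skeleton VD 3.52%   (true 4.22%)
sector VD: central 3.93  temporal 4.48  nasal 3.71  superior 3.92  inferior 4.47

Visual acuity SVR results
==============================================
n train / n test            160 / 40
selected hyperparameters    kernel=rbf, C=1.0, epsilon=0.01, gamma=0.01
test MAE  (log10 VA)        0.0435
test RMSE (log10 VA)        0.0607
RMSE-over-MAE increment     28.38%
==============================================
```

The segmented FAZ lands within ~2% of the generating disk; the
grid-searched SVR recovers the planted linear VA link to a test MAE of
0.04 on the log₁₀ scale, within the 0.05 noise floor of the simulated
acuity measurements.

## Command line

```sh
octava synth --n 20 --size-px 320 --out cohort/        # render a cohort
octava features --manifest cohort/manifest.csv --out features.csv
octava train --features features.csv --seed 7 --out model.joblib
octava faz --image scan.png --fov 3 --out mask.png     # single-scan tools
octava vd --image scan.png --method proposed
octava analyze --features features.csv --out report.json
```

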