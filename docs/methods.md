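# Methods

## Problem and pipeline

The package estimates decimal visual acuity (VA) of a pathological eye
from four en-face OCTA acquisitions of one consultation: 3 mm and 6 mm
fields of view, each for the superficial (SCP) and deep (DCP) capillary
plexus.  Two biomarker families are extracted automatically and fed to a
support-vector regressor: the foveal avascular zone (FAZ) area on the
3 mm SCP scan, and skeleton-based vessel densities (VD) over a five-sector
circular grid on all four scans.

VA is modelled on the logMAR-style scale `y = −log₁₀(VA_decimal)`, which
maps the clinical decimal range [0.1, 1.0] onto [1, 0] with equidistant
steps; errors (MAE, RMSE) are reported on this scale.  The *increment*
`100·(RMSE − MAE)/RMSE` summarises error-tail heaviness: identical errors
give 0%, a few large outliers push it up.

## FAZ segmentation

Chain: white top-hat (disk radius 7 px at 320 px width) → Canny-style
hysteresis edge detection → morphological closing (disk 6) and opening
(disk 2) to turn vessel edges into solid vascular bands → complement →
connected components ≥ 350 px → candidate selection → region growing.
All radii scale linearly with image width (areas quadratically); defaults
are validated at 320 px and degrade below that — callers working at lower
resolution should re-tune `FazConfig`.

Parameter choices that were genuinely open:

* **Edge thresholds.**  Percentile-based hysteresis (low = 80th, high =
  93rd percentile of the Gaussian gradient magnitude, σ = 1.5) keeps the
  detector exposure-invariant.  Sharper settings (σ = 1.0, 70th/90th)
  fire on speckle over a third of the frame and the closing then floods
  the FAZ; the chosen defaults mark ~4% of pixels and isolate the FAZ gap
  to within a few pixels of its true boundary on synthetic scans.
* **Candidate selection.**  The score `area / (1 + λ·d)` (λ = 0.01 px⁻¹,
  d = centroid-to-centre distance) implements "largest and centered" with
  deterministic tie-breaks (smaller d, then smaller label).  A candidate
  *containing the image centre* takes precedence over the score: the
  fovea centre lies inside the FAZ by definition, whereas the peripheral
  inter-vessel background forms a ring whose centroid also falls at the
  image centre, so a centroid score alone cannot separate the two.
* **Region growing.**  8-connected flood from the selected candidate; a
  frontier pixel joins while |intensity − running region mean| ≤ 40 gray
  levels, FIFO order with fixed neighbour order (deterministic).  The
  tolerance sits between background variation (speckle σ ≈ 10% of a
  30–60 gray-level background) and the ≳120 gray-level vessel contrast.

Area conversion is exact by construction: `area = p·fov² / (H·W)` mm².

## Vessel density

* **Threshold.**  Otsu's criterion is minimised by exhaustive search over
  t ∈ [0, 255] with classes {intensity < t} and {≥ t}; candidates leaving
  a class empty are skipped, ties return the smallest minimiser.
  Binarisation keeps pixels strictly above t ("higher-intensity pixels
  are vessels"); the strict inequality is the package's declared
  convention for tie pixels.
* **Thinning.**  Iterated morphological thinning with the standard
  Golay-L element pair over its eight rotations until a fixed point;
  homotopic (preserves 8-connectivity and holes), endpoint-preserving,
  idempotent.  Vessels fade gradually at their borders, so only the
  centerline pixels are counted.
* **Baselines.**  Four simpler literature variants are provided for
  comparison: raw intensity mass (`100·mean/255`), fixed-threshold pixel
  density, weighted density (weight 1 above t, intensity/t below — the
  weighting is the package's declared reading, since no formula is
  recoverable for it), and a skeleton density after a fixed threshold.
  The fixed threshold defaults to 128 (mid-scale), configurable.

Sector densities divide by the sector's own pixel count (not the whole
image) so sectors of different size are comparable; the global figure
uses the whole image.  The central disk is 1 mm diameter (ETDRS
convention) for both fields of view; the outer radius is the inscribed
circle.  Annulus pixels split by the ±45° diagonals; exact-diagonal ties
go to the vertical sectors, a rule symmetric under mirroring and 180°
rotation so the laterality and rotation equivariances hold exactly.

The default feature vector has 21 entries (FAZ area + 5 sectors × 4
scans); a layout switch appends the 4 global densities (25).  The layout
descriptor is persisted with any trained model and mismatching tables are
rejected at predict time.

## Regression

ε-SVR on standardised features (scaler fit inside each CV fold — no
leakage).  Split: seeded shuffle, train = ⌊0.8·n⌋ (215 → 172/43).  Grid:
kernels {RBF, linear} × C {0.1, 1, 10, 100} × ε {0.01, 0.05, 0.1} ×
γ {scale, 0.01, 0.1} (γ only for RBF; 48 points), scored by 5-fold CV
mean MAE, first grid point winning ties.  The statsmodels-style surface
(`VisualAcuityModel.fit() → VAResults.summary()`) wraps the functional
operations; both are exported.

MAE ≤ RMSE is asserted on every evaluation (power-mean inequality).  A
perfect fit (RMSE = 0) reports increment 0 with a degenerate flag.

## Synthetic angiograms

The generator emulates the image properties the pipeline must survive:

* **Vasculature.**  Walkers seeded on the border where the centre-to-aim
  ray exits the frame, biased toward an aim point in the currently most
  deficient sector, direction = momentum + aim pull + jitter, branching
  with probability 0.25 per segment up to depth 3.  Paths are drawn as
  Bresenham segments between waypoints, so the recorded centerline is a
  genuinely thin 8-connected set and its pixel count is an honest length
  (a per-pixel jittered walk overstates its own length by ~40% once
  thinned).  Spawning is closed-loop: walkers keep coming until every
  sector meets its target density; any walker stops when the sector under
  its tip has met its budget, which keeps overshoot within ~10% relative.
* **FAZ.**  Centerlines are rejected within the avascular disk plus one
  vessel half-width; a *complete* perifoveal arcade ring is drawn just
  outside the rim (the FAZ is anatomically bounded by a continuous
  capillary arcade, and a gapped ring would let contour refinement flood
  out).  Consequence: with a FAZ present the central sector has an
  anatomical density floor of ring-length/|central| (≈2.9% at 0.35 mm,
  320 px); density targets below the floor are exceeded by construction.
* **Rendering.**  Vessels get a Gaussian radial profile (σ = 1.5 px at
  320 px, scaled with width; peak 185 gray levels) over a background of
  28 plus a smooth additive ramp (default peak 30, random orientation).
  Speckle is multiplicative Gamma noise smoothed to a ~1.5 px grain
  (the imaging point-spread function imposes a finite speckle grain) and
  rescaled to a per-pixel σ of 10% of local intensity.  Defaults were
  chosen once as plausible for en-face OCTA; no quantitative noise
  characterisation of clinical scans was available to match.
* **Cohorts.**  Per consultation: one FAZ radius ~ U(0.2, 0.5) mm shared
  by all four scans, per-sector density targets U(3, 8)% (SCP) and
  U(2, 6)% (DCP, rendered with more speckle), laterality fair-coin.
  Features are taken from generator ground truth; log-scale VA =
  1.75 + w·features + N(0, σ), floored at 0, with default weights +0.5 on
  FAZ area and −0.015/−0.010 per SCP/DCP sector density — VA worsens with
  FAZ enlargement and improves with vessel density.  Cohort images render
  at 160 px by default (the VA link uses ground-truth features, so image
  resolution is irrelevant there); use `size_px=320` when the images
  themselves will be measured.

What the generator does **not** emulate: motion and projection artifacts,
vessel caliber heterogeneity and tortuosity statistics, capillary dropout
patterns of real disease, inter-scan registration error, and the true
(unknown) clinical noise spectrum.  Passing recovery tests therefore
demonstrates internal consistency of the measurement chain, not clinical
accuracy; the published clinical error figures are not reproducible
without the private dataset.

## Experiment sizes

The shipped experiments use sizes that keep the whole suite around a
minute of CPU: FAZ recovery over radii {0.2, 0.3, 0.4, 0.5} mm at 320 px;
density recovery at targets {1, 2, 4}%; the regression recovery cohort
n = 200 (160 train / 40 test) with VA noise σ = 0.05, for which the
grid-searched SVR reaches test MAE ≈ 0.04–0.05 — within the 2σ noise
budget of 0.10 used as the pass bound.

## Known limitations

* An Otsu threshold on a vessel-free noisy frame still splits the
  background and the homotopic skeleton of the resulting speckle mask is
  dense lace, so the pipeline reports *higher* density on pure noise than
  on sparse vasculature.  This is a known artifact of adaptive
  thresholding on structureless frames (and consistent with noisier
  deep-plexus scans degrading every density variant); only a noise-free
  background yields the intuitive near-zero density.
* Segmentation defaults are tuned for ~320 px scans; at 160 px the thin
  arcade is not reliably sealed and FAZ areas become unreliable.
* The 21-feature layout is the default; a 22nd feature (e.g. a global
  density) can be enabled via the layout switch, but nothing in the
  estimator depends on the choice.
* SVR solutions are deterministic given data order up to the SMO solver
  tolerance (~1e−3 on predictions), not bit-identical under permutation.
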