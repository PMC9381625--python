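# Methods

This note records the scientific and numerical choices behind `dlmvoi`,
what the synthetic phantom does and does not emulate, and the problem
sizes used by the test suite and the acceptance script.

## The VOI method

The input per lesion is a single click voxel on the ADC map. The method
assumes the reader can point at the visually lowest-ADC region of the
lesion within a couple of voxels; everything after the click is
deterministic.

**Search neighborhood.** The click's candidate set is itself plus the 56
integer offsets `v ≠ 0` with squared Euclidean lattice norm `‖v‖² ≤ 5`
(shells 1, 2, 3, 4, 5 contribute 6 + 12 + 8 + 6 + 24 offsets). This is the
unique small lattice ball with exactly 56 elements; the neighborhood
definition is configurable (`NeighborhoodSpec`) for sensitivity
analysis. The search is a single pass — one neighborhood check of the
click, not an iterated descent.

**Robust scoring.** Each candidate is scored by the mean ADC over itself
and its available in-bounds, in-mask face neighbors (up to 7 voxels). A
single-voxel outlier can shift this "cross-mean" by at most 1/7 of its
deviation, so an isolated dark voxel loses to a coherent dark blob. Ties
break by (score, physical distance to the click, then lexicographic
(k, j, i)), which makes a uniform image return the click itself.

**Sphere rasterization.** Voxel `(i, j, k)` belongs to the VOI iff the
Euclidean distance between voxel centers, computed with the anisotropic
spacing, is `≤ d/2` (non-strict; 0-based indices). On the default grid
(0.5 × 0.5 mm in-plane, 3 mm slices) an 18-mm sphere covers about 3.9 k
voxels over 7 slices. The rasterizer converges to the analytic volume
`(π/6) d³` as spacing shrinks (verified at 0.25 mm isotropic, < 2% error).

**Masking and quality control.** The sphere is intersected with the
whole-prostate mask. The seed voxel lies inside the lesion and hence the
prostate, so its removal can only mean a defective mask; that raises
`QualityControlError` rather than silently producing a VOI without its
seed.

## Radiomics features

93 features per sequence: 18 first-order, 24 GLCM, 16 GLRLM, 16 GLSZM,
14 GLDM, 5 NGTDM; 3 sequences (T2, ADC, DWI) give 279 per lesion.

* **Normalization:** whole-image z-score, then ×100. With unit-variance
  images a bin width of 30 would collapse the histogram to ~1 bin; scale
  100 yields the intended few-tens-of-bins regime.
* **Discretization:** fixed bin width `W = 30` inside the VOI;
  `level(x) = floor((x − min)/W) + 1`. Shift-invariant by construction.
* **Forced 2D:** texture matrices are built per axial slice (and per
  in-plane direction 0°/45°/90°/135° for GLCM and GLRLM) over VOI voxels
  only, with distance-1 neighbors — every interior voxel has exactly 8
  in-plane texture neighbors. Feature values are averaged uniformly over
  all matrices; slices (or slice-direction pairs) yielding no valid matrix
  are skipped, not zero-filled. First-order features use the full 3D VOI
  voxel set, which is geometry-free.
* **No resampling, no image filters, no shape features** (shape features
  belong to manual-segmentation workflows; a fixed-diameter sphere has no
  informative shape).
* **Degenerate conventions:** constant input has skewness = kurtosis = 0;
  zero-variance GLCM correlation = 1 and MCC = 1; NGTDM coarseness is
  capped at 10⁶ when its denominator vanishes; busyness/strength/contrast
  fall back to 0. These conventions are shared by the naive reference
  implementation used in the oracle-equivalence tests.

The equivalence suite compares every feature against an independent,
pure-Python, loop-based reference (`tests/reference_features.py`) on
random small VOIs at 1e-6 relative tolerance.

## Feature selection (JMIM)

Features are discretized by equal-frequency binning (default B = 10);
mutual information uses the plug-in estimator in bits. Greedy selection:
first pick maximizes `I(f; Y)`; each later pick maximizes
`min over selected s of I((f, s); Y)` — the maximin criterion that rejects
candidates redundant with *any* already-selected feature (a duplicated
column is never worth picking twice). Criterion values are snapped to
1e-10 bits before each argmax so mathematically tied candidates break by
column order rather than floating-point summation order.

## Model and optimization

XGBoost (`gbtree`) with the nested objective: stage 1 runs JMIM on each
training portion of a randomized five-times-repeated 5-fold split and
ranks features by selection frequency (ties by mean selection rank); the
top-k enter stage 2, a shuffled 10-fold CV scored by mean average
precision. Binning for stage 1 is computed once on the full training split
(it is unsupervised); the folds randomize which rows JMIM sees.

The optimizer is a seeded sequential random sampler over

| parameter | space |
|---|---|
| features k | 2 … 40 (integer) |
| boosting rounds | 5 … 200 |
| max depth | 2 … 6 |
| learning rate | log-uniform 0.01 … 0.3 |
| class weight w | log-uniform r/2 … 2r, r = (#non-CS)/(#CS) on training rows |

returning the argmax trial; any sequential model-based sampler with seeded
draws would satisfy the same contract — the bespoke part is the objective,
not the sampler. The final model refits on all training rows with the best
trial's parameters and its stage-1 feature list (fold-frequency
aggregation; `select_features_nested` also serves as the single-fit
alternative when called with one repeat).

Note the objective is optimistically biased: stage-1 selection sees rows
that stage-2 later validates on, and average precision itself has a
positive small-sample bias (≈ 0.46 for a random ranker on 30-sample folds
at prevalence 0.4, versus the asymptotic value 0.4). The held-out test
split is the only unbiased measurement and is touched exactly once.

## Evaluation

* AUC = normalized Mann-Whitney U, ties ½ (exhaustively verified by pair
  counting).
* CI: DeLong structural-components variance, normal approximation, clipped
  to [0, 1]; degenerate variance collapses to a point interval.
* Model comparison: two-sided paired DeLong. A multi-reader multi-case
  variance decomposition would be overkill here — there is exactly one
  "reader" per model and the cases are fully paired, for which paired
  DeLong is the standard test.
* Operating threshold: Youden's J maximization (score ≥ t calls positive),
  lowest threshold among maximizers. The criterion is applied to whichever
  set is being reported; thresholds are descriptive, not tuned parameters.
* Diameter sweep: one model per diameter on an identical train/test split,
  so the AUC-vs-diameter curve isolates the VOI-size effect.

## The phantom

The generator emulates the *data contract* of a multi-center bpMRI cohort,
not MR physics:

* **Geometry:** axis-aligned ellipsoidal gland (half-axes 25 × 20 × 15 mm,
  ±10% per-case jitter) on a 112 × 112 × 20 grid at 0.5 × 0.5 × 3 mm —
  anisotropy chosen to stress the physical-space sphere rasterizer.
* **Lesions:** 1–3 per case, spherical, radii uniform 4–8 mm (mean 6 mm);
  35% of lesion centers are placed within 5 mm of the gland boundary so a
  naive 18-mm sphere demonstrably leaks outside the prostate and the
  masking step is exercised.
* **Contrast:** ADC levels background 800, gland 1300, non-CS core 950,
  CS core 650 (arbitrary units on the 10⁻⁶ mm²/s scale; low ADC marks
  clinically significant disease). The cores blend radially into the
  gland. T2 shows lesions dark, high-b DWI bright, with analogous
  class-dependent levels. No reference protocol quantifies lesion
  contrast; these levels were chosen once as clinically plausible
  and are deliberately strong enough that recovery tests are well-posed.
* **Texture:** multiplicative smoothed-Gaussian random fields inside
  lesions — CS lesions get larger amplitude (0.20 vs 0.08) and shorter
  correlation length (1.2 vs 3.0 mm), giving texture features
  discriminative signal beyond mean intensity.
* **Center effects:** per-center global intensity scale ~U(0.8, 1.25) and
  additive Gaussian noise with per-center sd ~U(20, 60) ADC units
  (attenuated ×0.3 on T2/DWI whose scales are smaller).
* **Clicks:** the true in-lesion ADC argmin jittered uniformly within a
  Chebyshev radius of 2 voxels, restricted to lesion ∩ prostate.

Not emulated: b-value physics, zonal anatomy, registration error,
non-ellipsoidal glands, non-spherical lesions. Consequently, passing
recovery tests shows the *pipeline* is correct and leak-free, not that the
clinical effect size is reproduced — phantom AUCs (~0.9+) are far above
the clinical range by design, and the package makes no claim about
clinical AUC values.

## Problem sizes and budgets

Chosen as the package's defaults for routine verification:

* Recovery experiment: default phantom (120 cases, ~250 lesions, 40% CS,
  seed 7), 18-mm VOIs, optimizer budget 30, split seed 0. Expected:
  held-out AUC ≥ 0.85; after label permutation, AUC in [0.38, 0.62].
* Calibration: DeLong CI coverage over 1000 binormal cohorts (n = 200,
  true AUC 0.75), expected 93–97%; null p-value KS statistic over 2000
  replicates.
* Sweep: 45-case phantom, all 13 diameters, budget 10. Expected: the
  6-mm model does not beat the best mid-range (10–22 mm) model, because a
  sphere matching the mean lesion *radius* under-covers the lesion.

## Known limitations

* The phantom's class contrast is a free parameter; absolute AUCs on it
  are not transferable.
* The per-slice-per-direction matrix averaging is one defensible reading
  of unweighted forced-2D averaging; pooling counts across slices per
  direction is another and would shift texture feature values slightly.
* The plug-in MI estimator is biased upward at small n; selection
  frequencies across folds mitigate but do not remove this.
* The sequential optimizer is a random sampler; with large budgets a
  model-based sampler (e.g. TPE) would reach the same argmax contract
  faster.
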