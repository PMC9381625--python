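# dlmvoi

Single-click, prostate-masked spherical VOI radiomics for classifying
clinically significant prostate cancer (CS PCa, ISUP grade ≥ 2) on
biparametric MRI (T2-weighted, high-b DWI, ADC).

Manual 3D lesion segmentation for radiomics takes an expert minutes per
lesion and is a major source of inter-observer variance. This package
implements a semi-automatic alternative: the reader clicks once on the
visually lowest-ADC part of a lesion, and the method does the rest —

1. **Seed repositioning.** The click is moved to the voxel minimizing an
   outlier-robust *cross-mean* ADC score (the voxel averaged with its ≤ 6
   face neighbors) over a 56-offset search neighborhood (all nonzero integer
   offsets `v` with ‖v‖² ≤ 5), so a single noisy voxel cannot capture the
   seed.
2. **Auto-fixed spherical VOI.** A sphere of fixed physical diameter *d*
   (candidates 6–30 mm in 2-mm steps) is rasterized around the seed on the
   anisotropic voxel grid.
3. **Prostate masking.** The sphere is intersected with the whole-prostate
   segmentation; a quality check guarantees the seed voxel survives.
4. **Radiomics.** Per sequence: whole-image z-normalization (×100), fixed
   bin-width (30) discretization, 18 first-order features on the 3D VOI, and
   five texture families (GLCM, GLRLM, GLSZM, GLDM, NGTDM) in forced-2D with
   distance-1 neighbors (in-plane connectivity 8) and unweighted averaging of
   per-slice(-direction) matrices — 93 features × 3 sequences = 279.
5. **Selection + model.** Greedy joint-mutual-information-maximization
   (JMIM: each pick maximizes `min over selected s of I(f, s; Y)`) inside a
   five-times-repeated 5-fold split, followed by 10-fold CV of an XGBoost
   classifier scored by mean average precision; a seeded sequential
   optimizer searches feature count, boosting rounds, depth, learning rate
   and a class weight centered on the non-CS/CS imbalance ratio.
6. **Evaluation.** 4:1 train/test split, ROC AUC with DeLong 95% CI, paired
   DeLong model comparison, Youden-J operating threshold, and the
   AUC-vs-diameter sweep.

Because clinical bpMRI cohorts are private, the package ships a seeded
multi-center phantom generator (`dlmvoi.phantom`): ellipsoidal glands,
lesions with class-dependent low-ADC cores and texture heterogeneity,
per-center intensity scale and noise, and gland-edge lesions whose naive
sphere leaks outside the prostate. Every stage is tested against it.

## Worked example

```python
import dlmvoi as d
from dlmvoi.evaluation import extract_cohort_table, evaluate_scores

cfg = d.PhantomConfig(n_cases=40, seed=7)
cases, clicks = d.simulate_cohort_with_clicks(cfg)

les = cases[0].lesions[0]
voi = d.build_dlm_voi(cases[0].volumes["ADC"], d.ClickPoint(clicks[les.lesion_id]),
                      cases[0].prostate_mask, diameter_mm=18.0)

table = extract_cohort_table(cases, clicks, diameter_mm=18.0)
feats = table.drop(columns=["case_id", "lesion_id", "label"])
y = table["label"].to_numpy()
tr, te = d.split_cohort(len(table), y, d.SplitSpec(seed=0))
params, model, _ = d.optimize(feats.iloc[tr], y[tr], budget=10, seed=0)
res = evaluate_scores(d.predict(model, feats.iloc[te]), y[te], model_id="dlm_voi_18mm")

print(f"click {clicks[les.lesion_id]} -> seed {voi.seed_voxel}, VOI voxels {voi.voxel_count}")
print(f"{len(table)} lesions ({y.sum()} CS), {feats.shape[1]} features")
print(f"best trial: k={params.n_features}, rounds={params.n_rounds}, "
      f"depth={params.max_depth}, lr={params.learning_rate:.3f}, "
      f"w={params.class_weight:.2f}, objective={model.objective_value:.3f}")
print(f"test AUC {res.auc:.3f} [{res.ci_low:.3f}-{res.ci_high:.3f}], "
      f"sens {res.sensitivity:.2f} / spec {res.specificity:.2f} "
      f"at threshold {res.threshold:.3f}")
```

Output:

```
click (71, 61, 7) -> seed (71, 60, 8), VOI voxels 3927
82 lesions (36 CS), 279 features
best trial: k=12, rounds=39, depth=6, lr=0.223, w=1.35, objective=0.972
test AUC 0.955 [0.865-1.000], sens 1.00 / spec 0.91 at threshold 0.975
```

The click lands near the lesion's ADC minimum and is snapped to the robust
local minimum; the 18-mm sphere holds 3927 voxels after prostate masking.
On the 40-case phantom the tuned model separates CS from non-CS lesions
almost perfectly (test AUC 0.955) because the phantom's class contrast is
by construction strong; on clinical data the same pipeline would be
expected to score far lower.

A CLI mirrors the stages: `dlmvoi simulate | voi | extract | select |
train | evaluate | sweep` (see `dlmvoi --help`).

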