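# deltasurv

Delta-radiomics survival modelling for small paired-PET cohorts.

In rare cancers such as high-grade glioma, longitudinal imaging cohorts
are tiny — on the order of 18 patients with two PET scans. `deltasurv`
implements a sample-efficient pipeline for predicting progression-free
survival (PFS) from the *change* of radiomics features between two
scans, together with everything needed to exercise it end-to-end without
patient data: a synthetic-cohort generator with a planted delta-borne
prognostic signal, a parametric-imaging front end (TBR and TTP images
from dynamic PET), and a compact IBSI-style radiomics extractor.

## The method

From per-patient features F<sub>PET0</sub>, F<sub>PET1</sub> and scan
times t₀ < t₁, five feature sets are built: single time point (F₁),
delta-absolute (F₁ − F₀), delta-relative ((F₁ − F₀)/F₀), and their
time-weighted forms divided by t₁ − t₀. Per training fold the pipeline
fits, in order: zero-variance removal and Z-scoring; bootstrap consensus
clustering of features (complete-linkage agglomeration on
1 − |Spearman ρ| cut at ρ = 0.9, aggregated over 500 patient bootstraps
through a co-association matrix thresholded at 0.5) with one medoid
retained per cluster; one of four feature-selection methods (univariate
C-index filter, mutual-information filter, LASSO-Cox, RFE) choosing
k ∈ {1, 2, 3} features; and one of four linear time-to-event regressors
(CoxPH, elastic-net Cox, ranking survival SVM, componentwise gradient
boosting), a 4 × 4 model grid. Performance is Harrell's C-index and an
IPCW integrated time-dependent AUC under repeated stratified
cross-validation (4 folds × 25 repeats), summarized by 1000-bootstrap
mean ± SE with 95% CI; delta-vs-single-time-point and
radiomics-vs-conventional orderings are tested with one-sided
Mann–Whitney U and Benjamini–Hochberg correction. Robustness is
reported as mean pairwise adjusted Rand index of the fold partitions,
per-cluster medoid consistency, and exact linear SHAP feature rankings.
A two-stage "fine-tuned" strategy transfers Gaussian-process-optimized
hyperparameters and SHAP-ranked features from a larger single-scan
cohort to the paired cohort. See `docs/methods.md` for the full model
description and pinned conventions.

## Worked example

Generate the default synthetic cohort (18 patients, 6 correlated feature
blocks × 5 features + 9 conventional features, a planted log-hazard of
1.5 per SD carried by block 0's change, ~89% events, median PFS
≈ 11 months) and fit the best-performing pipeline of the emulated study
— survival SVM with RFE on delta-absolute radiomics, one selected
feature:

```python
import deltasurv as ds
from deltasurv.preprocessing import ClusteringConfig
from deltasurv.synthetic import CohortSpec, generate_cohort

cohort = generate_cohort(CohortSpec(seed=0))
model = ds.DeltaSurvivalModel.from_cohort(
    cohort.table, cohort.outcomes, kind="delta_abs", source="radiomics",
    selector="rfe", regressor="svm", k=1,
    clustering=ClusteringConfig(n_boot=100), selector_n_boot=100, seed=0)

print(model.fit().summary())
print(model.fit_cv(ds.CVScheme(n_folds=4, n_repeats=10, seed=0)).summary())
```

```
Delta-radiomics survival pipeline
  pipeline:          svm+rfe(k=1)
  patients / events: 18 / 14
  input features:    30
  clusters (medoids): 21
  selected features: rad_b00_f01
  training C-index:  0.865
  risk weights:
    rad_b00_f01                              -0.9092

Repeated cross-validation
  pipeline:  svm+rfe(k=1)
  scheme:    4-fold x 10 repeats (40 evaluated folds)
  cindex_train  0.819 ± 0.017 [0.785, 0.850]
  cindex_test   0.799 ± 0.032 [0.734, 0.855]
  iauc_train    0.876 ± 0.019 [0.836, 0.910]
  iauc_test     0.830 ± 0.040 [0.747, 0.900]
```

The pipeline selected `rad_b00_f01` — a member of the planted block
(block 0), whose change carries the simulated signal — and its test
C-index of 0.80 [0.73, 0.86] reflects the planted effect; the negative
risk weight simply mirrors that feature's randomized sign. On the same
cohort the single-time-point and delta-conventional counterparts hover
near chance (≈ 0.5), reproducing the qualitative ordering that motivates
delta radiomics.

A thin CLI wraps the common entry points:

```bash
deltasurv simulate --n-patients 18 --seed 0 --out cohort/
deltasurv run-default --cohort cohort/ --seed 0 --out results/
deltasurv extract --static static.nii --dynamic dynamic.nii \
    --brain-mask brain.nii --tumor-search tumor.nii \
    --striatum-search striatum.nii --out features.csv
```

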