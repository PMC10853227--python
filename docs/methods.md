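# Methods

`deltasurv` models progression-free survival (PFS) in small paired-PET
cohorts from the *change* of image features between two scans. This note
describes the statistical model behind the synthetic cohorts, the
analysis pipeline and its pinned conventions, the tunable parameters, and
the limits of what the synthetic experiments demonstrate.

## The analysis pipeline

For one training/test split, the pipeline fitted on the training rows
only is:

1. **Feature set construction.** From per-patient features
   F<sub>PET0</sub>, F<sub>PET1</sub> and acquisition times t₀ < t₁
   (months), one of five tables: single time point (F₁), delta-absolute
   (F₁ − F₀), delta-relative ((F₁ − F₀)/F₀), and the two weighted forms
   dividing by the scan gap t₁ − t₀. A feature whose baseline F₀ is zero
   for any patient is dropped cohort-wide under a relative kind (a
   per-patient infinity would corrupt Z-scoring); a warning names it.
2. **Scaling.** Zero-variance features removed; the rest Z-scored with
   training-fold mean and unbiased (n−1) standard deviation. The (n−1)
   convention is a pinned choice; nothing downstream is sensitive to it
   beyond a constant factor.
3. **Consensus clustering.** Features are clustered by agglomerative
   clustering on distance 1 − |Spearman ρ| with *complete* linkage, cut
   at |ρ| = 0.9 — complete linkage makes the cut a guarantee that every
   within-cluster pair correlates at ≥ 0.9. To stabilize the partition at
   small n, the clustering is repeated on 500 bootstrap resamples of the
   training patients; the fraction of resamples in which two features
   co-cluster forms the co-association matrix, and the final partition is
   average-linkage clustering on 1 − co-association cut at 0.5 (the
   standard evidence-accumulation choice; a bootstrap replicate in which
   a feature is constant treats that feature as a singleton). Each
   cluster is represented by its **medoid**: the member maximizing the
   summed |Spearman| to the other members on the full training fold,
   ties broken to the lexicographically smallest name.
4. **Feature selection** (k ∈ {1, 2, 3} medoids): univariate C-index and
   mutual-information filters (500 patient bootstraps; per-bootstrap
   ranks aggregated by mean reciprocal rank — the importance score is a
   pinned choice), LASSO-Cox (largest penalty on the L1 path with ≥ k
   nonzero coefficients), or recursive feature elimination (refit, drop
   the smallest-|weight| feature, step 1; the full elimination order is
   computed once so selections nest across k). The C-index filter scores
   each feature by max(C, 1−C), making it direction-invariant; the MI
   filter estimates k-nearest-neighbour (k=3) MI between the feature and
   the observed time on event cases only (all cases, with a warning, when
   a bootstrap has fewer than five events).
5. **Survival regression**: Cox proportional hazards (ridge 1e-5 for
   n < p stability), elastic-net Cox (l1_ratio 0.5; the fixed penalty is
   the midpoint of the regularization path fitted on the training fold —
   deterministic and train-fold-only), the linear ranking survival SVM
   (α = 1), or componentwise gradient-boosted Cox (100 base learners,
   learning rate 0.1). All four produce risk scores *affine in the
   features* with the orientation "higher risk ⇔ earlier predicted
   progression"; the per-feature weights that RFE and SHAP consume are
   stored in that orientation.

Evaluation uses repeated stratified k-fold cross-validation (default
4 × 25, stratified by event status so no test fold is event-free — with
18 patients and ~11% censoring an unstratified fold can easily carry no
event). Scores are Harrell's C-index (comparable pairs t_i < t_j with
event_i = 1; tied risks credited 0.5; tied event times not comparable)
and an integrated time-dependent AUC: the IPCW cumulative/dynamic AUC
with censoring weights from the training fold, evaluated on the test
event times inside the 10th–90th percentile of observed test times, and
integrated by the trapezoid rule normalized by the grid span (identical
risks are defined as 0.5; a grid with fewer than two usable points falls
back to a single-time AUC with a warning). The CV score distribution is
summarized by 1000 bootstrap resamples (mean, SE, percentile 95% CI).
Model comparisons are one-sided Mann–Whitney U tests on the per-fold
test C-indices with Benjamini–Hochberg correction across the comparison
family; fold scores are not independent, so these p-values are
heuristic summaries, not exact type-I guarantees. When every score in
both groups is identical the p-value is defined as exactly 0.5 and
flagged degenerate.

### Strategies

The **default strategy** runs the full grid — five feature-set kinds ×
{radiomics, conventional} × four selectors × four regressors ×
k ∈ {1, 2, 3} — with fixed hyperparameters, then tests delta-vs-single-
time-point and radiomics-vs-conventional orderings. Within one training
fold, preprocessing is fitted once per feature table and filter/LASSO
selections once per selector (they do not depend on the regressor); RFE
is refitted per regressor.

The **fine-tuned strategy** is a two-stage transfer: stage 1 learns
hyperparameters (Gaussian-process expected-improvement search, Matern-5/2
surrogate, exact evaluation budget, maximizing the mean CV test C-index)
and a SHAP-based single-time-point feature ranking on the larger
single-scan cohort under 7 × 20 CV; stage 2 rebuilds each feature-set
kind restricted to the top-1/2/3 named features on the paired cohort and
evaluates with the stage-1 hyperparameters under 4 × 25 CV. SHAP values
are exact for these models: every regressor's risk is affine in the
features, so φ_ij = w_j (x_ij − x̄_j) with the training fold as
background, and per-row attributions sum to the centered prediction to
machine precision. Stage-1 ranking is per model; each fold's fitted
pipeline attributes the whole cohort and |φ| is pooled across folds.

Cluster robustness is reported as the mean adjusted Rand index over all
pairs of training-fold partitions, plus per-cluster medoid consistency:
with fold 1 as reference, each reference cluster is matched to its
maximum-Jaccard cluster in every other fold and we report the percentage
of folds whose matched cluster has the same medoid.

## Imaging front end

Static scans are normalized to the mean uptake of a healthy-brain
reference VOI, giving tumor-to-background-ratio (TBR) images (brain mean
exactly 1 after normalization; all TBR-derived quantities are invariant
to rescaling the input). The tumor VOI is TBR ≥ 1.6 inside a
user-supplied search region (delineation is manual in practice), with
MTV = voxel count × voxel volume; the striatum VOI is ≥ 70% of the local
maximum. Dynamic series (30 × 1 min frames) become time-to-peak (TTP)
images: each voxel's TAC is smoothed with a cubic smoothing spline
(fixed regularization λ = 1; the spline is linear in the data, so the
whole fit is one 30×30 smoother matrix applied to every TAC), divided by
the smoothed brain-mean TAC, and the TTP is the frame time of the
maximum — always on the frame grid {1, …, 30} min; an all-zero TAC has
no peak and is reported missing. The functional form of the TAC fit is a
package choice; a smoothing spline is cheap, reproducible, and imposes no
shape constraint. The nine conventional features are TBR mean/max/peak
over the tumor (peak = max over tumor voxels of the mean in a 1 cm³
world-space sphere, clipped to the image grid — the standard SUVpeak
convention), the same three statistics as tumor-to-striatum ratios
(the ratio set is a package choice; only the count of nine is fixed),
MTV, the region TTP, and the 10–30 min OLS slope of the brain-normalized
tumor TAC. TTP images are resampled to 1 mm isotropic by trilinear
interpolation (nearest-neighbour for masks) sharing the input origin.

Radiomics features are computed on fixed-bin-width discretized images
(width 0.1 for TBR, 1 min for TTP, anchored at the in-mask minimum, so
adding a constant to the image changes nothing): first-order and
intensity-histogram statistics, GLCM features averaged over the 13
unique distance-1 directions in 3D with symmetric normalized matrices
(including Information Correlation 2, clipped to [0, 1], and Cluster
Prominence; a single-level region is degenerate with both defined as 0),
basic morphology, and the local intensity peak. This is a compact,
IBSI-conformant subset (~40 features per modality); the pipeline's
contract is the feature table, so a richer external extractor can be
substituted without touching anything downstream.

## The synthetic cohort model

The generator emulates the statistical structure the analysis assumes,
with defaults frozen at the emulated study's printed characteristics:
18 patients with two scans (35 with one), ~89% progression events,
median PFS 11 months, scan gap uniform on 3–9 months with the first scan
2–4 months after treatment start.

* **Features**: 6 latent-Gaussian blocks × 5 radiomics-like features;
  each feature loads on its block latent with the loading chosen via the
  Gaussian-copula relation ρ_Pearson = 2 sin(π ρ_Spearman / 6) so the
  population within-block |Spearman| equals the requested value
  (default 0.9; feature signs are randomized). The second scan equals
  the first plus a per-patient change with the same block structure and
  magnitude 0.5 SD of the baseline features (a package choice: a
  realistic moderate treatment-scale change).
* **Signal**: only the planted block's *change latent* enters the
  hazard, with log-hazard β per SD (default 1.5). Block levels carry no
  signal, so single-time-point tables are informative only through their
  correlation with the change.
* **Conventional features**: nine columns correlated (ρ = 0.6) with the
  planted block's *level*, with pure-noise changes — so conventional
  deltas are prognostically empty, mirroring the motivating observation
  that delta radiomics can beat delta conventional features.
* **Survival**: Weibull proportional hazards with shape 1.3 (mildly
  increasing hazard). The scale is calibrated by an internal Monte Carlo
  draw so the *marginal* median event time equals the requested median —
  at β = 1.5 a β=0 calibration would miss the printed median by more
  than a month. Censoring mixes an administrative horizon (2.5 × median,
  extended to the (target+0.02) quantile of the marginal event-time
  distribution when the Weibull tail would otherwise cap the event
  fraction below the target) with Uniform(0, horizon) random censoring,
  the mixture weight solved so the expected event fraction matches the
  target.

The dynamic phantom emulates a 30-frame amino-acid PET acquisition:
gamma-variate background kinetics peaking at 20 min, with tumor voxels
multiplying that kinetic by an uptake bump peaking at 7 min — because
TTP is defined on the *brain-normalized* TAC, this construction makes
the normalized tumor curve peak exactly at the requested frame while the
static (late-frame average) contrast stays controlled. The phantom makes
no attempt at scanner physics, attenuation, or reconstruction noise
spectra.

### What the synthetic experiments do and do not show

Passing the planted-effect experiments shows the pipeline *recovers a
known delta-borne signal and stays calibrated under the null* at the
study's sample size; it does not validate the clinical effect sizes,
the realism of inter-feature correlation magnitudes (the emulated study
does not report them; the block parameters are free knobs), or
robustness to acquisition differences between scanners.

Two statistical limitations are worth knowing when interpreting the
experiments.

First, the model-comparison machinery is anticonservative by
construction: the Mann–Whitney U test is applied, as in the emulated
design, to per-fold test C-indices that are heavily dependent (every
fold reuses the same 18 patients). On null cohorts (β = 0) the one-sided
p-values are median-centered — there is no directional bias, and every
pipeline's mean test C-index sits within 0.5 ± 0.05 at n = 500 — but
they are strongly overdispersed: roughly a quarter of raw p-values fall
below 0.05 instead of one in twenty, and all comparisons within a cohort
move together. Adding CV repeats makes this worse, not better (the
U-test's nominal sample size grows without new information). The
BH-corrected p-values should therefore be read as ordering summaries,
not calibrated error rates.

Second, a limitation affecting the cluster-stability
numbers: at n = 18, the sample Spearman correlation of a pair with
population |ρ| = 0.98 has enough rank-level noise that its minimum over
the 60 within-block pairs falls below the hard 0.9 clustering cut in
roughly half of generated cohorts (mean per-cohort minimum ≈ 0.89).
Complete linkage then splits a block, and bootstrap consensus — which
resamples the same realized cohort — cannot restore a merge absent from
the full sample. Exact block recovery at that correlation level is
therefore an ~50% event, not a near-certain one, and per-cluster medoid
consistency is correspondingly heterogeneous. This is a property of
rank correlation at small n, not of the consensus machinery; with exact
duplicate blocks (|ρ| = 1) recovery and medoid consistency are 100%.

## Numerical and problem-size choices

* Consensus and filter bootstrap counts default to the full 500; the
  bundled experiments and acceptance checks run 50–100 bootstraps and
  5–10 CV repeats per configuration, sizes at which the qualitative
  orderings are already stable across generator seeds.
* The null-calibration comparison family uses a 2 selector × 2 regressor
  sub-grid over single-time-point vs delta-absolute radiomics tables —
  large enough to exercise the Benjamini–Hochberg family, small enough
  to repeat over 20 generator seeds.
* The ranking SVM can stop on a precision-loss message at very small n
  after reaching a usable optimum; the fitted weights are still valid
  and the warning is suppressed. Near-separable Cox fits can overflow
  `exp` in the partial likelihood; a genuinely singular fit raises an
  explicit convergence error carrying the model identifier.
* All randomness flows from explicit integer seeds; identical
  seed + configuration reproduces every table, partition and score
  bit-for-bit.
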