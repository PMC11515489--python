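# Methods

`omicspred` implements a clustering-aided prediction workflow for
progressive-disease cohorts, modeled on idiopathic pulmonary fibrosis
(IPF) registry data: blood omics blocks (circulating proteins and
miRNAs) enter risk prediction models either as raw values or as
molecular-endotype cluster labels, and a repeated train/test design
measures what they add beyond demographic and clinical factors.

## The repeated evaluation workflow

Each repetition draws an event-stratified 80/20 split of the cohort.
Spectral clustering is fit on the training patients of each omics block
only; held-out patients receive labels through a Nyström extension, so
no test information reaches the clustering. For every model family
(a subset of the covariate blocks `demo`, `clin`, `raw_prot`,
`lbl_prot`, `raw_mirna`, `lbl_mirna`), the penalty of an L1-penalized
Cox model (composite time-to-event outcomes) or L1-penalized logistic
model (binary 1-year outcomes) is tuned by an inner 10-fold
cross-validation on the training set, the model is refit at the chosen
penalty, and the held-out fifth is scored with Harrell's C-index (Cox;
risk score = the linear predictor Xβ) or AUC (logistic). Metrics are
aggregated over repetitions as mean and standard error
(SE = sd/√R; the median is also reported), and the relative percent
change `100·(augmented − base)/base`, rounded to one decimal from the
unrounded means, quantifies the omics contribution. A companion value
computed from means pre-rounded to three decimals is also written,
since published tables often mix the two conventions.

Interpretation of the two sources of randomness: the outer repeated
80/20 splits estimate generalization performance; the inner 10-fold CV
serves penalty tuning only. All randomness flows from one master seed
through `numpy.random.SeedSequence` spawning, so a run is bit-for-bit
reproducible.

## Spectral clustering and out-of-sample assignment

Features are standardized with training means/SDs. The Gaussian
affinity `W_ij = exp(−‖x_i−x_j‖²/(2σ²))` uses the median of pairwise
Euclidean distances as the default bandwidth σ (scale-free; a fixed
bandwidth is available). The symmetric normalization
`D^{−1/2} W D^{−1/2}` is eigendecomposed; the top-k eigenvector rows
are normalized to unit length and clustered by k-means (10 seeded
restarts). Cluster indices are relabeled by descending cluster size
(ties by original index) so labels are deterministic. The affinity is
dense — at cohort sizes of a few hundred patients sparsification buys
nothing and adds knobs.

k defaults to 2, following the prior finding of two molecular
endotypes in this patient population; `choose_k` offers an advisory
eigengap heuristic (the k in [2, k_max] maximizing λ_k − λ_{k+1}),
returning the floor k=2 flagged `low_confidence` when the largest gap
is under 0.1. Note that the eigengap under the median-heuristic
bandwidth is only informative when clusters are separated in most
feature directions; abundant uninformative features flatten it.

Out-of-sample points are embedded by the Nyström extension: the kernel
vector from a test point to the training points is degree-normalized,
projected on the stored eigenvectors scaled by 1/eigenvalue,
row-normalized and assigned to the nearest k-means centroid. A test
point identical to a training point reproduces that point's embedding
exactly. A point so far from training data that its kernel vector
underflows to zero falls back to the nearest cluster mean in
standardized feature space (logged); a pure feature-space
nearest-centroid strategy is available as a sensitivity flag.

## Penalized models

Both solvers minimize a mean-scaled smooth loss plus `λ·Σ w_j|β_j|`:
the negative Cox partial log-likelihood with Breslow tie handling
(scaled by 1/n), or the mean binomial deviance with an unpenalized
intercept. All design columns — including demographic indicators and
cluster labels — are penalized identically by default (`w_j = 1`);
per-column weights allow forcing a named block into the model, since
published analyses do not always say whether base covariates were
penalized.

The optimizer is proximal Newton in the glmnet style: a quadratic
model built from per-observation gradients and curvatures, solved by
cyclic coordinate descent with soft-thresholding (active-set sweeps
between full sweeps), followed by a monotone line search — step
halving if the true objective would rise, doubling expansion while it
keeps falling (the diagonal-curvature model under-steps along flat,
correlated directions; expansion removes a long geometric tail of
iterations at dense ends of the path). Convergence is declared only
after a plain (t=1) coordinate-descent step, so the final iterate
carries the exact soft-threshold sparsity pattern, when either the
maximum coefficient change falls below 1e-7 or the objective
improvement sits below double-precision resolution twice in a row.
`λ_max` (the smallest penalty zeroing all penalized coefficients) is
inflated by a relative 1e-10 so the all-zero solution survives float
rounding at the top of the grid. Linear predictors are clipped at
±100 inside the likelihood kernels to keep exponentials finite on
diverging unpenalized fits; an unpenalized logistic fit whose
coefficients escape ±30 raises a separation error rather than
returning a meaningless iterate.

Penalty selection: 100 log-spaced λ from λ_max down to 0.001·λ_max,
warm-started descending; event-stratified K folds (default 10); the
criterion is the held-out partial-likelihood deviance per event (Cox)
or held-out mean deviance (logistic); the minimizing λ is returned,
ties toward the sparser end. The minimum-CV rule is used rather than
the 1-SE rule. DLco, the one covariate with substantial missingness, is
imputed by the training-set median (leak-free; the missingness
mechanism in the motivating data is unreported, so the robust choice).
Continuous covariates and raw omics features are standardized on
training statistics so a single λ is scale-meaningful; coefficients
are reported on the standardized scale.

## Metrics

Harrell's C-index counts pairs usable under right censoring (the
earlier time must be an event); tied risk scores count 1/2; higher
risk means shorter predicted survival. It is computed via lifelines'
concordance machinery and verified in the test suite against direct
pair enumeration. AUC is the rank-statistic (Mann–Whitney) form via
scikit-learn. Patients with a missing binary label are dropped from
that outcome's fits and scoring only.

## Variable importance

A covariate's importance is its selection frequency — the fraction of
repetitions with a nonzero coefficient — with ties broken by the mean
|β| over the repetitions where it was selected, then by name. Reduced
models refit with the protein block restricted to the top-k ranked
proteins (default k=4) reuse the same master seed, so reduced and full
reports are directly comparable; restriction preserves the block's own
column order, making k = all proteins an exact identity. Top-k
selection uses fits from the repetitions that precede the refit, so no
test information leaks into the restriction.

## The synthetic cohort generator

The generator is first-class, validated code: it produces the study
conditions every downstream stage is tested under, since the
motivating registry data are not redistributable.

* **Covariates** follow the published cohort marginals: male 74.0%,
  age 69.7 (7.8) years, BMI 29.4 (4.8) kg/m², ever-smoker 67.1%, FVC
  71.1 (16.9) % predicted, DLco 40.2 (13.6) % predicted, nintedanib
  18.2%, pirfenidone 35.9%. Continuous draws are clipped to plausible
  ranges (age 40–95, BMI 15–50, FVC 30–130, DLco 15–100); at these
  means/SDs the clipped mass is negligible.
* **Latent endotypes**: a 2-group label drawn with proportions
  (0.5, 0.5) shifts the first 8 of 44 protein features by 3 SD units
  (defaults). An independent 2-group label structures the miRNA block
  (shift 2 SD on 40 of 472 features), reflecting that different omics
  may cluster patients differently; it carries no hazard effect by
  default.
* **Outcomes**: each composite outcome is the minimum of independent
  exponential component processes (death/transplant, FVC decline ≥10,
  DLco decline ≥15, respiratory hospitalization) sharing one
  proportional-hazards linear predictor: endotype log HR log(2.5) plus
  per-unit covariate effects (age +0.03/yr, male +0.30, BMI −0.03,
  ever-smoker +0.15, FVC −0.030/%, DLco −0.025/%), centered at the
  generating means. Administrative censoring at 36 months. Component
  baseline hazards (death 0.00816/month; FVC, DLco, hospitalization
  components at ratios 1.13, 0.392, 0.259) were calibrated once by
  forward simulation so default event proportions are 41/62/50/47%
  across the four composites, matching a typical IPF registry cohort;
  they are configuration, not fitted quantities.
* **1-year binary outcomes**: the 1-year FVC change is normal with
  endotype-dependent mean decline (5.3 vs 11.3 points, SD 8); DLco
  change analogous (1.5 vs 4.0, SD 7). `fvc_decline_gt10_1yr` is 1 iff
  the decline strictly exceeds 10 points (a decline of exactly 10.0 is
  not an event); the progression composite adds DLco decline > 15 and
  death/transplant within 12 months. A small MCAR fraction (1/231) of
  1-year FVC changes is missing, propagating to a missing label.
  Under the defaults the FVC-binary prevalence is ≈0.42; the
  progression prevalence runs ≈0.53, a few points above a typical
  registry value, because the union of independent component processes
  overlaps less than correlated real-world events.
* **Missingness**: baseline DLco is missing completely at random at
  rate 59/231. Real cohorts likely have informative missingness; MCAR
  is the deliberate simplification.

What passing tests on this generator do and do not show: they verify
the machinery — leak-free out-of-sample clustering, penalty tuning,
censoring-aware scoring, seed-exact reproducibility — and that a
planted endotype signal of realistic size is detected as a positive
relative change. They cannot certify performance on real registry
data, where effects are weaker, missingness informative, features
correlated within assay panels, and the endotype structure less clean.

## Numerical and design choices

* Exponential baseline hazards (simplest PH-consistent components);
  a Weibull shape is a natural config extension, not implemented.
* Breslow tie handling throughout (ties are rare under continuous
  simulated times but the Breslow denominators are exact).
* Splits are stratified by the event indicator of the outcome under
  evaluation, preventing event-free test sets; Cox CV folds are
  likewise event-stratified, and a fold without events is an explicit
  error rather than a silent NaN.
* Degenerate clustering input (fewer than k distinct rows, or a zero
  median pairwise distance) raises a typed error; in the repeated
  workflow such a repetition is logged and skipped for the affected
  model families and the skip count is reported.
* Problem sizes in the test suite and acceptance script (20
  repetitions, cohorts of 231–300, 10 master seeds for the
  signal-detection check) were chosen as the smallest sizes at which
  the checked contrasts are stable.

## Known limitations

Only linear covariate effects are modeled (as in the motivating
analysis); no interactions, no elastic-net or group penalties, no
time-dependent effects or AUC(t), no bootstrap confidence intervals.
The number of repetitions (default 64) and the choice k=2 are
conventions, not estimated quantities. The eigengap heuristic is
advisory and unreliable when informative features are few.
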