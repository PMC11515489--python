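# omicspred

Does adding blood omics data — circulating proteins and miRNAs — to
risk prediction models based on demographic and clinical factors
improve prediction of disease progression in idiopathic pulmonary
fibrosis (IPF)? `omicspred` implements the full evaluation workflow
needed to answer that question on a progressive-disease cohort, for
biostatisticians and computational biologists working with registry
data of a few hundred patients.

## What it does

For a cohort with per-patient demographics (age, sex, BMI, smoking,
antifibrotic treatment), clinical lung function (FVC and DLco %
predicted), composite time-to-event outcomes and 1-year binary
outcomes, plus two omics matrices (patients × proteins, patients ×
miRNAs), the package runs a repeated train/test comparison of model
families:

1. **Split** the cohort 80/20, stratified by the event indicator.
2. **Cluster** each omics block on the training patients with spectral
   clustering (Gaussian affinity W_ij = exp(−‖x_i−x_j‖²/2σ²), symmetric
   normalization D^{−1/2}WD^{−1/2}, k-means on the top-k row-normalized
   eigenvectors; k = 2 by default, matching the two molecular endotypes
   reported for this population), and assign held-out patients cluster
   labels by a Nyström extension — the test set never touches the
   clustering.
3. **Fit** an L1-penalized model per covariate-family spec — Lasso Cox
   (Breslow ties) for time-to-event outcomes, L1 logistic for binary
   outcomes — minimizing e.g.
   `−(1/n) log PL(β) + λ‖β‖₁`, with λ tuned by an inner event-stratified
   10-fold cross-validation over 100 log-spaced values from λ_max down
   to 0.001·λ_max. Omics enter as raw standardized values (`raw_prot`,
   `raw_mirna`) and/or cluster-label indicators (`lbl_prot`,
   `lbl_mirna`), in any combination with `demo` and `clin`.
4. **Score** on the held-out fifth with Harrell's C-index (risk = Xβ)
   or AUC, aggregate over repetitions as mean (SE), and report the
   relative percent change `100·(augmented − base)/base` of the mean
   metric when omics are added to a base model.
5. **Rank** covariates by selection frequency across repetitions and
   optionally refit with the protein block restricted to the top 4
   predictors.

The solvers (proximal-Newton coordinate descent), the Nyström
extension, and a synthetic-cohort generator emulating an IPF registry
cohort (N=231, 44 proteins, 472 miRNAs, latent 2-endotype structure
with endotype hazard ratio 2.5, ~25% missing DLco) are part of the
package; see `docs/methods.md` for the model details and defaults.

## Worked example

```python
from omicspred import (GeneratorConfig, ModelSpec, generate_cohort,
                       run_repeated_workflow)

cohort, proteins, mirnas = generate_cohort(GeneratorConfig(seed=7))

base = ModelSpec.for_outcome(("demo",), "death_transplant")
aug  = ModelSpec.for_outcome(("demo", "lbl_prot"), "death_transplant")
report = run_repeated_workflow(cohort, proteins, mirnas, [base, aug],
                               n_repetitions=20, seed=11)
print(report.summary[["spec", "mean", "se"]].to_string(index=False))
print("relative change:", report.relative_change(base, aug), "%")
```

prints

```
         spec     mean       se
         demo 0.564829 0.015426
demo+lbl_prot 0.617888 0.013623
relative change: 9.4 %
```

Adding the training-derived protein cluster label to the demographics
model raises the mean held-out C-index for death-or-transplant from
0.565 to 0.618 — a +9.4% relative change — because the synthetic
cohort plants a 2-group protein endotype whose second group carries a
hazard ratio of 2.5. Under a null generator (no planted effects) both
means sit near 0.5 and the relative change is ~0.

The same workflow is available from the shell:

```bash
omicspred simulate --seed 7 --outdir data/
omicspred run --seed 7 --outdir results/     # full pipeline, all stages
omicspred evaluate --cohort data/cohort.csv --proteins data/proteins.csv \
    --mirnas data/mirnas.csv --outcome death_transplant \
    --spec demo --spec demo+raw_prot+lbl_mirna \
    --repetitions 64 --seed 7 --outdir results/
```

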