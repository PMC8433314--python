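# neuropathnet

Multi-task neural networks for predicting Alzheimer's-disease
neuropathology from bulk brain gene expression — across cohorts that each
measure only some of the phenotypes — together with the evaluation
protocol and the model-interpretation stack (attribution-based gene
rankings, consensus hidden-node embeddings, and a sex-interaction scan).

## Who this is for

Postmortem brain transcriptomic cohorts label their samples with different
subsets of neuropathology measures: plaque-related (amyloid-β IHC density,
neuritic plaque counts, CERAD score) and tangle-related (phospho-tau IHC
density, tangle counts, Braak stage).  Conventional analyses either
discard samples without a harmonized label or model each phenotype — and
often each cohort — separately.  This package is for researchers who want
one joint model over all samples: a network whose shared layers are
trained by *every* sample and whose per-phenotype branches are trained by
exactly the samples labeled for them.

## The model

For expression profile x (reduced to its top k principal components), a
shared ReLU trunk h(x) feeds six per-phenotype branches:

    ŷ_t(x) = w_tᵀ · ReLU(B_t h(x)),   t = 1 … 6

trained with the masked loss

    L = (1 / |O|) · Σ_{(i,t) ∈ O} (ŷ_t(x_i) − y_{i,t})²,

where O is the set of observed (sample, phenotype) cells.  The gradient at
a masked cell is exactly zero.  Performance is measured as
1 − R²_CV = MSE / Var(y) in the evaluation split (1 ≈ a mean predictor),
with nested 5×5 cross-validation and average-rank selection over an
8-point grid (kernel L2 ∈ {1e-3, 1e-5}, clip norm ∈ {0.1, 0.01}, learning
rate ∈ {1e-3, 1e-4}).  Trained models are interpreted with Integrated
Gradients

    IG_g(x) = (x_g − x′_g) · (1/m) Σ_j ∂F(x′ + (j/m)(x − x′)) / ∂x_g ,

aggregated over samples, retrainings, and phenotypes into consensus gene
rankings; hidden-node ensembles are clustered into medoid "consensus
nodes"; and per-sample gene importances are screened for sex interactions
with the per-gene OLS model  score = a·expr + b·sex + c·expr·sex + d  and
BH-FDR on the interaction term.

A synthetic multi-cohort generator (latent severity factor, six noisy
monotone phenotype measurements, signal genes, sex-differential coupling
genes, sex markers, batch effects, per-cohort label patterns) makes every
stage testable end to end; see `docs/methods.md` for the full model and
its assumptions.

## Worked example

```python
import numpy as np
from neuropathnet import (PHENOTYPES, SimulationConfig, generate,
                          MultiTaskNeuralRegressor, neuropathology_score,
                          group_compare, one_minus_r2cv)
from neuropathnet.preprocess import (minmax_normalize, harmonize_batches,
                                     fit_pca, apply_pca)

cfg = SimulationConfig(n_cohorts=2, samples_per_cohort=150, n_genes=500,
                       n_signal_genes=25, n_sex_interacting_genes=10,
                       n_sex_marker_genes=5, seed=0)
expr, pheno, covs, truth = generate(cfg)

norm, scaler = minmax_normalize(expr)
harm = harmonize_batches(norm, norm.cohort)

rng = np.random.default_rng(0)
test = rng.permutation(harm.n_samples)[:60]
train = np.setdiff1d(np.arange(harm.n_samples), test)
pca = fit_pca(harm.values[train], k=50)
X_tr, X_te = apply_pca(pca, harm.values[train]), apply_pca(pca, harm.values[test])

Y = pheno.masked_array()                      # NaN marks missing labels
model = MultiTaskNeuralRegressor(shared_widths=(64, 32), branch_widths=(16,),
                                 epochs=60, random_state=0)
model.fit(X_tr, Y[train])

preds = model.predict(X_te)
for t, name in enumerate(PHENOTYPES):
    if (~np.isnan(Y[test, t])).sum() >= 2:
        print(f"{name:10s} 1-R2_CV = {one_minus_r2cv(Y[test, t], preds[:, t]):.3f}")

scores = neuropathology_score(preds, ["test"] * len(test))
t, p = group_compare(scores, np.where(covs.dementia[test] > 0,
                                      "dementia", "control"))
print(f"neuropathology score: dementia vs control t = {t:.2f}, p = {p:.2g}")
```

prints

```
abeta_ihc  1-R2_CV = 0.680
plaques    1-R2_CV = 0.635
cerad      1-R2_CV = 0.652
tau_ihc    1-R2_CV = 0.562
tangles    1-R2_CV = 0.994
braak      1-R2_CV = 0.656
neuropathology score: dementia vs control t = 4.73, p = 1.5e-05
```

Every phenotype is predicted well below mean-predictor error (1.0) except
tangle counts, which in this two-cohort configuration are unlabeled in one
cohort entirely — at this tiny scale the network has too few tangle labels
to beat the mean.  That is precisely the regime where joint training
helps: the larger integration experiments (below) show the multi-task
network beating the matched single-task network on the sparsest phenotype.
The composite neuropathology score — the mean of within-dataset percentile
ranks of the six predictions — separates individuals with and without
dementia (t = 4.73) even though dementia status was never a training
label.

The command line mirrors the library:

```bash
neuropathnet pipeline --config config.yaml --out run/
```

runs simulate → preprocess → evaluate → train (ensemble) → attribute →
consensus → interactions, writing TSV/HDF5 artifacts and a manifest with
seeds, checksums, and timings; re-running resumes from existing artifacts.

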