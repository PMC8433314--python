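# Methods

## The model

`neuropathnet` predicts six semi-quantitative neuropathology phenotypes —
three plaque-related (amyloid-β IHC density, neuritic plaque counts, CERAD
score) and three tangle-related (phospho-tau IHC density, tangle counts,
Braak stage) — simultaneously from bulk brain gene expression, pooled
across cohorts that each measure only a subset of the six.

The predictor is a multi-task feed-forward network: a stack of shared ReLU
layers (defaults 256 → 100 units) followed by one small ReLU branch per
phenotype (default 50 units) ending in a linear scalar output.  Training
minimizes a *masked* mean squared error — the mean of squared errors over
observed (sample, phenotype) cells only.  The gradient at a masked cell is
identically zero, so a sample with k of 6 labels updates the shared trunk
and exactly its k branches.  This is the mechanism by which sparsely
labeled cohorts still contribute to the shared representation, and it is
why joint training helps most on the phenotype with the most missing
labels: the other five phenotypes are noisy measurements of the same
latent severity, and the trunk averages their noise out.

Optimization is Adam (b1=0.9, b2=0.999, eps=1e-7) with per-array
gradient-norm clipping (Keras `clipnorm` semantics), L2 penalty on kernels
only, inverted dropout (rate 0.1) on hidden layers during training, and
Glorot-uniform initialization.  The tuning grid is
{1e-3, 1e-5} × {0.1, 0.01} × {1e-3, 1e-4} for (kernel L2, clip norm,
learning rate); reference training settings are 200 epochs with batch size
20.  The network is implemented directly in NumPy with hand-written
forward/backward passes.  That choice buys three things the analyses
depend on: a provably exact zero gradient at masked cells, the exact
gradient of any output or hidden unit with respect to the *gene-space*
input (for attributions), and bitwise run-to-run determinism from one
integer seed.

Inputs are reduced by PCA before entering the network (default 500
components on full-size data; the desk-scale experiments use 50–100, which
retain essentially all structure of the synthetic cohorts since their
planted signal is low-rank).  The PCA map is stored with the model as a
fixed linear first layer.

## Preprocessing

Cohorts are combined by (1) removing, per cohort, genes with null values
in more than two-thirds of samples, then keeping the genes present in all
cohorts; (2) optional `log(1+x)`; (3) scaling each gene to [0, 1] within
the fitting population (constant genes map to 0 and are flagged, not
dropped, so gene indices stay stable); (4) scaling each phenotype to
[0, 1] within each cohort, over observed entries only; (5) batch
harmonization.  The default harmonization standardizes each gene within
batch and rescales to the pooled moments — a location/scale correction; a
pass-through accepts matrices corrected by external empirical-Bayes
tooling.  External-cohort transfer first restricts to overlapping genes
(hard floor 30% overlap), then moment-matches each gene to the training
population's mean/SD; genes absent from the external data are imputed at
the reference mean, which is neutral after PCA centering.  By default PCA
is refit on the training portion of each CV split (no leakage); fitting
once globally reproduces the single-shared-input-map behavior when
desired.

## Evaluation protocol

The error metric is `1 − R²_CV` = MSE over observed cells divided by the
*population* variance (ddof=0) of the observed labels in the evaluation
split: exactly 1 for the evaluation-split-mean predictor, 0 for a perfect
one.  Model selection uses nested CV: 5 outer rounds, each with an inner
5-fold CV over the 8-point grid minimizing the mean per-task inner error
(the unweighted mean over tasks, matching the symmetric joint objective);
outer-test labels are never visible to selection.  A final configuration
is chosen by average rank across rounds (rank 1 = best per round; ties
break by lower mean error, then grid order).

The *neuropathology score* summarizes the six predictions into one number
per sample: the mean over phenotypes of within-dataset percentile ranks,
with percentile = (rank − 1)/(n − 1) and mean-rank ties.  It spans [0, 1]
and is exactly invariant under any strictly increasing transform of each
phenotype's predictions, which is what makes it transferable across
datasets with different label conventions.  Group contrasts on the score
use a two-sided independent t test (Welch by default; pooled available).

## Interpretation stack

**Attributions.**  Integrated Gradients with a zero baseline in the
normalized [0, 1] gene space — zero is every gene's observed minimum, a
meaningful "reference patient".  The path integral is approximated with a
right-endpoint Riemann sum, 200 steps by default (midpoint available);
because the PCA layer is linear, gradients are accumulated in PC space and
projected to genes once, so a gene with zero loading on every retained
component receives exactly zero attribution.  Completeness (attributions
sum to F(x) − F(x′)) holds to ~1e-2 at 200 steps on trained networks and
to machine precision on freshly initialized ones (zero biases ⇒ no ReLU
kink along the path).  Targets are either the six outputs or the units of
the last shared layer (the truncated network).

**Gene rankings.**  Per training run, per target, attributions are
aggregated over samples with weights +1 for high-pathology samples, −1 for
low-pathology, 0 otherwise, divided by the count of nonzero-weight
samples.  On staged data the high/low groups are Braak ≥ 5 & CERAD ≥ 3
versus Braak ≤ 3 & CERAD = 1 (optionally age ≥ 85 and no dementia); the
synthetic phenotypes are continuous, so the pipeline uses the tercile
split of each sample's mean observed severity instead.  Genes are ranked
within each run/phenotype, ranks averaged over runs, converted to
percentiles per phenotype, and averaged across phenotypes into a consensus
score in [0, 1] (1 = most positively pathology-associated).  The linear
comparison ranking percentile-ranks plain Pearson correlations per
phenotype and averages the phenotype-specific rankings (ranking the
average correlation is available behind a flag).

**Consensus embedding.**  Because the loss is non-convex, node identities
vary across retrainings.  All last-shared-layer nodes from an ensemble of
runs are z-normalized over samples, pooled, k-means-clustered with samples
as coordinates (Euclidean distance on z-normalized vectors, equivalent up
to a monotone transform to correlation distance), and each cluster is
summarized by its *medoid* — an actual node of an actual run, never a
synthetic average.  Dead (constant) ReLU nodes are excluded with a logged
count.  Nodes are annotated with signed Pearson r and −log10(p) against
phenotypes and covariates (pairwise-complete), and optionally with
Fisher-overlap enrichment of their top genes against GMT gene sets.

**Sex-interaction scan.**  Per gene, the per-sample consensus importance
(mean of attributions over runs and phenotypes) is regressed on
`a·expr + b·sex + c·expr·sex + d` by OLS; the classical t-test p-value of
`c` is BH-FDR-adjusted across genes, with significance called at q < 0.05.
A shuffled-sex permutation null repeats the full scan, and Fisher's exact
test measures overlap between the significant set and gene sets of
interest (sample odds ratio; Haldane 0.5 correction only when a
denominator cell is zero, so a zero overlap honestly reports OR = 0).

## The synthetic cohort generator

The generator emulates exactly the structure the model assumes: a
per-individual latent severity z ~ N(0, 1); six phenotypes as independent
noisy monotone measurements of z (scaled logistic link by default —
bounded, ordinal-like values; identity link available) with per-phenotype
noise SDs (0.10 … 0.35) and per-cohort 0-1 rescaling; 50 signal genes
linear in z (coupling 0.8); 20 genes whose coupling differs by sex
(0.8 ± 0.6 for male/female); 10 sex-marker genes with a strong additive
mean shift by sex (effect 2.0, emulating X/Y-linked transcripts — without
them sex would be uninferable from expression and an expression-only
network could not produce sex-differential attributions at all); the
remaining genes pure noise; per-cohort per-gene batch offsets
(SD 0.3) and log-normal scales (SD 0.1); per-cohort label-availability
patterns plus i.i.d. extra masking.  An option generates 2–4
region-repeats per individual with correlated noise for individual-grouped
CV tests.  Everything is a deterministic function of (config, seed), and a
truth record (latent severities, gene block identities, couplings, batch
parameters) supports recovery tests.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: realistic marginal distributions and gene
counts, co-expression modules or LD-like structure beyond the planted
factors, region heterogeneity beyond correlated noise, and label
conventions beyond monotone links.  One consequence is documented
honestly: with a single planted severity factor, only severity-related
node directions reproduce across retrainings, so the consensus-node
reproducibility experiment uses a narrow embedding and two consensus
clusters; on data with richer latent structure more clusters are
identifiable, which is the regime the 50-cluster default targets.

## Numerical choices and degenerate inputs

Constant genes scale to 0; zero-SD external genes moment-match to the
reference mean; constant embedding nodes get p = 1; rank-deficient
interaction designs are flagged with p = 1; an all-masked batch
contributes zero loss and zero gradient; a dataset with one sample gets
neuropathology score 0.5 with a warning; zero label variance makes
`1 − R²_CV` undefined (reported missing, with a warning); k above the PCA-
feasible rank is truncated with a warning; exact selection ties resolve
deterministically by grid order.

## Desk-scale experiment sizes

The integration experiments run 3 × 200-sample cohorts with 2000 genes,
50–100 PCs, networks from (32, 8) to (256, 100) shared units, ensembles of
10 retrainings, 20–32 attribution steps, and 30–200 epochs — sizes chosen
so the full suite re-runs in minutes on one CPU while keeping every
qualitative property of the full-size configuration.  The reference
defaults (500 PCs, 100-dim embedding, 100 runs, k = 50 clusters, 200
epochs, 200 attribution steps) remain the package defaults throughout.

## Known limitations

- The generator's phenotypes share one latent factor; multi-factor
  pathology (e.g. partially decoupled amyloid and tau processes) is not
  modeled.
- The location/scale harmonization removes first- and second-moment batch
  effects only; empirical-Bayes shrinkage is delegated to external tools.
- The interaction scan covers binary covariates; continuous-covariate
  interactions (e.g. age) are out of scope.
- Attribution values at ReLU kinks are one-sided gradients; the Riemann
  sum converges to the path integral but individual step placements can
  differ across backends at machine precision.
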