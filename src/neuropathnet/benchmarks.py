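"""End-to-end study routines on synthetic cohorts.

Each function here re-runs a complete experiment from scratch — generate
data, preprocess, train, interpret, measure — and returns the headline
quantities.  They serve both as the package's reproducibility entry points
(``scripts/acceptance.py``) and as the substance behind the heavier
integration tests.

Problem sizes are desk-scale versions of the study conditions: 3 cohorts of
200 samples with 2000 genes (50 severity-coupled, 20 sex-differential in
their severity coupling, 10 sex markers), networks of a few tens of
thousands of parameters on 50-100 PCA components, ensembles of 10
retrainings.
"""

from __future__ import annotations

import copy
import hashlib
import tempfile
from pathlib import Path

import numpy as np

from ._nn import AdamState, MaskedMLP, masked_mse, masked_mse_grad
from .attribution import (
    AttributionConfig,
    aggregate_weighted,
    attribute_dataset,
    completeness_gap,
    consensus_gene_ranking,
    integrated_gradients,
    per_sample_consensus,
    weights_from_quantiles,
)
from .consensus import cluster_nodes, match_medoids, pool_nodes
from .evaluation import neuropathology_score, one_minus_r2cv
from .interactions import fisher_overlap, fit_interaction, interaction_scan, shuffled_null
from .models import LinearL2Regressor, MultiTaskNeuralRegressor, SingleTaskMLPRegressor
from .pipeline import FILES, pipeline_full
from .preprocess import apply_pca, fit_pca, harmonize_batches, minmax_normalize
from .simulate import SimulationConfig, generate

SPARSE_TASK = 5  # phenotype 6 (Braak column) carries the planted sparsity


def standard_fixture(seed: int, **overrides) -> SimulationConfig:
    """The evaluation fixture: 3 cohorts x 200 samples, 2000 genes, with
    60% of phenotype-6 labels removed at random."""
    base = dict(
        label_patterns=tuple((True,) * 6 for _ in range(3)),
        missing_fraction_within_observed=0.0,
        per_phenotype_missing=(0, 0, 0, 0, 0, 0.6),
        seed=seed,
    )
    base.update(overrides)
    return SimulationConfig(**base)


def _processed(cfg: SimulationConfig):
    expr, pheno, covs, truth = generate(cfg)
    norm, _ = minmax_normalize(expr)
    harm = harmonize_batches(norm, norm.cohort)
    return harm, pheno, covs, truth


# --------------------------------------------------------------------------
# attribution axioms


def ig_axioms(seed: int = 0, n_networks: int = 20, steps: int = 300) -> dict:
    """Completeness on freshly initialized small networks, exactness on a
    linear model, and the ReLU-hinge toy attribution."""
    worst = 0.0
    for i in range(n_networks):
        rng = np.random.default_rng(seed + i)
        net = MaskedMLP(5, (8, 4), (3,), n_tasks=2, dropout=0.0, seed=seed + i)
        X = rng.standard_normal((4, 5))
        cfg = AttributionConfig(steps=steps)
        tensor = attribute_dataset(net, X, cfg)
        worst = max(worst, float(completeness_gap(net, X, tensor, cfg).max()))

    rng = np.random.default_rng(seed)
    coefs = rng.standard_normal(6)
    lin = MaskedMLP(6, (), (), n_tasks=1, dropout=0.0, seed=0)
    lin.branches[0][0][0][:, 0] = coefs
    lin.branches[0][0][1][...] = 0.0
    X = rng.standard_normal((10, 6))
    tensor = attribute_dataset(lin, X, AttributionConfig(steps=50))
    linear_err = float(np.abs(tensor[:, :, 0] - coefs * X).max())

    hinge = MaskedMLP(1, (1,), (), n_tasks=1, dropout=0.0, seed=0)
    hinge.shared[0][0][...] = 1.0
    hinge.shared[0][1][...] = -0.5
    hinge.branches[0][0][0][...] = 1.0
    hinge.branches[0][0][1][...] = 0.0
    toy = float(
        integrated_gradients(hinge, np.array([1.0]), AttributionConfig(steps=200))[0, 0]
    )
    m = 10_000
    quadrature = sum(1.0 for j in range(1, m + 1) if j / m > 0.5) / m
    return {
        "completeness_max_gap": worst,
        "linear_exactness_max_err": linear_err,
        "relu_toy_attribution": toy,
        "relu_toy_quadrature": float(quadrature),
    }


# --------------------------------------------------------------------------
# masked-loss correctness


def masked_loss_checks(seed: int = 0) -> dict:
    rng = np.random.default_rng(seed)
    pred = rng.random((6, 4))
    target = rng.random((6, 4))
    mask = rng.random((6, 4)) < 0.5
    mask[0, 0] = True  # at least one observed cell
    grad = masked_mse_grad(pred, target, mask)
    eps = 1e-7
    fd_worst = 0.0
    for i, j in zip(*np.where(~mask)):
        up, dn = pred.copy(), pred.copy()
        up[i, j] += eps
        dn[i, j] -= eps
        fd = (masked_mse(up, target, mask) - masked_mse(dn, target, mask)) / (2 * eps)
        fd_worst = max(fd_worst, abs(fd))
    masked_grad_max = float(np.abs(grad[~mask]).max())

    full = np.ones_like(mask)
    plain_diff = abs(
        masked_mse(pred, target, full) - float(((pred - target) ** 2).mean())
    )

    # one optimizer step with task-1 unlabeled: branch-1 weights frozen
    net = MaskedMLP(4, (5, 3), (3,), n_tasks=2, dropout=0.0, seed=seed)
    before = copy.deepcopy(net.get_weights())
    X = rng.standard_normal((8, 4))
    Y = rng.random((8, 2))
    bmask = np.column_stack([np.ones(8, bool), np.zeros(8, bool)])
    adam = AdamState(net, learning_rate=1e-3, l2=0.0, clip_norm=0.1)
    preds, cache = net.forward(X)
    grads, _ = net.backward(cache, masked_mse_grad(preds, Y, bmask))
    adam.step(net, grads)
    after = net.get_weights()
    frozen_delta = max(
        float(np.abs(after[f"branch1:{i}"]["W"] - before[f"branch1:{i}"]["W"]).max())
        for i in range(2)
    )
    shared_delta = float(np.abs(after["shared:0"]["W"] - before["shared:0"]["W"]).max())
    return {
        "masked_cell_gradient_max": masked_grad_max,
        "masked_cell_fd_max": float(fd_worst),
        "full_mask_vs_plain_mse": float(plain_diff),
        "unlabeled_branch_weight_delta": frozen_delta,
        "shared_weight_delta": shared_delta,
    }


# --------------------------------------------------------------------------
# prediction benefits


def _split_and_project(harm, seed: int, k: int):
    rng = np.random.default_rng(seed + 1000)
    n = harm.n_samples
    perm = rng.permutation(n)
    te, tr = perm[: n // 5], perm[n // 5 :]
    pca = fit_pca(harm.values[tr], k=k)
    return tr, te, apply_pca(pca, harm.values[tr]), apply_pca(pca, harm.values[te])


def multitask_benefit(seeds=range(5), epochs: int = 50, k: int = 100) -> dict:
    """Median held-out error on the sparsest phenotype: joint multi-task
    network vs the matched single-task network (standard fixture), plus all
    three models on a strongly nonlinear-link fixture."""
    md_errs, st_errs = [], []
    for seed in seeds:
        harm, pheno, _, _ = _processed(standard_fixture(seed))
        Y = pheno.masked_array()
        tr, te, Xtr, Xte = _split_and_project(harm, seed, k)
        md = MultiTaskNeuralRegressor(
            shared_widths=(256, 100), branch_widths=(50,), epochs=epochs,
            random_state=seed,
        ).fit(Xtr, Y[tr])
        md_errs.append(one_minus_r2cv(Y[te, SPARSE_TASK], md.predict(Xte)[:, SPARSE_TASK]))
        st = SingleTaskMLPRegressor(
            shared_widths=(256, 100), branch_widths=(50,), epochs=epochs,
            random_state=seed,
        ).fit(Xtr, Y[tr, SPARSE_TASK])
        st_errs.append(one_minus_r2cv(Y[te, SPARSE_TASK], st.predict(Xte)))

    nl_md, nl_st, nl_lin = [], [], []
    for seed in seeds:
        harm, pheno, _, _ = _processed(
            standard_fixture(seed, link="logistic", link_scale=8.0)
        )
        Y = pheno.masked_array()
        tr, te, Xtr, Xte = _split_and_project(harm, seed, k=50)
        md = MultiTaskNeuralRegressor(
            shared_widths=(256, 100), branch_widths=(50,), epochs=2 * epochs,
            random_state=seed,
        ).fit(Xtr, Y[tr])
        nl_md.append(one_minus_r2cv(Y[te, SPARSE_TASK], md.predict(Xte)[:, SPARSE_TASK]))
        st = SingleTaskMLPRegressor(
            shared_widths=(256, 100), branch_widths=(50,), epochs=2 * epochs,
            random_state=seed,
        ).fit(Xtr, Y[tr, SPARSE_TASK])
        nl_st.append(one_minus_r2cv(Y[te, SPARSE_TASK], st.predict(Xte)))
        lin = LinearL2Regressor(epochs=2 * epochs, random_state=seed).fit(
            Xtr, Y[tr, SPARSE_TASK]
        )
        nl_lin.append(one_minus_r2cv(Y[te, SPARSE_TASK], lin.predict(Xte)))
    return {
        "multitask_median_error": float(np.median(md_errs)),
        "single_task_median_error": float(np.median(st_errs)),
        "nonlinear_multitask_median_error": float(np.median(nl_md)),
        "nonlinear_single_task_median_error": float(np.median(nl_st)),
        "nonlinear_linear_median_error": float(np.median(nl_lin)),
    }


def sparse_cohort_benefit(seeds=range(5), epochs: int = 50, k: int = 100) -> dict:
    """Phenotype-6 error on a held-out slice of the labeled cohort, with and
    without a second training cohort that carries no phenotype-6 labels."""
    alone, augmented = [], []
    for seed in seeds:
        cfg = SimulationConfig(
            n_cohorts=2,
            samples_per_cohort=200,
            label_patterns=((True,) * 6, (True, True, True, True, True, False)),
            missing_fraction_within_observed=0.0,
            seed=seed,
        )
        harm, pheno, _, _ = _processed(cfg)
        Y = pheno.masked_array()
        a_rows = np.flatnonzero(harm.cohort == "cohort0")
        b_rows = np.flatnonzero(harm.cohort == "cohort1")
        rng = np.random.default_rng(seed + 2000)
        perm = rng.permutation(len(a_rows))
        te = a_rows[perm[: len(a_rows) // 5]]
        a_tr = a_rows[perm[len(a_rows) // 5 :]]
        for bucket, tr in ((alone, a_tr), (augmented, np.concatenate([a_tr, b_rows]))):
            pca = fit_pca(harm.values[tr], k=k)
            Xtr, Xte = apply_pca(pca, harm.values[tr]), apply_pca(pca, harm.values[te])
            md = MultiTaskNeuralRegressor(
                shared_widths=(256, 100), branch_widths=(50,), epochs=epochs,
                random_state=seed,
            ).fit(Xtr, Y[tr])
            bucket.append(
                one_minus_r2cv(Y[te, SPARSE_TASK], md.predict(Xte)[:, SPARSE_TASK])
            )
    return {
        "single_cohort_median_error": float(np.median(alone)),
        "augmented_median_error": float(np.median(augmented)),
    }


# --------------------------------------------------------------------------
# metric sanity


def metric_checks() -> dict:
    rng = np.random.default_rng(0)
    y = rng.random(50)
    return {
        "perfect_predictor_error": one_minus_r2cv(y, y),
        "mean_predictor_error": one_minus_r2cv(y, np.full(50, y.mean())),
        "hand_case_error": one_minus_r2cv(
            np.array([0.0, 0.5, 1.0]), np.array([0.1, 0.5, 0.9])
        ),
    }


def score_checks() -> dict:
    hand = neuropathology_score(np.array([0.2, 0.4, 0.9]), ["d"] * 3)
    rng = np.random.default_rng(1)
    preds = rng.random((30, 6))
    base = neuropathology_score(preds, ["d"] * 30)
    warped = neuropathology_score(np.expm1(4 * preds), ["d"] * 30)
    return {
        "hand_scores": hand.tolist(),
        "monotone_invariance_max_dev": float(np.abs(base - warped).max()),
    }


# --------------------------------------------------------------------------
# consensus stability


def consensus_stability(
    seed: int = 11,
    runs_per_pool: int = 10,
    epochs: int = 100,
    k_pcs: int = 100,
    k_clusters: int = 2,
    steps: int = 32,
) -> dict:
    """Train two disjoint ensembles on one standard-fixture realization;
    compare their consensus gene rankings (Spearman) and their consensus
    medoid nodes (max |r| matching)."""
    from scipy.stats import spearmanr

    harm, pheno, _, _ = _processed(SimulationConfig(seed=seed))
    pca = fit_pca(harm.values, k=k_pcs)
    X = apply_pca(pca, harm.values)
    Y = pheno.masked_array()
    weights = weights_from_quantiles(np.nanmean(Y, axis=1))
    cfg = AttributionConfig(steps=steps)
    rankings, embeddings = [], []
    for pool_id in range(2):
        models, per_run = [], []
        for r in range(runs_per_pool):
            est = MultiTaskNeuralRegressor(
                shared_widths=(32, 8), branch_widths=(8,), epochs=epochs,
                random_state=1000 * pool_id + r + 7919 * seed,
            ).fit(X, Y)
            models.append(est)
            tensor = attribute_dataset(est, harm.values, config=cfg, pca=pca)
            per_run.append(aggregate_weighted(tensor, weights))
        rankings.append(consensus_gene_ranking(per_run, harm.gene_ids))
        pooled, sources = pool_nodes(models, X)
        embeddings.append(cluster_nodes(pooled, sources, k=k_clusters, seed=pool_id))
    rho = spearmanr(rankings[0]["consensus"], rankings[1]["consensus"]).statistic
    matches = match_medoids(embeddings[0], embeddings[1])
    return {
        "ranking_spearman": float(rho),
        "medoid_match_min_abs_r": float(matches.min()),
    }


def signal_gene_recovery(rankings_consensus, truth, gene_ids) -> float:
    from sklearn.metrics import roc_auc_score

    is_signal = truth.is_signal(gene_ids)
    deviation = np.abs(np.asarray(rankings_consensus) - 0.5)
    return float(roc_auc_score(is_signal, deviation))


# --------------------------------------------------------------------------
# interaction machinery


def interaction_machinery(
    seed: int = 11,
    n_runs: int = 10,
    epochs: int = 30,
    k_pcs: int = 100,
    steps: int = 32,
    n_shuffles: int = 20,
) -> dict:
    """Noiseless coefficient recovery, Monte-Carlo coverage of the
    interaction coefficient, recovery of planted sex-differential genes
    from trained-model attributions, the shuffled-sex null, and the
    Fisher-overlap oracle table."""
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(seed)
    expr = rng.standard_normal(200)
    feat = (rng.random(200) < 0.5).astype(float)
    score = 0.5 * expr + 0.2 * feat - 0.3 * expr * feat + 0.1
    fit = fit_interaction(score, expr, feat)
    noiseless_err = max(
        abs(fit.a - 0.5), abs(fit.b - 0.2), abs(fit.c + 0.3), abs(fit.d - 0.1)
    )

    hits = 0
    for rep in range(100):
        r = np.random.default_rng(seed * 100 + rep)
        e = r.standard_normal(500)
        f = (r.random(500) < 0.5).astype(float)
        s = 0.5 * e + 0.2 * f - 0.3 * e * f + 0.1 + r.standard_normal(500) * 0.1
        hits += abs(fit_interaction(s, e, f).c + 0.3) <= 0.05
    mc_coverage = hits / 100

    harm, pheno, covs, truth = _processed(SimulationConfig(seed=seed))
    pca = fit_pca(harm.values, k=k_pcs)
    X = apply_pca(pca, harm.values)
    Y = pheno.masked_array()
    cfg = AttributionConfig(steps=steps)
    tensors = []
    ranking_runs = []
    weights = weights_from_quantiles(np.nanmean(Y, axis=1))
    for r in range(n_runs):
        est = MultiTaskNeuralRegressor(
            shared_widths=(64, 32), branch_widths=(16,), epochs=epochs,
            random_state=1000 + r + 7919 * seed,
        ).fit(X, Y)
        tensor = attribute_dataset(est, harm.values, config=cfg, pca=pca)
        tensors.append(tensor)
        ranking_runs.append(aggregate_weighted(tensor, weights))
    importance = per_sample_consensus(tensors)
    scan = interaction_scan(importance, harm.values, covs.sex, gene_ids=harm.gene_ids)
    is_interacting = truth.is_interacting(harm.gene_ids)
    auroc = roc_auc_score(is_interacting, scan["neg_log10_p"].to_numpy())
    observed_significant = int(scan["significant"].sum())

    counts, _ = shuffled_null(
        importance, harm.values, covs.sex, n_shuffles=n_shuffles, seed=seed
    )
    null_fraction = float(counts.mean() / harm.n_genes)

    ranking = consensus_gene_ranking(ranking_runs, harm.gene_ids)
    signal_auroc = signal_gene_recovery(ranking["consensus"], truth, harm.gene_ids)

    # enrichment of truly interacting genes in the significant set
    enrich = fisher_overlap(
        list(scan.index[scan["significant"]]),
        list(truth.interaction_gene_ids),
        list(harm.gene_ids),
    )

    oracle = fisher_overlap(
        [f"g{i}" for i in range(10)],
        [f"g{i}" for i in range(5, 15)],
        [f"g{i}" for i in range(100)],
    )
    return {
        "noiseless_recovery_max_err": float(noiseless_err),
        "mc_coverage": float(mc_coverage),
        "interaction_recovery_auroc": float(auroc),
        "observed_significant": observed_significant,
        "shuffled_null_mean_fraction": null_fraction,
        "shuffled_null_max_count": int(counts.max()),
        "signal_gene_auroc": float(signal_auroc),
        "truth_enrichment_p": float(enrich["p_value"]),
        "fisher_oracle_p": float(oracle["p_value"]),
        "fisher_oracle_odds_ratio": float(oracle["odds_ratio"]),
    }


# --------------------------------------------------------------------------
# end-to-end determinism


def pipeline_determinism(seed: int = 4, work_dir=None) -> dict:
    """Run the full pipeline twice with identical config+seed and compare
    checksums of the text artifacts."""
    config = {
        "seed": seed,
        "simulation": {
            "n_cohorts": 2, "samples_per_cohort": 50, "n_genes": 120,
            "n_signal_genes": 12, "n_sex_interacting_genes": 5,
            "n_sex_marker_genes": 3,
        },
        "preprocess": {"pca_components": 20},
        "n_runs": 2,
        "model": {"shared_widths": [16, 8], "branch_widths": [4], "epochs": 5},
        "evaluation": {"n_rounds": 2},
        "attribution": {"steps": 20},
        "consensus": {"k": 4},
        "interactions": {"n_shuffles": 1},
    }
    artifacts = ("ranking", "corr_ranking", "annotation", "scan", "evaluation")
    with tempfile.TemporaryDirectory(dir=work_dir) as tmp:
        sums = []
        for rep in range(2):
            out = Path(tmp) / f"rep{rep}"
            pipeline_full(config, out)
            sums.append(
                {
                    key: hashlib.sha256((out / FILES[key]).read_bytes()).hexdigest()
                    for key in artifacts
                }
            )
    return {
        "identical_artifacts": float(sums[0] == sums[1]),
        "n_artifacts_compared": len(artifacts),
    }
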