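"""Evaluation protocol: normalized prediction error, nested cross-validation
with grid search, rank-based final-model selection, dataset-subset
experiments, the composite neuropathology score, and group comparisons.

The error metric throughout is ``1 - R^2_CV`` = mean squared error over
observed cells divided by the population variance of the observed labels in
the evaluation split.  It equals 1 exactly for a predictor that outputs the
evaluation-split mean, and 0 for a perfect predictor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import GroupKFold, KFold

from .models import MultiTaskNeuralRegressor
from .preprocess import apply_pca, fit_pca

logger = logging.getLogger(__name__)


def one_minus_r2cv(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """MSE over observed cells divided by the population variance (ddof=0)
    of the observed truth.  NaN in ``y_true`` marks unobserved cells.
    Returns NaN (with a warning) when the truth variance is zero."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    obs = ~np.isnan(y_true)
    yt, yp = y_true[obs], y_pred[obs]
    if yt.size < 2:
        raise ValueError("need >=2 observed truth values")
    var = yt.var()  # population convention
    if var == 0:
        logger.warning("zero label variance; 1-R^2_CV undefined")
        return np.nan
    return float(((yp - yt) ** 2).mean() / var)


def per_task_errors(Y_true: np.ndarray, Y_pred: np.ndarray) -> np.ndarray:
    """1-R^2_CV per task column; NaN where a task has <2 observed labels."""
    Y_true = np.asarray(Y_true, dtype=float)
    out = np.full(Y_true.shape[1], np.nan)
    for t in range(Y_true.shape[1]):
        obs = ~np.isnan(Y_true[:, t])
        if obs.sum() >= 2:
            out[t] = one_minus_r2cv(Y_true[:, t], Y_pred[:, t])
    return out


def _splitter(n_splits: int, groups, seed: int):
    if groups is None:
        return KFold(n_splits=n_splits, shuffle=True, random_state=seed), None
    if len(np.unique(groups)) < n_splits:
        raise ValueError("too few individuals for grouped splitting")
    return GroupKFold(n_splits=n_splits, shuffle=True, random_state=seed), groups


@dataclass
class CVPlan:
    n_outer: int = 5
    n_inner: int = 5
    grouping: str = "random_sample"  # or "by_individual"
    seed: int = 0


@dataclass
class EvaluationResult:
    """Nested-CV output: per-(round, task) outer-test metrics, the inner
    grid-search error matrix (rounds x configs) and per-round selections."""

    outer: pd.DataFrame
    config_errors: np.ndarray
    selected_configs: list
    grid: list
    predictions: dict = field(default_factory=dict)


def run_nested_cv(
    X: np.ndarray,
    Y: np.ndarray,
    grid,
    plan: CVPlan | None = None,
    groups=None,
    estimator_factory=None,
    pca_components: int | None = None,
) -> EvaluationResult:
    """Nested cross-validation with per-round grid search.

    For each of ``n_outer`` rounds one fold is withheld as a test set; an
    inner ``n_inner``-fold CV on the remainder selects the grid config
    minimizing the mean (over folds and tasks) 1-R^2_CV; the model is
    retrained on the full outer-training set with that config and scored on
    the withheld fold.  Outer-test labels are never visible to selection.

    ``pca_components`` fits the PCA input map on the training portion of
    each split only (no leakage); pre-transform X globally to reproduce a
    single shared input map instead.
    """
    plan = plan or CVPlan()
    grid = list(grid)
    if not grid:
        raise ValueError("hyperparameter grid must be nonempty")
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if estimator_factory is None:
        estimator_factory = lambda cfg: MultiTaskNeuralRegressor(**cfg)
    if plan.grouping == "by_individual" and groups is None:
        raise ValueError("by_individual grouping requires groups")
    eff_groups = groups if plan.grouping == "by_individual" else None

    def _transform(X_train, X_eval):
        if pca_components is None:
            return X_train, X_eval
        pca = fit_pca(X_train, k=pca_components)
        return apply_pca(pca, X_train), apply_pca(pca, X_eval)

    outer_cv, g = _splitter(plan.n_outer, eff_groups, plan.seed)
    rows, selected, preds_by_round = [], [], {}
    config_errors = np.zeros((plan.n_outer, len(grid)))
    for rnd, (tr, te) in enumerate(outer_cv.split(X, groups=g)):
        Xtr, Ytr = X[tr], Y[tr]
        inner_groups = eff_groups[tr] if eff_groups is not None else None
        inner_cv, gi = _splitter(plan.n_inner, inner_groups, plan.seed + 1 + rnd)
        inner_splits = list(inner_cv.split(Xtr, groups=gi))
        for ci, cfg in enumerate(grid):
            fold_scores = []
            for itr, ite in inner_splits:
                Xi, Xv = _transform(Xtr[itr], Xtr[ite])
                est = estimator_factory(cfg)
                est.fit(Xi, Ytr[itr])
                P = np.atleast_2d(est.predict(Xv).T).T
                errs = per_task_errors(np.atleast_2d(Ytr[ite].T).T, P)
                fold_scores.append(np.nanmean(errs))
            config_errors[rnd, ci] = float(np.mean(fold_scores))
        best = int(np.argmin(config_errors[rnd]))
        selected.append(grid[best])
        Xtr_t, Xte_t = _transform(Xtr, X[te])
        est = estimator_factory(grid[best])
        est.fit(Xtr_t, Ytr)
        P = np.atleast_2d(est.predict(Xte_t).T).T
        Yte = np.atleast_2d(Y[te].T).T
        preds_by_round[rnd] = (te, P)
        for t in range(Yte.shape[1]):
            obs = ~np.isnan(Yte[:, t])
            if obs.sum() < 2:
                continue
            mse = float(((P[obs, t] - Yte[obs, t]) ** 2).mean())
            var = float(Yte[obs, t].var())
            rows.append(
                {
                    "round": rnd,
                    "task": t,
                    "mse": mse,
                    "label_variance": var,
                    "one_minus_r2cv": mse / var if var > 0 else np.nan,
                    "config_index": best,
                }
            )
    return EvaluationResult(
        outer=pd.DataFrame(rows),
        config_errors=config_errors,
        selected_configs=selected,
        grid=grid,
        predictions=preds_by_round,
    )


def select_final_config(config_errors: np.ndarray, grid) -> tuple[int, dict]:
    """Average-rank final-model selection.

    ``config_errors[r, c]`` is config ``c``'s prediction error in round
    ``r`` (every config evaluated in every round).  Configs are ranked per
    round (rank 1 = lowest error); the config with the best mean rank wins;
    ties break by lower mean error, then by grid order."""
    E = np.asarray(config_errors, dtype=float)
    ranks = np.vstack([stats.rankdata(row, method="average") for row in E])
    mean_rank = ranks.mean(axis=0)
    mean_err = E.mean(axis=0)
    order = np.lexsort((np.arange(E.shape[1]), mean_err, mean_rank))
    best = int(order[0])
    return best, list(grid)[best]


def dataset_subset_experiment(
    X: np.ndarray,
    Y: np.ndarray,
    cohort: np.ndarray,
    target_cohort: str,
    subsets: list,
    config: dict,
    estimator_factory=None,
    n_rounds: int = 5,
    seed: int = 0,
    pca_components: int | None = None,
) -> pd.DataFrame:
    """Test error on the target cohort when training on subsets of cohorts.

    For each round, one fold of the target cohort is withheld for testing;
    the training set is the union of all samples from the subset's other
    cohorts plus (when the target cohort belongs to the subset) the target
    cohort's training portion.  Reported per task even for tasks unlabeled
    in the added cohorts."""
    cohort = np.asarray(cohort)
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if estimator_factory is None:
        estimator_factory = lambda cfg: MultiTaskNeuralRegressor(**cfg)
    target_rows = np.flatnonzero(cohort == target_cohort)
    if target_rows.size == 0:
        raise ValueError(f"target cohort {target_cohort!r} has no samples")
    kf = KFold(n_splits=n_rounds, shuffle=True, random_state=seed)
    rows = []
    for subset in subsets:
        subset = list(subset)
        if not subset:
            raise ValueError("empty training subset")
        other_rows = np.flatnonzero(
            np.isin(cohort, [c for c in subset if c != target_cohort])
        )
        for rnd, (tr_idx, te_idx) in enumerate(kf.split(target_rows)):
            test = target_rows[te_idx]
            train = other_rows
            if target_cohort in subset:
                train = np.concatenate([other_rows, target_rows[tr_idx]])
            if train.size == 0:
                raise ValueError("training subset selects no samples")
            Xtr, Xte = X[train], X[test]
            if pca_components is not None:
                pca = fit_pca(Xtr, k=pca_components)
                Xtr, Xte = apply_pca(pca, Xtr), apply_pca(pca, Xte)
            est = estimator_factory(config)
            est.fit(Xtr, Y[train])
            P = np.atleast_2d(est.predict(Xte).T).T
            errs = per_task_errors(np.atleast_2d(Y[test].T).T, P)
            for t, e in enumerate(errs):
                rows.append(
                    {
                        "subset": "+".join(map(str, subset)),
                        "round": rnd,
                        "task": t,
                        "one_minus_r2cv": e,
                    }
                )
    return pd.DataFrame(rows)


def neuropathology_score(preds: np.ndarray, dataset_ids) -> np.ndarray:
    """Per-sample composite severity: the mean over phenotype columns of
    within-dataset percentile ranks, percentile = (rank - 1) / (n - 1) with
    mean-rank ties.  Invariant under any strictly increasing per-phenotype
    transform; lies in [0, 1]."""
    preds = np.atleast_2d(np.asarray(preds, dtype=float).T).T
    dataset_ids = np.asarray(dataset_ids)
    out = np.full(preds.shape, np.nan)
    for ds in pd.unique(dataset_ids):
        rows = np.flatnonzero(dataset_ids == ds)
        n = rows.size
        if n == 1:
            logger.warning("dataset %r has a single sample; score set to 0.5", ds)
            out[rows] = 0.5
            continue
        for j in range(preds.shape[1]):
            col = preds[rows, j]
            ok = ~np.isnan(col)
            if ok.sum() < 2:
                continue
            r = stats.rankdata(col[ok], method="average")
            pct = (r - 1) / (ok.sum() - 1)
            vals = np.full(n, np.nan)
            vals[ok] = pct
            out[rows, j] = vals
    return np.nanmean(out, axis=1)


def group_compare(scores, group_labels, pooled: bool = False):
    """Two-sided independent two-sample t test (Welch by default) comparing
    scores between the two groups."""
    scores = np.asarray(scores, dtype=float)
    group_labels = np.asarray(group_labels)
    levels = pd.unique(group_labels)
    if len(levels) != 2:
        raise ValueError("group_compare requires exactly 2 group levels")
    a = scores[group_labels == levels[0]]
    b = scores[group_labels == levels[1]]
    if min(len(a), len(b)) < 2:
        raise ValueError("each group must have >=2 samples")
    res = stats.ttest_ind(a, b, equal_var=pooled)
    return float(res.statistic), float(res.pvalue)


def _pearson_columns(M: np.ndarray, y: np.ndarray):
    """Vectorized Pearson r and two-sided p for each column of M vs y;
    constant columns get r=0, p=1."""
    M = np.asarray(M, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    Mc = M - M.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((Mc * Mc).sum(axis=0))
    sy = np.sqrt((yc * yc).sum())
    denom = sx * sy
    ok = denom > 0
    r = np.zeros(M.shape[1])
    r[ok] = (Mc[:, ok] * yc[:, None]).sum(axis=0) / denom[ok]
    r = np.clip(r, -1.0, 1.0)
    p = np.ones(M.shape[1])
    if n > 2:
        with np.errstate(divide="ignore"):
            t = r * np.sqrt((n - 2) / np.maximum(1e-300, 1 - r * r))
        p_ok = 2 * stats.t.sf(np.abs(t[ok]), df=n - 2)
        p[ok] = np.clip(p_ok, np.finfo(float).tiny, 1.0)
    return r, p


def best_node_correlation(
    train_embed: np.ndarray,
    test_embed: np.ndarray,
    y_train: np.ndarray,
    y_test: np.ndarray,
) -> dict:
    """Select the embedding node most significantly Pearson-correlated with
    the label on the training split; report that node's test-split
    correlation as -log10(p) after BH-FDR adjustment across all nodes'
    test p-values."""
    from statsmodels.stats.multitest import multipletests

    obs_tr = ~np.isnan(np.asarray(y_train, dtype=float))
    obs_te = ~np.isnan(np.asarray(y_test, dtype=float))
    _, p_train = _pearson_columns(train_embed[obs_tr], np.asarray(y_train)[obs_tr])
    node = int(np.argmin(p_train))
    r_test, p_test = _pearson_columns(test_embed[obs_te], np.asarray(y_test)[obs_te])
    _, q_test, _, _ = multipletests(p_test, method="fdr_bh")
    return {
        "node": node,
        "test_r": float(r_test[node]),
        "neg_log10_q": float(-np.log10(max(q_test[node], np.finfo(float).tiny))),
    }


def unsupervised_baseline_embedding(
    X: np.ndarray, method: str = "pca", dim: int = 100, random_state: int = 0
) -> np.ndarray:
    """Unsupervised 100-dimensional comparison embeddings: distances to
    k-means centroids, or the first ``dim`` PCA scores."""
    from sklearn.cluster import KMeans
    from sklearn.decomposition import PCA

    X = np.asarray(X, dtype=float)
    if method == "kmeans":
        km = KMeans(n_clusters=dim, n_init=10, random_state=random_state)
        return km.fit_transform(X)
    if method == "pca":
        feasible = min(X.shape)
        if dim > feasible:
            logger.warning("PCA embedding truncated from %d to %d dims", dim, feasible)
            dim = feasible
        return PCA(n_components=dim, random_state=random_state).fit_transform(X)
    raise ValueError(f"unknown embedding method {method!r}")
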