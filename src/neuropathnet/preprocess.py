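"""Deterministic data transformations applied before modeling.

The canonical processing path for multi-cohort expression data is:

1. per-cohort removal of genes with too many null values, then restriction
   to the genes shared by every cohort (:func:`intersect_and_filter`);
2. optional ``log(1+x)`` transform and per-gene 0-1 scaling
   (:class:`GeneMinMaxScaler`);
3. per-cohort 0-1 scaling of the six phenotype columns
   (:func:`normalize_phenotypes`);
4. batch harmonization across cohorts (:func:`harmonize_batches`);
5. PCA to the top k components used as network input (:func:`fit_pca`).

External-cohort transfer additionally uses per-gene moment matching to the
training population (:func:`moment_match`), and covariate sensitivity
analyses use per-gene OLS residualization (:func:`residualize_covariates`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

from .datatypes import (
    N_PHENOTYPES,
    CovariateTable,
    ExpressionMatrix,
    PhenotypeTable,
    check_aligned,
)

logger = logging.getLogger(__name__)


def intersect_and_filter(
    matrices: list[ExpressionMatrix], max_null_fraction: float = 2.0 / 3.0
) -> list[ExpressionMatrix]:
    """Restrict every matrix to the genes shared by all of them, after
    per-matrix removal of genes whose null (NaN) fraction exceeds
    ``max_null_fraction``.  Gene order is identical across outputs."""
    if not matrices:
        raise ValueError("need at least one expression matrix")
    if not 0 <= max_null_fraction <= 1:
        raise ValueError("max_null_fraction must be in [0, 1]")
    kept_sets = []
    for m in matrices:
        null_frac = np.isnan(m.values).mean(axis=0)
        kept_sets.append({g for g, f in zip(m.gene_ids, null_frac) if f <= max_null_fraction})
    shared = set.intersection(*kept_sets)
    if not shared:
        names = [", ".join(map(str, m.cohort[:1])) or "?" for m in matrices]
        raise ValueError(
            "empty gene intersection after null filtering across inputs: "
            + "; ".join(names)
        )
    # deterministic order: order of the first matrix's genes
    order = [g for g in matrices[0].gene_ids if g in shared]
    return [m.subset_genes(order) for m in matrices]


class GeneMinMaxScaler(BaseEstimator, TransformerMixin):
    """Per-gene affine scaling to [0, 1], optionally after ``log(1+x)``.

    Constant genes map to 0 everywhere and their degenerate range is
    recorded in ``constant_mask_`` so that indices stay stable.  The fitted
    parameters apply the identical transform to new samples.
    """

    def __init__(self, log_first: bool = False):
        self.log_first = log_first

    def fit(self, X, y=None):
        X = self._maybe_log(np.asarray(X, dtype=float))
        self.min_ = X.min(axis=0)
        self.range_ = X.max(axis=0) - self.min_
        self.constant_mask_ = self.range_ == 0
        return self

    def transform(self, X):
        X = self._maybe_log(np.asarray(X, dtype=float))
        denom = np.where(self.constant_mask_, 1.0, self.range_)
        out = (X - self.min_) / denom
        out[:, self.constant_mask_] = 0.0
        return out

    def _maybe_log(self, X):
        if self.log_first:
            if np.nanmin(X) < 0:
                raise ValueError("negative values are incompatible with log_first")
            X = np.log1p(X)
        return X


def minmax_normalize(
    expr: ExpressionMatrix, log_first: bool = False
) -> tuple[ExpressionMatrix, GeneMinMaxScaler]:
    """0-1 scale each gene within the fitting population; returns the
    normalized matrix and the fitted scaler for reuse on new samples."""
    if expr.normalized:
        raise ValueError("expression matrix is already normalized")
    if np.isnan(expr.values).any():
        raise ValueError("missing values must be filtered before normalization")
    scaler = GeneMinMaxScaler(log_first=log_first).fit(expr.values)
    out = replace(expr, values=scaler.transform(expr.values), normalized=True)
    return out, scaler


def normalize_phenotypes(
    raw_values: np.ndarray,
    mask: np.ndarray,
    cohort: np.ndarray,
    sample_ids: np.ndarray,
) -> PhenotypeTable:
    """Scale each phenotype to [0, 1] within each cohort (min/max computed
    over observed entries only) before cohorts are concatenated.

    A phenotype observed in zero samples of a cohort simply stays fully
    masked for that cohort.
    """
    raw_values = np.asarray(raw_values, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    cohort = np.asarray(cohort, dtype=object)
    scaled = np.zeros_like(raw_values)
    for c in pd.unique(cohort):
        rows = cohort == c
        for j in range(N_PHENOTYPES):
            obs = mask[rows, j]
            if not obs.any():
                continue
            vals = raw_values[rows, j]
            lo, hi = vals[obs].min(), vals[obs].max()
            rng = hi - lo
            col = np.zeros_like(vals)
            if rng > 0:
                col[obs] = (vals[obs] - lo) / rng
            scaled[rows, j] = col
    return PhenotypeTable(values=scaled, mask=mask, sample_ids=sample_ids)


def harmonize_batches(
    expr: ExpressionMatrix, batch: np.ndarray, method: str = "location_scale"
) -> ExpressionMatrix:
    """Reduce per-batch location/scale differences gene by gene.

    ``location_scale`` standardizes each gene within batch and rescales to
    the pooled gene mean/SD; ``external`` passes through a matrix corrected
    by external tooling (e.g. empirical-Bayes batch correction).
    """
    if method == "external":
        return expr
    if method != "location_scale":
        raise ValueError(f"unknown harmonization method {method!r}")
    batch = np.asarray(batch)
    labels = np.unique(batch)
    if len(labels) < 2:
        raise ValueError("need at least 2 batches to harmonize")
    X = expr.values.copy()
    pooled_mean = X.mean(axis=0)
    pooled_sd = X.std(axis=0)
    for b in labels:
        rows = batch == b
        n_b = int(rows.sum())
        mu = X[rows].mean(axis=0)
        if n_b < 2:
            logger.warning("batch %r has a single sample; scale step skipped", b)
            sd = np.ones_like(mu)
        else:
            sd = X[rows].std(axis=0)
            sd = np.where(sd == 0, 1.0, sd)
        X[rows] = (X[rows] - mu) / sd * pooled_sd + pooled_mean
    return replace(expr, values=X)


@dataclass
class PCATransform:
    """Fixed linear input map: genes -> top-k principal component scores."""

    component_loadings: np.ndarray  # genes x k, orthonormal columns
    gene_means: np.ndarray
    explained_variance: np.ndarray

    @property
    def k(self) -> int:
        return self.component_loadings.shape[1]

    def apply(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X - self.gene_means) @ self.component_loadings

    def inverse(self, scores: np.ndarray) -> np.ndarray:
        return scores @ self.component_loadings.T + self.gene_means


def fit_pca(X, k: int = 500, random_state: int = 0) -> PCATransform:
    """PCA on mean-centered data; components ordered by decreasing explained
    variance.  If ``k`` exceeds the data rank the returned transform is
    truncated with a logged warning."""
    X = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, dtype=float)
    max_k = min(X.shape)
    if k > max_k:
        logger.warning("requested k=%d exceeds feasible rank %d; truncating", k, max_k)
        k = max_k
    pca = PCA(n_components=k, random_state=random_state)
    pca.fit(X)
    # drop numerically null trailing components (rank-deficient data)
    ev = pca.explained_variance_
    keep = ev > max(ev[0], 1.0) * 1e-12 if len(ev) else slice(None)
    return PCATransform(
        component_loadings=pca.components_[keep].T.copy(),
        gene_means=pca.mean_.copy(),
        explained_variance=ev[keep].copy(),
    )


def apply_pca(transform: PCATransform, X) -> np.ndarray:
    X = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, dtype=float)
    if X.shape[1] != transform.component_loadings.shape[0]:
        raise ValueError("gene dimension does not match fitted PCA transform")
    return transform.apply(X)


def moment_match(
    external: ExpressionMatrix, ref_mean: np.ndarray, ref_sd: np.ndarray
) -> ExpressionMatrix:
    """Affinely transform each external gene so its mean/SD equal the
    reference (training-population) mean/SD.  Zero-SD external genes are set
    to the reference mean."""
    X = external.values
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    ref_mean = np.asarray(ref_mean, dtype=float)
    ref_sd = np.asarray(ref_sd, dtype=float)
    if X.shape[1] != len(ref_mean):
        raise ValueError("reference stats do not match external gene dimension")
    safe_sd = np.where(sd == 0, 1.0, sd)
    out = (X - mu) / safe_sd * ref_sd + ref_mean
    out[:, sd == 0] = ref_mean[sd == 0]
    return replace(external, values=out)


def residualize_covariates(
    expr: ExpressionMatrix, covs: CovariateTable, which: tuple[str, ...] = ("pmi", "rin")
) -> tuple[ExpressionMatrix, CovariateTable]:
    """Per gene, OLS of expression on an intercept plus the selected
    covariates; residuals are returned.  Samples missing any selected
    covariate are dropped with a logged count."""
    check_aligned(expr, covs)
    C = np.column_stack([getattr(covs, name) for name in which])
    keep = ~np.isnan(C).any(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("dropping %d samples with missing %s", n_dropped, which)
    idx = np.flatnonzero(keep)
    expr = expr.subset_samples(idx)
    covs = covs.subset_samples(idx)
    design = np.column_stack([np.ones(len(idx)), C[keep]])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        logger.warning("collinear covariates %s; using pseudo-inverse fit", which)
    beta, *_ = np.linalg.lstsq(design, expr.values, rcond=None)
    residuals = expr.values - design @ beta
    return replace(expr, values=residuals), covs
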