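"""Path-integrated gradient attributions in gene space and their
aggregation into consensus gene rankings.

Integrated Gradients assigns gene ``g`` of sample ``x`` the signed score

    IG_g = (x_g - x'_g) * (1/m) * sum_{j=1..m} dF_t(x' + (j/m)(x - x')) / dx_g

(right-Riemann approximation of the path integral from baseline ``x'`` to
``x``), which satisfies completeness: attributions sum to F(x) - F(x').
Targets are either the task outputs or the units of the last shared layer
(the truncated network).  When the network consumes PCA scores, the fixed
linear input map is folded into the gradient so attributions land directly
on genes; a gene with zero loading on every retained component receives
exactly zero attribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._nn import MaskedMLP
from .preprocess import PCATransform


@dataclass
class AttributionConfig:
    baseline: str | np.ndarray = "zeros"  # "zeros", "mean", or explicit vector
    steps: int = 200
    targets: str = "outputs"  # "outputs" or "last_shared_nodes"
    scheme: str = "right"  # Riemann scheme: "right" or "midpoint"

    def __post_init__(self):
        if self.steps < 20:
            raise ValueError("need >= 20 integration steps")
        if self.targets not in ("outputs", "last_shared_nodes"):
            raise ValueError(f"unknown targets {self.targets!r}")
        if self.scheme not in ("right", "midpoint"):
            raise ValueError(f"unknown Riemann scheme {self.scheme!r}")


def _resolve_net(model) -> MaskedMLP:
    return model.net_ if hasattr(model, "net_") else model


def _resolve_baseline(config: AttributionConfig, X: np.ndarray) -> np.ndarray:
    if isinstance(config.baseline, str):
        if config.baseline == "zeros":
            return np.zeros(X.shape[1])
        if config.baseline == "mean":
            return X.mean(axis=0)
        raise ValueError(f"unknown baseline {config.baseline!r}")
    b = np.asarray(config.baseline, dtype=float)
    if b.shape != (X.shape[1],):
        raise ValueError("baseline dimension must equal the gene count")
    return b


def attribute_dataset(
    model,
    X: np.ndarray,
    config: AttributionConfig | None = None,
    pca: PCATransform | None = None,
    batch_size: int = 256,
) -> np.ndarray:
    """Integrated Gradients for every sample: (samples x genes x targets).

    ``X`` is in gene space (the space the baseline lives in); ``pca``, when
    given, is the fixed input map of the network.  Computation is batched
    over samples to bound memory.
    """
    config = config or AttributionConfig()
    net = _resolve_net(model)
    X = np.asarray(X, dtype=float)
    baseline = _resolve_baseline(config, X)
    kind = "output" if config.targets == "outputs" else "node"
    n_targets = net.n_tasks if kind == "output" else net.shared_widths[-1]

    out = np.empty((X.shape[0], X.shape[1], n_targets))
    for start in range(0, X.shape[0], batch_size):
        xb = X[start : start + batch_size]
        out[start : start + batch_size] = _ig_batch(
            net, xb, baseline, config.steps, kind, n_targets, pca, config.scheme
        )
    return out


def _ig_batch(net, X, baseline, steps, kind, n_targets, pca, scheme):
    n = X.shape[0]
    diff = X - baseline
    in_dim = net.input_dim
    acc = np.zeros((n_targets, n, in_dim))
    for j in range(1, steps + 1):
        alpha = (j - 0.5) / steps if scheme == "midpoint" else j / steps
        P = baseline + alpha * diff
        Z = pca.apply(P) if pca is not None else P
        preds, cache = net.forward(Z, training=False)
        for t in range(n_targets):
            if kind == "output":
                dpred = np.zeros_like(preds)
                dpred[:, t] = 1.0
                _, dZ = net.backward(cache, dpred)
            else:
                dshared = np.zeros_like(cache["shared_out"])
                dshared[:, t] = 1.0
                _, dZ = net.backward(cache, None, dshared_extra=dshared)
            acc[t] += dZ
    acc /= steps
    out = np.empty((n, X.shape[1], n_targets))
    for t in range(n_targets):
        grad_genes = acc[t] @ pca.component_loadings.T if pca is not None else acc[t]
        out[:, :, t] = diff * grad_genes
    return out


def integrated_gradients(
    model,
    x: np.ndarray,
    config: AttributionConfig | None = None,
    pca: PCATransform | None = None,
) -> np.ndarray:
    """Attributions for a single sample: (genes x targets)."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("x must be a single gene-space vector")
    return attribute_dataset(model, x[None, :], config=config, pca=pca)[0]


def completeness_gap(model, X, tensor, config=None, pca=None) -> np.ndarray:
    """|sum_g IG - (F(x) - F(x'))| per (sample, target) — the completeness
    axiom residual, shrinking as the step count grows."""
    config = config or AttributionConfig()
    net = _resolve_net(model)
    X = np.asarray(X, dtype=float)
    baseline = _resolve_baseline(config, X)

    def f(M):
        Z = pca.apply(M) if pca is not None else M
        if config.targets == "outputs":
            return net.predict(Z)
        return net.shared_forward(Z)

    delta = f(X) - f(baseline[None, :])
    return np.abs(tensor.sum(axis=1) - delta)


# --- sample weighting and aggregation ---------------------------------------

def pathology_weights(
    braak,
    cerad,
    braak_high: float = 5,
    cerad_high: float = 3,
    braak_low: float = 3,
    cerad_low: float = 1,
    age=None,
    dementia=None,
    age_min: float = 85,
) -> np.ndarray:
    """+1 for samples with high Braak and CERAD, -1 for low Braak and CERAD
    (optionally restricted to old, non-demented individuals), 0 otherwise.
    Thresholds are on the scales in which braak/cerad are supplied."""
    braak = np.asarray(braak, dtype=float)
    cerad = np.asarray(cerad, dtype=float)
    high = (braak >= braak_high) & (cerad >= cerad_high)
    low = (braak <= braak_low) & (cerad <= cerad_low)
    if age is not None:
        low = low & (np.asarray(age, dtype=float) >= age_min)
    if dementia is not None:
        low = low & (np.asarray(dementia, dtype=float) == 0)
    w = np.zeros(len(braak))
    w[high] = 1.0
    w[low & ~high] = -1.0
    return w


def weights_from_quantiles(severity, low_q: float = 1 / 3, high_q: float = 2 / 3) -> np.ndarray:
    """Quantile-based high/low pathology weights for continuous severities.
    NaN severities (samples with no observed phenotype) get weight 0."""
    severity = np.asarray(severity, dtype=float)
    ok = ~np.isnan(severity)
    if not ok.any():
        raise ValueError("all severities are missing")
    lo, hi = np.nanquantile(severity, [low_q, high_q])
    w = np.zeros(len(severity))
    w[ok & (severity >= hi)] = 1.0
    w[ok & (severity <= lo)] = -1.0
    return w


def aggregate_weighted(tensor: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted average of attributions over samples: per (gene, target)
    sum_i w_i * IG_{i,g,t} divided by the number of nonzero-weight samples.
    Genes whose high attributions coincide with high-pathology samples score
    highest."""
    tensor = np.asarray(tensor, dtype=float)
    weights = np.asarray(weights, dtype=float)
    n_active = int((weights != 0).sum())
    if n_active == 0:
        raise ValueError("no sample has a nonzero pathology weight")
    return np.tensordot(weights, tensor, axes=(0, 0)) / n_active


# --- rankings ----------------------------------------------------------------

def _percentile(x: np.ndarray) -> np.ndarray:
    """(rank - 1) / (n - 1) with mean-rank ties; spans [0, 1] exactly."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2:
        return np.full(n, 0.5)
    return (stats.rankdata(x, method="average") - 1) / (n - 1)


def consensus_gene_ranking(
    per_run_scores: list[np.ndarray], gene_ids, phenotype_names=None
) -> pd.DataFrame:
    """Consensus percentile ranking over repeated trainings.

    Within each run and phenotype, genes are ranked by aggregated
    attribution; ranks are averaged across runs, converted to a percentile
    per phenotype (mean-rank ties), and finally averaged across phenotypes
    for the ``consensus`` column: a gene near 1 has the highest average
    rank (most positively associated with pathology), near 0 the lowest."""
    per_run_scores = [np.asarray(s, dtype=float) for s in per_run_scores]
    if not per_run_scores:
        raise ValueError("need at least one run")
    g, t = per_run_scores[0].shape
    if len(gene_ids) != g:
        raise ValueError("gene_ids length mismatch with score matrices")
    for s in per_run_scores:
        if s.shape != (g, t):
            raise ValueError("all runs must cover the same gene/target universe")
    avg_ranks = np.zeros((g, t))
    for s in per_run_scores:
        for j in range(t):
            avg_ranks[:, j] += stats.rankdata(s[:, j], method="average")
    avg_ranks /= len(per_run_scores)
    pct = np.column_stack([_percentile(avg_ranks[:, j]) for j in range(t)])
    names = list(phenotype_names) if phenotype_names is not None else [
        f"target{j}" for j in range(t)
    ]
    df = pd.DataFrame(pct, index=np.asarray(gene_ids, dtype=object), columns=names)
    df["consensus"] = pct.mean(axis=1)
    df.index.name = "gene"
    return df


def correlation_ranking(
    expr_values: np.ndarray,
    pheno_values: np.ndarray,
    gene_ids,
    phenotype_names=None,
    order: str = "per_phenotype",
) -> pd.DataFrame:
    """Linear comparison ranking from plain Pearson correlations.

    Per phenotype, each gene's correlation with the phenotype is computed
    over the samples observed for it (constant genes count as r=0).  With
    ``order='per_phenotype'`` (default) genes are percentile-ranked within
    each phenotype and the final column averages the phenotype-specific
    rankings; ``order='average_r'`` instead percentile-ranks the mean
    correlation across phenotypes."""
    X = np.asarray(expr_values, dtype=float)
    Y = np.atleast_2d(np.asarray(pheno_values, dtype=float).T).T
    g = X.shape[1]
    n_ph = Y.shape[1]
    R = np.zeros((g, n_ph))
    for j in range(n_ph):
        obs = ~np.isnan(Y[:, j])
        if obs.sum() < 3:
            continue
        Xo = X[obs]
        yo = Y[obs, j]
        Xc = Xo - Xo.mean(axis=0)
        yc = yo - yo.mean()
        denom = np.sqrt((Xc * Xc).sum(axis=0)) * np.sqrt((yc * yc).sum())
        ok = denom > 0
        R[ok, j] = (Xc[:, ok] * yc[:, None]).sum(axis=0) / denom[ok]
    names = list(phenotype_names) if phenotype_names is not None else [
        f"target{j}" for j in range(n_ph)
    ]
    pct = np.column_stack([_percentile(R[:, j]) for j in range(n_ph)])
    df = pd.DataFrame(pct, index=np.asarray(gene_ids, dtype=object), columns=names)
    if order == "per_phenotype":
        df["consensus"] = pct.mean(axis=1)
    elif order == "average_r":
        df["consensus"] = _percentile(R.mean(axis=1))
    else:
        raise ValueError(f"unknown order {order!r}")
    df.index.name = "gene"
    return df


def per_sample_consensus(tensors: list[np.ndarray]) -> np.ndarray:
    """Per-sample, per-gene consensus importance: the plain mean of the
    attribution tensors over runs and targets -> (samples x genes)."""
    tensors = [np.asarray(t, dtype=float) for t in tensors]
    shape = tensors[0].shape
    for t in tensors:
        if t.shape != shape:
            raise ValueError("attribution tensors must share a common shape")
    return np.mean([t.mean(axis=2) for t in tensors], axis=0)
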