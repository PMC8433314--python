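"""Covariate-interaction detection on per-sample attribution scores.

For each gene ``g`` the per-sample consensus importance score is modeled as

    score_{g,i} = a * expr_{g,i} + b * feat_i + c * expr_{g,i} * feat_i + d

by ordinary least squares, where ``feat`` is a binary covariate (sex:
1 = male).  A statistically significant interaction coefficient ``c``
(p < alpha after BH-FDR over all genes) marks the gene's importance as
covariate-differential — the signature of a non-linearity the network
learned that a linear model cannot express.  A shuffled-covariate null and
Fisher-overlap gene-set enrichment complete the scan.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

_COEF = ("a", "b", "c", "d")


@dataclass
class InteractionFit:
    a: float
    b: float
    c: float
    d: float
    p_c: float
    flagged: bool = False


def _batched_ols(S: np.ndarray, E: np.ndarray, f: np.ndarray):
    """Per-gene OLS of score on [expr, feat, expr*feat, 1].

    Returns (beta (g,4), p (g,4), flagged (g,)) with classical t-test
    p-values; rank-deficient designs are flagged with p = 1.
    """
    n, g = E.shape
    ones = np.ones(n)
    cols = [E, np.broadcast_to(f[:, None], (n, g)), E * f[:, None],
            np.broadcast_to(ones[:, None], (n, g))]
    XtX = np.empty((g, 4, 4))
    Xty = np.empty((g, 4))
    for i in range(4):
        Xty[:, i] = (cols[i] * S).sum(axis=0)
        for j in range(i, 4):
            v = (cols[i] * cols[j]).sum(axis=0)
            XtX[:, i, j] = v
            XtX[:, j, i] = v
    scale = np.sqrt(np.maximum(np.einsum("gii->gi", XtX), 1e-300))
    cond_proxy = np.abs(np.linalg.det(XtX / (scale[:, :, None] * scale[:, None, :])))
    flagged = ~np.isfinite(cond_proxy) | (cond_proxy < 1e-12)
    beta = np.zeros((g, 4))
    p = np.ones((g, 4))
    ok = ~flagged
    if ok.any() and n > 4:
        inv = np.linalg.inv(XtX[ok])
        beta_ok = np.einsum("gij,gj->gi", inv, Xty[ok])
        ss_res = (S[:, ok] ** 2).sum(axis=0) - np.einsum(
            "gi,gi->g", beta_ok, Xty[ok]
        )
        sigma2 = np.maximum(ss_res, 0.0) / (n - 4)
        se = np.sqrt(np.maximum(sigma2[:, None] * np.einsum("gii->gi", inv), 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, beta_ok / se, 0.0)
        p_ok = 2 * stats.t.sf(np.abs(t), df=n - 4)
        beta[ok] = beta_ok
        p[ok] = np.clip(p_ok, np.finfo(float).tiny, 1.0)
    return beta, p, flagged


def fit_interaction(scores_g, expr_g, feat) -> InteractionFit:
    """Interaction fit for a single gene.  Requires >= 8 samples, both
    covariate levels present, and non-constant expression within at least
    one level; a rank-deficient design is flagged with p_c = 1."""
    s = np.asarray(scores_g, dtype=float)
    e = np.asarray(expr_g, dtype=float)
    f = np.asarray(feat, dtype=float)
    if len(s) < 8:
        raise ValueError("need at least 8 samples")
    levels = np.unique(f)
    if len(levels) != 2:
        raise ValueError("covariate must have exactly two levels present")
    if all(np.ptp(e[f == lv]) == 0 for lv in levels):
        raise ValueError("expression constant within both covariate levels")
    f01 = (f == levels.max()).astype(float)
    beta, p, flagged = _batched_ols(s[:, None], e[:, None], f01)
    return InteractionFit(
        a=float(beta[0, 0]),
        b=float(beta[0, 1]),
        c=float(beta[0, 2]),
        d=float(beta[0, 3]),
        p_c=float(p[0, 2]),
        flagged=bool(flagged[0]),
    )


def interaction_scan(
    importance: np.ndarray,
    expr: np.ndarray,
    feat: np.ndarray,
    gene_ids=None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene interaction fits with BH-FDR over all genes.

    Returns one row per gene with the four coefficients, the raw and
    BH-adjusted interaction p-values, -log10 of each, and the significance
    call at ``q < alpha``; rows are in gene order, ranking by
    ``neg_log10_p`` identifies the strongest interactions."""
    S = np.asarray(importance, dtype=float)
    E = np.asarray(expr, dtype=float)
    f = np.asarray(feat, dtype=float)
    if S.shape != E.shape:
        raise ValueError("importance and expression shapes differ")
    beta, p, flagged = _batched_ols(S, E, f)
    p_c = p[:, 2]
    _, q_c, _, _ = multipletests(p_c, method="fdr_bh")
    tiny = np.finfo(float).tiny
    df = pd.DataFrame(
        {
            "a": beta[:, 0],
            "b": beta[:, 1],
            "c": beta[:, 2],
            "d": beta[:, 3],
            "p_c": p_c,
            "q_c": q_c,
            "neg_log10_p": -np.log10(np.maximum(p_c, tiny)),
            "neg_log10_q": -np.log10(np.maximum(q_c, tiny)),
            "significant": q_c < alpha,
            "flagged": flagged,
        }
    )
    if gene_ids is not None:
        df.index = np.asarray(gene_ids, dtype=object)
        df.index.name = "gene"
    return df


def shuffled_null(
    importance: np.ndarray,
    expr: np.ndarray,
    feat: np.ndarray,
    n_shuffles: int = 10,
    seed: int = 0,
    alpha: float = 0.05,
    within: np.ndarray | None = None,
):
    """Repeat the full scan with the covariate permuted across samples
    (optionally within strata, e.g. cohorts); returns the per-shuffle
    significant-gene counts and the p-value matrix (shuffles x genes)."""
    if n_shuffles < 1:
        raise ValueError("need at least one shuffle")
    rng = np.random.default_rng(seed)
    f = np.asarray(feat, dtype=float)
    counts = np.empty(n_shuffles, dtype=int)
    pvals = np.empty((n_shuffles, expr.shape[1]))
    for s in range(n_shuffles):
        perm = f.copy()
        if within is None:
            perm = f[rng.permutation(len(f))]
        else:
            within = np.asarray(within)
            for lv in pd.unique(within):
                rows = np.flatnonzero(within == lv)
                perm[rows] = f[rows[rng.permutation(len(rows))]]
        scan = interaction_scan(importance, expr, perm, alpha=alpha)
        counts[s] = int(scan["significant"].sum())
        pvals[s] = scan["p_c"].to_numpy()
    return counts, pvals


def fisher_overlap(query_genes, gene_set, universe) -> dict:
    """Two-sided Fisher's exact test on the 2x2 overlap table of a query
    gene list and a gene set within a universe.  The reported odds ratio is
    the sample OR, with a Haldane 0.5 correction (flagged) when any cell is
    zero (a zero overlap is reported as OR = 0 uncorrected)."""
    universe = list(universe)
    if not universe:
        raise ValueError("empty gene universe")
    uset = set(universe)
    query = set(query_genes) & uset
    gset = set(gene_set) & uset
    n = len(uset)
    a = len(query & gset)
    b = len(query - gset)
    c = len(gset - query)
    d = n - a - b - c
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    corrected = b == 0 or c == 0  # denominator cells: avoid an infinite OR
    if corrected:
        aa, bb, cc, dd = (x + 0.5 for x in (a, b, c, d))
    else:
        aa, bb, cc, dd = a, b, c, d
    return {
        "overlap": a,
        "query_size": len(query),
        "set_size": len(gset),
        "universe_size": n,
        "odds_ratio": (aa * dd) / (bb * cc),
        "p_value": float(p),
        "haldane_corrected": corrected,
    }
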