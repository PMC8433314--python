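"""Consensus embedding: cluster last-shared-layer nodes pooled across many
independent retrainings and summarize each cluster by its medoid.

Because the training loss is non-convex, node identities vary from run to
run; pooling all nodes from ``n_runs`` networks (each node a vector of its
activation across samples, z-normalized), k-means clustering them with the
samples as coordinates, and taking each cluster's medoid yields a stable
50-node embedding in which each consensus node is an actual node of an
actual trained network, never a synthetic average.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .evaluation import _pearson_columns

logger = logging.getLogger(__name__)


@dataclass
class ConsensusEmbedding:
    medoid_nodes: np.ndarray  # k x samples (z-normalized activations)
    cluster_assignment: np.ndarray  # per pooled node
    medoid_sources: list  # (run_id, node_index) per medoid
    medoid_pool_indices: np.ndarray  # row of the pooled matrix per medoid
    annotation: pd.DataFrame | None = field(default=None)

    @property
    def k(self) -> int:
        return self.medoid_nodes.shape[0]

    def sample_embedding(self) -> np.ndarray:
        """Samples x k matrix of consensus node outputs."""
        return self.medoid_nodes.T


def pool_nodes(models, X: np.ndarray, dead_tol: float = 1e-12):
    """Stack every last-shared-layer node of every run as a z-normalized
    vector over samples -> ((n_runs * width) x samples) matrix plus the
    (run, node) source of each row.  Constant (dead ReLU) nodes are
    excluded with a logged count."""
    rows, sources = [], []
    n_dead = 0
    for run_id, model in enumerate(models):
        net = model.net_ if hasattr(model, "net_") else model
        H = net.shared_forward(np.asarray(X, dtype=float))  # samples x width
        sd = H.std(axis=0)
        for j in range(H.shape[1]):
            if sd[j] <= dead_tol:
                n_dead += 1
                continue
            rows.append((H[:, j] - H[:, j].mean()) / sd[j])
            sources.append((run_id, j))
    if n_dead:
        logger.info("excluded %d dead/constant nodes from the pool", n_dead)
    if not rows:
        raise ValueError("all pooled nodes are dead/constant")
    return np.vstack(rows), sources


def cluster_nodes(
    pooled: np.ndarray, sources, k: int = 50, seed: int = 0
) -> ConsensusEmbedding:
    """k-means over node vectors (samples as coordinates); each cluster is
    summarized by its medoid — the member minimizing the summed Euclidean
    distance to its co-members.  Deterministic given the seed."""
    pooled = np.asarray(pooled, dtype=float)
    if k > pooled.shape[0]:
        raise ValueError("k exceeds the number of pooled nodes")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(pooled)
    medoid_rows, medoid_sources = [], []
    for c in range(k):
        members = np.flatnonzero(labels == c)
        if members.size == 0:  # sklearn k-means does not leave empty clusters
            raise RuntimeError(f"empty cluster {c}")
        sub = pooled[members]
        d2 = ((sub[:, None, :] - sub[None, :, :]) ** 2).sum(axis=2)
        medoid = members[int(np.argmin(np.sqrt(d2).sum(axis=1)))]
        medoid_rows.append(medoid)
        medoid_sources.append(sources[medoid])
    medoid_rows = np.asarray(medoid_rows)
    return ConsensusEmbedding(
        medoid_nodes=pooled[medoid_rows],
        cluster_assignment=labels,
        medoid_sources=medoid_sources,
        medoid_pool_indices=medoid_rows,
    )


def annotate_nodes(
    embedding: ConsensusEmbedding,
    variables: dict[str, np.ndarray],
    gene_rankings_per_node: pd.DataFrame | None = None,
    gene_sets=None,
    top_n_genes: int = 100,
    enrichment_alpha: float = 0.05,
) -> ConsensusEmbedding:
    """Annotate each consensus node with its signed Pearson correlation and
    -log10(p) against every supplied variable (NaN handled pairwise-
    complete), and optionally with Fisher-overlap enrichment of the node's
    top genes against each gene set."""
    E = embedding.sample_embedding()  # samples x k
    rows = []
    for node in range(embedding.k):
        rec = {"node": node}
        for name, values in variables.items():
            v = np.asarray(values, dtype=float)
            obs = ~np.isnan(v)
            if obs.sum() < 3 or np.std(E[obs, node]) == 0:
                rec[f"{name}_r"] = 0.0
                rec[f"{name}_neg_log10_p"] = 0.0
                continue
            r, p = _pearson_columns(E[obs, node : node + 1], v[obs])
            rec[f"{name}_r"] = float(r[0])
            rec[f"{name}_neg_log10_p"] = float(
                -np.log10(max(p[0], np.finfo(float).tiny))
            )
        rows.append(rec)
    annotation = pd.DataFrame(rows).set_index("node")

    if gene_rankings_per_node is not None and gene_sets is not None:
        from .interactions import fisher_overlap

        universe = list(gene_rankings_per_node.index)
        for name, members in gene_sets.items():
            ps = []
            for node in range(embedding.k):
                col = gene_rankings_per_node[f"node{node}"]
                query = list(col.nlargest(top_n_genes).index)
                res = fisher_overlap(query, members, universe)
                ps.append(res["p_value"])
            _, q, _, _ = multipletests(ps, method="fdr_bh")
            annotation[f"set_{name}_neg_log10_q"] = -np.log10(
                np.maximum(q, np.finfo(float).tiny)
            )
    embedding.annotation = annotation
    return embedding


def match_medoids(embedding_a: ConsensusEmbedding, embedding_b: ConsensusEmbedding):
    """For each medoid of A, the maximum |correlation| with any medoid of B
    (used to assess consensus reproducibility between disjoint run pools)."""
    A = embedding_a.medoid_nodes
    B = embedding_b.medoid_nodes
    Ac = A - A.mean(axis=1, keepdims=True)
    Bc = B - B.mean(axis=1, keepdims=True)
    Ac /= np.linalg.norm(Ac, axis=1, keepdims=True)
    Bc /= np.linalg.norm(Bc, axis=1, keepdims=True)
    C = np.abs(Ac @ Bc.T)
    return C.max(axis=1)
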