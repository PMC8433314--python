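"""Reproducible end-to-end pipelines tying the stages together.

``pipeline_full`` sequences: simulate -> preprocess -> evaluate -> train
(N runs) -> attribute -> consensus -> interactions, writing each stage's
artifacts under an output directory together with a JSON manifest (config
snapshot, seeds, input checksums, per-stage timings).  Re-running with an
identical config resumes: stages whose outputs already exist are skipped;
a config that no longer matches the manifest is refused.

All stage randomness derives from the single config seed, so two runs with
identical config produce byte-identical text artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as npio
from .datatypes import PHENOTYPES, ExpressionMatrix
from ._nn import MaskedMLP
from .attribution import (
    AttributionConfig,
    aggregate_weighted,
    attribute_dataset,
    consensus_gene_ranking,
    correlation_ranking,
    per_sample_consensus,
    weights_from_quantiles,
)
from .consensus import annotate_nodes, cluster_nodes, pool_nodes
from .evaluation import group_compare, neuropathology_score, per_task_errors
from .interactions import interaction_scan, shuffled_null
from .models import MultiTaskNeuralRegressor
from .preprocess import PCATransform, apply_pca, fit_pca, harmonize_batches, minmax_normalize, moment_match
from .simulate import SimulationConfig, generate

logger = logging.getLogger(__name__)

FILES = {
    "expr": "expression.tsv",
    "pheno": "phenotypes.tsv",
    "covars": "covariates.tsv",
    "truth": "truth.h5",
    "processed": "processed.h5",
    "evaluation": "evaluation.tsv",
    "models": "models.h5",
    "ranking": "gene_ranking.tsv",
    "corr_ranking": "correlation_ranking.tsv",
    "importance": "importance.h5",
    "embedding": "consensus.h5",
    "annotation": "node_annotation.tsv",
    "scan": "interaction_scan.tsv",
    "null_counts": "interaction_null.tsv",
    "manifest": "manifest.json",
}

DEFAULT_CONFIG = {
    "seed": 0,
    "simulation": {},
    "preprocess": {"pca_components": 100, "log_first": False},
    "model": {
        "shared_widths": [64, 32],
        "branch_widths": [16],
        "epochs": 30,
        "learning_rate": 1e-3,
        "l2": 1e-5,
        "clip_norm": 0.1,
        "dropout": 0.1,
        "batch_size": 20,
    },
    "n_runs": 10,
    "evaluation": {"n_rounds": 5},
    "attribution": {"steps": 32},
    "consensus": {"k": 20},
    "interactions": {"alpha": 0.05, "n_shuffles": 0},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()


def _file_checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _model_params(config: dict) -> dict:
    p = dict(config["model"])
    p["shared_widths"] = tuple(p["shared_widths"])
    p["branch_widths"] = tuple(p["branch_widths"])
    return p


class PipelineRun:
    """Stateful handle on a pipeline output directory."""

    def __init__(self, config: dict | None, out_dir, resume: bool = True):
        self.out = Path(out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.config = _merge(DEFAULT_CONFIG, config or {})
        self.manifest_path = self.out / FILES["manifest"]
        chash = _config_hash(self.config)
        if self.manifest_path.exists():
            manifest = json.loads(self.manifest_path.read_text())
            if resume and manifest.get("config_hash") not in (None, chash):
                raise ValueError(
                    "refusing to resume: output directory was produced by a "
                    "different configuration"
                )
            self.manifest = manifest
        else:
            self.manifest = {
                "config": self.config,
                "config_hash": chash,
                "stages": {},
                "checksums": {},
            }
        self.manifest["config_hash"] = chash
        self.resume = resume

    def path(self, key: str) -> Path:
        return self.out / FILES[key]

    def _done(self, keys) -> bool:
        return self.resume and all(self.path(k).exists() for k in keys)

    def _record(self, stage: str, keys, t0: float) -> None:
        self.manifest["stages"][stage] = {
            "seconds": round(time.time() - t0, 3),
            "outputs": [FILES[k] for k in keys],
        }
        for k in keys:
            self.manifest["checksums"][FILES[k]] = _file_checksum(self.path(k))
        self.manifest_path.write_text(json.dumps(self.manifest, indent=2, sort_keys=True))

    # --- stages --------------------------------------------------------------
    def stage_simulate(self):
        keys = ("expr", "pheno", "covars", "truth")
        if self._done(keys):
            return
        t0 = time.time()
        sim_cfg = dict(self.config["simulation"])
        sim_cfg.setdefault("seed", self.config["seed"])
        cfg = SimulationConfig(**sim_cfg)
        expr, pheno, covs, truth = generate(cfg)
        npio.write_expression(expr, self.path("expr"))
        npio.write_phenotypes(pheno, self.path("pheno"))
        npio.write_covariates(covs, self.path("covars"))
        npio.save_array_container(
            self.path("truth"),
            {
                "latent_severity": truth.latent_severity,
                "signal_gene_ids": truth.signal_gene_ids,
                "interaction_gene_ids": truth.interaction_gene_ids,
                "sex_marker_gene_ids": truth.sex_marker_gene_ids,
                "male_coupling": truth.male_coupling,
                "female_coupling": truth.female_coupling,
                "batch_offsets": truth.batch_offsets,
                "batch_scales": truth.batch_scales,
            },
        )
        self._record("simulate", keys, t0)

    def _load_inputs(self):
        expr = npio.read_expression(self.path("expr"))
        pheno = npio.read_phenotypes(self.path("pheno"))
        covs = npio.read_covariates(self.path("covars"))
        return expr, pheno, covs

    def stage_preprocess(self):
        keys = ("processed",)
        if self._done(keys):
            return
        t0 = time.time()
        expr, pheno, covs = self._load_inputs()
        pcfg = self.config["preprocess"]
        norm, _ = minmax_normalize(expr, log_first=pcfg["log_first"])
        harm = harmonize_batches(norm, norm.cohort)
        pca = fit_pca(harm.values, k=pcfg["pca_components"])
        X_pc = apply_pca(pca, harm.values)
        npio.save_array_container(
            self.path("processed"),
            {
                "X_norm": harm.values,
                "X_pc": X_pc,
                "gene_ids": harm.gene_ids,
                "sample_ids": harm.sample_ids,
                "pca": {
                    "component_loadings": pca.component_loadings,
                    "gene_means": pca.gene_means,
                    "explained_variance": pca.explained_variance,
                },
            },
        )
        self._record("preprocess", keys, t0)

    def _load_processed(self):
        arrays, _ = npio.load_array_container(self.path("processed"))
        pca = PCATransform(
            component_loadings=arrays["pca"]["component_loadings"],
            gene_means=arrays["pca"]["gene_means"],
            explained_variance=arrays["pca"]["explained_variance"],
        )
        return arrays["X_norm"], arrays["X_pc"], arrays["gene_ids"], pca

    def stage_evaluate(self):
        keys = ("evaluation",)
        if self._done(keys):
            return
        t0 = time.time()
        from sklearn.model_selection import KFold

        _, X_pc, _, _ = self._load_processed()
        pheno = npio.read_phenotypes(self.path("pheno"))
        Y = pheno.masked_array()
        n_rounds = self.config["evaluation"]["n_rounds"]
        kf = KFold(n_splits=n_rounds, shuffle=True, random_state=self.config["seed"])
        rows = []
        for rnd, (tr, te) in enumerate(kf.split(X_pc)):
            est = MultiTaskNeuralRegressor(
                **_model_params(self.config), random_state=self.config["seed"] + rnd
            )
            est.fit(X_pc[tr], Y[tr])
            errs = per_task_errors(Y[te], est.predict(X_pc[te]))
            for t, e in enumerate(errs):
                rows.append(
                    {"round": rnd, "task": PHENOTYPES[t], "one_minus_r2cv": e}
                )
        pd.DataFrame(rows).to_csv(self.path("evaluation"), sep="\t", index=False)
        self._record("evaluate", keys, t0)

    def stage_train(self):
        keys = ("models",)
        if self._done(keys):
            return
        t0 = time.time()
        _, X_pc, _, _ = self._load_processed()
        pheno = npio.read_phenotypes(self.path("pheno"))
        Y = pheno.masked_array()
        runs = {}
        for r in range(self.config["n_runs"]):
            est = MultiTaskNeuralRegressor(
                **_model_params(self.config), random_state=self.config["seed"] * 1000 + r
            )
            est.fit(X_pc, Y)
            runs[f"run{r}"] = est.net_.get_weights()
        npio.save_array_container(
            self.path("models"),
            runs,
            attrs={
                "n_runs": self.config["n_runs"],
                "input_dim": X_pc.shape[1],
                "shared_widths": json.dumps(list(self.config["model"]["shared_widths"])),
                "branch_widths": json.dumps(list(self.config["model"]["branch_widths"])),
                "dropout": self.config["model"]["dropout"],
            },
        )
        self._record("train", keys, t0)

    def load_models(self) -> list[MaskedMLP]:
        arrays, attrs = npio.load_array_container(self.path("models"))
        nets = []
        for r in range(int(attrs["n_runs"])):
            net = MaskedMLP(
                input_dim=int(attrs["input_dim"]),
                shared_widths=tuple(json.loads(attrs["shared_widths"])),
                branch_widths=tuple(json.loads(attrs["branch_widths"])),
                n_tasks=len(PHENOTYPES),
                dropout=float(attrs["dropout"]),
            )
            net.set_weights(arrays[f"run{r}"])
            nets.append(net)
        return nets

    def _severity_weights(self, pheno):
        """High/low pathology weights from the tercile split of per-sample
        mean observed phenotype severity (synthetic phenotypes are
        continuous, so staged cut-offs do not apply)."""
        Y = pheno.masked_array()
        severity = np.nanmean(Y, axis=1)
        return weights_from_quantiles(severity)

    def stage_attribute(self):
        keys = ("ranking", "corr_ranking", "importance")
        if self._done(keys):
            return
        t0 = time.time()
        X_norm, _, gene_ids, pca = self._load_processed()
        pheno = npio.read_phenotypes(self.path("pheno"))
        nets = self.load_models()
        cfg = AttributionConfig(steps=self.config["attribution"]["steps"])
        weights = self._severity_weights(pheno)
        per_run, tensors = [], []
        for net in nets:
            tensor = attribute_dataset(net, X_norm, config=cfg, pca=pca)
            per_run.append(aggregate_weighted(tensor, weights))
            tensors.append(tensor)
        ranking = consensus_gene_ranking(per_run, gene_ids, phenotype_names=PHENOTYPES)
        ranking.to_csv(self.path("ranking"), sep="\t", float_format="%.10g")
        corr = correlation_ranking(
            X_norm, pheno.masked_array(), gene_ids, phenotype_names=PHENOTYPES
        )
        corr.to_csv(self.path("corr_ranking"), sep="\t", float_format="%.10g")
        importance = per_sample_consensus(tensors)
        npio.save_array_container(
            self.path("importance"),
            {"importance": importance, "gene_ids": gene_ids,
             "sample_ids": pheno.sample_ids},
        )
        self._record("attribute", keys, t0)

    def stage_consensus(self):
        keys = ("embedding", "annotation")
        if self._done(keys):
            return
        t0 = time.time()
        _, X_pc, _, _ = self._load_processed()
        pheno = npio.read_phenotypes(self.path("pheno"))
        covs = npio.read_covariates(self.path("covars"))
        nets = self.load_models()
        pooled, sources = pool_nodes(nets, X_pc)
        embedding = cluster_nodes(
            pooled, sources, k=self.config["consensus"]["k"], seed=self.config["seed"]
        )
        Y = pheno.masked_array()
        variables = {name: Y[:, i] for i, name in enumerate(PHENOTYPES)}
        variables.update(
            {"dementia": covs.dementia, "age": covs.age, "sex": covs.sex,
             "pmi": covs.pmi, "rin": covs.rin}
        )
        embedding = annotate_nodes(embedding, variables)
        npio.save_array_container(
            self.path("embedding"),
            {
                "medoid_nodes": embedding.medoid_nodes,
                "cluster_assignment": embedding.cluster_assignment,
                "medoid_sources": np.asarray(embedding.medoid_sources),
                "sample_ids": pheno.sample_ids,
            },
        )
        embedding.annotation.to_csv(self.path("annotation"), sep="\t", float_format="%.10g")
        self._record("consensus", keys, t0)

    def stage_interactions(self):
        keys = ("scan",) + (("null_counts",) if self.config["interactions"]["n_shuffles"] else ())
        if self._done(keys):
            return
        t0 = time.time()
        X_norm, _, gene_ids, _ = self._load_processed()
        covs = npio.read_covariates(self.path("covars"))
        arrays, _ = npio.load_array_container(self.path("importance"))
        scan = interaction_scan(
            arrays["importance"], X_norm, covs.sex, gene_ids=gene_ids,
            alpha=self.config["interactions"]["alpha"],
        )
        scan.to_csv(self.path("scan"), sep="\t", float_format="%.10g")
        n_sh = self.config["interactions"]["n_shuffles"]
        if n_sh:
            counts, _ = shuffled_null(
                arrays["importance"], X_norm, covs.sex, n_shuffles=n_sh,
                seed=self.config["seed"],
                alpha=self.config["interactions"]["alpha"],
            )
            pd.DataFrame({"shuffle": range(n_sh), "significant": counts}).to_csv(
                self.path("null_counts"), sep="\t", index=False
            )
        self._record("interactions", keys, t0)

    def run_all(self):
        self.stage_simulate()
        self.stage_preprocess()
        self.stage_evaluate()
        self.stage_train()
        self.stage_attribute()
        self.stage_consensus()
        self.stage_interactions()
        return {k: self.path(k) for k in FILES}


def pipeline_full(config: dict | None, out_dir, resume: bool = True) -> dict:
    """Run every stage; returns the artifact paths."""
    return PipelineRun(config, out_dir, resume=resume).run_all()


def transfer_predict(
    nets,
    pca: PCATransform,
    ref_mean: np.ndarray,
    ref_sd: np.ndarray,
    train_gene_ids,
    external: ExpressionMatrix,
    group_labels,
    gene_mapping: dict | None = None,
    age=None,
    age_bins=(75.0, 85.0),
    min_overlap: float = 0.3,
    retrain=None,
    retrain_overlap: float = 0.5,
):
    """Apply trained networks to an external expression cohort.

    External gene identifiers are optionally mapped to training identifiers,
    the matrix is restricted to the overlapping genes and per-gene moment
    matched to the training population; missing training genes are imputed
    at the reference mean (neutral after PCA centering).  When the overlap
    fraction falls below ``retrain_overlap`` and a ``retrain`` callable is
    supplied, models are retrained on the intersected gene space instead.
    Returns (neuropathology scores, group-comparison table).
    """
    train_gene_ids = np.asarray(train_gene_ids, dtype=object)
    if gene_mapping is not None:
        resolved = [gene_mapping.get(g) for g in external.gene_ids]
        keep = [i for i, g in enumerate(resolved) if g is not None]
        if not keep:
            raise ValueError("gene mapping resolves zero external genes")
        external = external.subset_genes(external.gene_ids[keep])
        external.gene_ids = np.asarray([resolved[i] for i in keep], dtype=object)
    train_index = {g: i for i, g in enumerate(train_gene_ids)}
    shared = [g for g in external.gene_ids if g in train_index]
    overlap = len(shared) / len(train_gene_ids)
    if overlap < min_overlap:
        raise ValueError(
            f"gene overlap {overlap:.1%} below the hard floor {min_overlap:.0%}"
        )
    external = external.subset_genes(shared)
    cols = np.asarray([train_index[g] for g in shared])
    matched = moment_match(external, np.asarray(ref_mean)[cols], np.asarray(ref_sd)[cols])
    if overlap < retrain_overlap and retrain is not None:
        nets, pca = retrain(shared)
    X = np.tile(np.asarray(ref_mean, dtype=float), (external.n_samples, 1))
    X[:, cols] = matched.values
    X_pc = pca.apply(X)
    preds = np.mean([net.predict(X_pc) for net in nets], axis=0)
    scores = neuropathology_score(preds, np.asarray(["external"] * len(preds)))
    rows = []
    t, p = group_compare(scores, group_labels)
    rows.append({"stratum": "all", "t": t, "p": p})
    if age is not None:
        age = np.asarray(age, dtype=float)
        edges = [-np.inf, *age_bins, np.inf]
        for lo, hi in zip(edges[:-1], edges[1:]):
            sel = (age >= lo) & (age < hi)
            labels = np.asarray(group_labels)[sel]
            if len(np.unique(labels)) == 2 and min(
                (labels == u).sum() for u in np.unique(labels)
            ) >= 2:
                t, p = group_compare(scores[sel], labels)
                rows.append({"stratum": f"[{lo}, {hi})", "t": t, "p": p})
    return scores, pd.DataFrame(rows)
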