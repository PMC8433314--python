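"""Synthetic multi-cohort expression and neuropathology generator.

The generator emulates the statistical structure the multi-task model
assumes: a per-individual latent disease severity ``z`` of which all six
phenotype columns are independent noisy monotone measurements; a block of
signal genes linear in ``z``; a block of genes whose coupling to ``z``
differs by sex; a few sex-marker genes with a strong additive mean shift by
sex (emulating X/Y-linked transcripts, which make sex inferable from
expression alone); per-cohort batch offset/scale effects; and per-cohort
phenotype label-availability patterns with additional random missingness.

Everything is a deterministic function of ``(config, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import (
    N_PHENOTYPES,
    CovariateTable,
    ExpressionMatrix,
    PhenotypeTable,
)

#: Default per-cohort label availability, loosely mirroring a three-cohort
#: consortium where only one cohort measures everything and tangle counts
#: are the most sparsely available column overall.
DEFAULT_LABEL_PATTERNS = (
    (True, True, True, True, True, True),
    (True, False, True, True, False, True),
    (False, True, True, False, False, True),
)


@dataclass
class SimulationConfig:
    n_cohorts: int = 3
    samples_per_cohort: int = 200
    n_genes: int = 2000
    n_signal_genes: int = 50
    n_sex_interacting_genes: int = 20
    n_sex_marker_genes: int = 10
    latent_noise_sd: float = 0.0
    phenotype_noise_sds: tuple = (0.10, 0.15, 0.20, 0.25, 0.30, 0.35)
    label_patterns: tuple | None = None  # per-cohort boolean 6-vectors
    batch_offset_sd: float = 0.3
    batch_scale_sd: float = 0.1
    missing_fraction_within_observed: float = 0.1
    per_phenotype_missing: tuple | None = None  # extra i.i.d. masking per column
    effect_size: float = 0.8
    interaction_size: float = 0.6
    sex_marker_effect: float = 2.0
    interaction_mode: str = "sign"  # "sign": +/-1 by sex; "on_off": 1/0
    link: str = "logistic"  # phenotype link of z; "identity" available
    link_scale: float = 1.0
    regions_per_individual: int = 1
    region_noise_corr: float = 0.7
    seed: int = 0

    def __post_init__(self):
        if min(self.n_cohorts, self.samples_per_cohort, self.n_genes) <= 0:
            raise ValueError("counts must be positive")
        n_special = (
            self.n_signal_genes + self.n_sex_interacting_genes + self.n_sex_marker_genes
        )
        if n_special > self.n_genes:
            raise ValueError("special gene blocks exceed n_genes")
        if len(self.phenotype_noise_sds) != N_PHENOTYPES:
            raise ValueError(f"need {N_PHENOTYPES} phenotype noise SDs")
        if not 0 <= self.missing_fraction_within_observed < 1:
            raise ValueError("missing fraction must be in [0, 1)")
        if self.per_phenotype_missing is not None and (
            len(self.per_phenotype_missing) != N_PHENOTYPES
            or not all(0 <= f < 1 for f in self.per_phenotype_missing)
        ):
            raise ValueError("per_phenotype_missing must be 6 rates in [0, 1)")
        if self.label_patterns is not None:
            pats = np.asarray(self.label_patterns, dtype=bool)
            if pats.shape != (self.n_cohorts, N_PHENOTYPES):
                raise ValueError("label_patterns must be n_cohorts x 6")
            if not pats.any(axis=0).all():
                raise ValueError("every phenotype must be observed in >=1 cohort")

    def resolved_label_patterns(self) -> np.ndarray:
        if self.label_patterns is not None:
            return np.asarray(self.label_patterns, dtype=bool)
        pats = [
            DEFAULT_LABEL_PATTERNS[c % len(DEFAULT_LABEL_PATTERNS)]
            for c in range(self.n_cohorts)
        ]
        pats = np.asarray(pats, dtype=bool)
        pats[0] = True  # guarantee every phenotype observed somewhere
        return pats


@dataclass
class SimulationTruth:
    """Ground truth stored alongside generated data for recovery tests."""

    latent_severity: np.ndarray  # per sample (individual value repeated per region)
    signal_gene_ids: np.ndarray
    interaction_gene_ids: np.ndarray
    sex_marker_gene_ids: np.ndarray
    male_coupling: np.ndarray  # per interaction gene
    female_coupling: np.ndarray
    batch_offsets: np.ndarray  # cohorts x genes
    batch_scales: np.ndarray  # cohorts x genes

    def is_interacting(self, gene_ids) -> np.ndarray:
        s = set(self.interaction_gene_ids.tolist())
        return np.asarray([g in s for g in gene_ids], dtype=bool)

    def is_signal(self, gene_ids) -> np.ndarray:
        s = set(self.signal_gene_ids.tolist())
        return np.asarray([g in s for g in gene_ids], dtype=bool)


def _link(z: np.ndarray, kind: str, scale: float) -> np.ndarray:
    if kind == "logistic":
        return 1.0 / (1.0 + np.exp(-scale * z))
    if kind == "identity":
        return z
    raise ValueError(f"unknown link {kind!r}")


def make_label_mask(
    patterns: np.ndarray, cohort_index: np.ndarray, extra_missing: float, rng
) -> np.ndarray:
    """Per-sample observed mask: phenotype columns absent in a cohort are
    fully masked; observed columns are further masked i.i.d. at rate
    ``extra_missing``."""
    patterns = np.asarray(patterns, dtype=bool)
    mask = patterns[cohort_index]
    if extra_missing > 0:
        mask = mask & (rng.random(mask.shape) >= extra_missing)
    return mask


def generate(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, PhenotypeTable, CovariateTable, SimulationTruth]:
    rng = np.random.default_rng(config.seed)
    n_reg = config.regions_per_individual
    n_ind_per_cohort = config.samples_per_cohort
    n_ind = config.n_cohorts * n_ind_per_cohort
    n_samples = n_ind * n_reg
    G = config.n_genes

    individual_ids = np.array([f"I{i:05d}" for i in range(n_ind)], dtype=object)
    cohort_of_ind = np.repeat(np.arange(config.n_cohorts), n_ind_per_cohort)

    z_ind = rng.standard_normal(n_ind)
    sex_ind = (rng.random(n_ind) < 0.5).astype(float)  # 1 = male

    # expand individuals to samples (one per region)
    ind_idx = np.repeat(np.arange(n_ind), n_reg)
    region = np.tile(np.arange(n_reg), n_ind)
    sample_ids = np.array(
        [f"S{i:05d}R{r}" for i, r in zip(ind_idx, region)], dtype=object
    )
    z = z_ind[ind_idx]
    sex = sex_ind[ind_idx]
    cohort_idx = cohort_of_ind[ind_idx]
    cohort = np.array([f"cohort{c}" for c in cohort_idx], dtype=object)

    # --- gene blocks ---
    n_sig = config.n_signal_genes
    n_int = config.n_sex_interacting_genes
    n_mark = config.n_sex_marker_genes
    gene_ids = np.array([f"G{j:05d}" for j in range(G)], dtype=object)

    coupling = np.zeros((n_samples, G))
    coupling[:, :n_sig] = config.effect_size
    if config.interaction_mode == "sign":
        s_male, s_female = 1.0, -1.0
    elif config.interaction_mode == "on_off":
        s_male, s_female = 1.0, 0.0
    else:
        raise ValueError(f"unknown interaction_mode {config.interaction_mode!r}")
    male_c = config.effect_size + s_male * config.interaction_size
    female_c = config.effect_size + s_female * config.interaction_size
    int_cols = slice(n_sig, n_sig + n_int)
    coupling[:, int_cols] = np.where(sex[:, None] == 1.0, male_c, female_c)

    mean = coupling * z[:, None]
    mark_cols = slice(n_sig + n_int, n_sig + n_int + n_mark)
    mean[:, mark_cols] += config.sex_marker_effect * (sex[:, None] - 0.5)

    # unit expression noise, correlated across regions of an individual
    if n_reg > 1:
        rho = config.region_noise_corr
        shared = rng.standard_normal((n_ind, G))[ind_idx]
        own = rng.standard_normal((n_samples, G))
        noise = np.sqrt(rho) * shared + np.sqrt(1 - rho) * own
    else:
        noise = rng.standard_normal((n_samples, G))
    X = mean + noise

    # per-cohort batch offset and scale per gene
    offsets = rng.normal(0.0, config.batch_offset_sd, size=(config.n_cohorts, G))
    scales = np.exp(rng.normal(0.0, config.batch_scale_sd, size=(config.n_cohorts, G)))
    X = X * scales[cohort_idx] + offsets[cohort_idx]

    # --- phenotypes: six noisy monotone measurements of z ---
    z_obs = z + (
        rng.standard_normal(n_samples) * config.latent_noise_sd
        if config.latent_noise_sd > 0
        else 0.0
    )
    raw = np.empty((n_samples, N_PHENOTYPES))
    for p, sd in enumerate(config.phenotype_noise_sds):
        eps = rng.standard_normal(n_samples) * sd if sd > 0 else 0.0
        raw[:, p] = _link(z_obs + eps, config.link, config.link_scale)

    patterns = config.resolved_label_patterns()
    mask = make_label_mask(
        patterns, cohort_idx, config.missing_fraction_within_observed, rng
    )
    if config.per_phenotype_missing is not None:
        rates = np.asarray(config.per_phenotype_missing, dtype=float)
        mask = mask & (rng.random(mask.shape) >= rates[None, :])
    # per-cohort 0-1 scaling over observed entries
    values = np.zeros_like(raw)
    for c in range(config.n_cohorts):
        rows = cohort_idx == c
        for p in range(N_PHENOTYPES):
            obs = mask[rows, p]
            if not obs.any():
                continue
            v = raw[rows, p]
            lo, hi = v[obs].min(), v[obs].max()
            col = np.zeros_like(v)
            if hi > lo:
                col = np.clip((v - lo) / (hi - lo), 0.0, 1.0)
            values[rows, p] = col

    expr = ExpressionMatrix(
        values=X,
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        cohort=cohort,
        region=np.array([f"region{r}" for r in region], dtype=object),
        normalized=False,
    )
    pheno = PhenotypeTable(values=values, mask=mask, sample_ids=sample_ids)

    age = np.clip(rng.normal(85.0, 6.0, size=n_ind), 65.0, 105.0)[ind_idx]
    dementia_prob = 1.0 / (1.0 + np.exp(-1.5 * z_ind))
    dementia = (rng.random(n_ind) < dementia_prob).astype(float)[ind_idx]
    pmi = np.clip(rng.normal(6.0, 2.0, size=n_samples), 1.0, None)
    rin = np.clip(rng.normal(7.0, 1.0, size=n_samples), 4.0, 10.0)
    apoe4 = (rng.random(n_ind) < 0.25).astype(float)[ind_idx]
    covs = CovariateTable(
        sample_ids=sample_ids,
        individual_id=individual_ids[ind_idx],
        sex=sex,
        age=age,
        dementia=dementia,
        pmi=pmi,
        rin=rin,
        apoe4=apoe4,
    )

    truth = SimulationTruth(
        latent_severity=z,
        signal_gene_ids=gene_ids[:n_sig],
        interaction_gene_ids=gene_ids[int_cols],
        sex_marker_gene_ids=gene_ids[mark_cols],
        male_coupling=np.full(n_int, male_c),
        female_coupling=np.full(n_int, female_c),
        batch_offsets=offsets,
        batch_scales=scales,
    )
    return expr, pheno, covs, truth
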