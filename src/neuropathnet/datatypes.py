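"""Core data containers shared across the package.

All containers are thin, validated wrappers around numpy arrays plus
identifier metadata.  Samples are rows everywhere; gene identifiers and
sample identifiers must be unique and aligned between containers that are
consumed together.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Canonical ordering of the six neuropathology phenotype columns:
#: three plaque-related (amyloid-beta IHC density, neuritic plaque counts,
#: CERAD score) and three tangle-related (phospho-tau IHC density, tangle
#: counts, Braak stage).
PHENOTYPES = ("abeta_ihc", "plaques", "cerad", "tau_ihc", "tangles", "braak")
N_PHENOTYPES = len(PHENOTYPES)


def _check_unique(ids, what: str) -> np.ndarray:
    ids = np.asarray(ids, dtype=object)
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicated {what} identifiers")
    return ids


@dataclass
class ExpressionMatrix:
    """Samples x genes expression values with per-sample cohort/region labels.

    ``normalized`` flags whether per-gene 0-1 scaling has been applied; it
    guards against accidentally applying an affine per-gene transform twice.
    """

    values: np.ndarray
    gene_ids: np.ndarray
    sample_ids: np.ndarray
    cohort: np.ndarray
    region: np.ndarray = None
    normalized: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be 2-D (samples x genes)")
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        n, g = self.values.shape
        if len(self.gene_ids) != g:
            raise ValueError("gene_ids length does not match value columns")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match value rows")
        self.cohort = np.asarray(self.cohort, dtype=object)
        if len(self.cohort) != n:
            raise ValueError("cohort labels must align with samples")
        if self.region is None:
            self.region = np.asarray(["NA"] * n, dtype=object)
        else:
            self.region = np.asarray(self.region, dtype=object)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        cols = [idx[g] for g in gene_ids]
        return replace(
            self,
            values=self.values[:, cols],
            gene_ids=np.asarray(list(gene_ids), dtype=object),
        )

    def subset_samples(self, row_idx) -> "ExpressionMatrix":
        row_idx = np.asarray(row_idx)
        return replace(
            self,
            values=self.values[row_idx],
            sample_ids=self.sample_ids[row_idx],
            cohort=self.cohort[row_idx],
            region=self.region[row_idx],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)


@dataclass
class PhenotypeTable:
    """Samples x 6 phenotype values in [0, 1] with an explicit observed mask.

    Masked-out cells hold NaN and must never be read by a consumer; the mask
    is the single source of truth for label availability.
    """

    values: np.ndarray
    mask: np.ndarray
    sample_ids: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if self.values.shape[1] != N_PHENOTYPES:
            raise ValueError(f"expected {N_PHENOTYPES} phenotype columns")
        if len(self.sample_ids) != self.values.shape[0]:
            raise ValueError("sample_ids length does not match rows")
        # sentinel for unobserved cells
        self.values = np.where(self.mask, self.values, np.nan)
        obs = self.values[self.mask]
        if obs.size and (np.nanmin(obs) < -1e-9 or np.nanmax(obs) > 1 + 1e-9):
            raise ValueError("observed phenotype values must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def masked_array(self) -> np.ndarray:
        """Values with NaN at unobserved cells (a copy)."""
        return np.where(self.mask, self.values, np.nan)

    def subset_samples(self, row_idx) -> "PhenotypeTable":
        row_idx = np.asarray(row_idx)
        return PhenotypeTable(
            values=np.where(self.mask, self.values, 0.0)[row_idx],
            mask=self.mask[row_idx],
            sample_ids=self.sample_ids[row_idx],
        )


@dataclass
class CovariateTable:
    """Per-sample covariates: individual id, sex (1 = male), age, dementia
    status, postmortem interval (hours), RNA integrity number, APOE e4."""

    sample_ids: np.ndarray
    individual_id: np.ndarray
    sex: np.ndarray
    age: np.ndarray = None
    dementia: np.ndarray = None
    pmi: np.ndarray = None
    rin: np.ndarray = None
    apoe4: np.ndarray = None

    def __post_init__(self):
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        n = len(self.sample_ids)
        self.individual_id = np.asarray(self.individual_id, dtype=object)
        self.sex = np.asarray(self.sex, dtype=float)
        if len(self.individual_id) != n or len(self.sex) != n:
            raise ValueError("covariate columns must align with sample_ids")
        for name in ("age", "dementia", "pmi", "rin", "apoe4"):
            v = getattr(self, name)
            if v is None:
                v = np.full(n, np.nan)
            else:
                v = np.asarray(v, dtype=float)
                if len(v) != n:
                    raise ValueError(f"covariate {name!r} must align with sample_ids")
            setattr(self, name, v)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "individual_id": self.individual_id,
                "sex": self.sex,
                "age": self.age,
                "dementia": self.dementia,
                "pmi": self.pmi,
                "rin": self.rin,
                "apoe4": self.apoe4,
            },
            index=self.sample_ids,
        )

    def subset_samples(self, row_idx) -> "CovariateTable":
        row_idx = np.asarray(row_idx)
        return CovariateTable(
            sample_ids=self.sample_ids[row_idx],
            individual_id=self.individual_id[row_idx],
            sex=self.sex[row_idx],
            age=self.age[row_idx],
            dementia=self.dementia[row_idx],
            pmi=self.pmi[row_idx],
            rin=self.rin[row_idx],
            apoe4=self.apoe4[row_idx],
        )


@dataclass
class GeneSetCollection:
    """Named gene sets with GMT semantics (name, description, members)."""

    sets: dict = field(default_factory=dict)
    descriptions: dict = field(default_factory=dict)

    def __post_init__(self):
        for name, members in self.sets.items():
            members = list(members)
            if len(set(members)) != len(members):
                raise ValueError(f"duplicate members in gene set {name!r}")
            self.sets[name] = members

    def __len__(self):
        return len(self.sets)

    def __getitem__(self, name):
        return self.sets[name]

    def items(self):
        return self.sets.items()


def check_aligned(*tables) -> None:
    """Assert identical sample_id ordering across containers; fail loudly."""
    ref = tables[0].sample_ids
    for t in tables[1:]:
        if len(t.sample_ids) != len(ref) or not np.array_equal(t.sample_ids, ref):
            raise ValueError(
                "sample identifiers are not aligned between "
                f"{type(tables[0]).__name__} and {type(t).__name__}"
            )
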