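"""Readers and writers for the package's on-disk formats.

Delimited text (TSV by default) for expression matrices and sample tables,
GMT for gene sets, and an HDF5 container for attribution tensors,
embeddings and trained-model weights.  write -> read round-trips reproduce
values to 1e-12 and metadata exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import h5py

from .datatypes import (
    PHENOTYPES,
    CovariateTable,
    ExpressionMatrix,
    GeneSetCollection,
    PhenotypeTable,
)

_META_COLS = ("cohort", "region")


def write_expression(expr: ExpressionMatrix, path, sep: str = "\t") -> None:
    df = expr.to_frame()
    df.insert(0, "cohort", expr.cohort)
    df.insert(1, "region", expr.region)
    df.index.name = "sample_id"
    df.to_csv(path, sep=sep, float_format="%.17g")


def read_expression(path, sep: str = "\t", transpose: bool = False,
                    normalized: bool = False) -> ExpressionMatrix:
    """Read a delimited expression matrix (samples as rows canonically;
    ``transpose=True`` accepts genes-as-rows input without metadata columns)."""
    df = pd.read_csv(path, sep=sep, index_col=0)
    if transpose:
        df = df.T
    cohort = df.pop("cohort").to_numpy() if "cohort" in df.columns else ["NA"] * len(df)
    region = df.pop("region").to_numpy() if "region" in df.columns else None
    return ExpressionMatrix(
        values=df.to_numpy(dtype=float),
        gene_ids=df.columns.to_numpy(dtype=object),
        sample_ids=df.index.to_numpy(dtype=object),
        cohort=cohort,
        region=region,
        normalized=normalized,
    )


def write_phenotypes(pheno: PhenotypeTable, path, sep: str = "\t") -> None:
    df = pd.DataFrame(pheno.masked_array(), index=pheno.sample_ids, columns=PHENOTYPES)
    df.index.name = "sample_id"
    df.to_csv(path, sep=sep, float_format="%.17g")


def read_phenotypes(path, sep: str = "\t") -> PhenotypeTable:
    df = pd.read_csv(path, sep=sep, index_col=0)
    values = df[list(PHENOTYPES)].to_numpy(dtype=float)
    mask = ~np.isnan(values)
    return PhenotypeTable(
        values=np.where(mask, values, 0.0),
        mask=mask,
        sample_ids=df.index.to_numpy(dtype=object),
    )


def write_covariates(covs: CovariateTable, path, sep: str = "\t") -> None:
    df = covs.to_frame()
    df.index.name = "sample_id"
    df.to_csv(path, sep=sep, float_format="%.17g")


def read_covariates(path, sep: str = "\t") -> CovariateTable:
    df = pd.read_csv(path, sep=sep, index_col=0)
    return CovariateTable(
        sample_ids=df.index.to_numpy(dtype=object),
        individual_id=df["individual_id"].to_numpy(dtype=object),
        sex=df["sex"].to_numpy(dtype=float),
        age=df["age"].to_numpy(dtype=float),
        dementia=df["dementia"].to_numpy(dtype=float),
        pmi=df["pmi"].to_numpy(dtype=float),
        rin=df["rin"].to_numpy(dtype=float),
        apoe4=df["apoe4"].to_numpy(dtype=float),
    )


def read_gmt(path) -> GeneSetCollection:
    sets, descriptions = {}, {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(
                    f"malformed GMT line {lineno}: expected >=2 tab-separated fields"
                )
            name, desc, *members = fields
            members = [m for m in members if m]
            sets[name] = members
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


def save_array_container(path, arrays: dict, attrs: dict | None = None) -> None:
    """Write named arrays (attribution tensors, embeddings, weights) to HDF5.

    Nested dict values become HDF5 groups; string arrays are stored as
    variable-length UTF-8.
    """
    with h5py.File(path, "w") as f:
        _write_group(f, arrays)
        for k, v in (attrs or {}).items():
            f.attrs[k] = v


def _write_group(group, arrays: dict) -> None:
    for name, value in arrays.items():
        if isinstance(value, dict):
            _write_group(group.create_group(name), value)
        else:
            arr = np.asarray(value)
            if arr.dtype == object or arr.dtype.kind in "US":
                dt = h5py.string_dtype(encoding="utf-8")
                group.create_dataset(name, data=arr.astype(str).astype(object), dtype=dt)
            else:
                group.create_dataset(name, data=arr)


def load_array_container(path) -> tuple[dict, dict]:
    with h5py.File(path, "r") as f:
        arrays = _read_group(f)
        attrs = dict(f.attrs)
    return arrays, attrs


def _read_group(group) -> dict:
    out = {}
    for name, item in group.items():
        if isinstance(item, h5py.Group):
            out[name] = _read_group(item)
        else:
            arr = item[()]
            if item.dtype.kind == "O" or h5py.check_string_dtype(item.dtype):
                arr = np.asarray(arr).astype(str).astype(object)
            out[name] = arr
    return out
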