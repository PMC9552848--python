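"""Readers and writers for the on-disk formats used by the pipeline.

Supported formats: plain TSV expression matrices, GCT v1.2, GMT gene-set
files, tab-separated MAF mutation tables, survival TSV, and label TSV.
All files are UTF-8 text with LF line endings.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (CohortLabels, ExpressionMatrix, GeneSetCollection,
                         MutationTable, SurvivalTable)

#: genes missing in more than this fraction of samples are dropped at load time
MAX_MISSING_FRACTION = 0.2


def _collapse_duplicate_genes(df: pd.DataFrame) -> pd.DataFrame:
    """Collapse duplicated gene ids keeping the max-variance row per id."""
    if not df.index.duplicated().any():
        return df
    variances = df.var(axis=1, ddof=1).fillna(0.0)
    order = np.argsort(-variances.to_numpy(), kind="stable")
    best = df.iloc[order]
    best = best[~best.index.duplicated(keep="first")]
    return best.loc[df.index.unique()]


def _impute_missing(df: pd.DataFrame, batch: pd.Series | None) -> pd.DataFrame:
    """Per-gene median imputation within batch; drop genes >20% missing."""
    missing_frac = df.isna().mean(axis=1)
    dropped = missing_frac[missing_frac > MAX_MISSING_FRACTION]
    if len(dropped):
        warnings.warn(f"dropping {len(dropped)} genes missing in "
                      f">{MAX_MISSING_FRACTION:.0%} of samples")
        df = df.loc[missing_frac <= MAX_MISSING_FRACTION]
    if not df.isna().any().any():
        return df
    if batch is None:
        med = df.median(axis=1)
        return df.apply(lambda col: col.fillna(med))
    out = df.copy()
    for b in batch.unique():
        cols = batch.index[batch == b]
        block = out[cols]
        med = block.median(axis=1)
        out[cols] = block.apply(lambda col: col.fillna(med))
    # a gene entirely missing within one batch falls back to the global median
    if out.isna().any().any():
        med = out.median(axis=1)
        out = out.apply(lambda col: col.fillna(med))
    return out


def read_expression(path: str | Path, format: str = "tsv",
                    batch: pd.Series | None = None) -> ExpressionMatrix:
    """Read a genes x samples expression matrix from TSV or GCT v1.2.

    Duplicate gene ids are collapsed to the max-variance row; missing values
    are median-imputed (within batch when batch labels are given) and genes
    missing in >20% of samples are dropped.
    """
    path = Path(path)
    if format == "tsv":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")[1:]
        if len(set(header)) != len(header):
            raise ValueError("duplicate sample id in header")
        df = pd.read_csv(path, sep="\t", index_col=0)
    elif format == "gct":
        with open(path) as fh:
            version = fh.readline().strip()
            if not version.startswith("#1.2"):
                raise ValueError(f"unsupported GCT version line {version!r}")
            dims = fh.readline().split()
            if len(dims) != 2:
                raise ValueError("malformed GCT dimensions line")
            n_genes, n_samples = int(dims[0]), int(dims[1])
            df = pd.read_csv(fh, sep="\t", index_col=0)
        df = df.drop(columns=["Description"], errors="ignore")
        if df.shape != (n_genes, n_samples):
            raise ValueError(f"GCT dims line says {n_genes}x{n_samples} "
                             f"but data block is {df.shape[0]}x{df.shape[1]}")
    else:
        raise ValueError(f"unknown expression format {format!r}")
    if df.columns.duplicated().any():
        raise ValueError("duplicate sample id in header")
    non_numeric = df.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    introduced = non_numeric.isna() & df.notna()
    if introduced.any().any():
        gene = introduced.any(axis=1).idxmax()
        raise ValueError(f"non-numeric expression value at gene {gene!r}")
    df = non_numeric
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns.name = None
    df = _collapse_duplicate_genes(df)
    df = _impute_missing(df, batch)
    return ExpressionMatrix(df, batch=batch)


def write_expression(X: ExpressionMatrix, path: str | Path,
                     format: str = "tsv") -> None:
    path = Path(path)
    if format == "tsv":
        X.values.to_csv(path, sep="\t", index_label="gene_id", lineterminator="\n")
    elif format == "gct":
        with open(path, "w", newline="\n") as fh:
            fh.write("#1.2\n")
            fh.write(f"{X.n_genes}\t{X.n_samples}\n")
            out = X.values.copy()
            out.insert(0, "Description", "na")
            out.to_csv(fh, sep="\t", index_label="NAME", lineterminator="\n")
    else:
        raise ValueError(f"unknown expression format {format!r}")


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one set per line (name, description, members...)."""
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            members = [f for f in fields[2:] if f]
            if len(fields) < 3 or not members:
                raise ValueError(f"GMT line {lineno}: fewer than 3 fields "
                                 "or no members")
            name = fields[0]
            if name in sets:
                raise ValueError(f"GMT line {lineno}: duplicate set name {name!r}")
            sets[name] = set(members)
            descriptions[name] = fields[1]
    return GeneSetCollection(sets, descriptions)


def write_gene_sets(sets: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        for name in sets.names:
            desc = sets.descriptions.get(name, "na")
            members = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")


MAF_COLUMNS = {"Hugo_Symbol": "gene",
               "Tumor_Sample_Barcode": "sample_id",
               "Variant_Classification": "variant_classification"}


def read_maf(path: str | Path) -> MutationTable:
    """Read a tab-separated MAF; silent variants are retained but flagged."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = set(MAF_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"MAF missing mandatory columns: {sorted(missing)}")
    out = df.rename(columns=MAF_COLUMNS)
    if "Variant_Type" in out.columns:
        out = out.rename(columns={"Variant_Type": "variant_type"})
    else:
        out["variant_type"] = "SNP"
    out = out[["sample_id", "gene", "variant_classification", "variant_type"]]
    return MutationTable(out.reset_index(drop=True))


def write_maf(maf: MutationTable, path: str | Path) -> None:
    inv = {v: k for k, v in MAF_COLUMNS.items()}
    out = maf.records.rename(columns={**inv, "variant_type": "Variant_Type"})
    cols = ["Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification",
            "Variant_Type"]
    out[cols].to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_survival(path: str | Path) -> SurvivalTable:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    return SurvivalTable(df)


def write_survival(surv: SurvivalTable, path: str | Path) -> None:
    surv.data.to_csv(path, sep="\t", index_label="sample_id", lineterminator="\n")


def read_labels(path: str | Path) -> CohortLabels:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    stage = df["stage"].iloc[0] if "stage" in df.columns else "predicted"
    return CohortLabels(df["subtype"], stage_tag=stage)


def write_labels(labels: CohortLabels, path: str | Path) -> None:
    labels.to_frame().to_csv(path, sep="\t", lineterminator="\n")
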