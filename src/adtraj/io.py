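"""Readers and writers for the delimited text formats the pipeline consumes."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd


class ParseError(ValueError):
    pass


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a gene x sample integer count matrix (TSV, gene ids in column 1).

    Rejects duplicate gene ids and non-integer cells, naming the offending
    location.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ParseError(f"duplicate gene ids in {path}: {dups[:5]}")
    for col in df.columns:
        vals = df[col]
        if not np.issubdtype(vals.dtype, np.number):
            bad = vals[pd.to_numeric(vals, errors="coerce").isna()].index[:1].tolist()
            raise ParseError(f"non-numeric count at gene {bad}, sample {col!r} in {path}")
        if np.any(vals != np.floor(vals)):
            gene = vals.index[vals != np.floor(vals)][0]
            raise ParseError(f"non-integer count at gene {gene!r}, sample {col!r} in {path}")
        if np.any(vals < 0):
            gene = vals.index[vals < 0][0]
            raise ParseError(f"negative count at gene {gene!r}, sample {col!r} in {path}")
    return df.astype(np.int64)


def write_counts(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read the phenotype table (CSV with a subject_id column)."""
    df = pd.read_csv(path)
    if "subject_id" not in df.columns:
        raise ParseError(f"phenotype table {path} lacks a subject_id column")
    if df.subject_id.duplicated().any():
        raise ParseError(f"duplicate subject ids in {path}")
    return df


def read_madrs(path: str | Path) -> pd.DataFrame:
    """Read the subjects x weeks MADRS panel (CSV, subject_id index)."""
    df = pd.read_csv(path, index_col=0)
    expected = [f"week_{w}" for w in (0, 2, 4, 6, 8)]
    if list(df.columns) != expected:
        raise ParseError(f"MADRS table must have columns {expected}, got {list(df.columns)}")
    return df


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Read a qPCR Ct table (CSV: condition, replicate, gene, ct)."""
    df = pd.read_csv(path)
    required = {"condition", "replicate", "gene", "ct"}
    if not required <= set(df.columns):
        raise ParseError(f"Ct table {path} needs columns {sorted(required)}")
    return df
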