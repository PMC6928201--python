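"""Tabular I/O: TSV matrices and tables, GMT gene sets, result writers.

The canonical dialect everywhere is tab-separated UTF-8 text with ``.`` as
the decimal mark. Matrices carry gene ids in the first column and sample ids
in the header row.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    DetectionMatrix,
    ExpressionMatrix,
    GeneSetCollection,
    ProteinTable,
    SampleTable,
)
from .exceptions import FormatError, SchemaError

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_detection_tsv",
    "write_detection_tsv",
    "read_sample_table",
    "write_sample_table",
    "read_protein_table",
    "write_protein_table",
    "read_gmt",
    "write_gmt",
    "read_annotation",
    "read_atlas",
    "write_results_table",
    "read_results_table",
]


def _read_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    # pinpoint non-numeric cells before the container rejects the matrix
    for j, col in enumerate(df.columns):
        coerced = pd.to_numeric(df[col], errors="coerce")
        original_na = df[col].isna()
        bad = coerced.isna() & ~original_na
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise FormatError(
                f"{path}: non-numeric value at gene {row!r}, sample {col!r}"
            )
        df[col] = coerced
    return df


def read_expression_tsv(path) -> ExpressionMatrix:
    """Read a log2 gene x sample matrix (header = sample ids, column 1 = gene ids)."""
    return ExpressionMatrix(_read_matrix(path))


def write_expression_tsv(matrix: ExpressionMatrix, path) -> None:
    matrix.data.to_csv(path, sep="\t", float_format="%.6g", index_label="gene_id")


def read_detection_tsv(path) -> DetectionMatrix:
    """Read a detection p-value matrix on the same layout as the expression TSV."""
    return DetectionMatrix(_read_matrix(path))


def write_detection_tsv(matrix: DetectionMatrix, path) -> None:
    matrix.data.to_csv(path, sep="\t", float_format="%.6g", index_label="gene_id")


def read_sample_table(path) -> SampleTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "subject_id": str, "batch": str})
    if "labor_at_draw" in df.columns:
        df["labor_at_draw"] = df["labor_at_draw"].map(
            {True: True, False: False, "True": True, "False": False, 1: True, 0: False,
             "1": True, "0": False}
        )
        if df["labor_at_draw"].isna().any():
            raise FormatError(f"{path}: labor_at_draw must be boolean")
    return SampleTable(df)


def write_sample_table(table: SampleTable, path) -> None:
    table.data.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_protein_table(path) -> ProteinTable:
    df = pd.read_csv(
        path, sep="\t",
        dtype={"protein_id": str, "gene_id": str, "sample_id": str, "subject_id": str},
    )
    return ProteinTable(df)


def write_protein_table(table: ProteinTable, path) -> None:
    table.data.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_gmt(path, collection_name: str | None = None) -> GeneSetCollection:
    """Read gene sets in GMT dialect: ``name<TAB>description<TAB>member...``.

    Member order is preserved; duplicate members within a line are collapsed
    with a warning. A line with fewer than three fields is a format error.
    """
    path = Path(path)
    sets: dict = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, desc, *members = fields
            members = [m for m in members if m]
            if len(set(members)) != len(members):
                warnings.warn(f"{path}:{lineno}: duplicate members collapsed in {name!r}")
                members = list(dict.fromkeys(members))
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = (desc, members)
    return GeneSetCollection(collection_name or path.stem, sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, (desc, members) in collection.sets.items():
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_annotation(path) -> pd.DataFrame:
    """Gene annotation table with at least ``gene_id`` and ``chromosome`` columns."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("gene_id", "chromosome"):
        if col not in df.columns:
            raise FormatError(f"{path}: annotation missing column {col!r}")
    if df["gene_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate gene ids in annotation")
    return df


def read_atlas(path) -> pd.DataFrame:
    """Tissue atlas: genes x tissues, linear-scale nonnegative values."""
    df = _read_matrix(path)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: atlas needs at least 2 tissues")
    if (df.to_numpy() < 0).any():
        raise FormatError(f"{path}: atlas values must be nonnegative")
    return df


def write_results_table(table: pd.DataFrame, path, sort: bool = True) -> None:
    """Write a result table as TSV with a deterministic layout.

    Column order is preserved, floats are rendered at 6 significant digits,
    and rows are ordered by ``q`` (ascending) then ``gene_id``/``set_name``
    when those columns exist, so identical analyses yield identical bytes.
    """
    if not isinstance(table, pd.DataFrame):
        raise SchemaError("result table must be a DataFrame")
    out = table.copy()
    if sort:
        keys = [c for c in ("q", "gene_id", "set_name", "protein_id", "signature") if c in out.columns]
        if keys:
            out = out.sort_values(keys, kind="mergesort")
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_results_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
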