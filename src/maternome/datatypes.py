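"""Validated domain containers for the longitudinal transcriptome pipeline.

All containers are thin wrappers around :class:`pandas.DataFrame` that
enforce the invariants the analysis relies on (unique axes, finite values,
gestational ages in a plausible range, ...). Readers construct them; analysis
functions accept and return them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import FormatError

__all__ = [
    "ExpressionMatrix",
    "SampleTable",
    "DetectionMatrix",
    "GeneSetCollection",
    "ProteinTable",
]


def _check_unique(labels, what: str) -> None:
    idx = pd.Index(labels)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()[:5]
        raise FormatError(f"duplicate {what}: {dups}")


@dataclass(frozen=True)
class ExpressionMatrix:
    """log2-scale gene x sample expression matrix.

    ``data`` has gene ids on the index and sample ids on the columns; every
    value must be finite. This is the pipeline's central object.
    """

    data: pd.DataFrame

    def __post_init__(self):
        _check_unique(self.data.index, "gene ids")
        _check_unique(self.data.columns, "sample ids")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise FormatError("expression values must be numeric")
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise FormatError(
                f"non-finite expression value at gene "
                f"{self.data.index[bad[0]]!r}, sample {self.data.columns[bad[1]]!r}"
            )

    @property
    def gene_ids(self) -> list:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def select_genes(self, gene_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(gene_ids)])

    def select_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[:, list(sample_ids)])


_SAMPLE_COLUMNS = ["sample_id", "subject_id", "ga_weeks", "batch", "labor_at_draw"]


@dataclass(frozen=True)
class SampleTable:
    """Per-sample metadata: subject, gestational age (weeks), batch, labor flag."""

    data: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in _SAMPLE_COLUMNS if c not in self.data.columns]
        if missing:
            raise FormatError(f"sample table missing columns: {missing}")
        _check_unique(self.data["sample_id"], "sample ids")
        ga = self.data["ga_weeks"].to_numpy(dtype=float)
        if not np.isfinite(ga).all():
            raise FormatError("non-finite gestational age")
        if ((ga <= 4) | (ga >= 45)).any():
            bad = self.data["sample_id"][(ga <= 4) | (ga >= 45)].tolist()[:5]
            raise FormatError(f"gestational age outside (4, 45) weeks for samples {bad}")
        pairs = self.data[["subject_id", "ga_weeks"]]
        if pairs.duplicated().any():
            raise FormatError("duplicate (subject_id, ga_weeks) pair")

    @property
    def sample_ids(self) -> list:
        return list(self.data["sample_id"])

    @property
    def subject_ids(self) -> list:
        return list(self.data["subject_id"].unique())

    def aligned_to(self, sample_ids) -> "SampleTable":
        """Rows reordered to ``sample_ids``; raises if any id is unknown."""
        indexed = self.data.set_index("sample_id")
        missing = [s for s in sample_ids if s not in indexed.index]
        if missing:
            raise FormatError(f"samples absent from sample table: {missing[:5]}")
        return SampleTable(indexed.loc[list(sample_ids)].reset_index())

    def drop_samples(self, sample_ids) -> "SampleTable":
        drop = set(sample_ids)
        return SampleTable(self.data[~self.data["sample_id"].isin(drop)].reset_index(drop=True))

    def column(self, name: str, sample_ids=None) -> np.ndarray:
        tab = self if sample_ids is None else self.aligned_to(sample_ids)
        return tab.data[name].to_numpy()


@dataclass(frozen=True)
class DetectionMatrix:
    """Detection-above-background p-values on the same axes as an ExpressionMatrix."""

    data: pd.DataFrame

    def __post_init__(self):
        _check_unique(self.data.index, "gene ids")
        _check_unique(self.data.columns, "sample ids")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number) or not np.isfinite(values).all():
            raise FormatError("detection p-values must be finite numbers")
        if ((values < 0) | (values > 1)).any():
            raise FormatError("detection p-values must lie in [0, 1]")

    def validate_against(self, expr: ExpressionMatrix) -> None:
        if list(self.data.index) != expr.gene_ids or list(self.data.columns) != expr.sample_ids:
            raise FormatError("detection matrix axes differ from expression matrix axes")

    def select_samples(self, sample_ids) -> "DetectionMatrix":
        return DetectionMatrix(self.data.loc[:, list(sample_ids)])


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets (GMT semantics): set name -> (description, members)."""

    collection_name: str
    sets: dict = field(default_factory=dict)

    def __post_init__(self):
        for name, (_desc, members) in self.sets.items():
            if len(members) == 0:
                raise FormatError(f"gene set {name!r} is empty")
            if len(set(members)) != len(members):
                raise FormatError(f"gene set {name!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.sets)

    def set_names(self) -> list:
        return list(self.sets)

    def members(self, name: str) -> list:
        return list(self.sets[name][1])

    @staticmethod
    def from_dict(name: str, mapping: dict) -> "GeneSetCollection":
        """Build from ``{set_name: iterable of genes}`` with empty descriptions."""
        sets = {}
        for set_name, genes in mapping.items():
            genes = list(genes)
            if len(set(genes)) != len(genes):
                warnings.warn(f"duplicate members collapsed in set {set_name!r}")
                genes = list(dict.fromkeys(genes))
            sets[set_name] = ("", genes)
        return GeneSetCollection(name, sets)


_PROTEIN_COLUMNS = ["protein_id", "gene_id", "sample_id", "subject_id", "abundance"]


@dataclass(frozen=True)
class ProteinTable:
    """Long-format log2 protein abundances with protein->gene and sample->subject maps."""

    data: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in _PROTEIN_COLUMNS if c not in self.data.columns]
        if missing:
            raise FormatError(f"protein table missing columns: {missing}")
        if self.data[["protein_id", "sample_id"]].duplicated().any():
            raise FormatError("duplicate (protein_id, sample_id) pair")
        ab = self.data["abundance"].to_numpy(dtype=float)
        if not np.isfinite(ab).all():
            raise FormatError("non-finite protein abundance")

    @property
    def protein_ids(self) -> list:
        return list(self.data["protein_id"].unique())

    @property
    def subject_ids(self) -> list:
        return list(self.data["subject_id"].unique())

    def validate_subjects(self, meta: SampleTable) -> None:
        extra = set(self.subject_ids) - set(meta.data["subject_id"])
        if extra:
            raise FormatError(f"protein subjects absent from sample table: {sorted(extra)[:5]}")
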