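"""Sample and gene filtering, batch correction, outlier detection.

Fixed stage order, each recorded in the report:

1. batch correction (per-gene OLS with sum-to-zero batch indicators plus the
   cubic gestational-age basis, so the longitudinal signal is preserved by
   construction; only the fitted batch component is subtracted),
2. removal of samples drawn at the time of labor,
3. removal of gross outlier samples (minimum-attainment rule),
4. detection filter: keep genes called present (p_DBAG < 0.05) in strictly
   more than 25% of the remaining samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import DetectionMatrix, ExpressionMatrix, SampleTable
from .de import make_ga_basis
from .exceptions import AnalysisError

__all__ = [
    "PreprocessReport",
    "call_present",
    "remove_labor_samples",
    "correct_batch",
    "detect_outlier_samples",
    "preprocess",
]

logger = logging.getLogger(__name__)


@dataclass
class PreprocessReport:
    genes_in: int = 0
    genes_retained: int = 0
    samples_removed_labor: list = field(default_factory=list)
    outlier_samples: list = field(default_factory=list)
    batch_terms_removed: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [("genes_in", self.genes_in), ("genes_retained", self.genes_retained),
                ("samples_removed_labor", ";".join(self.samples_removed_labor)),
                ("outlier_samples", ";".join(self.outlier_samples))]
        for batch, offset in sorted(self.batch_terms_removed.items()):
            rows.append((f"batch_offset_{batch}", f"{offset:.6g}"))
        return pd.DataFrame(rows, columns=["field", "value"])


def call_present(expr: ExpressionMatrix, det: DetectionMatrix,
                 p_thresh: float = 0.05, frac: float = 0.25,
                 probe_map: dict | None = None) -> list:
    """Genes detected (p_DBAG < p_thresh) in strictly more than ``frac`` of samples.

    ``probe_map`` optionally maps a gene id to several matrix rows (probe
    sets); the gene is then present in a sample when any of its rows is.
    """
    det.validate_against(expr)
    p = det.data.to_numpy()
    present = p < p_thresh
    if probe_map is None:
        frac_present = present.mean(axis=1)
        retained = [g for g, f in zip(expr.gene_ids, frac_present) if f > frac]
    else:
        row_of = {g: i for i, g in enumerate(expr.gene_ids)}
        retained = []
        for gene, rows in probe_map.items():
            idx = [row_of[r] for r in rows]
            if present[idx].any(axis=0).mean() > frac:
                retained.append(gene)
    return retained


def remove_labor_samples(expr: ExpressionMatrix, meta: SampleTable):
    """Drop samples collected at the time of labor from both objects."""
    meta = meta.aligned_to(expr.sample_ids)
    flagged = [s for s, f in zip(meta.sample_ids, meta.column("labor_at_draw")) if f]
    if not flagged:
        return expr, meta, []
    keep = [s for s in expr.sample_ids if s not in set(flagged)]
    expr2 = expr.select_samples(keep)
    meta2 = meta.aligned_to(keep)
    lost = set(meta.data["subject_id"]) - set(meta2.data["subject_id"])
    if lost:
        logger.warning("subjects lost all samples during labor removal: %s", sorted(lost))
    return expr2, meta2, flagged


def correct_batch(expr: ExpressionMatrix, meta: SampleTable):
    """Remove additive batch offsets while preserving gestational-age variation.

    Per gene, ordinary least squares of log2 expression on [intercept,
    sum-to-zero batch indicators, cubic GA basis]; only the fitted batch
    component is subtracted. With a single batch this is the identity.
    Returns (corrected matrix, per-batch estimated offsets in log2 units).
    """
    meta = meta.aligned_to(expr.sample_ids)
    batches = sorted(set(meta.column("batch")))
    if len(batches) < 2:
        return expr, {batches[0]: 0.0} if batches else {}
    counts = pd.Series(meta.column("batch")).value_counts()
    small = [b for b in batches if counts[b] < 2]
    if small:
        raise AnalysisError(f"batches with fewer than 2 samples: {small}")

    n = expr.n_samples
    # sum-to-zero coding: one column per batch except the last, which carries -1
    codes = np.array([batches.index(b) for b in meta.column("batch")])
    B = np.zeros((n, len(batches) - 1))
    for k in range(len(batches) - 1):
        B[codes == k, k] = 1.0
    B[codes == len(batches) - 1, :] = -1.0

    ga_cols = make_ga_basis(meta.column("ga_weeks")).columns
    D = np.column_stack([np.ones(n), B, ga_cols])
    rank = np.linalg.matrix_rank(D)
    if rank < D.shape[1]:
        raise AnalysisError(
            "singular batch-correction design: a batch is confounded with the "
            f"gestational-age basis (batches: {batches})")

    coef, *_ = np.linalg.lstsq(D, expr.values.T, rcond=None)
    batch_coef = coef[1:len(batches), :]          # (n_batches-1, n_genes)
    fitted_batch = B @ batch_coef                 # (n_samples, n_genes)
    corrected = ExpressionMatrix(pd.DataFrame(
        expr.values - fitted_batch.T, index=expr.gene_ids, columns=expr.sample_ids))

    mean_coef = batch_coef.mean(axis=1)
    offsets = {b: float(mean_coef[k]) for k, b in enumerate(batches[:-1])}
    offsets[batches[-1]] = float(-mean_coef.sum())
    return corrected, offsets


def detect_outlier_samples(expr: ExpressionMatrix, multiplier: float = 10.0) -> list:
    """Flag samples that carry a row minimum far more often than chance.

    For each sample, f = fraction of genes whose row minimum is attained at
    that sample (exact ties split equally); samples with
    f > multiplier / n_samples are flagged. Under exchangeable noise f is
    about 1/n_samples, so the default multiplier 10 only catches samples that
    are consistently and grossly low.
    """
    if expr.n_samples < 3:
        raise AnalysisError("outlier detection needs at least 3 samples")
    values = expr.values
    row_min = values.min(axis=1, keepdims=True)
    at_min = values == row_min
    weights = at_min / at_min.sum(axis=1, keepdims=True)
    f = weights.mean(axis=0)
    cutoff = multiplier / expr.n_samples
    return [s for s, fi in zip(expr.sample_ids, f) if fi > cutoff]


def preprocess(expr: ExpressionMatrix, det: DetectionMatrix, meta: SampleTable,
               p_thresh: float = 0.05, frac: float = 0.25,
               outlier_multiplier: float = 10.0):
    """Full preprocessing chain; returns (expr, meta, report)."""
    det.validate_against(expr)
    report = PreprocessReport(genes_in=expr.n_genes)

    expr, report.batch_terms_removed = correct_batch(expr, meta)
    expr, meta, report.samples_removed_labor = remove_labor_samples(expr, meta)
    report.outlier_samples = detect_outlier_samples(expr, multiplier=outlier_multiplier)
    if report.outlier_samples:
        keep = [s for s in expr.sample_ids if s not in set(report.outlier_samples)]
        expr = expr.select_samples(keep)
        meta = meta.aligned_to(keep)

    det = det.select_samples(expr.sample_ids)
    retained = call_present(expr, det, p_thresh=p_thresh, frac=frac)
    report.genes_retained = len(retained)
    expr = expr.select_genes(retained)
    return expr, meta, report
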