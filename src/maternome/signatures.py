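"""Cell-type signature meta-genes and their gestational-age trends.

Expression is first standardized gene-wise against term samples (draws at
> 37 weeks): z = (x - mean_term) / sd_term. A cell type's meta-gene score in
a sample is the unweighted mean of the standardized values of the
signature's member genes; the score series is then fit with the same
random-intercept cubic gestational-age model used for single genes and
tested by the 3-df likelihood ratio.

The "fc_equivalent" column applies the single-gene fold-change formula
2^(max - min) to the fitted meta-gene curve; because the curve is on the
z-score scale this is a descriptive index, not a true expression ratio —
output headers carry that caveat.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .datatypes import ExpressionMatrix, GeneSetCollection, SampleTable
from .de import GRID_WEEKS, fit_gene_lmm, fitted_curve, fold_change, lrt_gene, make_ga_basis
from .exceptions import AnalysisError

__all__ = [
    "standardize_by_term",
    "metagene_score",
    "MetaGeneSeries",
    "test_metagene",
    "run_signatures",
]

logger = logging.getLogger(__name__)


def standardize_by_term(expr: ExpressionMatrix, meta: SampleTable,
                        term_cutoff: float = 37.0) -> ExpressionMatrix:
    """Per-gene z-scores against term samples (gestational age > term_cutoff).

    Uses the sample (n-1) standard deviation; genes constant across term
    samples are dropped with a logged list.
    """
    meta = meta.aligned_to(expr.sample_ids)
    term = meta.column("ga_weeks") > term_cutoff
    if term.sum() < 2:
        raise AnalysisError(
            f"need >= 2 term samples (> {term_cutoff} weeks), found {int(term.sum())}")
    values = expr.values
    mean_term = values[:, term].mean(axis=1, keepdims=True)
    sd_term = values[:, term].std(axis=1, ddof=1, keepdims=True)
    constant = sd_term[:, 0] == 0
    if constant.any():
        dropped = [g for g, c in zip(expr.gene_ids, constant) if c]
        logger.warning("dropping %d genes constant across term samples: %s",
                       len(dropped), dropped[:5])
    keep = ~constant
    z = (values[keep] - mean_term[keep]) / sd_term[keep]
    return ExpressionMatrix(pd.DataFrame(
        z, index=[g for g, k in zip(expr.gene_ids, keep) if k], columns=expr.sample_ids))


@dataclass(frozen=True)
class MetaGeneSeries:
    """Per-sample signature score: mean standardized expression of member genes."""

    signature_name: str
    scores: pd.Series           # indexed by sample id, z-score units
    n_genes_used: int
    genes_missing: list = field(default_factory=list)


def metagene_score(standardized: ExpressionMatrix, signature_name: str,
                   members) -> MetaGeneSeries:
    """Average the standardized rows of a signature's member genes per sample."""
    members = list(members)
    present = [g for g in members if g in standardized.data.index]
    missing = [g for g in members if g not in standardized.data.index]
    if not present:
        raise AnalysisError(f"signature {signature_name!r} has no genes in the matrix")
    scores = standardized.data.loc[present].mean(axis=0)
    return MetaGeneSeries(signature_name, scores, len(present), missing)


def test_metagene(series: MetaGeneSeries, meta: SampleTable):
    """Gestational-age trend test for one meta-gene score series.

    Returns (lrt_p, fitted curve on the 10-40 wk grid, fc_equivalent). The
    score is fit exactly like a single gene (random-intercept cubic model,
    3-df LRT); fc_equivalent = 2^(max - min) of the curve, on the z-score
    scale.
    """
    meta = meta.aligned_to(list(series.scores.index))
    basis = make_ga_basis(meta.column("ga_weeks"))
    subjects = meta.column("subject_id")
    y = series.scores.to_numpy(dtype=float)
    fit_full = fit_gene_lmm(y, basis, subjects, use_ga_terms=True)
    fit_null = fit_gene_lmm(y, basis, subjects, use_ga_terms=False)
    _stat, p = lrt_gene(fit_full, fit_null)
    curve = fitted_curve(fit_full, basis)
    fc_eq, _direction = fold_change(curve)
    return p, curve, fc_eq


def run_signatures(expr: ExpressionMatrix, meta: SampleTable,
                   signatures: GeneSetCollection, term_cutoff: float = 37.0):
    """Score and test every signature; returns (summary table, scores table).

    The summary holds p, BH q across signatures, fc_equivalent (z-score
    scale) and the ages of the fitted curve's extrema; the scores table holds
    the per-sample series of each signature.
    """
    standardized = standardize_by_term(expr, meta, term_cutoff=term_cutoff)
    rows, score_cols = [], {}
    for name in signatures.set_names():
        try:
            series = metagene_score(standardized, name, signatures.members(name))
        except AnalysisError:
            logger.warning("signature %s skipped: no member genes in matrix", name)
            continue
        p, curve, fc_eq = test_metagene(series, meta)
        rows.append((name, series.n_genes_used, len(series.genes_missing), p, fc_eq,
                     float(GRID_WEEKS[np.argmin(curve)]),
                     float(GRID_WEEKS[np.argmax(curve)])))
        score_cols[name] = series.scores
    summary = pd.DataFrame(rows, columns=[
        "signature", "n_genes_used", "n_genes_missing", "p",
        "fc_equivalent_zscale", "argmin_weeks", "argmax_weeks"])
    if not summary.empty:
        summary["q"] = multipletests(summary["p"], method="fdr_bh")[1]
        summary = summary.sort_values(["q", "signature"], kind="mergesort").reset_index(drop=True)
    else:
        summary["q"] = pd.Series(dtype=float)
    scores = pd.DataFrame(score_cols)
    scores.index.name = "sample_id"
    return summary, scores
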