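"""Repeated-measures mRNA-protein correlation.

Each protein is paired with its transcript and modeled as

    protein = alpha + beta * mrna + u_subject + eps,

a random-intercept model fit by ML over the samples shared by both layers.
The slope's t-score (beta / SE) and a 1-df likelihood-ratio p-value are
reported per pair, together with a naive Spearman correlation that ignores
the subject structure. BH FDR runs across all tested pairs, separately for
the LRT and Spearman p-values; a pair is "doubly significant" when both
q-values clear their thresholds. Whether coupling is stronger for
differentially expressed transcripts is tested by a two-sided Wilcoxon
rank-sum on the t-scores of DE vs non-DE pairs.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, spearmanr

from .datatypes import ExpressionMatrix, ProteinTable, SampleTable
from .exceptions import AnalysisError
from .lmm import RandomInterceptModel, lrt

__all__ = ["pair_lmm", "spearman_pair", "run_pairs", "compare_tscores"]

logger = logging.getLogger(__name__)


def pair_lmm(protein, mrna, subject_ids):
    """Slope, SE, t-score and LRT p for one protein ~ mRNA pair.

    Requires >= 3 subjects, >= 6 observations and non-constant mRNA.
    """
    protein = np.asarray(protein, dtype=float)
    mrna = np.asarray(mrna, dtype=float)
    if len(protein) < 6:
        raise AnalysisError("pair model needs at least 6 observations")
    if len(np.unique(subject_ids)) < 3:
        raise AnalysisError("pair model needs at least 3 subjects")
    if np.ptp(mrna) == 0:
        raise AnalysisError("constant mRNA vector")
    X = np.column_stack([np.ones(len(mrna)), mrna])
    fit_full = RandomInterceptModel(X, subject_ids).fit(protein)
    fit_null = RandomInterceptModel(np.ones((len(mrna), 1)), subject_ids).fit(protein)
    slope = float(fit_full.beta[1])
    se = float(fit_full.se_beta[1])
    t_score = slope / se if se > 0 else np.nan
    _stat, p = lrt(fit_full, fit_null, df=1)
    return slope, se, t_score, p


def spearman_pair(protein, mrna):
    """Rank correlation over all samples, ignoring subjects (>= 4 observations)."""
    protein = np.asarray(protein, dtype=float)
    mrna = np.asarray(mrna, dtype=float)
    if len(protein) < 4:
        raise AnalysisError("Spearman needs at least 4 observations")
    rho, p = spearmanr(mrna, protein)
    return float(rho), float(p)


def run_pairs(protein_table: ProteinTable, expr: ExpressionMatrix, meta: SampleTable,
              de_table: pd.DataFrame | None = None,
              q_lmm: float = 0.1, q_sp: float = 0.05) -> pd.DataFrame:
    """Fit every resolvable mRNA-protein pair on the shared samples.

    Pairs whose gene is absent from the matrix, whose shared samples are too
    few, or whose mRNA is constant are skipped with a logged reason. Returns
    a PairResult table with BH q-values across tested pairs (``q_lmm_value``
    for the LRT, ``q_spearman`` for Spearman) and the ``doubly_significant``
    call (q_lmm < 0.1 and q_spearman < 0.05 by default). ``de_table`` only
    adds the per-pair ``de_gene`` flag.
    """
    protein_table.validate_subjects(meta)
    long = protein_table.data
    shared = set(expr.sample_ids) & set(long["sample_id"])
    if not shared:
        raise AnalysisError("no samples shared between protein and mRNA layers")
    de_genes = set()
    if de_table is not None and not de_table.empty:
        de_genes = set(de_table.loc[de_table["significant"], "gene_id"])

    rows = []
    n_skipped = 0
    for (protein_id, gene_id), grp in long.groupby(["protein_id", "gene_id"], sort=True):
        grp = grp[grp["sample_id"].isin(shared)]
        if gene_id not in expr.data.index or len(grp) < 6:
            n_skipped += 1
            continue
        samples = grp["sample_id"].tolist()
        mrna = expr.data.loc[gene_id, samples].to_numpy(dtype=float)
        prot = grp["abundance"].to_numpy(dtype=float)
        subjects = grp["subject_id"].to_numpy()
        try:
            slope, se, t_score, lrt_p = pair_lmm(prot, mrna, subjects)
            rho, sp_p = spearman_pair(prot, mrna)
        except AnalysisError as exc:
            logger.info("pair %s/%s skipped: %s", protein_id, gene_id, exc)
            n_skipped += 1
            continue
        rows.append((gene_id, protein_id, slope, se, t_score, lrt_p, rho, sp_p,
                     len(samples), len(np.unique(subjects)), gene_id in de_genes))
    if n_skipped:
        logger.info("%d pairs skipped", n_skipped)
    table = pd.DataFrame(rows, columns=[
        "gene_id", "protein_id", "slope", "se_slope", "t_score", "lrt_p",
        "spearman_rho", "spearman_p", "n_samples", "n_subjects", "de_gene"])
    if table.empty:
        for col in ("q_lmm_value", "q_spearman"):
            table[col] = pd.Series(dtype=float)
        table["doubly_significant"] = pd.Series(dtype=bool)
        return table
    from statsmodels.stats.multitest import multipletests
    table["q_lmm_value"] = multipletests(table["lrt_p"], method="fdr_bh")[1]
    table["q_spearman"] = multipletests(table["spearman_p"], method="fdr_bh")[1]
    table["doubly_significant"] = (table["q_lmm_value"] < q_lmm) & (table["q_spearman"] < q_sp)
    return table.sort_values(["q_lmm_value", "gene_id", "protein_id"],
                             kind="mergesort").reset_index(drop=True)


def compare_tscores(pair_table: pd.DataFrame, de_gene_set) -> dict:
    """Two-sided Wilcoxon rank-sum on pair t-scores: DE transcripts vs the rest.

    Normal approximation with tie correction and no continuity correction,
    so identical groups give p = 1 exactly.
    """
    de_gene_set = set(de_gene_set)
    in_de = pair_table["gene_id"].isin(de_gene_set)
    t_de = pair_table.loc[in_de, "t_score"].dropna().to_numpy()
    t_other = pair_table.loc[~in_de, "t_score"].dropna().to_numpy()
    if len(t_de) == 0 or len(t_other) == 0:
        raise AnalysisError("both comparison groups must be nonempty")
    stat, p = mannwhitneyu(t_de, t_other, alternative="two-sided",
                           method="asymptotic", use_continuity=False)
    return {"n_de_pairs": int(len(t_de)), "n_other_pairs": int(len(t_other)),
            "wilcoxon_stat": float(stat), "p": float(p)}
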