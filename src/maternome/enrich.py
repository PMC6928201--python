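"""Over-representation analysis of gene lists.

Hypergeometric one-sided enrichment of a differentially expressed gene list
against gene-set collections (GMT), chromosome sets, and tissue-specific
sets derived from an expression atlas by the 30x-median rule. The background
is the compendium of genes called present; Benjamini-Hochberg FDR is applied
within each collection.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .datatypes import GeneSetCollection
from .exceptions import AnalysisError

__all__ = [
    "hypergeom_test",
    "odds_ratio",
    "enrich_collection",
    "derive_tissue_specific",
    "chromosome_sets",
]

logger = logging.getLogger(__name__)


def _check_table(a: int, K: int, n: int, N: int) -> None:
    if not (0 <= a <= min(K, n) and 0 <= K <= N and 0 <= n <= N):
        raise AnalysisError(f"inconsistent 2x2 table: a={a}, K={K}, n={n}, N={N}")


def hypergeom_test(a: int, K: int, n: int, N: int) -> float:
    """Over-representation tail P(X >= a), X ~ Hypergeometric(N, K, n).

    ``a`` hits among ``n`` drawn genes, ``K`` set members in a background of
    ``N``. a = 0 gives p = 1 (the full tail).
    """
    _check_table(a, K, n, N)
    return float(hypergeom.sf(a - 1, N, K, n))


def odds_ratio(a: int, K: int, n: int, N: int) -> float:
    """Cross-product ratio of the 2x2 membership table.

    Cells: (a, n-a, K-a, N-K-n+a). When any cell is zero all four get the
    Haldane-Anscombe +0.5 correction first, keeping the ratio finite.
    """
    _check_table(a, K, n, N)
    cells = np.array([a, n - a, K - a, N - K - n + a], dtype=float)
    if (cells == 0).any():
        cells = cells + 0.5
    return float(cells[0] * cells[3] / (cells[1] * cells[2]))


def enrich_collection(de_genes, background, collection: GeneSetCollection,
                      q_thresh: float = 0.05, min_size: int = 5) -> pd.DataFrame:
    """Hypergeometric enrichment of every set in a collection.

    Sets are intersected with the background first; sets smaller than
    ``min_size`` within the background are skipped. Rows: set_name, count,
    size, odds_ratio, p, q (BH within this collection), significant; sorted
    by q then set name.
    """
    background = set(background)
    de = set(de_genes)
    stray = de - background
    if stray:
        raise AnalysisError(f"DE genes missing from background: {sorted(stray)[:5]}")
    N, n = len(background), len(de)
    rows = []
    for name in collection.set_names():
        members = set(collection.members(name)) & background
        K = len(members)
        if K < min_size:
            continue
        a = len(members & de)
        rows.append((name, a, K, odds_ratio(a, K, n, N), hypergeom_test(a, K, n, N)))
    table = pd.DataFrame(rows, columns=["set_name", "count", "size", "odds_ratio", "p"])
    if table.empty:
        table["q"] = pd.Series(dtype=float)
        table["significant"] = pd.Series(dtype=bool)
        return table
    table["q"] = multipletests(table["p"], method="fdr_bh")[1]
    table["significant"] = table["q"] < q_thresh
    return table.sort_values(["q", "set_name"], kind="mergesort").reset_index(drop=True)


def derive_tissue_specific(atlas: pd.DataFrame, ratio: float = 30.0) -> GeneSetCollection:
    """Tissue-specific gene sets from a linear-scale atlas (genes x tissues).

    A gene is specific to tissue t when its expression in t (the median over
    t's columns when the tissue is replicated) is strictly greater than
    ``ratio`` times the median over all other tissues' values. A zero
    other-tissue median with positive expression counts as specific
    (infinite ratio) and is logged. With ratio > 1 a gene can satisfy the
    rule for at most one tissue; this is asserted.
    """
    if atlas.shape[1] < 2:
        raise AnalysisError("atlas needs at least 2 tissues")
    if (atlas.to_numpy() < 0).any():
        raise AnalysisError("atlas values must be nonnegative")
    tissues = list(dict.fromkeys(atlas.columns))
    # median per tissue (collapses replicated columns)
    per_tissue = pd.DataFrame(
        {t: atlas.loc[:, atlas.columns == t].median(axis=1) for t in tissues})
    col_idx = {t: [c == t for c in atlas.columns] for t in tissues}

    sets = {t: [] for t in tissues}
    values = atlas.to_numpy(dtype=float)
    for i, gene in enumerate(atlas.index):
        hits = []
        for t in tissues:
            others = values[i, ~np.array(col_idx[t])]
            med_others = float(np.median(others))
            v = float(per_tissue.at[gene, t])
            if med_others == 0.0:
                if v > 0.0:
                    logger.info("gene %s specific to %s with zero other-tissue median",
                                gene, t)
                    hits.append(t)
            elif v > ratio * med_others:
                hits.append(t)
        if ratio > 1 and len(hits) > 1:
            raise AssertionError(
                f"gene {gene} specific to multiple tissues {hits} at ratio {ratio}")
        for t in hits:
            sets[t].append(gene)
    nonempty = {t: ("tissue-specific genes", genes) for t, genes in sets.items() if genes}
    return GeneSetCollection("tissue_specific", nonempty)


def chromosome_sets(annotation: pd.DataFrame) -> GeneSetCollection:
    """One gene set per chromosome from a (gene_id, chromosome) table."""
    for col in ("gene_id", "chromosome"):
        if col not in annotation.columns:
            raise AnalysisError(f"annotation missing column {col!r}")
    if annotation["gene_id"].duplicated().any():
        raise AnalysisError("duplicate gene ids in annotation")
    sets = {
        str(chrom): ("chromosome gene set", group["gene_id"].tolist())
        for chrom, group in annotation.groupby("chromosome", sort=True)
    }
    return GeneSetCollection("chromosomes", sets)
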