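"""Shape clustering of fitted expression trajectories.

Strongly changing genes (q < 0.1 and FC > 1.5 by default) are represented by
their fitted population-average log2 curves on the 10-40 week grid,
re-baselined to 0 at 10 weeks, and grouped by agglomerative hierarchical
clustering (average linkage by default) on the 1 - Pearson correlation
distance. The result is deterministic regardless of input order: genes are
sorted lexicographically before the distance matrix is built, and cluster
labels are numbered by size (largest first, ties by smallest member id).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .exceptions import AnalysisError

__all__ = [
    "select_high_fc",
    "make_profiles",
    "pearson_distance",
    "cluster_profiles",
]


def select_high_fc(de_table: pd.DataFrame, q_thresh: float = 0.1,
                   fc_thresh: float = 1.5) -> list:
    """Genes with q < q_thresh and fc > fc_thresh (both strict)."""
    if de_table.empty:
        return []
    mask = (de_table["q"] < q_thresh) & (de_table["fc"] > fc_thresh)
    return de_table.loc[mask.fillna(False), "gene_id"].tolist()


def make_profiles(gene_ids, curves: dict) -> pd.DataFrame:
    """Profiles = fitted curves re-baselined to 0 at 10 weeks.

    ``curves`` maps gene id -> 301-point fitted log2 curve. Returns a genes x
    grid DataFrame whose first column is exactly 0 for every gene.
    """
    missing = [g for g in gene_ids if g not in curves]
    if missing:
        raise AnalysisError(f"no fitted curve for genes: {missing[:5]}")
    rows = {g: np.asarray(curves[g], dtype=float) - curves[g][0] for g in gene_ids}
    return pd.DataFrame.from_dict(rows, orient="index")


def pearson_distance(p1, p2) -> float:
    """1 - Pearson correlation of two profiles; in [0, 2]."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    s1, s2 = p1.std(), p2.std()
    if s1 == 0 or s2 == 0:
        raise AnalysisError("Pearson distance undefined for a zero-variance profile")
    r = float(np.corrcoef(p1, p2)[0, 1])
    return float(np.clip(1.0 - r, 0.0, 2.0))


def _distance_matrix(profiles: np.ndarray) -> np.ndarray:
    sd = profiles.std(axis=1)
    if (sd == 0).any():
        raise AnalysisError("zero-variance profile in distance matrix")
    corr = np.corrcoef(profiles)
    d = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(d, 0.0)
    return d


def cluster_profiles(profiles: pd.DataFrame, k: int = 3,
                     linkage_method: str = "average") -> pd.DataFrame:
    """Cut an average-linkage tree on 1 - Pearson distances into ``k`` groups.

    Zero-variance (flat) profiles are excluded with a warning — their
    correlation is undefined (they cannot occur for genes passing the
    fold-change filter). Returns a DataFrame (gene_id, cluster) with cluster
    labels 1..k ordered by cluster size, largest first.
    """
    if k < 1:
        raise AnalysisError("k must be >= 1")
    flat = profiles.index[profiles.std(axis=1).to_numpy() == 0].tolist()
    if flat:
        warnings.warn(f"excluding zero-variance profiles: {flat[:5]}")
        profiles = profiles.drop(index=flat)
    if k > len(profiles):
        raise AnalysisError(f"k={k} exceeds number of usable profiles ({len(profiles)})")

    # lexicographic order makes the result independent of input order
    profiles = profiles.sort_index(kind="mergesort")
    d = _distance_matrix(profiles.to_numpy())
    if len(profiles) == 1:
        labels = np.array([1])
    else:
        tree = linkage(squareform(d, checks=False), method=linkage_method)
        labels = fcluster(tree, t=k, criterion="maxclust")

    # relabel by (size desc, smallest member id) for a stable presentation
    out = pd.DataFrame({"gene_id": profiles.index, "cluster_raw": labels})
    order = (out.groupby("cluster_raw")["gene_id"]
                .agg(size="size", first="min")
                .sort_values(["size", "first"], ascending=[False, True]))
    relabel = {raw: i + 1 for i, raw in enumerate(order.index)}
    out["cluster"] = out["cluster_raw"].map(relabel)
    return out[["gene_id", "cluster"]].reset_index(drop=True)
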