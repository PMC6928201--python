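"""Longitudinal differential expression over gestation.

Each gene's log2 expression is modeled as a cubic polynomial of gestational
age with a per-subject random intercept:

    y_ij = beta0 + beta1 z + beta2 z^2 + beta3 z^3 + u_j + eps_ij,

where z = (t - 25) / 15 is gestational age centered at 25 weeks and scaled to
roughly [-1, 1] for conditioning. Association with gestational age is tested
by a likelihood ratio against the intercept-only model (chi-square, 3 df),
with Benjamini-Hochberg FDR across genes. The effect size is the fold change
2^(max - min) of the fitted population-average curve evaluated on a 0.1-week
grid from 10 to 40 weeks; a gene is called significant when q < 0.1 and
FC > 1.25 (both strict, both configurable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .datatypes import ExpressionMatrix, SampleTable
from .exceptions import AnalysisError
from .lmm import LmmFit, RandomInterceptModel, lrt

__all__ = [
    "GaBasis",
    "make_ga_basis",
    "fit_gene_lmm",
    "lrt_gene",
    "fitted_curve",
    "fold_change",
    "run_de",
    "GRID_WEEKS",
]

GRID_WEEKS = np.linspace(10.0, 40.0, 301)
_GA_CENTER, _GA_SCALE = 25.0, 15.0


@dataclass(frozen=True)
class GaBasis:
    """Cubic gestational-age basis [z, z^2, z^3] with z = (t - 25)/15."""

    ga_weeks: np.ndarray
    columns: np.ndarray  # (n, 3)
    grid: np.ndarray = None
    grid_columns: np.ndarray = None

    @property
    def design(self) -> np.ndarray:
        """Full fixed-effect design [1, z, z^2, z^3]."""
        return np.column_stack([np.ones(len(self.ga_weeks)), self.columns])


def _poly_columns(t: np.ndarray) -> np.ndarray:
    z = (np.asarray(t, dtype=float) - _GA_CENTER) / _GA_SCALE
    return np.column_stack([z, z**2, z**3])


def make_ga_basis(ga_weeks) -> GaBasis:
    """Build the scaled cubic basis at the observed ages plus the 10-40 wk grid."""
    t = np.asarray(ga_weeks, dtype=float)
    if ((t <= 4) | (t >= 45)).any():
        raise AnalysisError("gestational ages must lie in (4, 45) weeks")
    return GaBasis(
        ga_weeks=t,
        columns=_poly_columns(t),
        grid=GRID_WEEKS,
        grid_columns=_poly_columns(GRID_WEEKS),
    )


def fit_gene_lmm(y, basis: GaBasis, subject_ids, use_ga_terms: bool = True) -> LmmFit:
    """ML random-intercept fit of one gene; ``use_ga_terms=False`` gives the null model."""
    X = basis.design if use_ga_terms else np.ones((len(basis.ga_weeks), 1))
    return RandomInterceptModel(X, subject_ids).fit(np.asarray(y, dtype=float))


def lrt_gene(fit_full: LmmFit, fit_null: LmmFit):
    """Likelihood-ratio test of the three gestational-age terms (chi-square, 3 df)."""
    return lrt(fit_full, fit_null, df=3)


def fitted_curve(fit: LmmFit, basis: GaBasis) -> np.ndarray:
    """Population-average prediction on the 10-40 week grid (random effects excluded)."""
    beta = np.asarray(fit.beta, dtype=float)
    if beta.shape[0] != 4:
        raise AnalysisError("fitted_curve expects the 4-coefficient cubic fit")
    X = np.column_stack([np.ones(len(basis.grid)), basis.grid_columns])
    return X @ beta


def fold_change(curve: np.ndarray, grid: np.ndarray = GRID_WEEKS,
                flat_fc: float = 1.01, edge_weeks: float = 5.0):
    """Fold change and direction label from a fitted log2 curve.

    FC = 2^(max - min) over the grid (linear scale, always >= 1). The
    direction is a convenience label: ``up``/``down`` when both extrema sit
    near the grid ends (within ``edge_weeks``), ``u_shape`` when an extremum
    is interior, ``flat`` when FC < ``flat_fc``.
    """
    curve = np.asarray(curve, dtype=float)
    i_max, i_min = int(np.argmax(curve)), int(np.argmin(curve))
    fc = float(2.0 ** (curve[i_max] - curve[i_min]))
    lo, hi = grid[0], grid[-1]
    near_edge = lambda i: grid[i] - lo <= edge_weeks or hi - grid[i] <= edge_weeks
    if fc < flat_fc:
        direction = "flat"
    elif near_edge(i_max) and near_edge(i_min):
        direction = "up" if grid[i_max] > grid[i_min] else "down"
    else:
        direction = "u_shape"
    return fc, direction


def run_de(expr: ExpressionMatrix, meta: SampleTable,
           q_thresh: float = 0.1, fc_thresh: float = 1.25,
           return_fits: bool = False):
    """Per-gene LMM scan: LRT p, BH q, curve fold change, significance call.

    Genes whose fits do not converge (rare) get ``p = NaN`` and are excluded
    from the FDR adjustment. Returns a DataFrame (and the full fits keyed by
    gene when ``return_fits``).
    """
    meta = meta.aligned_to(expr.sample_ids)
    subjects = meta.column("subject_id")
    if len(np.unique(subjects)) < 2:
        raise AnalysisError("differential expression needs at least 2 subjects")
    basis = make_ga_basis(meta.column("ga_weeks"))
    full_model = RandomInterceptModel(basis.design, subjects)
    null_model = RandomInterceptModel(np.ones((expr.n_samples, 1)), subjects)

    Y = expr.values
    rows, fits = [], {}
    for g, gene in enumerate(expr.gene_ids):
        fit_full = full_model.fit(Y[g])
        fit_null = null_model.fit(Y[g])
        stat, p = lrt_gene(fit_full, fit_null)
        if np.isfinite(stat):
            curve = fitted_curve(fit_full, basis)
            fc, direction = fold_change(curve)
        else:
            fc, direction = np.nan, "na"
        rows.append((gene, stat, p, fc, direction))
        if return_fits:
            fits[gene] = fit_full
    table = pd.DataFrame(rows, columns=["gene_id", "lrt_stat", "p", "fc", "direction"])

    ok = table["p"].notna().to_numpy()
    q = np.full(len(table), np.nan)
    if ok.any():
        q[ok] = multipletests(table.loc[ok, "p"], method="fdr_bh")[1]
    table["q"] = q
    table["significant"] = (table["q"] < q_thresh) & (table["fc"] > fc_thresh)
    table["significant"] = table["significant"].fillna(False)
    table = table[["gene_id", "lrt_stat", "p", "q", "fc", "direction", "significant"]]
    table = table.sort_values(["q", "gene_id"], kind="mergesort").reset_index(drop=True)
    if return_fits:
        return table, fits
    return table
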