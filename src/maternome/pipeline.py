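"""Config-driven end-to-end pipeline.

Stages: simulate (optional) -> preprocess -> de -> cluster -> enrich ->
signatures -> protein-corr. Each stage writes one TSV into the output
directory; a plain-text run log records thresholds, seed and stage
statistics. Reruns with the same config and seed are byte-identical.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cluster as cluster_mod
from . import de as de_mod
from . import enrich as enrich_mod
from . import io as io_mod
from . import proteins as proteins_mod
from . import signatures as signatures_mod
from .datatypes import GeneSetCollection
from .exceptions import ConfigError
from .preprocess import preprocess
from .simulate import SimulationConfig, simulate_all

__all__ = ["DEFAULT_THRESHOLDS", "load_config", "run_pipeline", "STAGE_TABLES"]

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = {
    "q_de": 0.1,
    "fc_de": 1.25,
    "fc_cluster": 1.5,
    "q_enrich": 0.05,
    "q_pairs": 0.1,
    "q_spearman": 0.05,
}

STAGE_TABLES = [
    "expression.tsv",      # simulate (or copy of the input matrix)
    "preprocessed.tsv",
    "de.tsv",
    "clusters.tsv",
    "enrichment.tsv",
    "signatures.tsv",
    "pairs.tsv",
]


def load_config(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        config = yaml.safe_load(fh) or {}
    if not isinstance(config, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    return config


def _require_inputs(config: dict) -> None:
    if config.get("simulate", True):
        return
    inputs = config.get("inputs") or {}
    for key in ("expression", "detection", "meta"):
        path = inputs.get(key)
        if not path:
            raise ConfigError(f"missing required input {key!r}")
        if not Path(path).exists():
            raise ConfigError(f"input file not found: {path}")


def run_pipeline(config: dict | str | Path, outdir, seed: int | None = None) -> Path:
    """Execute every stage; returns the output directory.

    ``config`` is a mapping (or path to a YAML file) with keys ``simulate``
    (bool, default true), ``sim`` (SimulationConfig overrides), ``inputs``
    (paths when not simulating), ``thresholds``, ``k_clusters``,
    ``linkage`` and ``seed``. ``seed`` given here overrides the config.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    _require_inputs(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    thresholds = {**DEFAULT_THRESHOLDS, **(config.get("thresholds") or {})}
    if seed is None:
        seed = int(config.get("seed", 0))
    log_lines = [f"seed: {seed}"]
    log_lines += [f"threshold {k}: {v}" for k, v in sorted(thresholds.items())]

    signatures_gmt = None
    annotation = None
    atlas = None
    protein_table = None

    if config.get("simulate", True):
        sim_kwargs = dict(config.get("sim") or {})
        sim_kwargs["seed"] = seed
        if "samples_per_subject" in sim_kwargs:
            sim_kwargs["samples_per_subject"] = tuple(sim_kwargs["samples_per_subject"])
        sim_config = SimulationConfig(**sim_kwargs)
        sim = simulate_all(sim_config)
        expr, det, meta = sim["expression"], sim["detection"], sim["schedule"]
        signatures_gmt = sim["signatures"]
        annotation = sim["annotation"]
        protein_table = sim["proteins"]
        io_mod.write_detection_tsv(det, outdir / "detection.tsv")
        io_mod.write_sample_table(meta, outdir / "meta.tsv")
        io_mod.write_gmt(signatures_gmt, outdir / "signatures.gmt")
        annotation.to_csv(outdir / "annotation.tsv", sep="\t", index=False)
        io_mod.write_protein_table(protein_table, outdir / "proteins.tsv")
        io_mod.write_results_table(sim["truth"].genes, outdir / "ground_truth.tsv",
                                   sort=False)
        log_lines.append(f"simulated: {expr.n_genes} genes x {expr.n_samples} samples")
    else:
        inputs = config.get("inputs") or {}
        expr = io_mod.read_expression_tsv(inputs["expression"])
        det = io_mod.read_detection_tsv(inputs["detection"])
        meta = io_mod.read_sample_table(inputs["meta"])
        if inputs.get("signatures"):
            signatures_gmt = io_mod.read_gmt(inputs["signatures"])
        if inputs.get("annotation"):
            annotation = io_mod.read_annotation(inputs["annotation"])
        if inputs.get("atlas"):
            atlas = io_mod.read_atlas(inputs["atlas"])
        if inputs.get("protein"):
            protein_table = io_mod.read_protein_table(inputs["protein"])
    io_mod.write_expression_tsv(expr, outdir / "expression.tsv")

    # -- preprocess --------------------------------------------------------
    expr_pp, meta_pp, report = preprocess(expr, det, meta)
    io_mod.write_expression_tsv(expr_pp, outdir / "preprocessed.tsv")
    io_mod.write_results_table(report.to_frame(), outdir / "preprocess_report.tsv",
                               sort=False)
    log_lines.append(f"preprocess: {report.genes_retained}/{report.genes_in} genes, "
                     f"{len(report.samples_removed_labor)} labor samples removed, "
                     f"{len(report.outlier_samples)} outliers")

    # -- differential expression ------------------------------------------
    de_table, fits = de_mod.run_de(expr_pp, meta_pp, q_thresh=thresholds["q_de"],
                                   fc_thresh=thresholds["fc_de"], return_fits=True)
    io_mod.write_results_table(de_table, outdir / "de.tsv")
    n_sig = int(de_table["significant"].sum())
    log_lines.append(f"de: {n_sig} significant of {len(de_table)}")
    de_genes = de_table.loc[de_table["significant"], "gene_id"].tolist()

    # -- trajectory clustering --------------------------------------------
    basis = de_mod.make_ga_basis(meta_pp.column("ga_weeks", expr_pp.sample_ids))
    high_fc = cluster_mod.select_high_fc(de_table, q_thresh=thresholds["q_de"],
                                         fc_thresh=thresholds["fc_cluster"])
    k = int(config.get("k_clusters", 3))
    if len(high_fc) >= k and k >= 1:
        curves = {g: de_mod.fitted_curve(fits[g], basis) for g in high_fc}
        profiles = cluster_mod.make_profiles(high_fc, curves)
        assignment = cluster_mod.cluster_profiles(
            profiles, k=k, linkage_method=config.get("linkage", "average"))
    else:
        assignment = pd.DataFrame(columns=["gene_id", "cluster"])
    io_mod.write_results_table(assignment, outdir / "clusters.tsv", sort=False)
    log_lines.append(f"cluster: {len(high_fc)} genes, k={k}")

    # -- enrichment --------------------------------------------------------
    background = expr_pp.gene_ids
    pieces = []
    if de_genes:
        collections = []
        if annotation is not None:
            known = annotation[annotation["gene_id"].isin(background)]
            collections.append(enrich_mod.chromosome_sets(known))
        if config.get("gmt"):
            for path in np.atleast_1d(config["gmt"]):
                collections.append(io_mod.read_gmt(path))
        if atlas is not None:
            collections.append(enrich_mod.derive_tissue_specific(atlas))
        for coll in collections:
            rows = enrich_mod.enrich_collection(
                de_genes, background, coll, q_thresh=thresholds["q_enrich"])
            rows.insert(0, "collection", coll.collection_name)
            pieces.append(rows)
    enrichment = (pd.concat(pieces, ignore_index=True) if pieces
                  else pd.DataFrame(columns=["collection", "set_name", "count", "size",
                                             "odds_ratio", "p", "q", "significant"]))
    io_mod.write_results_table(enrichment, outdir / "enrichment.tsv", sort=False)
    log_lines.append(f"enrich: {len(enrichment)} sets tested")

    # -- cell-type signatures ---------------------------------------------
    if signatures_gmt is not None and len(signatures_gmt):
        summary, scores = signatures_mod.run_signatures(expr_pp, meta_pp, signatures_gmt)
        io_mod.write_results_table(scores.reset_index(), outdir / "signature_scores.tsv",
                                   sort=False)
    else:
        summary = pd.DataFrame(columns=["signature", "n_genes_used", "n_genes_missing",
                                        "p", "fc_equivalent_zscale", "argmin_weeks",
                                        "argmax_weeks", "q"])
    io_mod.write_results_table(summary, outdir / "signatures.tsv", sort=False)
    log_lines.append(f"signatures: {len(summary)} tested")

    # -- mRNA-protein correlation -----------------------------------------
    if protein_table is not None:
        pairs = proteins_mod.run_pairs(protein_table, expr_pp, meta_pp, de_table,
                                       q_lmm=thresholds["q_pairs"],
                                       q_sp=thresholds["q_spearman"])
        if not pairs.empty and pairs["de_gene"].any() and (~pairs["de_gene"]).any():
            comparison = proteins_mod.compare_tscores(
                pairs, set(pairs.loc[pairs["de_gene"], "gene_id"]))
            log_lines.append(f"protein-corr: wilcoxon p={comparison['p']:.4g} "
                             f"({comparison['n_de_pairs']} DE vs "
                             f"{comparison['n_other_pairs']} other pairs)")
        else:
            logger.warning("t-score group comparison skipped: a group is empty")
            log_lines.append("protein-corr: group comparison skipped (empty group)")
    else:
        pairs = pd.DataFrame(columns=["gene_id", "protein_id", "slope", "se_slope",
                                      "t_score", "lrt_p", "spearman_rho", "spearman_p",
                                      "n_samples", "n_subjects", "de_gene",
                                      "q_lmm_value", "q_spearman", "doubly_significant"])
    io_mod.write_results_table(pairs, outdir / "pairs.tsv", sort=False)
    log_lines.append(f"pairs: {len(pairs)} tested")

    (outdir / "run_log.txt").write_text("\n".join(log_lines) + "\n", encoding="utf-8")
    return outdir
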