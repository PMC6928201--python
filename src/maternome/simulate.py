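"""Synthetic longitudinal maternal-blood transcriptome generator.

Emulates the design of a pregnancy cohort in which each of 49 women
contributes 4-6 blood draws falling in six gestational-age windows
(8-<16, 16-<24, 24-<28, 28-<32, 32-<37 and >37 weeks, capped at 41), with
per-subject random intercepts, Gaussian log2 noise, additive batch effects,
trajectory classes (null / increasing / decreasing / U-shaped), detection
p-values, cell-type signature gene blocks and a protein layer linearly
coupled to mRNA for a subset of genes. Every draw records its ground truth so
recovery of known parameters can be tested.

Randomness: one global seed drives a named sub-stream per operation
(schedule, expression, detection, signatures, proteins, annotation), so each
stage regenerates identically on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datatypes import (
    DetectionMatrix,
    ExpressionMatrix,
    GeneSetCollection,
    ProteinTable,
    SampleTable,
)
from .exceptions import ConfigError

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "GA_WINDOWS",
    "TRAJECTORY_CLASSES",
    "trajectory_mean",
    "true_fold_change",
    "simulate_ga_schedule",
    "simulate_expression",
    "simulate_detection",
    "simulate_signatures",
    "simulate_proteins",
    "simulate_annotation",
    "simulate_all",
]

# gestational-age sampling windows in weeks; the last window (term) is capped
GA_WINDOWS = ((8.0, 16.0), (16.0, 24.0), (24.0, 28.0), (28.0, 32.0), (32.0, 37.0), (37.0, 41.0))
TRAJECTORY_CLASSES = ("null", "increasing", "decreasing", "u_shape")

_STREAMS = {"schedule": 1, "expression": 2, "detection": 3, "signatures": 4,
            "proteins": 5, "annotation": 6}


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; defaults emulate the study design."""

    n_subjects: int = 49
    samples_per_subject: tuple = (4, 6)
    n_genes: int = 1000
    class_proportions: dict = field(default_factory=lambda: {
        "null": 0.90, "increasing": 0.04, "decreasing": 0.04, "u_shape": 0.02})
    amplitude_log2: float = 1.0
    sd_subject: float = 0.5
    sd_resid: float = 0.5
    n_batches: int = 3
    batch_effect_sd: float = 0.3
    absent_fraction: float = 0.1
    n_labor_subjects: int = 21
    n_signatures: int = 13
    signature_size: int = 10
    signature_classes: tuple | None = None  # optional per-signature planted class
    class_assignment: tuple | None = None   # optional explicit per-gene classes
    n_pairs: int = 100
    slope_true: float = 1.0
    sd_protein: float = 0.5
    sd_protein_subject: float = 0.3
    n_protein_subjects: int = 16
    n_protein_samples: int = 71
    n_chromosomes: int = 23
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ConfigError("n_subjects must be >= 2")
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"class proportions sum to {total}, not 1")
        unknown = set(self.class_proportions) - set(TRAJECTORY_CLASSES)
        if unknown:
            raise ConfigError(f"unknown trajectory classes: {sorted(unknown)}")
        for name in ("sd_subject", "sd_resid", "batch_effect_sd", "sd_protein",
                     "sd_protein_subject"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        lo, hi = self.samples_per_subject
        if not (1 <= lo <= hi <= len(GA_WINDOWS)):
            raise ConfigError("samples_per_subject must satisfy 1 <= lo <= hi <= 6")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), _STREAMS[stream]])


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually planted, for recovery tests."""

    genes: pd.DataFrame        # gene_id, trajectory_class, amplitude, baseline, true_fc, expressed
    samples: pd.DataFrame      # sample_id, batch, batch_effect
    batches: pd.DataFrame      # batch, effect
    pairs: pd.DataFrame | None = None  # protein_id, gene_id, true_slope


def trajectory_mean(cls: str, amplitude: float, t) -> np.ndarray:
    """Population-mean log2 offset of a trajectory class at gestational age t (weeks).

    null -> 0; increasing -> a*(t-10)/30; decreasing -> the negation;
    u_shape -> a*((t-25)/15)^2. Exact closed forms.
    """
    t = np.asarray(t, dtype=float)
    if cls == "null":
        return np.zeros_like(t)
    if cls == "increasing":
        return amplitude * (t - 10.0) / 30.0
    if cls == "decreasing":
        return -amplitude * (t - 10.0) / 30.0
    if cls == "u_shape":
        return amplitude * ((t - 25.0) / 15.0) ** 2
    raise ConfigError(f"unknown trajectory class {cls!r}")


def true_fold_change(cls: str, amplitude: float) -> float:
    """Closed-form FC of the noiseless trajectory over [10, 40] weeks: 2^(max-min)."""
    if cls == "null":
        return 1.0
    # increasing/decreasing span [0, a] over the interval; u_shape spans [0, a]
    # as well (vertex 0 at 25 wk, value a at both 10 and 40 wk)
    return float(2.0 ** abs(amplitude))


def simulate_ga_schedule(config: SimulationConfig) -> SampleTable:
    """Draw the longitudinal visit schedule.

    Per subject: k ~ uniform over the configured range of distinct windows;
    windows chosen without replacement and visited in chronological order,
    one draw uniform within each window. Batches are assigned round-robin
    over subjects; the chronologically last draw of the first
    ``n_labor_subjects`` subjects is flagged as collected at labor.
    """
    rng = config.rng("schedule")
    lo, hi = config.samples_per_subject
    rows = []
    width = len(str(config.n_subjects))
    for i in range(config.n_subjects):
        subject = f"W{i + 1:0{width}d}"
        k = int(rng.integers(lo, hi + 1))
        windows = np.sort(rng.choice(len(GA_WINDOWS), size=k, replace=False))
        batch = f"B{i % config.n_batches + 1}"
        for draw, w in enumerate(windows, start=1):
            w_lo, w_hi = GA_WINDOWS[w]
            ga = float(rng.uniform(w_lo, w_hi))
            rows.append((f"{subject}_{draw}", subject, ga, batch, False))
    df = pd.DataFrame(rows, columns=["sample_id", "subject_id", "ga_weeks", "batch",
                                     "labor_at_draw"])
    labor_subjects = sorted(df["subject_id"].unique())[: config.n_labor_subjects]
    for subject in labor_subjects:
        sub = df[df["subject_id"] == subject]
        last = sub["ga_weeks"].idxmax()
        df.loc[last, "labor_at_draw"] = True
    return SampleTable(df)


def _assign_classes(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    if config.class_assignment is not None:
        if len(config.class_assignment) != config.n_genes:
            raise ConfigError("class_assignment length must equal n_genes")
        classes = np.array(config.class_assignment, dtype=object)
    else:
        props = [config.class_proportions.get(c, 0.0) for c in TRAJECTORY_CLASSES]
        classes = rng.choice(TRAJECTORY_CLASSES, size=config.n_genes, p=props)
    # planted signature blocks override the random class assignment so that a
    # signature's members share a trajectory
    if config.signature_classes is not None:
        for s, cls in enumerate(config.signature_classes):
            if cls is None:
                continue
            start = s * config.signature_size
            classes[start:start + config.signature_size] = cls
    return classes


def simulate_expression(config: SimulationConfig, schedule: SampleTable):
    """Generate the log2 expression matrix plus its ground truth.

    value(g, s) = baseline_g + trajectory(class_g, a_g, ga_s) + u_{g,subject(s)}
                  + b_batch(s) + eps, with gene-specific subject intercepts
    u ~ N(0, sd_subject^2) — matching the per-gene mixed model's assumption,
    so genes are mutually independent — fixed batch offsets
    b ~ N(0, batch_effect_sd^2) shared across genes (a technical shift) and
    eps ~ N(0, sd_resid^2); baselines uniform in [4, 12] log2 units.
    """
    rng = config.rng("expression")
    meta = schedule.data
    n_samples = len(meta)
    width = len(str(config.n_genes))
    gene_ids = [f"G{g + 1:0{width}d}" for g in range(config.n_genes)]

    classes = _assign_classes(config, rng)
    amplitudes = np.where(classes == "null", 0.0, config.amplitude_log2)
    baselines = rng.uniform(4.0, 12.0, size=config.n_genes)

    subjects = sorted(meta["subject_id"].unique())
    subj_codes = meta["subject_id"].map({s: i for i, s in enumerate(subjects)}).to_numpy()
    u = rng.normal(0.0, config.sd_subject, size=(config.n_genes, len(subjects)))
    batches = sorted(meta["batch"].unique())
    b = dict(zip(batches, rng.normal(0.0, config.batch_effect_sd, size=len(batches))))

    ga = meta["ga_weeks"].to_numpy()
    batch_offsets = meta["batch"].map(b).to_numpy()
    values = np.empty((config.n_genes, n_samples))
    for g in range(config.n_genes):
        mean = baselines[g] + trajectory_mean(classes[g], amplitudes[g], ga)
        values[g] = mean + u[g, subj_codes] + batch_offsets
    values += rng.normal(0.0, config.sd_resid, size=values.shape)

    expr = ExpressionMatrix(pd.DataFrame(values, index=gene_ids,
                                         columns=meta["sample_id"].tolist()))
    expressed = _expressed_mask(config, len(gene_ids))
    truth = GroundTruth(
        genes=pd.DataFrame({
            "gene_id": gene_ids,
            "trajectory_class": classes,
            "amplitude": amplitudes,
            "baseline": baselines,
            "true_fc": [true_fold_change(c, a) for c, a in zip(classes, amplitudes)],
            "expressed": expressed,
        }),
        samples=pd.DataFrame({"sample_id": meta["sample_id"],
                              "batch": meta["batch"],
                              "batch_effect": batch_offsets}),
        batches=pd.DataFrame({"batch": batches, "effect": [b[k] for k in batches]}),
    )
    return expr, truth


def _expressed_mask(config: SimulationConfig, n_genes: int) -> np.ndarray:
    # deterministic: the last ceil(absent_fraction * n) genes are always-absent
    n_absent = int(round(config.absent_fraction * n_genes))
    mask = np.ones(n_genes, dtype=bool)
    if n_absent:
        mask[n_genes - n_absent:] = False
    return mask


def simulate_detection(config: SimulationConfig, expr: ExpressionMatrix,
                       truth: GroundTruth) -> DetectionMatrix:
    """Detection p-values: expressed genes uniform on (0, 0.05) in every sample,
    always-absent genes uniform on (0.05, 1)."""
    rng = config.rng("detection")
    expressed = truth.genes["expressed"].to_numpy()
    p = np.empty((expr.n_genes, expr.n_samples))
    p[expressed] = rng.uniform(0.0, 0.05, size=(int(expressed.sum()), expr.n_samples))
    p[~expressed] = rng.uniform(0.05, 1.0, size=(int((~expressed).sum()), expr.n_samples))
    return DetectionMatrix(pd.DataFrame(p, index=expr.gene_ids, columns=expr.sample_ids))


def simulate_signatures(config: SimulationConfig, truth: GroundTruth) -> GeneSetCollection:
    """Cell-type signature gene sets as consecutive blocks of the gene list.

    Signature s holds genes [s*size, (s+1)*size); when ``signature_classes``
    is set those blocks were planted with the requested trajectory class by
    ``simulate_expression``.
    """
    genes = truth.genes["gene_id"].tolist()
    needed = config.n_signatures * config.signature_size
    if needed > len(genes):
        raise ConfigError("not enough genes for the requested signatures")
    sets = {}
    for s in range(config.n_signatures):
        members = genes[s * config.signature_size:(s + 1) * config.signature_size]
        sets[f"celltype_{s + 1:02d}"] = ("synthetic cell-type signature", members)
    return GeneSetCollection("synthetic_signatures", sets)


def simulate_proteins(config: SimulationConfig, expr: ExpressionMatrix,
                      schedule: SampleTable,
                      pair_genes=None, pair_slopes=None):
    """Protein layer linearly coupled to mRNA for half of the selected pairs.

    A subset of subjects (default 16) is profiled; their draws are subsampled
    to ``n_protein_samples`` when more are available. protein(p, s) =
    slope_p * mrna(g_p, s) + v_{p,subject(s)} + eta with protein-specific
    subject intercepts v ~ N(0, sd_protein_subject^2) and eta ~ N(0,
    sd_protein^2); half the pairs get ``slope_true``, half slope 0
    (recorded in the returned pair truth).
    """
    if config.n_pairs > expr.n_genes:
        raise ConfigError("n_pairs exceeds number of genes")
    rng = config.rng("proteins")
    meta = schedule.data
    subjects = sorted(meta["subject_id"].unique())
    chosen = sorted(rng.choice(subjects, size=min(config.n_protein_subjects,
                                                  len(subjects)), replace=False))
    sub_meta = meta[meta["subject_id"].isin(chosen)]
    if len(sub_meta) > config.n_protein_samples:
        keep = np.sort(rng.choice(len(sub_meta), size=config.n_protein_samples,
                                  replace=False))
        sub_meta = sub_meta.iloc[keep]

    if pair_genes is not None:
        genes = np.asarray(pair_genes)
        slopes = np.asarray(pair_slopes, dtype=float)
        if len(genes) != len(slopes):
            raise ConfigError("pair_genes and pair_slopes must have equal length")
    else:
        genes = rng.choice(expr.gene_ids, size=config.n_pairs, replace=False)
        slopes = np.where(np.arange(config.n_pairs) % 2 == 0, config.slope_true, 0.0)

    sample_ids = sub_meta["sample_id"].tolist()
    subject_of = dict(zip(sub_meta["sample_id"], sub_meta["subject_id"]))
    mrna = expr.data.loc[genes, sample_ids].to_numpy()
    rows = []
    for p_idx, (gene, slope) in enumerate(zip(genes, slopes)):
        protein_id = f"P{p_idx + 1:04d}"
        # protein-specific subject intercepts, matching the pair model
        v = dict(zip(chosen, rng.normal(0.0, config.sd_protein_subject,
                                        size=len(chosen))))
        eta = rng.normal(0.0, config.sd_protein, size=len(sample_ids))
        for j, sample in enumerate(sample_ids):
            subj = subject_of[sample]
            rows.append((protein_id, gene, sample, subj,
                         slope * mrna[p_idx, j] + v[subj] + eta[j]))
    table = ProteinTable(pd.DataFrame(
        rows, columns=["protein_id", "gene_id", "sample_id", "subject_id", "abundance"]))
    pair_truth = pd.DataFrame({
        "protein_id": [f"P{i + 1:04d}" for i in range(len(genes))],
        "gene_id": genes,
        "true_slope": slopes,
    })
    return table, pair_truth


def simulate_annotation(config: SimulationConfig, truth: GroundTruth) -> pd.DataFrame:
    """Assign each gene a chromosome uniformly at random (chr1..chr22, chrX)."""
    rng = config.rng("annotation")
    chroms = [f"chr{i}" for i in range(1, config.n_chromosomes)] + ["chrX"]
    chroms = chroms[: config.n_chromosomes]
    return pd.DataFrame({
        "gene_id": truth.genes["gene_id"],
        "chromosome": rng.choice(chroms, size=len(truth.genes)),
    })


def simulate_all(config: SimulationConfig):
    """Run every generator stage; returns a dict of all artifacts."""
    schedule = simulate_ga_schedule(config)
    expr, truth = simulate_expression(config, schedule)
    det = simulate_detection(config, expr, truth)
    signatures = simulate_signatures(config, truth)
    proteins, pair_truth = simulate_proteins(config, expr, schedule)
    annotation = simulate_annotation(config, truth)
    truth = replace(truth, pairs=pair_truth)
    return {
        "schedule": schedule,
        "expression": expr,
        "detection": det,
        "signatures": signatures,
        "proteins": proteins,
        "annotation": annotation,
        "truth": truth,
    }
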