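# Methods

## The longitudinal model and test

Each gene's log2 expression is modeled as a cubic polynomial of gestational
age with a per-woman random intercept. Age is rescaled to z = (t − 25)/15 so
the basis [z, z², z³] is well conditioned over the observed 8–41 week range;
the fitted curve is invariant to this reparameterization (checked
numerically in the tests), only the conditioning changes.

Fitting is by maximum likelihood, not REML, because the gene-level test is a
likelihood ratio between models that differ in fixed effects (the cubic
terms vs intercept only); REML likelihoods are not comparable across fixed
effect structures. The implementation profiles β and the residual variance
out of the likelihood analytically and minimizes the resulting 1-D deviance
over the variance ratio λ = σ²u/σ²e by bounded scalar search, with the λ = 0
boundary (pure OLS) checked explicitly and preferred on ties so
unidentifiable random effects report var_subject = 0 exactly. Per-subject
sufficient statistics are precomputed once per design, making a fit ~1 ms;
agreement with statsmodels `MixedLM(reml=False)` is ~1e-6 in log-likelihood
(test-suite cross-check). The LRT statistic is referred to χ² with 3 df —
both models share the random intercept, so there is no boundary problem —
and ML's mild small-sample anti-conservatism is visible in the type-I error
study as a p<0.05 fraction of ~0.055 rather than 0.050 at 30 subjects; this
is a property of the method, not of the implementation.

Fold change is 2^(max − min) of the fitted population-average curve on a
fixed 0.1-week grid from 10 to 40 weeks (301 points). It is ≥ 1 by
construction and deliberately direction-free; the `direction` label
(up/down/u_shape/flat, with "near the ends" meaning within 5 weeks of the
grid boundary and "flat" meaning FC < 1.01) is a reading convenience, not
part of the significance call. Significance requires q < 0.1 (BH across all
converged genes) and FC > 1.25, both strict and both configurable.
Nonconverged fits (rare; the profiled deviance is smooth) are reported with
p = NA and excluded from the FDR.

## Preprocessing

Stage order is fixed: batch correction → removal of labor-draw samples →
outlier-sample removal → detection filter, each recorded in the report.
Batch correction fits, per gene, OLS on [intercept, sum-to-zero batch
indicators, the same cubic age basis] and subtracts only the fitted batch
component; including the age basis as covariates protects the longitudinal
signal by construction, and with additive batch offsets and no noise the
correction is exact up to the (unidentifiable) grand mean. The correction is
idempotent. A batch exactly confounded with the age basis leaves a singular
design and is an error, not a silent drop.

The detection filter keeps genes with p_DBAG < 0.05 in strictly more than
25% of the remaining samples. The outlier rule formalizes "one sample is the
lowest for a large fraction of genes": per sample, the fraction f of genes
whose row minimum is attained there (exact ties split equally); samples with
f > 10/n_samples are flagged. Under exchangeable noise f ≈ 1/n, so the
default multiplier 10 only catches gross, consistent outliers.

## Trajectory clustering

Genes with q < 0.1 and FC > 1.5 are represented by their fitted curve minus
its value at 10 weeks, and clustered by agglomerative hierarchical
clustering (average linkage by default; complete linkage available) on
1 − Pearson correlation of the 301-point profiles, cut at k = 3 by default.
Pearson distance sees only shape — positive per-gene rescaling does not
change the partition — and flat profiles (undefined correlation; impossible
after the FC filter) are excluded with a warning. Genes are sorted
lexicographically before the distance matrix is built and clusters are
renumbered by size, so the output is independent of input order.

## Enrichment

Over-representation uses the one-sided hypergeometric tail P(X ≥ a) with the
background defined as the genes passing the detection filter; sets are
intersected with the background and those smaller than 5 (the configurable
`min_size`) skipped; BH runs within each collection because collections are
reported as separate tables. The odds ratio is the 2×2 cross-product with
the Haldane–Anscombe +0.5 applied to all cells whenever one is zero.
Tissue-specific sets are derived from a linear-scale atlas: a gene is
specific to the tissue whose (median) expression exceeds 30× the median of
all other tissues' values, with a zero other-median and positive value
counted as specific; with ratio > 1 a gene can qualify for at most one
tissue, which the code asserts. Chromosome sets are simply one set per
chromosome from the annotation table.

## Cell-type signature meta-genes

Expression is standardized per gene against term samples (draws at > 37.0
weeks; sample sd with n − 1; genes constant at term are dropped and logged),
and a signature's score per sample is the unweighted mean of its members'
z-scores; missing members are tolerated (≥ 1 required) and reported. The
score series is fit and LRT-tested exactly like a single gene. The
`fc_equivalent_zscale` column applies the 2^(max − min) formula to the
fitted curve; because the curve lives on the z-score scale this is a
descriptive index rather than an expression ratio, and the column name and
output headers carry that caveat.

## mRNA–protein coupling

Each protein is regressed on its transcript's log2 expression over the
samples shared by both layers, with a random intercept per subject, by ML.
Reported per pair: the slope (change in log2 protein per unit log2 mRNA),
its ML standard error and t-score, the 1-df LRT p against the no-slope
model, and a naive Spearman correlation that ignores subject structure. BH
runs across all tested pairs separately for the two p-values; a pair is
"doubly significant" when q_lmm < 0.1 and q_spearman < 0.05. Whether
coupling is stronger for gestation-modulated transcripts is tested by a
two-sided Wilcoxon rank-sum on t-scores (normal approximation with tie
correction, no continuity correction, so identical groups give p = 1).

## The synthetic-data generator

The generator emulates the cohort design the pipeline targets: 49 subjects,
each drawing 4–6 samples in distinct windows among 8–<16, 16–<24, 24–<28,
28–<32, 32–<37 and >37 weeks (term capped at 41.0), windows chosen uniformly
without replacement and visited in order, one uniform draw per window;
batches assigned round-robin over subjects; the final draw of 21 subjects
flagged as collected at labor. Gene trajectories are fixed closed forms —
null 0, increasing a·(t−10)/30, decreasing its negation, U-shaped
a·((t−25)/15)² — the simplest curves reproducing the three observed shape
groups; for all non-null classes the true FC over [10, 40] is exactly 2^a.

Noise structure: gene-specific subject intercepts u ~ N(0, sd_subject²) —
one draw per (gene, subject), matching the per-gene mixed model's assumption
and keeping genes mutually independent — additive batch offsets shared
across genes (a technical shift, removable by the batch model), and i.i.d.
Gaussian residuals. Baselines are uniform in [4, 12] log2 units. Detection
p-values are Uniform(0, 0.05) for expressed genes and Uniform(0.05, 1) for a
configurable always-absent fraction. The protein layer restricts to 16
subjects subsampled to 71 draws, with protein = slope·mRNA + v + η and
protein-specific subject intercepts v; half the pairs get the configured
slope, half zero. One global seed drives a named sub-stream per stage, so
any stage regenerates identically on its own.

Defaults not fixed by the emulated design were chosen once as plausible for
whole-blood arrays and are not tuned: class proportions 0.90 / 0.04 / 0.04 /
0.02, amplitude 1.0 log2 (FC 2), sd_subject 0.5, sd_resid 0.5, three batches
with offset sd 0.3, 10% always-absent genes, 13 signatures of 10 genes,
protein slope 1.0 with sd_protein 0.5 and subject sd 0.3.

What the generator does **not** emulate: probe-level microarray intensities
and RMA, spatial artifacts, heavy-tailed or heteroskedastic noise, gene–gene
correlation beyond the planted signature blocks, dropout-style missingness,
or realistic visit-date distributions (ages are uniform within windows).
Passing recovery tests therefore demonstrates correctness of the statistical
machinery under its own assumptions, not robustness to everything real
cohorts can contain.

## Validation studies and problem sizes

`maternome.studies` (backing both `tests/test_acceptance.py` and
`scripts/acceptance.py`) measures: LRT calibration on 2,000 null genes at 30
subjects × 5 samples; sensitivity/FDR on 900 null + 100 planted twofold
genes at 49 subjects; mean FC over 200 planted genes; cluster/class
agreement for 20 genes per shape; hypergeometric exactness against integer
enumeration for every table with N ≤ 60 (~1.2 M tail values); the tissue
rule on an enumerated 5-gene atlas covering the edge cases; meta-gene
recovery over 100 replicates (10-gene blocks, amplitude 0.5); Wilcoxon
discrimination over 100 replicates at 53 coupled vs 1,011 uncoupled pairs on
16 subjects / 71 samples; and byte-level determinism of two pipeline runs.
These sizes keep the full suite under a few minutes on one core while
leaving the binomial error of the rate estimates small relative to the
asserted margins.

## Numerical choices and edge cases

- Variance-ratio search window λ ∈ [1e−8, 1e6] on the log scale, xatol 1e−6;
  residual variance floored at 1e−12 so constant responses yield error-free
  degenerate fits (LRT exactly 0).
- LRT statistic clipped at 0 (optimizer jitter can make it infinitesimally
  negative).
- Result tables are written with 6 significant digits, sorted by (q, id),
  ties broken lexicographically — the source of byte-level reproducibility.
- Readers reject, rather than coerce: duplicate ids, non-numeric cells
  (reported with row and column), non-finite values, gestational ages
  outside (4, 45) weeks, GMT lines with fewer than three fields.
- Missing expression values are not imputed; they are errors by contract.

## Known limitations

Random slopes, spline bases, moderated variance estimators and deconvolution
into cell-type proportions are deliberately out of scope. The χ²(3)
reference is asymptotic; at very small cohorts (≪ 30 subjects) the LRT will
be noticeably anti-conservative and a parametric bootstrap would be
preferable. The Spearman test ignores repeated measures by design (it is the
"naive" comparator to the mixed model, not a recommendation).
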