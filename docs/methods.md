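# Methods

This note documents the models, defaults and design decisions behind each
stage of the pipeline, what the synthetic-data generator does and does not
emulate, and the numerical conventions used throughout.

## Study design and synthetic data

The generator (`toxregulon.synthdata`) emulates a 5-day acute rat exposure
design: four chemicals (three PFAS — 6:1 FTOH, 10:2 FTOH, PFHxSAm — and one
PAH, 2,3-benzofluorene), nine ascending doses per chemical
(0.15–1,000 mg/kg for three of them, 0.07–475 mg/kg for 10:2 FTOH), both
sexes, n = 5 treated animals per (chemical, dose, sex) group, and n = 10
vehicle controls per (chemical, sex) shared across that chemical's dose arms.
`default_design()` carries these values; tests and the acceptance script
scale the gene dimension down (1,100–2,500 genes instead of ~17K) while
keeping the sample-level design intact, since every per-gene statistic is
independent across genes.

**Expression model.** Per-sample latent log2 expression is
`baseline_g + effect_g(condition) + N(0, noise_sd)`, with per-gene baselines
drawn from N(6, 2) clipped to [0.5, 14] (a plausible log2 RPM range) and
default `noise_sd = 0.5`. Two output modes exist:

- `lognormal` (default): the latent log2 matrix is emitted directly. This is
  the mode used for calibration studies because the fold-change noise is then
  exactly `noise_sd * sqrt(1/n_treated + 1/n_control)` per condition.
- `counts`: latent values are converted to intensities `2^x − 1` (clipped at
  0), scaled to a library size drawn uniformly from `libsize_range`
  (default 1–3 M reads), and Poisson-sampled. Column sums therefore match the
  drawn library size only up to Poisson fluctuation (sd ≈ √L). The platform's
  true count-dispersion model is not published, so Poisson is an explicit
  stand-in, not an estimate; stages that only need log2 values should use the
  log-normal mode.

**Planted effects.** An effect entry targets an explicit gene list or the
regulon of a TF (optionally its first `n_targets` targets, sorted), has a
direction and a maximum log2 fold change reached at the top dose, and applies
only to matching sexes and chemical classes. Direction can be overridden per
sex (e.g. up in females, down in males) or per chemical class (e.g. up under
PAH, down under PFAS), which is how sex-dependent and class-dependent genes
are planted. Two dose shapes are provided, both monotone so dose-trend
detection has clean ground truth:

- `linear_in_log_dose` (default): `effect(d) = max · log(d/d_min + 1) / log(d_max/d_min + 1)`,
  reaching exactly `max` at the top dose;
- `hill`: `effect(d) = max · d / (d + EC50)` with EC50 at the geometric
  mid-dose (saturates below `max`).

The truth table records the exact planted mean log2 effect for every planted
(gene, chemical, dose, sex); unlisted combinations are zero by construction.

**What the generator does not emulate:** batch effects, probe-level
ambiguity, gene–gene correlation beyond shared planted effects,
platform-specific attenuation, or sequence-level artifacts. Passing tests
therefore demonstrate correctness of the analysis logic and its calibration
under the stated noise model — not robustness to those real-data phenomena.

**QC metrics** are drawn in comfortably passing ranges; `qc_fail_fraction`
(default 0) injects failures by setting one randomly chosen metric clearly
below its threshold, for boundary-testing the QC filter.

## QC and normalization

A sample fails QC iff any metric is **strictly below** its threshold —
defaults: sequencing depth and aligned reads 300,000; total alignment 40%;
unique alignment 30%; fraction of probes with ≥ 5 reads 50%. A metric exactly
at its threshold passes; this reads the protocol's "below the following
thresholds" literally and gives a deterministic boundary rule.

RPM normalization divides each sample by its column total and scales to 10⁶
(computed over the genes present in the matrix; no external denominator), and
the log transform is `log2(x + 1)`. The two steps make the pipeline invariant
to per-sample library scaling.

**Replicate outliers.** The source protocols name principal-component,
hierarchical-cluster and inter-replicate-correlation diagnostics without
criteria, so one reproducible rule is fixed: within each
(chemical, dose, sex) replicate group of size ≥ 3, a sample is flagged iff
the median of its pairwise Spearman correlations with its group is below
`min_median_corr` (default 0.8, exposed in config). Groups of ≤ 2 samples are
never flagged. Spearman is used because it is insensitive to monotone
distortions of the expression scale.

## Transcriptome extrapolation

`fit_pcr_extrapolator` performs classical principal-component regression:
the measured-gene submatrix of a reference compendium is centered per gene,
its principal components computed by SVD, and every compendium gene regressed
by ordinary least squares on the component scores. New samples are centered
with the stored offsets, projected onto the loadings, and all genes predicted
from the scores; measured genes are passed through verbatim by default rather
than re-predicted. When `n_components` is not given, the smallest number of
components explaining ≥ 95% of measured-panel variance is used, capped at
100. These defaults are this package's own choices — the referenced
extrapolation tools do not publish their hyperparameters, and no claim of
reproducing them is made. With a noiseless rank-r compendium and
`n_components = r`, recovery of unmeasured genes is exact (machine
precision), which the tests verify.

## Differential expression

For each treated (chemical, dose, sex) condition, the control group is the
same chemical's same-sex vehicle samples pooled across its dose arms
(n = 10 in the reference design). Then per gene:

- `log2FC = mean(log2 treated) − mean(log2 control)`;
- a two-group one-way ANOVA (hand-vectorised sums of squares; for two groups
  F equals the squared pooled-variance t statistic). "Per dose" is read as
  one treated-vs-control test per dose — matching the per-dose fold-change
  columns of the profiling output; a global all-doses one-way ANOVA
  (`anova_all_doses`) is available as an optional mode.
- Genes with zero within- and between-group variance get F = 0 and p = 1 and
  are retained, keeping table cardinality stable. Zero within-group variance
  with a mean difference gives p = 0.
- Benjamini–Hochberg q-values, adjusted **across genes within each
  condition**. The adjustment family is a documented choice (the source
  protocol names neither the FDR method nor the family); tests pin the exact
  step-up behavior against a hand-coded oracle.

## MIE regulons and profiling

Regulatory tables use the TRRUST 4-column dialect (TF, target, mode ∈
{Activation, Repression, Unknown}, references; no header). Exact duplicate
rows collapse silently; a (TF, target) pair with conflicting modes collapses
to a single `Unknown` edge with a logged warning — preserving network size
rather than dropping evidence. Symbol mapping applies a user-supplied
source→destination table (one-to-many entries fan out into multiple edges);
symbols without an entry fall back to title-case conversion (ABCC3 → Abcc3),
recorded in the mapping report. MIE names match TF symbols case-insensitively
and alias reconciliation (e.g. GR vs NR3C1) is the input list's
responsibility; MIEs without edges are retained with zero counts.

Dysregulation counting is per MIE over its mapped targets with **inclusive**
thresholds (log2FC ≥ 0.6 up, ≤ −0.6 down; each MIE counts its own targets,
so a gene shared by two MIEs counts once for each). Counting ignores the
regulation mode because up- and downregulated targets are profiled together;
direction splits (`direction_split`) report up/down fractions, with
zero-count cells marked undefined rather than 0/0. The tabular view keeps the
k highest doses per (chemical, sex), default k = 3.

Network exports color nodes by fold-change sign (`up` / `down`, `neutral` at
exactly 0 or when missing — a deterministic tie rule) and carry a separate
dysregulation class at the ±0.6 thresholds.

## Response patterns and dose trends

Patterns are called from the top-dose fold change of every (chemical, sex)
cell, in precedence order consistent > sex-dependent > class-dependent >
none; precedence resolves genes that would match several categories. A cell
at exactly 0 counts as neither direction. `min_support` (default 1.0 — all
cells must pass |log2FC| ≥ 0.6; a relaxed 0.75 mode is available) stands in
for the unstated number of chemicals/doses that must agree.

**Dose trends.** A trend is called when, over the top-3-dose window, all fold
changes share one sign and the top-dose |log2FC| ≥ 0.6, and the fold change
moves with dose. The motion clause defaults to a **net** rule: the
least-squares slope of fold change against log-dose over the whole series
must not oppose the sign. A step-by-step non-decreasing variant
(`monotone="pointwise"`) is provided but is not the default: with the
reference design's dose ladder, adjacent top-dose effect increments
(≈ 0.125 log2 units at a top-dose effect of 1.0) are small against
replicate-level fold-change noise (sd ≈ 0.16 at noise sd 0.3), so a
point-wise rule rejects roughly half of genuinely monotone genes, whereas the
net-slope rule keeps the false-flag rate on null genes far below 1% while
detecting ≥ 90% of planted monotone responses. The window size, threshold and
strictness are all exposed.

**Signature concordance** compares the sign of a gene's fold change against
its signed weight in a supplied pathology signature, restricted to genes
significant at q < 0.1 (strict); non-significant and absent genes are
reported as such rather than dropped.

## Pipeline, determinism and output conventions

`run_pipeline` executes preprocess → differential expression → regulon →
profiling → classification → renderers from one YAML config, writes every
artifact under the output directory, and emits a manifest (config echo, seed,
SHA-256 of input files, per-stage record counts, warnings) on success and
failure alike. All floating-point TSV output is rounded to 6 decimals and the
manifest echoes the output directory as "."; two runs with the same config
and seed are therefore byte-identical wherever they are written. Heatmap
matrices fix columns by chemical and ascending dose and order rows by
average-linkage Euclidean hierarchical clustering of fold-change vectors
(scipy's deterministic leaf order); clustering parameters are a package
choice, as the source figures do not state theirs.

## Problem sizes used in tests and acceptance

Oracle checks run on 100 random regulon fixtures and 1,000 random two-group
datasets (n = 5 vs 10). Calibration and recovery studies use the full sample
design (440 samples for four chemicals) with 1,100–2,000 genes; planted-MIE
recovery uses 100 independent studies of one chemical (110 samples, 1,200
genes). Extrapolation tests use a 2,000-gene, 300-sample, rank-5 compendium
with a 200-gene measured panel. These sizes make the entire suite run in
well under a minute per stage while leaving the per-gene statistics at the
design's actual group sizes.

## Known limitations

- The Poisson count model and the log-normal latent model are stand-ins; no
  dispersion estimation is attempted.
- No attenuation-factor correction, probe-level processing, or batch-effect
  modeling.
- No enrichment statistics over the per-MIE counts (the profiling is
  descriptive counting by design) and no reconstruction of supervised
  signature classifiers — only direction concordance against supplied
  weights.
- Live database access (TRRUST, DAVID, AOP repositories) is out of scope;
  all such inputs are user-supplied files.
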