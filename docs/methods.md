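# Methods

This note documents the models implemented in `sigtrace`, the synthetic
study that exercises them, and the numerical and design choices made where
the procedures are conventionally under-specified.

## Single-cell stage

**QC.** A barcode is viable when its total UMI count is ≥ `min_umi`
(default 2000, inclusive) and its mitochondrial UMI fraction is strictly
below `max_mito_fraction` (default 0.08). The filter is idempotent and
reports removals per criterion. An all-removed outcome warns rather than
raises, so callers can distinguish an empty result from a crash.

**Normalization.** Counts are scaled per cell to a fixed total
(default 10⁴) and transformed with log1p — the common droplet default.
The merge rule and fold changes below operate on linear-scale means of
this normalized expression (i.e. `expm1` of the log values), with a
pseudocount of 1e-9 in denominators; whether log- or linear-scale means
are used for such rules is a known point of variation between toolkits,
and the linear scale is chosen here because marker folds are defined
multiplicatively on expression.

**Clustering.** Genes are z-scored (within donor when donor labels exist —
a deliberately simple stand-in for cross-donor alignment, adequate because
the generator plants no donor shifts), reduced to 30 PCs, and a symmetric
kNN graph (k = 15) is partitioned with Leiden at resolution 0.3
("relatively low", aiming at broad cell types). Everything is
deterministic given the seed. A spherical k-means method
(`method="kmeans"`) is available as a graph-free alternative.

**Cluster merging.** A cluster must elevate at least `min_markers`
(default 30) genes at ≥ `min_fold` (default 1.5) linear-scale one-vs-rest
fold. Failing clusters are merged — weakest first, ties by smallest id —
into the cluster with the highest Pearson correlation of log-space
centroids ("most similar"; the similarity metric is a design choice, and
correlation is scale-robust). The loop strictly decreases the cluster
count, so it terminates in at most k − 1 merges.

**Markers and signatures.** Per cluster, a two-sided Wilcoxon rank-sum
test per gene (exact enumeration over all C(n₁+n₂, n₁) assignments when
both groups have ≤ 10 cells; mid-rank/tie-corrected normal approximation
otherwise, no continuity correction) with BH adjustment within the
cluster. A signature keeps genes with FDR < 0.01 and positive log₂ fold
change, ordered by descending fold change with gene-id tie-breaks
(deterministic), capped at 50 genes. "Most differential" is interpreted as
largest positive fold change: signatures must mark presence, so negative
markers are excluded.

## Bulk stage

**Filtering and transform.** Genes enter the analysis with > 10 reads in
> 31 samples (both strict; the 31 is cohort-specific and configurable).
CPM is count × 10⁶ / library; log₂-CPM uses a 0.5 pseudocount on counts
and +1 on the library size.

**Precision weights.** Gene-wise OLS of log₂-CPM on the design gives
residual standard deviations; lowess (span 0.5, 3 robustness iterations)
of √sd against average log₂ count defines the mean-variance trend, which
is interpolated at each observation's fitted log₂ count (constant beyond
the range); the observation weight is trend⁻⁴. Degenerate trends (a single
gene, or a zero-spread abundance axis) fall back to unit weights with a
warning.

**Moderated fit.** Per-gene weighted least squares; residual variances are
shrunk toward a scaled-F prior whose hyperparameters (prior variance,
prior df) are moment-matched on log variances via digamma/trigamma
identities (the standard published estimator; the trigamma inverse is
solved by Newton iteration). The moderated t uses residual + prior df.
Setting the prior df to 0 recovers ordinary t-statistics. When all raw
variances are identical the log-variance spread is at (or below) its
sampling expectation, the prior df becomes infinite, and the posterior
equals the common value up to the finite-df bias factor
exp(log(d/2) − ψ(d/2)) — exact equality holds when the prior variance is
supplied directly. The whole chain reproduces R limma's voom/lmFit/eBayes
to ~1e-3 in t on NB data (cross-checked in the test suite).

**Design and strata.** 0/1 indicators: arm (treatment = 1), anti-TNF
(yes = 1), location (ileum = 1), visit (week 14 = 1), and the arm×visit
product; the treatment-effect contrast is the interaction coefficient.
Location-restricted strata subset the samples and drop the location
column. The active-vs-inactive model uses screening biopsies only
(week-14 samples are excluded before the gene filter, so their content
cannot leak in) with activity, location and anti-TNF terms. Fixed effects
only — no patient-level random effect is modelled. The clinical inclusion
rule (complete pair, active at screening) is available as
`restrict_to_active_screening` and is off by default in synthetic runs,
where the planted effect applies to every treated patient.

**Treatment-modulated call.** A gene passes when |fold change| ≥ 1.5 with
FDR < 0.05 in the combined analysis and unadjusted p < 0.05 in both the
colon-only and ileum-only analyses. "Fold change" here is the interaction
coefficient — the modelled treatment-specific effect — rather than a
within-arm paired change; this is an interpretive choice, flagged as such.

**Signature scores.** Genes of a signature are z-scored across samples;
the score is the first right singular vector of that matrix, sign-oriented
to correlate non-negatively with the per-sample mean z-score, standardized
to mean 0 / unit variance. This is a reconstruction of eigengene-style
set summarization validated behaviorally (mixture recovery r ≥ 0.9 on
synthetic data, affine- and order-invariance) rather than by numeric
identity to any particular package. Missing signature genes are dropped
with a warning if at least half remain, otherwise an error; zero-variance
genes are dropped with a warning. Paired changes are week-14 − screening
scores from the same patient and bowel segment; arm comparison is a Welch
t-test by default (`student` available). Per-patient changes are computed
on scores (not per-gene-then-scored); the per-gene route is available via
`concordance.treatment_change_per_gene`.

**Concordance.** Treatment axis: per-gene mean paired week-14 − screening
log₂-CPM change within an arm. Activity axis: the active-vs-inactive
coefficient. Pearson correlation by default (the axes are linear log₂
scales); Spearman available. The gene set can be the three-clause call
(the restriction used for the headline statistic) or all filtered genes
(the per-gene scatter variant); at the default synthetic conditions the
planted per-gene effects sit below the 1.5-fold interaction cut, so the
call is small and the all-genes mode is what the pipeline reports.

## The synthetic study

The generator defines the study conditions; its defaults are fixed, not
tuning knobs.

* **Programs.** 2000 genes with lognormal(0, 1) baseline rates; 5 cell
  types (CD8_IEL, CD8_LP, CD4_Th, CD4_Treg, MAIT) with 40 disjoint marker
  genes each at 8-fold elevation; 100 inflammation ("activity") genes
  disjoint from markers; 20 mitochondrial genes pinned at a 3% share of a
  baseline cell. Programs derive from a dedicated RNG stream of the seed,
  so the single-cell and trial datasets plant identical gene sets.
* **Counts.** Negative binomial via gamma-Poisson with var = μ + φμ²,
  φ = 0.1 for both modalities — the standard RNA-seq noise model, and the
  source of the decreasing mean-variance trend the weighting step must
  estimate.
* **Single cell.** 200 cells per type at an expected depth of 6000 UMIs
  (lognormal cell-to-cell spread, σ = 0.25); 10% of barcodes are low
  quality, split between one-fifth-depth (fails the UMI rule) and 25%
  mitochondrial share (fails the mito rule), so each QC clause is
  exercised independently. Four donors are labeled but carry no planted
  shift.
* **Trial.** 100 patients randomized exactly 1:4 (placebo:treatment);
  one screening and one week-14 biopsy per patient from the same segment,
  half colon / half ileum (the per-arm location split is an assumption —
  the design leaves it open); anti-TNF history Bernoulli(½). Mixture
  proportions are Dirichlet around a base of 25% target type; bulk
  expected counts are library × (mixture of type programs), library sizes
  lognormal around 2×10⁶. Treatment multiplies the target proportion by
  `effect_size` (default 0.5) at week 14 only.
* **Activity.** Latent severity couples to the target-type proportion
  (the population is modelled as driving inflammation) plus noise;
  SES-CD-like segment scores are 12 × severity (colon) or 8 × severity
  (ileum), rounded, thresholded at ≥ 7 / ≥ 4 for the activity label.
  Activity genes are up-regulated by `activity_fold_change` (default 3) in
  samples labeled active. Treatment multiplies week-14 severity by
  `effect_size`, so treated segments can resolve and lose the inflammation
  program — producing the planted inverse treatment/activity concordance.
  The default fold and program size are realistic for inflamed-vs-quiescent
  IBD mucosa (a program of O(100) genes at a few-fold).

**What the generator does not emulate:** read-level data, doublets,
ambient RNA, batch/chemistry effects, donor shifts, patient-level random
effects, compositional sequencing artifacts, or dropout beyond what NB
sampling produces. Passing tests therefore demonstrate correctness of the
statistical chain under its stated noise model, not robustness to every
real-data pathology.

## Problem sizes used in checks

The automated checks run the default conditions: a 1111-barcode,
2000-gene single-cell dataset; 20 independent null trials (effect size 1)
of 2000 genes × 200 samples for calibration; a four-point effect-size
curve; and one default trial for concordance. These sizes give stable
statistics (e.g. ±0.003 on a 0.05 type-I rate pooled over ~40k tests)
while keeping a full run in well under a minute of compute per stage.

## Known limitations

* The merge rule's "most similar" metric and the fold-change scale are
  reconstructions of under-specified conventions; both are configurable.
* The eigengene scorer is a behavioral reconstruction (see above).
* With heavy treatment effects the z-scoring that underlies signature
  scores absorbs part of the effect into the scale; paired deltas remain
  monotone in the true effect but are not calibrated in proportion units.
* Compositional coupling means reducing one cell type slightly raises the
  measured scores of the others; the arm comparison of the target
  signature remains the most negative by a wide margin.
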