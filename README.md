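# sigtrace

From single-cell T-cell subtype signatures to longitudinal treatment-effect
quantification in bulk RNA-seq.

## The problem

Gut-homing and tissue-retention integrins (α4β7, αEβ7) can be blocked
therapeutically in inflammatory bowel disease; the anti-β7 antibody
etrolizumab targets both. Assessing whether such a drug actually depletes a
specific intestinal T-cell population — for example CD8⁺ intraepithelial
lymphocytes — from standard clinical-trial biopsies requires a chain of
analyses:

1. **Define the population transcriptionally.** Droplet single-cell RNA-seq
   of gut tissue is QC-filtered (viable barcodes: ≥ 2000 UMIs with < 8%
   mitochondrial UMIs), normalized, clustered on a kNN graph (Leiden), and
   clusters that fail to elevate at least 30 genes at ≥ 1.5-fold over the
   rest are merged into their most similar neighbor. One-vs-rest Wilcoxon
   rank-sum tests define per-cluster markers, and the most differential
   genes (BH-FDR < 0.01, positive fold change) form signatures of at most
   50 genes per subtype.
2. **Score the population in trial biopsies.** Each signature is summarized
   per bulk sample as an *eigengene*: the first principal component of the
   z-scored expression of the signature genes, sign-oriented to track their
   mean.
3. **Quantify the treatment effect.** In a paired two-visit (screening /
   week 14), two-location (colon / ileum), 1:4-randomized design, per-gene
   treatment effects come from a precision-weighted linear model of
   log₂-CPM, `~ arm + anti_tnf + location + visit + arm:visit`, with
   observation weights from the fitted mean-variance trend (voom-style) and
   empirical-Bayes variance moderation; genes are called treatment-modulated
   when |FC| ≥ 1.5 at FDR < 0.05 in the combined analysis *and* nominally
   significant (p < 0.05) in both the colon-only and ileum-only analyses.
   Signature-level effects are paired week-14 − screening score changes
   from the same bowel segment, compared between arms with a Welch t-test.
4. **Relate treatment to disease activity.** Per-gene treatment fold
   changes are correlated with active-vs-inactive fold changes (screening
   biopsies only, SES-CD activity rule: colonic score ≥ 7, ileal score ≥ 4);
   an inverse correlation means treatment pushes the mucosa away from the
   inflamed transcriptional state.

Because clinical and single-cell data cannot be bundled, the package ships
a synthetic-data generator (`sigtrace.simdata`) that plants known ground
truth — cell types with marker programs, low-quality barcodes, a
randomized paired trial whose bulk profiles are mixtures of the cell-type
programs with a treatment-arm reduction of one target type, and an
inflammation program tied to endoscopic-activity labels — so every stage
is exercisable and testable end to end.

## Worked example

Score the planted subtype signatures on a simulated trial (100 patients,
1:4 placebo:treatment, the CD8-IEL-like proportion halved at week 14 in the
treatment arm) and fit the treatment-effect model:

```python
from sigtrace import SimConfig, simulate_trial
from sigtrace.bulkstats import DifferentialExpressionModel
from sigtrace.sigscore import score_all_signatures
from sigtrace.containers import SignatureSet

cfg = SimConfig(seed=1)            # 100 patients randomized 1:4, effect_size 0.5
study, truth = simulate_trial(cfg)

sigs = SignatureSet()
for name, genes in truth.true_markers.items():
    sigs.add(name, genes[:50])

table, comp = score_all_signatures(study, sigs)
print(comp.summary())

res = DifferentialExpressionModel.from_study(study).fit("arm_visit")
print(res.summary(top=3))
```

prints

```
signature  delta_treatment  delta_placebo   diff      t         p       fdr
  CD8_IEL           -1.465        0.04219 -1.508 -17.08 1.538e-17 7.688e-17
   CD8_LP            0.613        -0.0711 0.6841  6.744 6.291e-08 1.573e-07
   CD4_Th           0.6598         0.1158 0.5441  4.095 0.0003285 0.0003285
 CD4_Treg           0.7283      -0.005475 0.7338  5.636 2.816e-06 4.694e-06
     MAIT           0.6605        0.07143  0.589  4.846 3.002e-05 3.752e-05

Differential expression: stratum=combined, contrast=arm_visit
genes=2000, samples=200, residual df=194.0, prior df=50.49, prior variance=1.0277
FDR<0.05: 17 genes
...
```

The target CD8-IEL signature drops by ~1.5 score units in treated patients
(paired week-14 − screening change) while the placebo arm stays near zero;
the other subtypes drift slightly upward because mixture proportions are
compositional. The interaction column of the gene-level model (`arm_visit`)
is the modelled treatment-specific log₂ fold change.

The same chain is available from the shell:

```bash
sigtrace run-all --seed 1 --out out/       # simulate + all stages + report.json
sigtrace de --counts counts.tsv --meta meta.tsv --stratum combined
```

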