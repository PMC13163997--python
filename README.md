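# cernax

Integrative discovery of competing-endogenous-RNA (ceRNA) axes from
tumor-vs-normal transcriptomic cohorts — built for the oral / head-and-neck
squamous cell carcinoma setting, where a candidate axis couples a lncRNA
(e.g. an XIST-like transcript), the miRNAs it sponges, and a protein-coding
target (e.g. a ZNF662-like putative tumor suppressor).

The package is aimed at computational biologists who want the whole
multi-dataset workflow — differential expression, cross-dataset consensus,
target-prediction intersection, sign-consistent network assembly, and joint
diagnostic/prognostic evaluation — as a tested, reproducible, offline
library instead of a chain of web tools. A synthetic-cohort generator with
planted ground truth makes every stage verifiable end to end.

## What it computes

**Differential expression (per dataset).** Two-group linear models with
empirical-Bayes variance moderation. For gene *g* with residual variance
*s²_g* on *d* df, hyperparameters (*d₀*, *s₀²*) are moment-matched from the
scaled-F distribution of log *s²_g*, and the posterior variance is

    s̃²_g = (d₀·s₀² + d·s²_g) / (d₀ + d)

giving a moderated t with *d₀ + d* df. Microarray-style matrices are log2
transformed where required and quantile normalized; count matrices go
through a voom-style route (log-CPM = log₂((count+0.5)/(lib+1)·10⁶) with
precision weights from a lowess mean–variance trend). Calls use strict
|log₂FC| > 1 and Benjamini–Hochberg q < 0.05.

**Directional consensus.** A gene enters the consensus only if it is called
in the same direction in the required number of datasets and never in the
opposite direction anywhere.

**Interaction filtering.** Two target predictors (TargetScan-like and
miRDB-like dialects) are intersected, unscored; lncRNA–miRNA pairs
(ENCORI/starBase-like dialect) are kept only with CLIP-seq support; edges
are then restricted to differentially expressed endpoints.

**ceRNA network.** All (lncRNA, miRNA, mRNA) triplets with both edges
present and the sign rule direction(lncRNA) = direction(mRNA) ≠
direction(miRNA); triplets are the retention unit. Exports: SIF, GraphML,
node/edge TSV.

**Survival.** Median-split (ties → low) Kaplan–Meier screening with the
Mantel–Cox log-rank test and a single-binary-covariate Cox model (Efron
ties, Newton–Raphson, Wald 95% CI = exp(β ± 1.96·SE)).

**Diagnostics.** Mann–Whitney AUC with tie half-credit and automatic
orientation (AUC ≥ 0.5), stratified percentile-bootstrap CIs (400
resamples, adaptively reduced for tiny classes), DeLong
structural-component CIs, and repeated stratified K-fold cross-validation;
AUC > 0.8 is flagged as strong.

**Enrichment.** One-sided hypergeometric over-representation against GMT
collections, with the union of all DE mRNAs as the background universe.

## Worked example

`examples/06_full_pipeline.py` simulates the full six-dataset study shape —
four mRNA cohorts (167/45, 6/6, 5/2, 3/3 tumor/normal), one miRNA cohort
(17/3), one lncRNA cohort (8/2), predictor/CLIP tables with decoys, a
499-patient survival cohort — with a planted XIST-like → 6-miRNA →
ZNF662-like axis, and runs every stage:

```
consensus mRNAs : 15 up, 10 down
target panel    : 21 genes
network         : {'lncRNA': {'up': 0, 'down': 1}, 'miRNA': {'up': 6, 'down': 0}, 'mRNA': {'up': 0, 'down': 1}}
recovered nodes : ['XIST-LIKE', 'ZNF662-LIKE', 'hsa-mir-ax1-5p', ..., 'hsa-mir-ax6-5p']

axis report (ranked by survival significance, log-rank p, AUC):
 rank        gene  de_concordance  best_auc     hr  logrank_p  survival_significant
    1 ZNF662-LIKE               4       1.0 0.6444     0.0003                  True

enrichment hits (q < 0.05): ['HALLMARK_EMT_LIKE']
```

The 25-gene consensus is recovered exactly; the network contains all eight
planted axis members and nothing else; the Cox hazard ratio for the planted
mRNA (0.64, truth 0.65) is protective and significant; and the planted
EMT-like program is the unique enrichment hit. The other examples
(`examples/01`–`05`) exercise each stage individually.

A thin CLI wraps the library (`cernax run --config config.yaml`, plus
per-stage subcommands `simulate`, `de`, `consensus`, `targets`, `network`,
`survival`, `roc`, `enrich`).

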