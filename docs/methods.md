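# Methods

This note documents the statistical machinery, the synthetic-data model,
the numerical choices, and the known limitations of `cernax`.

## Differential expression

Each dataset is analyzed independently (no cross-dataset batch
correction; the consensus step is what enforces cross-dataset agreement).

*Scale handling.* Matrices declared `linear` are transformed as
log₂(x + 1); a heuristic (`looks_linear`: maximum above 50 and
right-skew) is available for undeclared GEO-style matrices but the
declared scale always wins. Count matrices are refused by the microarray
route and must go through voom.

*Quantile normalization.* Each column's sorted values are replaced by the
across-column mean of sorted values; ties receive the mean of the
reference values they span, so equal inputs map to equal outputs and the
operation is idempotent. Single-sample matrices pass through with a
warning.

*voom route.* log-CPM = log₂((count + 0.5)/(library + 1)·10⁶) with
library = column sum after dropping all-zero genes. The precision weight
of a gene is 1/σ̂⁴ where σ̂^{1/2} comes from a lowess fit (span 0.5) of
√(residual SD) on mean log-CPM, interpolated with flat extrapolation and
clipped at 10⁻⁴. Weights are per-gene (constant across samples), a
simplification of observation-level weights that leaves the two-group
coefficient untouched and only reweights genes relative to one another.

*Moderated fit.* Per-gene two-group (weighted) least squares; residual
df = n − 2. Hyperparameters are moment-matched on the log-variance scale:
with e_g = log s²_g − ψ(d/2) + log(d/2), solve ψ′(d₀/2) = var(e) − ψ′(d/2)
by monotone bisection (tolerance 10⁻⁸) and set
s₀² = exp(mean(e) + ψ(d₀/2) − log(d₀/2)). When var(e) ≤ ψ′(d/2) the prior
df is infinite and the pooled mean variance (the scale MLE in that limit)
is used. The moderated t uses the posterior variance
(d₀s₀² + d·s²)/(d₀ + d) and d₀ + d df, capped at the pooled residual df
(moderation cannot borrow more information than all residuals carry).
These conventions agree with Bioconductor limma 3.58 to ~10⁻⁶ on shared
fixtures, and with an independently coded brute-force reference to 10⁻¹⁰.
Features with exactly zero residual variance receive p = 1 (their fold
change is still reported). Two-sided p-values throughout; BH adjustment.

*Calls.* Strict inequalities |log₂FC| > 1 and q < 0.05; a gene at
log₂FC = 1.0 exactly is never called, however significant.

## Consensus, interactions, network

Symbols are harmonized (trim, uppercase, drop trailing dot-versions);
miRNA names are case-folded with the `hsa-` prefix kept. A direction
conflict in any dataset excludes a gene from the consensus entirely —
conservative, but concordance is the point of multi-dataset integration.
Predictor tables are ingested without score filtering (frozen column
dialects documented in `interactions.DIALECTS`); the CLIP filter defaults
to ≥ 1 supporting experiment. Triplets are the retention unit of the
network: a miRNA–mRNA edge with no sign-consistent lncRNA partner is
dropped. All outputs are sorted lexicographically so exports are diffable.

## Survival

Median split sends ties to the low group, matching the generator's
definition of the high-hazard stratum so planted and estimated hazard
ratios refer to the same contrast. The log-rank test and KM estimator are
delegated to lifelines. The Cox model is a purpose-built single-binary-
covariate Newton–Raphson with Efron tie handling (ties are certain in
day-resolution data), convergence tolerance 10⁻⁸; monotone likelihood
(e.g. all events in one arm) is flagged — converged = False, CI = (0, ∞)
— rather than raised. Wald CIs exp(β ± 1.96·SE). Multi-gene screens are
labeled exploratory; there is no multivariable adjustment by design.

## Diagnostics

AUC is the Mann–Whitney U statistic with half-credit ties, computed from
ranks; auto-orientation reports 1 − AUC with a flag when the raw value is
below 0.5, so low expression of a downregulated marker still scores as
discriminative. The bootstrap CI is stratified percentile (2.5/97.5) with
400 resamples by default, reduced to the smaller class's number of
distinct resamples (the multiset coefficient C(2n−1, n)) with a floor of
50 when a class is tiny; below 2 members per class the interval is
refused and reported as the uninformative [0, 1]. The DeLong CI uses the
structural-component variance S₁₀/m + S₀₁/n with a Wald interval clipped
to [0, 1]; perfect separation collapses it to a point and is flagged.
Cross-validation pools out-of-fold scores per repeat; for a single
monotone marker it reproduces the plain AUC exactly, which is the
intended sanity behavior, not a bug.

## Enrichment

One-sided hypergeometric upper-tail p per term, with query and sets
restricted to the supplied background (here: the union of DE mRNAs across
the expression datasets). Using the DE-derived background rather than the
genome is deliberately conservative: for a fixed overlap, enlarging the
universe can only shrink p, so genome backgrounds inflate significance.
BH across tested terms; terms without background overlap are skipped.

## Synthetic data model

The generator emulates the statistical structure of small GEO-style
two-group cohorts and a TCGA-style survival cohort:

- **Microarray**: per-feature baseline ~ U(5, 9) log2 intensity, group
  shift for planted features, i.i.d. Gaussian noise (default SD 0.5).
  Planted baselines are drawn from the central U(5.4, 8.6): a shifted
  feature whose baseline sits at the boundary of the range occupies the
  same extreme rank in both groups, and quantile normalization then pins
  it to the reference tail, erasing the shift — a real pathology of
  rank-based normalization that the fixture avoids by construction.
- **RNA-seq**: negative-binomial counts, one dispersion per run (default
  0.1, i.e. ~32% CV at high counts), library sizes U(0.5M, 1.5M), with
  the planted log₂ fold change exact in the expected counts. Because
  log-CPM is a relative measure, strongly shifted features compress
  everyone else's fold changes slightly (compositional bias) — kept, as
  real CPM pipelines share it.
- **Survival**: exponential event times; patients above the expression
  median have their hazard multiplied by the planted HR (default 0.65,
  baseline hazard 0.05/time unit); independent exponential censoring with
  per-patient rate chosen so the expected censored fraction equals the
  requested rate (default 0.5). n = 499 mirrors the evaluation cohort
  size this workflow targets.
- **Interaction tables**: all true axis edges present in both predictor
  tables and in the CLIP table (≥ 1 experiment); decoys with an exact
  shared fraction between predictors; half the lncRNA decoys carry CLIP
  count 0 to exercise the filter.

Default cohort shapes (167/45, 6/6, 5/2, 3/3 mRNA; 17/3 miRNA; 8/2
lncRNA) reproduce the class-size regime of the six public series this
pipeline is designed around, at scaled-down feature counts (300 mRNA
features by default) chosen to keep the full test suite and the
acceptance script fast while leaving enough null features for stable
hyperparameter estimation.

**The clean fixture.** Recovery guarantees (all and only planted axis
members in the network, planted mRNA ranked first, across 20 seeds) are
stated for `SimulationConfig.clean_fixture()`: effect 3.0, microarray
noise 0.3, extra RNA-seq log-noise 0.15, NB dispersion 0.02, and a larger
null universe (1000 mRNA features). Two findings shaped it: with > 10% of
features strongly shifted, quantile normalization visibly distorts null
genes (hence the larger universe rather than a larger effect), and at
dispersion 0.1 a 2-normal count cohort leaves a few-percent chance that a
planted 3-log₂ effect misses the q < 0.05 call. Under the study-like
defaults (effect 2.5, dispersion 0.1) recovery is high but not
guaranteed — which is itself a faithful property of n = 2 designs.

What the generator does **not** emulate: probe-level artifacts, batch
effects, paired-sample correlation, gene–gene correlation, and
non-proportional hazards. Passing tests therefore demonstrate the
correctness and calibration of the machinery, not robustness to those
real-data complications.

## Prioritization

The axis report ranks candidate mRNAs deterministically: survival
significance (log-rank p < 0.05) first, then log-rank p ascending, then
best AUC descending, then DE concordance count, then name. The joint
evaluation this formalizes is inherently partly narrative in practice;
this ordering is one defensible, reproducible choice and is documented as
such rather than presented as canonical.

## Numerical choices

- Trigamma inversion: bracketed bisection, 200 iteration cap, relative
  tolerance 10⁻⁸.
- Cox Newton: |β| > 30 or non-positive information triggers the monotone-
  likelihood flag; step tolerance 10⁻⁸.
- Probe collapsing: duplicate feature ids keep the row with the highest
  mean expression.
- All generators and resampling procedures take explicit seeds; pipeline
  stages derive per-stage seeds from the global seed via a stable hash,
  and outputs carry a provenance header (stage, config hash, seed) so
  reruns are byte-identical.
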