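# Methods

This note documents the models and procedures implemented in `immunoclass`,
the parameters that matter, the synthetic data-generating model, the
numerical choices, and the known limitations.

## Normalisation

`normalize_housekeeping` maps a raw counts matrix to the log2 scale using
housekeeping genes as controls, emulating panel-style housekeeping
normalisation. The per-sample factor is
$s_j = \big(\prod_{h\in HK} c_{hj}\big)^{1/|HK|}$ (geometric mean of raw
housekeeping counts; a zero housekeeping count is an error — housekeeping
controls are by construction robustly expressed), the cohort factor is the
geometric mean $m$ of the $s_j$, and each value becomes
$\log_2(c_{gj}\, m/s_j + 1)$.

Scaling happens *before* the pseudocount so the transform is exactly
equivariant to library size: multiplying one sample's counts by a constant
changes only the cohort factor $m$, i.e. the whole normalised-count matrix
by one global multiplicative constant, which row-standardised downstream
analyses ignore. A single-sample cohort reduces to plain $\log_2(c+1)$.

## Scoring

* **Cell-type / functional signature scores** are the arithmetic mean of
  log2 expression over the signature's genes present in the matrix (median
  available via `statistic="median"`). Signatures matching no gene are
  dropped with a warning and the matched-gene count is reported.
* **Immune score** is a single-sample GSEA: per sample, genes are ranked by
  expression with average ranks for ties; walking the list from the
  top-expressed gene down, the score accumulates the difference between the
  weighted in-set ECDF (steps $\propto$ rank$^\alpha$, ranks ascending in
  expression) and the unweighted out-of-set ECDF, summed over the whole
  list. Default $\alpha = 0.25$; no normalisation by gene count, so scores
  are comparable only within a fixed matrix. $\alpha=0$ reduces to the
  unweighted Kolmogorov–Smirnov running-sum integral. The score is
  rank-based, hence invariant to any strictly monotone per-sample
  transform. Only the immune arm of the ESTIMATE-style scoring is
  implemented (no stromal/purity arm).

## Classification

* **Clustering**: agglomerative clustering of samples, dendrogram cut at
  exactly two clusters. Default Ward linkage on Euclidean distances of
  row-z-scored features; complete/average linkage and correlation distance
  are available to mimic common heatmap defaults. Zero-variance rows are
  dropped before z-scoring with a warning; a matrix with all-zero pairwise
  distances is rejected as degenerate.
* **Infiltrate orientation**: the cluster with the higher mean over all
  cell-type signatures and member samples is IIH. An exact tie (possible
  only on contrived data) goes to the smaller cluster, with a warning.
* **Function labels**: each functional signature is clustered on the
  submatrix of its own genes; the cluster with higher mean expression of
  those genes is "high". The consensus rule is a strict majority of
  per-signature calls; exact ties follow the sign of the sample's mean
  z-score over all functional-signature genes (≥ 0 → FH). The alternative
  consensus — a second-level two-cluster cut on the per-signature
  mean-score matrix — is available via `consensus="cluster"`, and the
  fitted results record the agreement fraction between the two rules.
* **Stratified mode**: by default function clustering is cohort-wide;
  `function_within_infiltrate=True` reruns it separately inside IIL and
  IIH (falling back to cohort-wide with a warning when a stratum has fewer
  than 4 samples).
* No randomness enters the classification; every tie-break is
  deterministic and logged.

## Group statistics

* **Benjamini–Hochberg** step-up FDR adjustment, applied within each
  analysis family separately (one adjustment per feature panel). Note the
  step-up adjustment is not idempotent in general — re-adjusting an
  adjusted vector can only inflate it — so adjusted values are reported
  once and never re-fed.
* **Kruskal–Wallis** across the four classes: tie-corrected H, chi-square
  reference with (#classes − 1) df, BH across the tested features. Classes
  with no matched sample are dropped with a warning.
* **Differential expression** is deliberately rank-based: per gene,
  log2FC = mean(group B) − mean(group A) and a two-sided Wilcoxon rank-sum
  p (exact when the smaller group has ≤ 8 samples and the gene has no
  ties; normal approximation with tie and continuity correction
  otherwise), BH across genes, significance at adjusted p < 0.05 and
  |log2FC| > 1. This substitutes for negative-binomial Wald differential
  expression, whose dispersion-shrinkage machinery is out of scope here;
  gene counts from this method are labelled method-substituted in pipeline
  reports, and recovery (not equality with any particular count model) is
  what the tests validate.
* **Over-representation**: one-sided upper-tail hypergeometric p for the
  overlap of a hit list with each gene set (sets intersected with the
  universe first), BH across sets.
* **Preranked GSEA**: weighted Kolmogorov–Smirnov enrichment score
  (in-set steps ∝ |ranking stat|, uniform out-steps, score = maximum
  running-sum deviation), null by gene-label permutation (seeded;
  phenotype permutation is unreliable at these class sizes), NES = ES
  normalised by the mean same-sign null ES, FDR q by the positive/negative
  pooling rule. Sets with fewer than 5 matched genes are dropped; fewer
  than 100 permutations is an error (q undefined below that resolution).
  An all-zero ranking metric degrades gracefully to the unweighted
  statistic.
* **Fisher's exact test** for 2×K response-by-class tables: exact
  conditional p by full enumeration of tables with the observed margins,
  two-sided by the probability-mass rule (sum the probabilities of tables
  no more probable than the observed one). For 2×2 this is the classical
  two-sided Fisher test. Any zero margin leaves the test undefined.
* **CPS vs CPS + class**: maximum-likelihood logistic fits of
  logit P(response) = β₀ + β₁·CPS (null) and + class indicators (full);
  likelihood-ratio statistic against chi-square with df = added
  indicators. A class factor with a single observed level adds nothing
  (statistic 0, p 1). Suspected separation — non-convergence or exploding
  coefficients — is flagged and warned about, with the statistic still
  reported.

## Survival

* **Penalised Cox screening**: the Breslow-ties partial likelihood with an
  L1 penalty, maximised by cyclic coordinate descent on the local
  quadratic (IRLS) approximation, with a backtracking line search on the
  true penalised objective so iterations are monotone even near likelihood
  saturation (p ≫ n, small penalties). The penalty path is log-spaced over
  two decades from λ_max (the smallest penalty with an all-zero solution,
  computed from the null-model gradient); warm starts along the path; the
  path exits early once the active set reaches the sample count (standard
  saturation guard) and carries the last solution forward. Features are
  standardised internally and coefficients reported on the original scale.
  Ten-fold cross-validation (folds stratified by event status, seeded)
  selects the penalty minimising the mean partial-likelihood deviance
  −2[ℓ_all(β₋k) − ℓ_train(β₋k)]. Convergence tolerance is 1e-5 for path
  fits and tightenable (1e-10 reproduces an independent Newton–Raphson fit
  to < 1e-4 at λ → 0). The inner sweep kernel is numba-compiled with a
  pure-numpy behavioural reference kept alongside.
* **Maximally selected rank statistics**: candidate cutpoints are
  midpoints between consecutive sorted unique feature values inside
  quantile bounds (default 0.1–0.9, avoiding degenerate extreme splits);
  for each candidate the standardised two-group log-rank statistic
  (hypergeometric variance) is computed by a vectorised engine; the
  reported cutpoint maximises |Z| with ties to the lower cutpoint, and
  High means feature > cutpoint. Inference is by permutation of the
  feature across samples (default 10,000 permutations, seeded, +1
  correction), which accounts exactly for the cutpoint search and requires
  no approximation-validity conditions. The Miller–Siegmund
  improved-Bonferroni tail bound over the quantile window is available via
  `approximation=True` and reported alongside.
* **Kaplan–Meier / log-rank**: K-group log-rank chi-square with
  df = K − 1 and per-class KM step tables (time, at-risk, events,
  survival), via lifelines.

## Synthetic cohorts

The generator encodes the data-generating assumptions the classification
relies on, with ground-truth labels for every sample.

* Baseline log2 expression: gene means μ_g ~ N(5, 1.5), noise sd 1.0
  (housekeeping genes at μ ~ N(9, 0.3) so the counts-mode controls are
  stable). A counts mode draws negative-binomial counts with mean 2^x and
  dispersion 0.2 for normalisation testing.
* Planted structure, on top of the baseline:
  * +2.0 log2 on 65 cell-type marker genes (13 signatures × 5) in IIH;
  * +1.5 log2 on 72 functional-signature genes (9 signatures × 8) in FH;
  * +1.0 log2 on checkpoint/immunomodulatory genes (PDCD1, CD274, HAVCR2,
    IDO1, LAG3, TIGIT, TNFRSF4, BTK, TGFB1) in IIH-FH — CTLA4 is present
    but deliberately not shifted, since the source cohorts showed no class
    difference for it;
  * −1.5 log2 on CDH1 in IIH-FH (epithelial–mesenchymal component);
  * plasma IL-18 ~ N(300, 80) pg/mL, +150 in FH.
* Class proportions default to (0.30, 0.15, 0.25, 0.30) over
  (IIL-FL, IIL-FH, IIH-FL, IIH-FH); the external-cohort configuration
  (0.40, 0, 0.30, 0.30) reproduces the three observed profiles of a
  CPI-exposed validation cohort of 45 patients.
* Survival: PFS ~ exponential with log-hazard Σ β_g z_g over named genes
  (defaults: HLA-DQA1 +1; DUSP4, IRF4, CCRL2 −1, i.e. hazardous and
  protective immune features), 12-month baseline median; independent
  exponential censoring with its rate calibrated by bisection so the
  expected censored fraction matches the target (default 0.30).
* Response: CPS uniform on {0..4} (both study cohorts are CPS < 5 by
  design); P(response) = logit⁻¹(−2.0 + 0.4·CPS + 2.5·1[IIH-FH]). The
  external-cohort generator guarantees at least one responder and one
  non-responder by a deterministic seeded redraw.
* Everything derives from one integer seed; the same seed reproduces the
  cohort bit for bit.

What the generator does *not* emulate: read-level data, probe chemistry,
batch effects, gene–gene correlation beyond the planted block structure,
heavy-tailed expression noise, and class-dependent censoring. Passing
tests on these cohorts therefore demonstrates that the procedures recover
the structure they assume — not that real GEA cohorts satisfy those
assumptions.

## Problem sizes and reproducibility

The test suite and the acceptance script run the classification on 20
cohorts of 60 samples × 2000 genes, differential-expression recovery on
20 replicates of 2000 genes (200 planted, 15 vs 15 samples), null
calibration of Kruskal–Wallis, the maxstat permutation p (199
permutations per simulation), Fisher's exact test and the logistic LRT on
500–1000 null simulations each, and oracle-equivalence checks on small
instances (12-sample cutpoint toys, 40 × 3 Cox fits, ≤ 30-count
contingency tables). Pipeline runs use 30 penalty values and 1000
permutations per maxstat feature. All randomness flows from explicit
integer seeds; pipeline stages draw their seeds from one master seed by
fixed offsets, so a report's provenance block reproduces the run exactly.

## Known limitations

* The chi-square reference for the CPS-vs-CPS+class likelihood ratio is
  mildly anticonservative with four classes at n ≈ 45 (sparse class×response
  cells; measured ≈ 0.078 rejection at nominal 0.05). With the three
  observed profiles of the validation-cohort configuration the test is
  well calibrated (≈ 0.06). For small four-class cohorts, an exact or
  permutation LRT would be preferable.
* Fisher's exact test is conservative by construction on heavily discrete
  tables; its null p-values are only approximately uniform.
* The classification is cohort-relative: cluster cuts and orientations
  depend on the cohort composition, and there is no single-sample
  predictor (nearest-centroid assignment would be a natural extension).
* The DE statistic is rank-based and less powerful than count models with
  dispersion shrinkage at very small n; it is used here for its
  robustness and freedom from distributional tuning.
* ssGSEA scores are unnormalised running sums; comparing them across
  matrices with different gene universes is not meaningful.
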