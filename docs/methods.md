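# Methods

## The perturbation statistic

Expression enters on the log2(TPM+1) scale. Within each sample, genes
are ranked (average ranks for ties, ascending with expression) over a
shared gene universe: the intersection of the background network's
genes with the genes present in the reference cohort and in every
analyzed cohort. Ranks are recomputed inside this universe rather than
sliced from full-transcriptome ranks, so they are self-consistent and
comparable across cohorts regardless of each platform's total gene
count.

The reference benchmark orders genes by mean expression over the
normal reference cohort; ties are broken lexicographically by gene
identifier so the ranking is deterministic. For a canonical edge
(a, b) with a < b, the perturbation of sample s is

    p_s(a, b) = [rank_s(a) - rank_s(b)] - [ref(a) - ref(b)].

Values are stored signed — swapping the endpoints flips the sign —
and bounded by 2(G−1) in magnitude. A sample whose expression ordering
equals the reference ordering produces an exactly zero column. The
per-sample summary score `log2(mean_e |p_s(e)| + 1)` and the
differential-edge test both use magnitudes: the deviation's size, not
its direction, is the interpretable signal, while the sign is retained
for downstream flexibility. The +1 in the summary keeps the
unperturbed sample at score 0.

Rank differences are used instead of expression differences because
ranks are invariant to monotone per-sample transforms, which absorbs
platform scaling and batch distortions; this invariance is enforced by
property tests.

Differentially perturbed edges come from a per-edge two-sided
Wilcoxon rank-sum test of |p| between tumor and normal samples,
Benjamini–Hochberg adjusted across edges (q < 0.05), sorted by q then
|mean difference|. The union of endpoint genes of the significant
edges is the candidate pool for survival modeling.

## Subtype discovery

Consensus clustering follows the Monti resampling scheme: in each of
`n_resamples = 200` iterations, 80% of tumor samples are drawn without
replacement and clustered by partitioning-around-medoids on a
1 − Spearman-correlation distance computed over edge features
(perturbation values are rank-derived and heavy-tailed, so a
correlation distance on ranks is the natural choice). PAM is
deterministic here — greedy BUILD initialization plus Voronoi
iteration — so all stochasticity lives in the subsampling stream.
Consensus entries are co-clustering counts divided by co-sampling
counts.

For each k in 2..6 the empirical CDF of the consensus entries is
integrated; the optimal k is the largest one whose relative area gain
over k−1 still exceeds an elbow threshold of 0.1 (the scan stops at
the first k below it). Final labels come from average-linkage
hierarchical clustering of 1 − consensus. Known limitation: the
delta-area elbow is a blunt instrument. Under the default noise level
the relative gain at k = (true k + 1) hovers near the 0.1 threshold,
so while the separable regime and the default study condition select
the planted k = 3, individual reruns at other seeds can report 4. The
threshold, resample count, subsample fraction and k range are all
exposed.

Subtype survival differences are compared with the k-group log-rank
test (lifelines), with ties handled by the hypergeometric variance
formula; the statistic is validated against an independent risk-table
loop.

## Survival modeling

**Screening.** Per-gene univariate Cox fits use an in-house vectorized
single-covariate Newton–Raphson maximizer of the Efron partial
likelihood (all genes fit simultaneously via suffix cumulative sums;
~1000 genes in milliseconds). It is cross-checked against lifelines,
which it matches to that package's convergence precision.
Non-converged genes are flagged and assigned p = 1. Cohort p-values
are combined by Fisher's method, X = −2Σ ln p ~ χ²(2k); a gene is kept
when the meta-p falls below 0.05 **and** its coefficient signs agree
across cohorts — sign-discordant genes would make an incoherent linear
index. Zero p-values are clamped to 1e-300 with a warning. Both the
concordance requirement and the combination method are switchable.

**Benchmark.** A two-stage registry crosses feature selectors
(stepwise Cox by AIC, cross-validated lasso Cox, random-survival-forest
permutation importance, componentwise boosting) with survival learners
(stepwise Cox, lasso, ridge, elastic-net grid with l1 ratios
0.1–0.9, random survival forest, gradient-boosted Cox, supervised
component, survival SVM, PLS-Cox), 36 pairs by default; the registry
is configurable. Fitting uses the training cohort only; every cohort
including the training one is scored, and pairs are ranked by mean
Harrell C-index. Selectors that keep fewer than two genes are skipped
with a logged reason. Stepwise selection is bidirectional from the
null model under AIC. The supervised-component learner screens genes
univariately and uses the univariate coefficients as component
loadings — for z-scaled, weakly correlated screened genes the sample
covariance is near the identity, where an unsupervised first principal
component is direction-degenerate and the coefficient-weighted
combination is the leading supervised direction. PLS-Cox regresses
null-model deviance residuals (martingale residuals under a
Nelson–Aalen baseline) on expression with two PLS components, then
calibrates the components in a Cox fit. All stochastic learners are
seeded.

**The index.** The final signature is linear:
`score_s = Σ_g β_g z_g(s)` over z-scaled expression, fitted by
stepwise Cox (or a plain multivariate Cox on a fixed gene list).
Scoring drops up to 20% missing signature genes with a warning and
refuses beyond that. The packaged 11-gene signature ships as a gene
list; its published coefficients are available only as a plot, so
coefficients are refit on whatever cohort the user trains on.

**Evaluation.** Harrell's C counts a pair as usable when one member
has a strictly earlier observed event; ties in score contribute 0.5;
censored–censored and same-time pairs are unusable. Time-dependent
cumulative/dynamic AUC weights cases (events at or before the horizon)
by 1/G(t⁻) where G is the Kaplan–Meier estimator of the censoring
distribution evaluated just before the event time; controls are
samples still under observation after the horizon. Horizons with no
prior events are reported as missing. Both metrics are validated
against brute-force pair enumeration, and the AUC additionally against
scikit-survival on uncensored data (where weighting conventions
coincide).

**Stratification.** Every observed score between the 10th and 90th
percentiles is tried as a binary cutpoint; the one minimizing the
two-group log-rank p wins, with ties broken toward the median. The
minimal p is reported uncorrected for the multiplicity of the search,
matching common practice for cutpoint selection; it should be read as
a separation diagnostic, not a calibrated significance level.

## ssGSEA

For each sample, genes are walked in decreasing-expression order
(gene identifier as deterministic tie-break, making scores invariant
to storage order). The score is the running sum of the difference
between the in-set ECDF weighted by rank^α (α = 0.25) and the
unweighted out-of-set ECDF. Scores are optionally min–max normalized
over the whole matrix. Sets with fewer than two genes present are
skipped, absent genes dropped per set, both logged. Association with
the index uses tie-corrected Spearman correlation with BH adjustment;
constant score vectors are reported as missing rather than zero.

## The synthetic-data generator

The generator emulates the study design the method assumes, not real
tissue biology.

*Bulk.* Gene g has a fixed latent mean from a strictly decreasing
sequence spanning 10 down to 0 (a log2(TPM+1)-like range); samples add
i.i.d. Gaussian noise (σ = 1), so the normal ordering is stable in
expectation — the method's core premise. Perturbation is planted on
latent means, not on ranks, so it must survive the entire real
pipeline: genes are drawn until the edges incident to them reach
`frac_perturbed_edges` (10%) of the network, and every tumor sample
shifts each chosen gene by `direction × perturb_shift × intensity`,
where the per-sample intensity is log-normal around 1 and the ±1
direction vector is drawn per molecular subtype. Subtypes therefore
share the perturbed subnetwork but differ in its direction pattern.
The recorded ground-truth edge set is the full incident closure, since
a node shift genuinely perturbs every edge touching it.

*Survival.* Event times are exponential with hazard
`λ0 · exp(hazard_beta · z(burden))`, burden being the per-sample shift
magnitude standardized across each cohort's tumors (λ0 = 1/36 on a
months-like scale). Censoring is independent exponential with its rate
solved by bisection so the expected censored fraction matches
`censor_rate` (0.3) despite hazard heterogeneity. A second generator
(`simulate_prognostic`) draws expression i.i.d. standard normal and
ties the hazard linearly to five planted gene coefficients of
magnitude up to 1.5 — the testbed for coefficient recovery and
cross-cohort generalization.

*Single cell.* Negative-binomial counts (gamma–Poisson, dispersion
0.5) over ~1000 genes for a malignant and a benign epithelial cluster
plus a smaller unrelated cluster; 50 planted DEGs at |log2FC| = 2 with
alternating sign; 10 mitochondrially named genes contributing a ~5%
baseline mito fraction; 10% of epithelial cells engineered to violate
one QC bound each so the filters are exercised.

Defaults (200 genes, 600 edges, 50 normals and 50 tumors per cohort,
2 cohorts, shift 3, hazard coefficient 1.5, 3 subtypes, seed 17) are
desk-scale: large enough for the planted structure to be recoverable
with comfortable margins, small enough that the full test suite runs
in well under a minute of simulation time. What the generator does
**not** model: batch effects, platform differences between cohorts,
correlated baseline expression, ambient RNA or doublets, copy-number
structure. Passing tests therefore demonstrate that the
implementation recovers the structure the method is designed to
detect — not that the method is robust to every artifact of real
cohorts.

## Single-cell stage

QC bounds are inclusive on both ends (min/max phrasing read as closed
intervals, locked by boundary tests): 200–6000 detected genes,
500–40000 counts, ≤20% mitochondrial counts. Normalization scales each
cell to 10,000 counts then log1p. Differential expression between
labeled cell groups uses the two-sided Wilcoxon rank-sum test with
fold change `log2((mean expm1(a)+pc)/(mean expm1(b)+pc))`, pc = 1e-9,
BH across all tested genes, and thresholds |log2FC| > 0.25, q < 0.05
(0.5 for bulk). Clustering, embedding, and malignancy assignment are
consumed as labels — they are upstream of this package's scope. The
single-cell/bulk intersection requires direction concordance:
"consistently dysregulated" is read as sign-consistent.

## Numerical conventions

- z-scaling uses the sample (n−1) standard deviation; constant genes
  map to zero rows and are flagged; cohorts are always scaled
  independently.
- Duplicate expression rows collapse by per-sample maximum; duplicate
  network edges keep the maximum confidence (STRING convention);
  STRING-style 0–999 scores are divided by 1000; the confidence
  threshold is a strict lower bound (< 0.8 drops).
- All ranks are average-tie; all BH adjustments use
  statsmodels' `fdr_bh`.
- Every stochastic operation takes an explicit seed; identical seed
  and configuration give bit-identical outputs.
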