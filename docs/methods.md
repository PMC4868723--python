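# Methods

`metabconsensus` implements a consensus-based workflow for finding
metabolites that discriminate two groups of serum samples (here: pancreatic
cancer vs healthy controls) in targeted, concentration-calibrated (μM)
metabolomics panels. Three independent feature selectors are intersected
into a consensus set; the consensus is validated by random-forest
permutation importance and by per-metabolite ROC analysis with DeLong
confidence intervals. Because no public cohort accompanies the design, a
synthetic generator reproduces the study's statistical structure so that
every stage is testable end to end.

## Synthetic cohorts

A cohort is 40 cases + 40 controls over 206 metabolites on two platforms: a
commercial "kit" panel (40 acylcarnitines, 40 amino acids and biogenic
amines, 1 hexose, 10 sphingomyelins, 90 glycerophospholipids = 181
analytes) and a custom "lipids" panel (25 analytes: bile acids, fatty
acids, sterols, glycerolipids, sphingolipids).

Null metabolites are drawn lognormal — the standard model for
right-skewed, strictly positive concentration data — with the configured
concentration as the median and a geometric coefficient of variation of
30% by default. The within-group spread of the planted fold-change
metabolites is not reported anywhere, so the 30% CV is a deliberate,
fixed choice of what a practitioner would call a typical biological CV for
serum metabolites; it is configurable per metabolite via
`control_sd / control_mean`.

Three discriminative metabolites are planted at the study's reported
effect sizes:

| metabolite     | model                                   | effect            |
|----------------|-----------------------------------------|-------------------|
| palmitic acid  | lognormal, control median 270 μM        | 20-fold **down**  |
| oleanolic acid | lognormal, control median 0.05 μM       | 10-fold **up**    |
| D-sphingosine  | zero-truncated normal (only metabolite reported as mean ± SD) | cases 0.24 ± 0.04 μM vs controls 0.09 ± 0.08 μM |

At a 30% CV a 20-fold (or 10-fold) shift is ≈ 11σ (8.8σ) on the log
scale, so both fold-planted markers separate the groups *completely* with
overwhelming probability at n = 40 + 40 — exactly the degenerate-ROC
regime the study reports for palmitic acid (AUC 1.000, CI 1.000–1.000,
sensitivity = specificity = 100%). The sphingosine model yields a
population AUC ≈ 0.946, consistent with the reported 0.942.

Missing values are i.i.d. Bernoulli(0.05) per cell on null metabolites
only, so the planted effects are never confounded by missingness (both
rates configurable). Each metabolite draws from its own random substream
keyed by `(seed, column index)`: adding or removing columns elsewhere
never perturbs an existing column.

What the generator does **not** emulate: batch/instrument drift,
platform-specific dynamic ranges, censoring at a true LOD (missingness is
uniform, not concentration-dependent), inter-metabolite correlation
(columns are independent), and CA 19-9 (no generative parameters are
published for it). Passing tests therefore demonstrate correctness of the
machinery and recoverability of planted effects under clean conditions,
not performance on correlated, batch-affected real data.

## Standardization and PCA

Columns are z-scored over non-missing entries with the population (divisor
n) convention; missing entries are imputed to the column mean (0 after
standardization) for decompositions and centroid geometry only. PCA is the
SVD of the standardized matrix; loadings are orthonormal, variances
non-increasing and summing to the total, and each loading's sign is fixed
by making its largest-magnitude entry positive so outputs are stable.

## Sparse PLS-DA

The class response is a dummy matrix Y (n × 2, one column per class),
centered. For each component h the cross-product M_h = X_hᵀY_h is
approximated by a rank-1 product a_h b_hᵀ under a lasso-style penalty on
a_h, solved by alternating updates

    a ← soft_threshold(M b, λ) / ‖·‖ ,   b ← Mᵀ a / ‖Mᵀ a‖ ,

where `soft_threshold(v, λ) = sign(v)(|v| − λ)₊`. Sparsity is specified
as a per-component count `keep[h]` of retained features, the
parameterization common for this method family; λ_h is derived as the
smallest threshold retaining exactly that many nonzeros (boundary ties
resolved toward the lower column index). b is initialized from the first
right singular vector of M_h; convergence is a relative change of a below
1e-9 (500-iteration cap, error on failure). Both blocks are
regression-deflated by t_h = X_h a_h, making the latent variables
mutually orthogonal. With a two-class centered dummy response M_h has
rank 1, so the inner loop converges in a couple of iterations and the
per-component support is nested in `keep[h]`.

Defaults: H = 3 components, keep = (10, 10, 10). In the λ → 0 / keep = p
limit the algorithm reproduces dense two-block PLS (verified against an
independent implementation in the tests). An LDA on the latent variables
is included only as a sanity error-rate report; selection is the product.

## Wrapper selectors and their evaluator

Both search selectors maximize a class-separation evaluator built from the
per-feature squared standardized group-mean gap d²_j (group means over
non-missing entries). Three normalizations are available for a subset S of
size k:

* `rms` — √(Σ_S d²_j / k), the per-feature RMS centroid gap. This is the
  default of `class_distance` itself, but it is maximized by the single
  best feature: under strict hill-climbing, adding any feature to the
  current best singleton lowers the mean, so a greedy search always stops
  after one feature.
* `energy` (selector default) — Σ_S d²_j / √k. Adding a feature increases
  the score iff its d² exceeds ≈ half the current subset mean, so greedy
  search accumulates every strong feature and still stops well before the
  noise floor. This keeps the intended behavior — "larger subsets aren't
  trivially favored" — while letting multi-feature signal sets win.
* `none` — the bare centroid distance, monotone in S (useful only for
  diagnostics).

Greedy stepwise: forward from the empty set (first feature added
unconditionally, then additions only on strict increase) or backward from
the full set; ties break toward the lower column index; fully
deterministic.

Genetic search: feature-presence bitstrings; generational GA with the
published parameters (population 20, generations 20, crossover 0.6 as
single-point over randomly paired chromosomes, mutation 0.033 as
independent bit flips, roulette selection p_i = f_i/Σf with the
cumulative-probability rule q_i > r). The fitness function is not
specified in the source description, so the same evaluator as greedy
stepwise is used, which keeps the three-method consensus coherent. The
best chromosome ever evaluated is returned (reporting-level elitism only;
the population itself is purely generational). An empty chromosome scores
0 rather than erroring.

## Consensus and clustering

The default rule is the strict three-way intersection ("consensus"); a
k-of-3 vote is provided because published consensus tables can contain
rows missing from one selector. Selected metabolites are clustered as
points in standardized sample space with Euclidean distance and average
linkage (monotone merge heights); the dendrogram serializes to Newick.

In the full pipeline the selectors run per panel by default (platforms
are analyzed separately to avoid platform-specific biases) and each
method's panel results are unioned before the vote; `--pooled` runs each
selector once on the 206-column matrix. On an all-null panel the three
selectors necessarily agree on some of the same sample-noise features —
they share one evaluator and one data draw — so the per-panel consensus
carries more noise rows than the pooled one. The planted-recovery
guarantees quoted below are for the pooled application.

## Random forest

Unpruned classification trees on n-with-replacement bootstraps (leaving
≈ 1 − e⁻¹ ≈ 36.8% of samples out of bag per tree), best Gini split per
node over `mtry` candidate features drawn without replacement
(`mtry = "auto"` → ⌊√p⌋ = 14 at p = 206; the validating analyses use the
study's mtry = 20), midpoint thresholds, ties toward the lower feature
index then lower threshold. Missing values never enter the split
statistic; at build time a sample missing the split feature is routed by
drawing a replacement from the node's non-missing in-bag values (the
imputation is transient — data stay missing), and at prediction time by a
Bernoulli draw with the node's non-missing left fraction, which is the
same distribution. The desk default is 1000 trees (the published analysis
used 100 000); everything is reproducible from the config seed via
per-tree substreams.

OOB error is reported both as the majority-vote aggregate and as the mean
per-tree error; samples never out of bag are excluded with a warning.
Importance is mean decrease in accuracy: per tree, each feature the tree
actually uses is permuted among that tree's OOB samples and the increase
in the tree's OOB misclassification is averaged over all trees (features
a tree never splits on contribute exactly 0 for that tree, which is also
why the computation only permutes used features). Relative VIMP rescales
MDA so the maximum is 100%.

A note on ranking resolution: with two *completely separating* planted
markers, their Gini splits tie exactly and the MDA gap between them is
only the systematic tie-break/usage advantage of the stronger effect
(~5% relative — the same order as the 100% vs 95.3% relative-VIMP gap the
study reports at 100 000 trees). Stable rank-1 recovery of the fold-20
marker across replicate cohorts therefore needs the tree-sampling noise
on usage frequencies to drop below that gap; the validation suite runs
4000 trees per forest (a 25× downscale of the published setting), where
the fold-20 marker ranks first in 20/20 replicate cohorts. At a few
hundred trees the two perfect separators swap ranks in an occasional
cohort, as expected.

## ROC and DeLong analysis

AUC is the Mann–Whitney statistic over all case–control pairs (ties one
half; missing scores excluded pairwise). DeLong variance comes from the
placement values (per-case fraction of controls beaten and vice versa);
the 95% CI is auc ± 1.96·SE clipped to [0, 1], degenerating to [1, 1]
under complete separation. The optimal cutoff scans all midpoints between
adjacent distinct scores plus ±∞ and maximizes sensitivity + specificity,
preferring higher specificity then the lower threshold on ties. The
per-metabolite table auto-orients each marker so AUC ≥ 0.5 and records
the orientation; reported thresholds stay on the original μM scale. Two
markers on the same subjects are compared with the paired DeLong test
(covariance of placements); an unpaired variant is available. Degenerate
self-comparisons return p = 1 at delta = 0.

## Numerical and reproducibility choices

* One global seed per run; every stochastic stage (cohort, GA, forest,
  permutations) gets a `SeedSequence`-derived substream, so pipeline
  outputs are bit-identical across runs and machines.
* Standardization errors on zero-variance columns, naming the metabolite.
* Greedy/GA subset scores are computed from the additive d² decomposition
  of the centroid distance — exactly the evaluator, just factored.
* The validation problem sizes (20 replicate cohorts; 4000-tree forests;
  200 replicate cohorts for the sphingosine AUC; n = 2000 per group for
  generator calibration) are the package's chosen desk scales for each
  statistic's required resolution.

## Known limitations

* Columns are generated independently; real metabolomic panels are
  strongly correlated (e.g. within lipid classes), which inflates
  real-data consensus sizes relative to the clean-simulation guarantees.
* The GA at the published 20 × 20 scale is a weak optimizer on 206-bit
  strings; it reliably contains the strong planted features but returns
  large subsets. That is faithful to the configured search, not a bug.
* The 0.632+ *error estimator* is out of scope; the forest uses the plain
  bootstrap whose in-bag uniqueness fraction converges to 0.632.
* `class_distance` treats features as exchangeable after standardization;
  no covariance (Mahalanobis) correction is applied.
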