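# Methods

## Scope and data model

`plsnet` analyzes two-class (case = tumor = 1, control = 0) expression
matrices stored genes × samples, an interaction network given as a signed,
directed edge list, and plain gene lists. All model fitting happens on the
samples × genes orientation through scikit-learn-style estimators; the
functional API wraps those estimators for dataset-level work.

## Differential expression

Per gene, the two-sample pooled-variance Student t statistic with a two-sided
p-value (`scipy.stats.ttest_ind`; Welch's correction available via
`equal_var=False`). Genes with zero pooled variance are reported as t = 0,
p = 1 rather than NaN, so constant probes can never become candidates.
Multiplicity is controlled with Benjamini–Hochberg adjusted q-values
(`statsmodels`). BH rather than a π₀-estimated q-value was chosen because it
is deterministic and tuning-free; at a 0.05 cut-off the two rarely disagree
materially. Candidate selection requires q ≤ threshold with a *consistent
direction* in every input dataset (the up- and down-regulated lists are
intersected separately), optionally restricted to a user-supplied concept
gene list by plain set intersection.

## Hub selection

Degree is the number of distinct neighbors on the undirected simple view of
the network: antiparallel edges collapse, self-loops are dropped at ingest,
and the positive/negative/unspecified effect annotation plays no role in
topology. The default hub rule is degree ≥ 31 ("more than thirty
connections") with the threshold exposed as a parameter, since reasonable
analyses also use lower cut-offs (e.g. 20 for smaller candidate networks).
When a reference (global knowledge-base) network is supplied, a node's hidden
fraction is 1 − degree_sub/degree_ref — the share of its known interactions
absent from the candidate subnetwork — and hubs must have hidden fraction
< 0.5. "Hidden edges" has no published formal definition in the source
software; this proportion-of-missing-neighbors reading is this package's
documented interpretation, and the criterion is simply skipped when no
reference network is available. Isolated reference nodes get hidden
fraction 0 by convention. Subnetwork edges absent from the reference are kept
with a warning (degree_sub may then exceed degree_ref; the fraction is floored
at 0).

## PLS score classifier

Predictors are standardized by training mean and SD (ddof = 1); the 0/1 class
indicator is centered. One latent component is the default because the
classifier's score is a single linear form; the one-component weight vector
has the closed form w ∝ Xᵀy_c, normalized to ‖w‖₂ = 1. When more components
are requested, PLS1 components are extracted by NIPALS deflation
(w_t ∝ X_tᵀy_c, X deflated on its scores) and collapsed to the equivalent
single coefficient vector B = W(PᵀW)⁻¹q, rescaled to unit norm so the scoring
formula never changes. Zero-variance predictors are dropped with a warning
(weight 0); an all-zero-variance signature is an error.

The decision threshold maximizes Youden's J = sensitivity + specificity − 1
over candidate cutoffs: midpoints between adjacent distinct training scores
plus sentinels below the minimum and above the maximum. Ties in J are broken
toward the smallest cutoff; the decision rule is score ≥ θ → case, so a
sample exactly at the threshold is called a case. A cutoff-free "maximize the
AUC" rule is not well defined — Youden's J is the standard single-operating-
point optimum on the training ROC and is what this package implements.
Standardization, component count and the threshold rule are all exposed so
their sensitivity can be explored.

## Evaluation

Accuracy, sensitivity and specificity follow the usual confusion-matrix
definitions; undefined ratios (no positives or no negatives tested) are
returned as NaN with a warning rather than silently as 0. The ROC is the
empirical curve over all distinct cutoffs (no smoothing) and the AUC its
trapezoidal area, which equals the Mann–Whitney concordance probability with
ties counted one half — asserted against a pair-counting oracle in the tests.

Repeated-split validation draws stratified train/test partitions
(default 100 repeats, train fraction 0.5 — the least-assumptive reading of
"split into training and test sets" — both exposed as parameters), refits the
classifier *including its threshold* on the training half only, and reports
mean ± SD (not SEM) of test accuracy and AUC. Stratified splitting guarantees
both classes on both sides, so no degenerate repeats arise for the supported
sample sizes. k-fold cross-validation is stratified with shuffling, errors
when k exceeds the minority class size, and returns one test ROC per fold.

## Perturbation experiments

Both experiments pre-draw the repeat splits once per run so every
configuration is evaluated on identical resamples (paired design):

* **addition** — signature = all hubs plus k non-hubs drawn uniformly without
  replacement per repeat (k = 0 is the baseline);
* **substitution** — signature size fixed; h hubs and size − h non-hubs drawn
  per repeat (h = size is the all-hub baseline).

Per-configuration random draws are seeded by (seed, hub_count, nonhub_count),
so results are invariant to configuration order. Each configuration is
compared with the baseline by pooling all test predictions over the repeats
into one 2×2 configuration × correct/incorrect table and applying the
two-sided Fisher exact test. The pooled table is this package's documented
construction (the published design never specified one); note its power grows
with repeats × test-set size, so with many repeats even scientifically
negligible accuracy drifts reach small p-values — judgments of "no change"
for the addition experiment should therefore use the effect size (mean AUC
shift relative to its repeat-to-repeat SD), which is how the acceptance test
phrases it, with the Fisher p reserved for the substitution ladder where the
effects are large. The non-hub pool is always an explicit input: candidate
non-hub genes in real analyses, pure-noise genes in synthetic runs isolating
the topology effect.

## Synthetic data generator

The generator defines the conditions under which the pipeline's claims are
tested. Networks grow by Barabási–Albert preferential attachment (m = 2); the
first `n_hubs` nodes are designated hubs and, where attachment alone falls
short, are topped up with edges to uniformly chosen non-neighbors until each
reaches `hub_min_degree` (default 31, matching the hub rule). The graph is
connected and bit-reproducible from the seed.

Expression follows x_is = μ_i + β_i·y_s + ε_is with μ_i ~ N(0, 1);
β_i = ±hub_effect on hubs (split half up/half down, mirroring the two
published hub classes), ±nonhub_effect on a `nonhub_de_fraction` of non-hubs,
0 otherwise. The noise is N(0, noise_sd²·R) with a unit-diagonal correlation
matrix R = I + (α/c)·A_norm, where A_norm = D^(−1/2)AD^(−1/2) is the
degree-normalized adjacency (degrees floored at 1),
c = (1 + 10⁻⁶)·|λ_min(A_norm)|, and α ∈ [0, 1] is chosen so the mean
correlation over edges equals `neighbor_correlation` (default 0.3), capped at
the α = 1 positive-definiteness limit. The unit diagonal makes the marginal
noise variance exactly noise_sd², verified by Monte Carlo in the tests.
Missing entries are masked uniformly at `missing_rate`. One master seed
spawns independent sub-streams for network, baselines, effect assignment,
noise and mask, so changing the sample sizes never perturbs the network.

Default study conditions (`paperlike_config`): 29 case vs 17 control samples,
300 genes, 7 hubs of degree ≥ 31 with standardized effect 2 and no non-hub
signal — a cohort of the size the classifier targets, with all class signal
carried by hubs so the substitution experiment isolates topology. Fixtures:
`separable7` (7 informative genes with a 4-noise-SD class gap + 93 noise
genes, 20 vs 20 — perfectly separable, for exactness tests), `null`
(2000 genes, 20 vs 20, no signal, independent noise — for calibration tests;
independence keeps the across-gene KS uniformity test exact) and `paperlike`.

What the generator does **not** emulate: array-platform artifacts (dye bias,
batch effects, probe-level intensity distributions), heavy-tailed or
non-Gaussian noise, and sample-level confounding. Passing tests therefore
demonstrate correctness of the algorithms and the topology-vs-expression
phenomenon under the stated generative model, not clinical performance on
real cohorts — real-data evaluation is delegated to `plsnet
reproduce-table1`, which requires the user to supply the microarray tables
and a probe map.

## Clinical statistics

Fisher's exact two-sided p uses the probability-mass criterion (all
margin-fixed tables no more probable than the observed, with a 1 + 10⁻⁷
relative tolerance guarding float ties), delegated to scipy and verified
against exhaustive hypergeometric enumeration. A zero margin returns p = 1 by
convention. The IHC composite score is Σ intensity-grade (0–3) ×
percentage-of-tumor-cells, with percentages summing to ≤ 100 and an inclusive
positivity cutoff at 100.

## Numerical and size choices

Probe collapse keeps, per gene symbol, the probe with the highest mean
expression across all samples (ties: first in input order) — a standard,
deterministic rule. Default missing-value gene filter: > 30 % missing drops
the gene; survivors are median-imputed per gene. The smallest normalized-
adjacency eigenvalue is computed densely up to 1500 genes and by sparse
Lanczos iteration above. Simulation sizes in the test and acceptance suites
(300–2000 genes, 20 master seeds × 100 repeats for the perturbation
phenomenon) were chosen as the smallest problems at which the tested claims
are stable across seeds.

## Known limitations

* The hidden-fraction interpretation of the hub rule is one plausible reading
  of an undefined vendor notion; alternative definitions would change which
  borderline nodes qualify.
* The candidate counts of any specific historical database snapshot are not
  reproducible; concept filters are user-supplied lists by design.
* BH q-values are slightly conservative relative to π₀-adapted estimates.
* The pooled-prediction Fisher comparison treats predictions across repeats
  as independent; overlapping test sets make it anti-conservative for tiny
  effects (see the perturbation section).
* No multiclass support, no kernel/sparse PLS, no survival endpoints.
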