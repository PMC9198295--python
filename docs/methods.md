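# Methods

## Scope and data model

The package analyzes two-group (control = normal tissue, treatment =
tumor) expression cohorts on the log2 scale. Matrices are pandas
DataFrames (genes × samples); group assignments live in a `CohortLabels`
object carrying the train/test role and source accession. All tabular
outputs are TSV; gene sets use GMT; the classifier serializes to JSON.

## Ingestion

`parse_series_matrix` reads the GEO series-matrix dialect directly:
"!"-prefixed metadata lines, a tab-separated data table between
`!series_matrix_table_begin`/`_end`, quoted sample ids, `null`/empty cells
as missing. Group labels come from configurable case-insensitive substring
rules over the free-text sample metadata. Because normal tissue in these
series is described as "para-tumor" (which contains "tumor"), a sample
matching both sides is resolved by pattern specificity — the longer
matched pattern wins — and an exact tie raises.

Probe tables collapse to gene symbols by keeping, per symbol, the probe
with the highest mean expression (ties broken by probe id). If the matrix
maximum exceeds 50 the values are taken as linear-scale intensities and
log2(x+1)-transformed; the threshold is configurable. Cohorts merge on
their symbol intersection after per-dataset quantile normalization (each
sample mapped to the mean order-statistic profile); no explicit batch
correction is applied — the simplest defensible harmonization for
same-tissue arrays, and switchable off. These collapse/normalization
choices are package decisions; nothing in the underlying study pins them.

## Differential expression

The moderated t-statistic shrinks per-gene pooled variances toward an
inverse-chi-square prior fitted by moment matching on log s²
(digamma/trigamma matching; the trigamma inverse is solved by Newton
iteration). If the observed excess variance of log s² is non-positive the
prior degrees of freedom become infinite (complete shrinkage to s₀², with
a normal reference distribution). `d0_override=0` disables shrinkage and
reproduces the ordinary pooled t-test exactly — the oracle route used in
the tests. Development cross-checks against the established empirical-
Bayes implementation in R agreed to ~1e-14 on 200-gene fixtures.

Thresholds default to |logFC| ≥ 2 (inclusive) and FDR < 0.05. The FDR
default follows the stricter of the two wordings in the source study
(raw p < 0.05 is available behind `use_fdr=False`). Output ordering is |t|
descending with lexicographic gene-id tie-breaks for determinism.

## Random-forest screening

The ensemble is built from scikit-learn CART trees (Gini criterion,
`max_features = mtry`, default ⌊√p⌋) on bootstrap resamples of size n with
replacement, unstratified. The OOB curve reports, after each tree, the
misclassification rate of majority votes over trees for which a sample was
out of bag (samples not yet out of bag are excluded; the rate is 1.0 until
any sample is covered). The forest is truncated at the smallest tree count
attaining the curve's minimum.

Importance is the mean over retained trees of the total Gini impurity
decrease of each gene's splits weighted by **sample counts** — the
MeanDecreaseGini scale of the classic R implementation, on which scores
routinely exceed 1 and the 0.30 screening cut is meaningful. A normalized
(fraction-weighted) scale is bounded by the root impurity (~0.5) and would
make the cut nearly unattainable.

Two honest caveats established by the test suite:

* On strongly separable data the OOB curve often reaches its minimum at
  1–4 trees, so the truncated forest concentrates importance on very few
  genes; panels of 1–10 genes are typical at the default study scale.
* At n = 16 samples, chance label associations give noise genes
  count-scale importances up to ~1, so after label permutation several
  genes can still exceed 0.30. The screening cut does **not** control
  false selections at these sample sizes; this is a property of the
  procedure itself (the R scale behaves identically), and the
  corresponding permutation bound in the acceptance tests is left failing
  rather than papered over.

## Gene scoring

Per-gene medians are computed over **all** samples of a cohort (arms
pooled; even counts use the midpoint of the central order statistics).
Up-regulated genes score 1 strictly above their median, down-regulated
genes strictly below; values exactly at the median score 0. The test
cohort is scored against its own medians — each cohort is binarized
against itself, mirroring the study's procedure — while the feature list
and classifier weights stay frozen from training; `freeze_train_medians`
switches to deployment-style scoring with training medians.

## Neural network

Input (one unit per feature gene, binary scores) → one hidden layer of 5
logistic units → one sigmoid output = P(treatment). Weights initialize
uniform(−0.5, 0.5) under the seed; training is full-batch gradient descent
(rate 0.1) on binary cross-entropy, stopping when the loss change drops
below 1e-6 or at 10 000 epochs. No momentum, regularization or early
stopping on held-out data — the cohorts are far too small to spare
validation samples. Probabilities are clipped to (1e-12, 1−1e-12) so
outputs stay in the open interval even when saturated. The 0.5 decision
threshold is fixed, with exactly 0.5 counting as treatment. The "scores
and weights" wording of the source study is resolved as: inputs are the
binary scores; "weights" are the learned parameters. (An input variant
weighting scores by forest importance was considered and rejected as
non-canonical.)

## ROC and confidence intervals

AUC is the normalized Mann–Whitney U with midrank tie handling, which
equals trapezoidal integration of the empirical ROC (asserted to 1e-12 in
tests). The 95% CI is a stratified percentile bootstrap (resampling within
each class; default 2000 resamples); the source study does not state its
CI method, and DeLong would be the documented alternative. Classes with
fewer than 2 samples report [0, 1] with a warning.

## Over-representation analysis

p = P(X ≥ k) for X ~ Hypergeometric(N, K, n) via the stable survival
function; BH across sets; enrichment factor k/(nK/N) (observed over
expected, the common web-service definition — the source study does not
define it). Reporting filters: p < 0.01 and EF > 1.5 strict, overlap ≥ 3
inclusive. The universe defaults to all genes of the expression matrix.
Term clustering, ontology traversal and pathway topology are out of scope.

## Deconvolution

Fractions solve min‖Sf − b‖₂ s.t. f ≥ 0 (Lawson–Hanson NNLS via scipy, an
active-set method with KKT-accurate solutions) and are normalized to sum
to one — a transparent replacement for ν-SVR-based suites; no reference
signature is bundled, any non-negative marker × cell-type TSV works, and
log2 bulk matrices are linearized (2^x) before fitting since mixing is
linear in expression space. The per-sample permutation p-value compares
the Pearson correlation of fitted vs. observed profiles against gene-label
permutations: p = (1 + #{null ≥ obs})/(n_perm + 1), minimum 1/(n_perm+1),
default 100 permutations. Samples with p < 0.05 are retained for the
summaries. Wilcoxon rank-sum contrasts enumerate all C(n, n₁) assignments
of pooled midranks when n ≤ 10 (two-sided p = twice the smaller tail,
capped at 1) and use the tie-corrected normal approximation otherwise.

## Synthetic data: what it emulates and what it does not

`generate_expression` draws per-gene baselines Normal(8, 2²), per-gene
standard deviations Uniform(0.3, 1.0) and i.i.d. Gaussian noise — a
microarray-like log2-intensity model matched to the empirical-Bayes
assumptions. Planted genes (defaults: 25 up, 25 down at |logFC| = 3, arm
sizes 6 control / 10 treatment for training, 3+3 for testing, mirroring
the merged study cohorts) occupy fixed positions so train and test share
ground truth. It does **not** simulate probe-level structure, batch
effects, correlated genes, or heavy-tailed noise; passing tests therefore
demonstrate correctness of the procedures under their stated model, not
robustness on real arrays. A planted effect of 3 log2 units at these noise
levels makes cohorts nearly separable — deliberately: every downstream
stage then has an unambiguous oracle — which is also why end-to-end AUCs
sit near 1 rather than at the 0.95/0.667 level of real data.

`generate_mixtures` gives each cell type an exclusive high-expression
marker block over lognormal background (full column rank enforced, 10
redraws), Dirichlet(1) fractions, and additive Gaussian noise (default
sd 0.1 in expression units). `generate_gmt` plants one set with a chosen
overlap against a supplied list inside a synthetic universe.

## Seeds and determinism

Every stochastic component takes an explicit seed (numpy Generator).
Pipeline stage seeds derive from the global seed by fixed offsets, so a
single integer reproduces the entire run; manifests are byte-identical
across reruns.

## Problem sizes in tests and the acceptance script

Calibration uses 50 null seeds; recovery, screening, end-to-end and
enrichment checks use 20 seeds at the 1000-gene study scale; deconvolution
error uses 200 mixtures; bootstrap CIs inside the batch runs use 100–200
resamples (the CI width is not under test there). These sizes give
Monte-Carlo error comfortably below the asserted margins while keeping a
full run around a minute.

## Known limitations

* Real-cohort headline numbers (DEG counts, the 14-gene panel, the
  0.950/0.667 AUCs) depend on the original GEO data and unstated settings
  (probe collapse, importance metric, architecture) and are not asserted.
* The importance cut 0.30 is scale- and n-sensitive (see screening
  caveats); treat selected panel sizes on other data as exploratory.
* The OOB first-minimum rule is noisy at small n; on separable data it
  truncates aggressively.
* NNLS deconvolution omits the quantile normalization and support-vector
  machinery of the reference tool; recovered fractions on real bulk data
  will differ from it.
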