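# Methods

## Model and procedure

The pipeline classifies patients into cases and controls from binarized
problem-list features and ranks features by their attribution to the
classifier's decisions.

**Classifier.** A soft-margin SVM with the Gaussian (RBF) kernel
`K(x,x′) = exp(−γ‖x−x′‖²)` fitted by scikit-learn's SVC. Binary features
make linear kernels weak (XOR-like interactions between comorbidities are
plausible), hence RBF. Defaults: `C = 1`, `γ = "scale"`
(`1/(M·Var(X))`), no class weighting (the intended cohorts are nearly
balanced). These were design choices, not fitted values; every pipeline
output echoes the resolved hyperparameters in its provenance block. The
signed decision margin — not a calibrated probability — is used both for
AUC and as the quantity SHAP decomposes, which avoids an extra
calibration step that would itself need choices.

**Shapley attribution.** For one explained row `x`, the value of a
coalition `S` of "present" features is the interventional expectation

    v(S) = mean over background rows b of f(x_S, b_{∉S}),

i.e. absent features are replaced by background values and averaged. The
background is a deterministic subsample (default 16 rows, seeded) of the
current training fold, so attribution never sees held-out rows during
marginalization. Two estimators:

* `exact_shapley` — the textbook formula over all `2^M` coalitions,
  restricted to `M ≤ 15`. Used as the oracle in tests.
* `kernel_shap` — weighted least squares over coalition indicator
  vectors with Shapley kernel weights
  `π(s) = (M−1)/(C(M,s)·s·(M−s))`, efficiency
  (`φ_0 + Σφ_i = f(x)`) eliminated into the regression exactly. With
  full enumeration of proper non-empty coalitions this reproduces the
  exact values to machine precision (verified on 200 random games in the
  test suite).

Coalition sampling is stratified by size: complementary size pairs
(1, M−1), (2, M−2), … are enumerated completely while the budget allows,
then the remaining budget is split across the remaining sizes in
proportion to their total kernel mass, each sampled coalition carrying
`mass_s / count_s` so every stratum keeps its correct total weight. The
default budget is `2M + 512`, capped at full enumeration. Budgets below
`M + 2` leave the regression underdetermined; the minimum-norm
least-squares solution is returned rather than an error — it is
deterministic, satisfies efficiency exactly, and lets the elimination
loop run with small per-iteration budgets where only the *ranking* of
importances matters and misestimated features are re-ranked in later,
smaller iterations. `shap_matrix` exploits that the sampled masks depend
only on `(M, budget, seed)`: the weighted design is pseudo-inverted once
per fold and reused for every explained row, which is what makes a full
319-feature sweep affordable.

**Cross-validation and metrics.** Repeated stratified k-fold (default
k = 4, 5 repetitions; per-fold class counts within one of perfect
stratification, via scikit-learn). Held-out decision scores are pooled
over folds and repetitions; precision, sensitivity, F1 and accuracy come
from the pooled confusion matrix at threshold 0, AUC from the
Mann–Whitney statistic with midranks (constant scores give exactly 0.5).
Pooling, rather than averaging per-repetition metrics, keeps AUC
well-defined with 12-patient folds. The number of repetitions is a free
parameter; 5 stabilizes fold noise at n ≈ 48 without dominating runtime.

**Confidence intervals.** 95% percentile intervals from 200 bootstrap
rounds. What is resampled is a genuine design choice; this package uses
a cluster bootstrap over patients on the pooled out-of-fold predictions
(a drawn patient brings all its repetitions), which respects the patient
as the sampling unit and avoids refitting the model 200 times per
iteration. Resamples that lose a class are redrawn (at most 1000
attempts). All five metrics share one resampling stream so their CIs are
computed on identical resamples.

**Elimination and selection.** Each iteration removes the feature with
the smallest mean |φ| over all pooled held-out attributions; exact ties
(common with binary features) break toward the lexicographically
smallest name so runs are reproducible. Importances are computed on
held-out rows, consistent with how performance is measured. The loop
runs down to `min_features = 1`, producing `M` records. `select_optimal`
lets every record attaining a metric's maximum point estimate win that
metric (CIs are reported but not used for selection) and returns the
record with the most wins, ties toward fewer features.

**Cohort statistics.** Welch's t statistic with Welch–Satterthwaite
degrees of freedom for continuous covariates; the two-sided Fisher exact
p-value by full hypergeometric enumeration using the sum-of-no-more-
probable-tables convention (the SPSS/R convention; the "double the
one-sided p" convention is not implemented). Point probabilities are
compared with a relative tolerance of 1e-7 to absorb floating error;
tables with a zero margin get p = 1 with a warning. Percentages in the
formatted table round half away from zero; p-values print to three
decimals.

## Synthetic cohorts

`generate_cohort` emulates a small EHR case-control study: by default 23
cases and 25 controls with 319 binary features. A configurable handful
of *informative* features have class-specific Bernoulli prevalences; all
other features draw a single background prevalence, shared by both
classes, from Beta(0.6, 5) (median ≈ 0.08), matching the sparsity of
real problem lists. Optional patient metadata (a lognormal serum-marker
level per class) exercises the continuous branch of the summary table.
Features are independent by default; an optional block-correlation mode
(features within a block copy a shared latent draw with probability
`block_rho`) exists because real comorbidities co-occur, but it is off
by default and not part of the validated study conditions.

What the generator does **not** emulate: temporal structure, coding
heterogeneity beyond case/whitespace noise, missingness mechanisms, and
realistic correlation between comorbidities. Passing the planted-
recovery tests therefore demonstrates that the algorithm recovers
class-prevalence contrasts under independence — not that it would rank
real, correlated comorbidities correctly.

`binarize_problem_lists` ingests real-format long records: items are
whitespace-stripped and case-folded, optionally consolidated through a
user-supplied synonym map (e.g. mapping "depressive symptoms" and "major
depressive disorder" to "depression"), then presence is the logical OR
of a patient's records. No ICD/SNOMED normalization is attempted; the
consolidation map is deliberately user-supplied.

## Numerical choices and degenerate inputs

* Seeds: a single master seed spawns named child streams (cohort, folds,
  shap, bootstrap) via `numpy.random.SeedSequence`, so modules are
  independently reproducible and every run is bit-reproducible.
* One fold assignment is drawn per run and reused across all elimination
  iterations, so per-size metric differences reflect the feature set,
  not fold noise.
* Per-iteration bootstrap seeds derive from (bootstrap stream, feature
  count), keeping records independent of execution order on resume.
* Welch with two zero variances: t = 0, p = 1 when means agree, p = 0
  otherwise. Fisher with a zero margin: p = 1 with a warning. No
  predicted positives: precision = 0 with a warning.
* The trace TSV is written incrementally with a full-fidelity
  importances column (JSON), so an interrupted run resumes from the file
  (`run_csa(..., resume=True)`) and finishes identically to an
  uninterrupted one.

## Problem sizes used in validation

The test suite and acceptance script run at desk scale, chosen as the
smallest sizes at which each property is meaningful: the full 319 → 1
elimination sweep uses 1 CV repetition, 64 sampled coalitions,
background size 8 and 20 bootstrap rounds; planted-feature recovery uses
48 × 60 cohorts with four features planted at case/control prevalence
0.65 / 0.10 over 10 seeds; null calibration uses 200-patient pure-noise
cohorts with 20 features over 20 seeds; the Shapley oracle comparison
uses 200 random games with up to 10 features.

## Limitations

* Performance numbers from any one cohort carry wide CIs at n ≈ 48; the
  pipeline is a hypothesis-generation tool, not a validated diagnostic.
* The cluster-bootstrap CI does not propagate fold-assignment or
  refitting variability; it quantifies patient-sampling uncertainty of
  the pooled predictions only.
* Backward elimination is greedy: a feature discarded early on an
  underdetermined SHAP estimate cannot return.
* Mean |φ| importance ignores attribution sign and correlation between
  features; with strongly correlated features interventional
  marginalization can produce off-manifold evaluation rows.
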