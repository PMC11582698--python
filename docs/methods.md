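# Methods

This note documents the model behind each stage of the audit, the
parameters that matter, the numerical choices, what the synthetic study
does and does not emulate, and known limitations.  It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Problem setting

The object under audit is a fixed prediction model M scoring tabular units
(e.g., patient encounters) for a binary outcome.  The evaluator supplies an
evaluation dataset, a set of subgroup-defining features W (which may
overlap with the model's inputs or not), a per-row loss ℓ, and a
performance metric (AUROC throughout).  The question is whether there exist
W-definable subgroups on which M performs materially worse than its
average, without requiring the subgroups to be enumerated in advance.

## Stage 1: worst-case subsets and the stability curve

For a subset fraction α ∈ (0, 1], the uncertainty set U_α contains every
subset of the W sample space with probability mass α under the evaluation
distribution.  The audit targets

    sup_{S ∈ U_α}  E[ ℓ(M(X), Y) | W ∈ S ].

**Plug-in estimator.**  The conditional loss E[ℓ | W] is estimated by
regressing the realized per-row loss on W and ranking rows by the fitted
value; the worst subset of size ⌈αN⌉ is the top-α fraction.  This is the
direct empirical realization of the supremum: any W-definable subset is a
union of W-cells, and at fixed size the mean conditional loss is maximized
by taking cells (rows, at the granularity of the estimate) in decreasing
order.  A debiased/orthogonalized estimator of the same functional exists
in the stability-analysis literature; the plug-in form is used here because
it is what the downstream phenotype stage consumes (a concrete membership
vector).

**Cross-fitting.**  The regression (histogram gradient boosting by
default; random forest via `estimator="rf"`) is 5-fold cross-fitted: every
row is predicted by a model that never saw it.  Without this, rows with
noisy high realized loss would be selected for having been overfit, not for
belonging to a genuinely hard region.  Predictions are clipped at 0
(losses are nonnegative).

**Loss.**  The per-row loss is log loss by default — the natural proper
scoring rule for a risk score in [0, 1] — with scores clipped to
[1e−12, 1 − 1e−12]; Brier score is available.  The choice matters only
through the ranking it induces on rows; both penalize confident mistakes.

**Stability curve.**  For each α on a grid (default 0.05 to 1.00 in steps
of 0.05) the subset AUROC is reported with a percentile bootstrap CI
(default 100 row-resamples *within* the fixed subset; the subset is not
re-identified per resample, so the band reflects sampling noise of the
metric, not of the selection — re-identification variance is an open
choice and would widen the bands).  Single-class resamples are redrawn up
to 100 rounds.  Worst subsets are nested across α by construction, and
their mean conditional loss is non-increasing in α.

**Choosing α.**  With a reference threshold (an accepted model's
performance, a standard-of-care value), the working subset is the largest
grid α whose point estimate falls below it.  Without one, the fallback
maximizes Cohen's d between per-row losses inside vs. outside the worst
subset over the grid — the subset size at which the selected region is
most cleanly separated in loss.  Point estimates, not CI bounds, drive
both rules.

## Stage 2: stable rule phenotypes

The worst subset is only a bag of row indices; the audit needs a
communicable description.  Membership (in worst subset vs. not) is treated
as a classification target over W, learned with a stabilized rule
extractor in the SIRUS tradition:

- numeric features are discretized to q = 10 empirical quantile cutpoints
  (so identical split thresholds recur across trees and rules can be
  recognized as equal); binary/categorical features split on category.
- 500 trees of depth ≤ 3 are grown on bootstrap samples with random
  feature subsets (`sqrt` of the feature count per split).  Depth 3 bounds
  phenotype degree at three features.
- every root-to-node path (internal prefixes included, both split
  polarities) is canonicalized into a phenotype — literals sorted,
  duplicate literals merged, same-feature numeric bounds collapsed to one
  interval, binary `!=` rewritten to `==` of the other category — and
  counted at most once per tree.
- paths appearing in at least a fraction p₀ of the trees form the rule
  set.  Stability across independently grown trees is the selector; the
  shipped default p₀ = 0.022 follows the cross-validated value of the
  clinical audit this tool models.  `select_p0` implements the
  cross-validated alternative: it scores each grid p₀ by k-fold CV AUROC
  of the rule-set membership score (mean over rules of the
  inside/outside-condition membership rate; empty rule sets fall back to
  the training prevalence, i.e., chance discrimination) and returns the
  largest p₀ within one standard error of the best — a parsimony
  preference over a log-spaced grid.

Trees use unweighted impurity despite membership prevalence α: with
N ≥ 10⁴ and α around 0.05–0.25 the positive class is ample, and the
frequency threshold, not the class weighting, is the effective selector.
The original SIRUS post-treatment that removes linearly redundant rules is
replaced by canonical-key deduplication, because this pipeline consumes
rule *conditions* as candidate subgroups rather than aggregating rule
responses into a regression.

## Stage 3: the statistical filter

Each candidate phenotype is evaluated on the full evaluation frame:

- **Bootstrap.**  100 with-replacement resamples of the member rows;
  within-subgroup AUROC per resample; percentile 2.5/97.5 CI (widened to
  include the point estimate in the rare case the point falls outside).
  The bootstrap SD serves as the standard error of the metric.
- **Test.**  One-sided z-test of "subgroup AUROC < threshold":
  p = Φ((boot mean − threshold)/boot SD), with the degenerate SD = 0 case
  mapping to p ∈ {0, 1}.  Using the bootstrap SD as the SE is an
  approximation (it ignores the selection of candidates by the same data);
  the exchangeable-null experiment below measures its practical error
  control.
- **Multiplicity.**  Holm–Bonferroni step-down across all candidates
  evaluated in one call (rule candidates and slice candidates form
  separate families, mirroring their separate pipelines); rejection
  requires adjusted p < 0.05.
- **Effect size.**  Cohen's d (pooled-SD form, sample variances) between
  cross-fitted conditional losses inside vs. outside the subgroup, gated
  at d ≥ 0.4.  Conditional rather than raw losses are used because the
  quantity of interest is the systematic W-explainable loss elevation, not
  per-row noise.  A pooled SD at rounding-noise scale raises a degenerate
  error instead of producing an inflated ratio.
- **Size.**  Findings need at least `min_n` members: 100 for rule
  candidates (configurable; rule subgroups of a few hundred members are
  the practical floor for a meaningful AUROC CI), 400 for the slice
  baseline (its customary setting).

Findings are reported worst-AUROC-first.  Candidates whose membership
contains a single outcome class are skipped with a warning and excluded
from the Holm family.

## Slice-search baseline

The exhaustive comparator enumerates every degree-≤2 EQ-conjunction over
binary/categorical features (numeric features are decile-binned first) and
pushes all of them through the *same* test battery with min_n = 400 and
d ≥ 0.4.  The original comparator's lattice search with α-investing is
deliberately replaced by full enumeration plus the shared battery: the
comparison is then about search strategy (stable rules vs. exhaustive
enumeration), not about two different statistical filters.  Rule findings
of degree ≤ 2 are by construction members of the enumerated slice
universe.

## Subgroup similarity embedding

To compare findings from both routes, subgroup indicator columns
(N × J binary) are regressed on the cross-fitted conditional loss with a
2-component PLS (scikit-learn NIPALS, mean-centering, no variance scaling
— indicator columns share a scale).  Each subgroup's row of the X-block
loading matrix is its 2-D coordinate; cosine similarity between rows
measures relatedness (overlapping membership and similar loss association
align directions).  The sign of each component is fixed by making the
largest-magnitude entry of its weight vector positive, so embeddings are
deterministic; pairwise cosines are invariant to that convention.  The
first weight vector is proportional to the centered cross-covariance
Xᵀy.  Coordinates are interpreted qualitatively (which findings cluster),
never metrically.

## Learning-curve diagnostic

For a confirmed finding, the diagnostic asks whether the gap is
correctable by targeted data collection: hold the non-subgroup training
data fixed, add s rows sampled without replacement from a subgroup pool,
refit (any `Trainer`; a logistic trainer is included), and record subgroup
and full-population AUROC on the evaluation set, averaged over 10
repetitions with 95% normal-approximation CIs (mean ± 1.96·SD/√reps, over
the subgroup-data draws only — not over evaluation resamples).  Size 0 is
the exact baseline model with no resampling variance.  A rising subgroup
curve indicates underrepresentation; a curve pinned at 0.5 indicates the
outcome is not learnable from the features inside the subgroup (as with
coin-flip label noise).

## The simulated study

The generator emulates a minimal, fully-specified audit scenario:
d = 10 iid Rademacher (±1) features; coefficients β drawn per replication
from 0.5·N(1, 0.5²) + 0.5·N(−1, 0.5²) (mean 0, variance 1.25);
Y ~ Bernoulli(σ(Xᵀβ)); a well-specified logistic target model fit on
50,000 clean samples; a 10,000-sample evaluation set whose labels are
flipped with probability 0.5 inside the slice X2 = −1 ∧ X3 = 1 (analytic
mass 0.25).  Inside the faulted slice the label is a fair coin independent
of the features, so the target model's within-slice AUROC converges to
0.5 while the clean region stays near its nominal discrimination — a
strong, unambiguous planted fault.

**Recovery experiment.**  50 independent replications; in each, both the
rule pipeline and the slice baseline run end-to-end and a method succeeds
if one of its reported findings has an evaluation-set membership vector
identical to the planted slice's.  Membership equality is the primary
criterion because it is robust to syntactically different but semantically
identical rules; canonical-key equality and planted-slice containment are
logged alongside for sensitivity.  Within trials the subset fraction is
chosen by the maximum-effect-size rule and the test threshold is the
full-evaluation-set AUROC point estimate (no external reference model
exists in the simulation); p₀ stays at the 0.022 default — on this task
the cross-validated selector lands at the smallest grid value and keeps
the same planted rule, so it changes nothing but runtime.  Accuracies are
reported with 95% Wilson score intervals.

Because the planted fault is overwhelming at these sample sizes (subgroup
AUROC ≈ 0.5 against a threshold near 0.85–0.97, with ≈ 2,500 members),
both methods recover the slice in essentially every replication under this
configuration; the recovery rates printed by `scripts/acceptance.py` are
computed, never assumed.

**What the generator does not emulate:** correlated or high-cardinality
features, multiple overlapping faulted subgroups, partial (milder) faults,
calibration drift, and covariate shift.  Passing the synthetic suite
therefore demonstrates mechanism correctness, not field performance on
real clinical data.

**Null control.**  A separate experiment measures false-discovery
behavior.  Two regimes must be distinguished:

- *No planted fault, W = the model's inputs.*  This is **not** a null:
  conditioning on a strong-coefficient feature value removes that
  feature's contribution to discrimination, so slices genuinely have
  within-slice AUROC below the pooled value and genuinely elevated
  conditional loss.  Findings in this regime are true performance
  disparities of a well-specified model, and the pipeline reports them in
  most runs.
- *Exchangeable null (the implemented control):* audit features drawn
  independently of scores and outcomes, no fault.  Every slice is then a
  random subsample whose true performance equals the pooled performance,
  so any finding is a false positive.  `null_control_experiment` runs 100
  seeded replications of the full pipeline in this regime at a reduced
  problem size (n_train 20,000, n_eval 4,000, 200 trees — chosen so 100
  replicates fit in a few minutes) and reports the fraction of runs with
  at least one finding; the suite asserts it stays within the soft 15%
  bound appropriate for the approximate bootstrap z-test.

**Scalability sweep.**  `scalability_experiment` times both methods as the
feature count grows through {25, 50, 250, 500, 2500, 5000} (five trials
each).  Runtimes are reported, never asserted — they are
hardware-dependent; the structural expectation is that exhaustive slice
enumeration grows quadratically in feature count while the rule pipeline
does not.

## Numerical choices and degenerate inputs

- AUROC is the Mann–Whitney statistic with 0.5 tie credit; single-class
  samples raise a typed error rather than returning a sentinel.  The
  bootstrap uses an O(B·m) tie-group counting identity (resampling never
  creates new score values), exact including cross-class ties.
- All randomness flows from named integer seeds through spawned
  `SeedSequence` streams; no global RNG state.  Derived seeds stay below
  2³¹.  Experiments are bit-reproducible given their master seed (wall
  clock timings aside).
- Worst-subset ties at the cutoff break by ascending row index.
- Rows with missing values in any subgroup feature are dropped at load
  with a logged count; imputation is out of scope.
- Categorical values compare by string form end-to-end, making in-memory
  frames and CSV round-trips consistent.

## Limitations

- Only subgroups represented in the evaluation data can be found; a
  subgroup absent from the data is invisible to any resampling-based
  audit.
- The bootstrap-z test is approximate and the candidates are selected by
  the same data that tests them; the Holm correction is applied within,
  not across, discovery routes.  P-values should be read as strong
  screening evidence, not calibrated error statements.
- The plug-in worst-subset estimator is not debiased; at small α and
  small N its subsets chase estimation noise (the cross-fitting mitigates,
  the stability curve's CI widening signals it).
- Encounter-level evaluation only; alert-level metrics (precision/recall
  over time) and other shift types are out of scope.
- Hierarchical structure between features (e.g., diagnosis-code trees) is
  not exploited; redundant findings over related features are reported
  separately.
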