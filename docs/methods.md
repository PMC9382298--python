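# Methods

This note documents the statistical machinery, the defaults, and the
choices made where the problem left the design open. It states no
empirical result the test suite or `scripts/acceptance.py` does not itself
compute.

## Variables and discretization

All modelling is on categorical variables. The dictionary
(`build_variable_dictionary`) holds 25 variables: sex and age (background,
tier 0), 22 baseline factors (tier 1) and the new-onset diabetes outcome
(tier 2). Insomnia is tabulated in the published baseline cross-tabulation
but was not part of the published network; it is kept in the count table
(`GBCS_COUNTS`) and excluded from the dictionary.

Raw-measurement bands follow the printed cut-offs. Where the printed
notation leaves a boundary ambiguous, bands are half-open with the upper
band's cut-off taking precedence: BMI 30.0 → "≥30.0", heart rate 60 and 99
→ "60–99", age 65 → "≥65". The IFG band is closed at both ends
(5.6 ≤ FPG ≤ 6.9 mmol/L). Waist circumference is cut at ≥90 cm for men and
≥80 cm for women. The outcome rule is: follow-up FPG ≥ 7.0 mmol/L, or
physician-diagnosed diabetes, or initiation of hypoglycemic medication or
insulin during follow-up; a record with none of the three sources is
flagged incomplete. Exclusion (baseline diabetes, type 1 diabetes,
incomplete) removes the union of the flags, so overlapping flags are not
double-counted and the filter is idempotent. Category labels are matched
case-insensitively after trimming; an unknown label is an error, not a
missing value — dictionary drift should fail fast.

## Structure learning

**Score.** Default is BIC: Σᵢ [loglik(Xᵢ | Pa(Xᵢ)) − (log n / 2)·qᵢ(rᵢ−1)],
with qᵢ parent configurations and rᵢ child categories; BDeu (imaginary
sample size 1) is available by flag. BIC is prior-free and the common
default for score-based averaging. Zero-count parent configurations
contribute zero log-likelihood but still count toward the penalty.

**Search.** Hill climbing over add/delete/reverse moves, starting from the
whitelist-only graph. Family scores are cached by (node, parent set), so
each candidate move costs one lookup or one `bincount`. Moves that violate
the blacklist, remove a whitelisted arc, or create a cycle are never
considered. Ties are broken by move type, then lexicographic
(parent, child) — the search is deterministic, and the `seed` argument is
interface-only. A move is accepted only if it improves the score by more
than 1e-9, so the accepted-move score sequence is strictly increasing and
termination is guaranteed.

**Constraints.** The tier blacklist forbids every arc into a background
variable and every arc from a later tier into a strictly earlier one (so
the outcome is always a sink). The packaged whitelist encodes four
prior-knowledge arcs: family history → IFG, drinking → HDL-C, waist
circumference → hypertension, smoking → BMI.

**Structural EM.** With missing cells, the package alternates: (M) hill
climbing plus Laplace CPT fitting on the current completed data; (E)
re-drawing each originally-missing cell from its full conditional given
the row's current other values — which reduces to the cell's own family
times its children's families. Default `em_mode="sample"` draws from the
conditional (posterior sampling), producing the concrete completed dataset
that every later stage consumes; `em_mode="map"` takes the posterior mode
for a deterministic variant. The classical expected-sufficient-statistics
E-step is deliberately not offered: it yields no completed dataset, which
the downstream stages require. Rows with several missing cells are updated
one variable at a time per iteration (a systematic Gibbs scan).
Convergence: relative score change below 1e-4, at most 20 iterations
(non-convergence returns the last iterate with a warning).

**Bootstrap averaging.** B resamples of size n with replacement (default
B = 200); one network per resample (structural EM if the resample has
missing cells, hill climbing otherwise); directed-arc frequencies over the
B networks form the arc-strength table. The averaged network keeps arcs
with frequency strictly above the threshold (default 0.6, a literal
reading of "higher than 60%"). If both orientations pass, the more
frequent wins; exact ties drop the edge. A residual cycle (possible in
principle after direction resolution) is broken by removing the weakest
arc in the cycle, with a warning. In the packaged pipeline the data are
completed once by structural EM before bootstrapping — matching the
published sequence (initial structure by structural EM, then bootstrap "on
the dataset") and keeping the bootstrap loop cheap.

**Curated edits.** The packaged list removes age → family history, WC →
education, education → family history, IFG → physical activity, diabetes →
TG and drinking → LDL-C, and re-orients lipid-lowering drugs → TG to TG →
lipid-lowering drugs. Removals of absent arcs warn and skip; a reversal
that would create a cycle is an error naming the cycle.

## Parameters and inference

CPT entries are Dirichlet posterior means, (count + α)/(total + α·r), with
α = 1 (Laplace) by default: "Bayesian parameter estimation" with a
guarantee that every entry is strictly positive, which exact inference
needs. α = 0 gives maximum-likelihood frequencies (unseen configurations
fall back to uniform). Families are counted over rows fully observed for
that family (available-case), unbiased under MCAR; the pipeline fits on
the structural-EM completed dataset anyway.

Posteriors are computed by variable elimination with a greedy min-degree
ordering; evidence is applied by slicing factors before elimination, and
evidence with probability zero raises an error rather than returning NaN.
A sink node queried given all its parents short-circuits to its CPT row.
`posterior_brute_force` (full-joint enumeration) is retained as the test
oracle and agrees to 1e-9 on random networks up to a ~4,096-state joint.

The post-test table enumerates all configurations of the target's Markov
blanket (2³ = 8 rows for the diabetes model). Confidence intervals: the
published table's CIs are implausibly narrow for ~600 exposed cases and
their method is unstated, so two labelled interpretations are offered —
`bootstrap` (default): percentile 2.5/97.5 over 200 cohort resamples with
parameters refitted on the fixed structure; `cv`: min–max across 5
cross-validation training folds.

Arc signs compare P(child in its top category | parent level) across
ordered parent levels, with the child's other parents averaged at their
model marginals: strictly increasing → positive, strictly decreasing →
negative, otherwise non-monotone. "Top category" is the last label in the
declared category order, which is therefore part of the variable
dictionary's contract.

## Evaluation

Folds are stratified on the outcome (seeded `StratifiedKFold`), so each
validation fold is a 20% hold-out with near-global prevalence. Per fold,
the full pipeline re-runs on the training 80% (structure re-learned;
`fixed_structure` skips that), risks are predicted for the validation
rows — via the Markov blanket when fully observed, exact inference over
the observed cells otherwise — and the threshold maximizes the Youden
index **on the validation fold**, which is the published procedure;
`threshold_from="train"` gives the methodologically cleaner variant. AUC
is the Mann–Whitney concordance probability with ties counted ½
(identical to trapezoidal ROC integration). Across-fold 95% CIs are
mean ± 1.96·SD/√k.

Stepwise logistic selection treats each categorical variable as one dummy
block and greedily minimizes AIC (forward from the intercept or backward
from the full model). Forced-entry logistic fits exactly the given
predictors; `interactions=True` adds all products of dummy columns, which
saturates the design for binary predictors. Perfect separation falls back
to a ridge-stabilized fit (CIs omitted) with a warning.

## The synthetic cohort generator

The generator is an honest stand-in for the non-deposited study data, not
a re-creation of it. What is pinned to published values: the cohort size
(15,934; raw 18,105 with 2,123 + 48 exclusions), every variable's marginal
category frequencies, the outcome CPT (the eight published post-test
probabilities, e.g. 0.275 for hypertension + IFG + raised WC; the
apparently mistyped CI of the second row is ignored and the point estimate
0.043 used), the per-variable missingness deficits (MCAR), and the arc
list recoverable from the published description with its printed signs —
including the two explicitly non-monotone effects (former smokers shifted
toward higher BMI, current smokers lower; overweight raises and obesity
lowers the odds of a high waist-to-hip ratio).

What is constructed by documented heuristic: every intermediate CPT.
Children respond through a cumulative-logit (proportional-odds) curve; a
monotone arc contributes a linear shift of ±0.8 on the logit scale across
the parent's full range (odds ratio ≈ 2.2), non-monotone arcs contribute
their stated level-specific shifts, and the thresholds are solved by 1-D
root finding (`brentq`) against the exact parent joint (computed by
variable elimination on the partially built model) so each node's marginal
hits its published value. Nodes with no described arcs are independent
roots. Consequences: the generator's joint dependence beyond
marginals + outcome CPT + arc signs is an assumption; a green structure
or calibration test establishes that the pipeline recovers this stated
world, not that it would reproduce the original cohort's joint
distribution. The published real-data performance numbers (AUC 0.746,
sensitivity 0.727, specificity 0.660, the stepwise variable lists and
odds ratios) are accordingly not targets anywhere in the suite.

## Numerical choices and degenerate inputs

* Bootstrap resample size = n (standard nonparametric bootstrap).
* Hill-climb acceptance epsilon 1e-9; CPT row normalization checked to
  1e-9; fixture CPT cells floored at 1e-12 before renormalization.
* Youden threshold candidates are the observed score values; rule is
  score ≥ threshold → positive; ties prefer the higher-specificity
  (larger) threshold. Constant scores give J = 0, AUC = 0.5.
* Empty cohorts pass through exclusions; zero-row data cannot be scored;
  a fold containing a single outcome class warns (AUC undefined there).
* One global seed expands to per-stage seeds as
  (seed·1,000,003 + 7,919·stage) mod 2³¹.

## Known limitations

* Structural EM with posterior-sampling E-steps is stochastic; two runs
  differ unless seeded, and the completed dataset is a single imputation,
  not a multiple-imputation ensemble.
* The averaging direction-conflict rule (keep the more frequent
  orientation, drop ties) is one of several defensible conventions.
* No constraint-based or exact structure search, no continuous or hybrid
  nodes, no survival-time modelling (onset is binary over the follow-up
  window), and no approximate inference — the target networks are small
  enough for exact methods throughout.
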