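# Methods

This note documents the models, defaults and design choices behind
`adbn`, and what the synthetic-data experiments do and do not establish.

## Problem setting

The package classifies Alzheimer's disease severity from heterogeneous
subject-visit tables. Severity is indexed by the Clinical Dementia Rating
(CDR), an ordinal score in {0, 0.5, 1, 2, 3}. In the cohorts this design
targets, no subjects occupy the severe category and few occupy the
moderate one, so the working target has three classes: normal (0), very
mild (0.5) and mild/moderate (1 or 2 merged). Encountering CDR = 3 is
treated as out of support rather than silently binned. Clinical diagnosis
(HC / MCI / AD) is deliberately *not* the target; instead its Pearson
correlation with CDR is computed as a validation step, since CDR is the
more objective severity measure.

All analysis is complete-case: missing values are a single sentinel and
are never imputed. The longitudinal structure (visits BL, M18, M36, M54)
yields three analysis groups — baseline-complete plus later-complete
subjects (group 1), subjects complete at both baseline and at least one
later visit (group 2, one earliest-complete later record per subject) and
subjects complete at all four visits (group 3). When several later visits
are complete, the earliest is used, which maximizes consistency of the
time separation across subjects; the choice is a package convention.

## Discretization

Continuous features are discretized against the merged CDR classes with
the CAIM criterion, `(1/n) Σ_r max_r²/M_{+r}` over the class-by-interval
quanta matrix. Candidate boundaries are midpoints of consecutive distinct
sorted values; the greedy search adds the best candidate while the
criterion strictly improves or while the scheme has fewer intervals than
classes; ties break toward the smaller cut point so results are
deterministic. Features without clinical conventions get at most 3
intervals (the number of CDR classes). Intervals are left-open /
right-closed with infinite outer bounds, so schemes learned on the
development set are total on unseen test values; a value exactly on a cut
belongs to the lower interval.

Fixed conventions: CDR as above; ApoE keeps its five genotypes
(ε3ε2, ε3ε3, ε4ε2, ε4ε3, ε4ε4); MMSE uses the common clinical bands
24–30 / 19–23 / 10–18 / 0–9. The MMSE cut points are a configurable
stand-in — the bands are standard, but other conventions exist.

Schemes are always fitted on the development partition and applied frozen
to test data; no test row influences a cut point.

## Feature selection

Three plug-in entropy filters (base-2 logs, no smoothing) score each
discretized feature against the target: information gain, gain ratio and
symmetrical uncertainty. Under k-fold cross-validation (default 10), each
fold ranks all features on its training portion; the features whose
median rank across the three filters is among the `keep` smallest
(default 8) count as selected in that fold, and the final set is the
features selected in 100% of folds.

Two design points deserve emphasis:

* **Median-rank aggregation.** CAIM's forced growth to the class count
  can isolate a tiny class-pure tail interval on an *uninformative*
  feature. Such a split has both small IG and small attribute entropy, so
  its gain ratio stays at a non-vanishing value (~0.1) no matter how
  large the sample — a known small-split pathology of the gain ratio. A
  rule that requires joint top-k membership in all three filters then
  permanently excludes genuinely informative low-gain features (age,
  ApoE) in favour of lucky noise splits. The median rank across the three
  filters is robust: a single aberrant filter can neither promote nor
  demote a feature. The strict three-way intersection remains available
  via `select_features(combination="intersection")`.
* **Significance gate.** Cross-validation folds share most of their rows,
  so sampling noise is nearly constant across folds and the "luckiest"
  noise feature would otherwise be stably top-ranked in every fold. A
  feature is therefore only eligible in a fold if its G² independence
  test against the target (G² = 2·N·ln2·IG, df = (r−1)(c−1)) clears a
  Bonferroni-corrected threshold α/|features| with α = 0.05. Informative
  features pass this gate by ~30 orders of magnitude; pure-noise cohorts
  end with an empty stable set in ~90% of runs.

## Class balancing

SMOTE runs on the discretized development data. Distances on mixed codes
are Euclidean over ordinal codes treated as integers plus a per-mismatch
penalty of 1 for nominal codes; synthetic continuous/ordinal coordinates
are convex combinations `x + u(z − x)` (u uniform), ordinal results are
snapped to the nearest valid code, nominal coordinates take the majority
value among the k neighbours (ties keep the seed record). Default k = 5.
Every class is raised exactly to the majority count; original rows are
untouched and synthetic rows carry an `is_synthetic` flag, so balancing
is reversible.

Placement relative to cross-validation is a policy switch: the default
balances inside training folds only during the scoring-function CV (no
leakage into validation folds); `paper_mode=True` balances the whole
development set before CV, which mirrors a common published workflow but
yields optimistic CV loss estimates. The final model is always trained on
the balanced full development set. Severity classes with a single record
cannot be interpolated; the pipeline leaves them at their observed count
(the low-level API raises by default).

## Bayesian-network learning

Structures are learned by deterministic hill climbing over single-edge
additions, deletions and reversals, starting from the required-edge
graph, with a family-score cache so each move rescores only the changed
families. Constraints: required edges (never removed), forbidden edges
(never added), and tier ordering — edges may not point from a later tier
to an earlier one. The default tiers encode the clinical prior that
predisposing factors {age, ApoE} may influence the imaging biomarkers
{GM, WM, CSF, PiB-PET}, which may influence CDR, which may influence the
cognitive assessments {MMSE, LMIR, LMDR}; edges within a tier are free.

Four decomposable scores (natural logs throughout):

* **K2** — Cooper–Herskovitz marginal likelihood, Dirichlet(1,…,1) rows.
* **BDe** — equivalent sample size `ess` (default 10, configurable; the
  value is a convention, not an estimate) spread uniformly over the
  family's joint configurations; satisfies score equivalence (covered-edge
  reversals leave the score unchanged).
* **mBDe** — implemented as BDe with data-adaptive row priors: each
  observed parent row receives prior mass `ess·N_j/N`, uniform over child
  states. This is an interpretation of the "modified BDe" family; the
  exact prior is not standardized.
* **BIC** — maximized multinomial log likelihood minus `(d/2)·log N`,
  `d = (r−1)·q` free parameters per family.

The scoring function used for the final model is chosen by k-fold
cross-validated log-likelihood loss (negative mean per-record log joint
probability) on the development set, then frozen before the test set is
touched. CPTs for prediction are fitted with Laplace smoothing 1 (scores
use raw counts — the Bayesian scores embed their own priors); unseen
parent configurations get the uniform row.

Posteriors come from exact variable elimination (eliminating hidden
variables in topological order), verified against full joint enumeration
to 1e-10. Hard predictions take the posterior argmax with ties broken
toward the more severe class — the clinically conservative direction.
Arc strengths default to the G² conditional-independence test of child vs
parent given the child's other parents; score-delta and nonparametric
bootstrap relearning are alternatives.

## Evaluation

Multi-class accuracy carries an exact Clopper–Pearson 95% CI (the CI
method is a package choice; alternatives exist). Multi-class AUC is the
macro average of one-vs-rest Mann–Whitney AUCs computed from posterior
probabilities with midrank tie handling; a Hand–Till-style pairwise
variant is available (`average="pairwise"`). Sensitivity and specificity
are one-vs-rest per class, with undefined denominators reported as
not-available rather than 0. Holdout fractions follow the two study
designs: 10% test for cross-sectional runs, 30% for the smaller
longitudinal slices.

## Synthetic cohorts

Two generators provide ground truth:

* `generate_cohort` emulates the raw table: 861 subjects by default, with
  later-visit retention probabilities 0.30/0.26/0.16 (the approximate
  follow-up fractions of a large ageing cohort), CDR prevalence
  (0.65, 0.29, 0.045, 0.015) over {0, 0.5, 1, 2}, an 8% per-visit
  progression drift, eight CDR-informative features (age, ApoE, GM, CSF,
  PiB-PET, MMSE, LMIR, LMDR) drawn from per-class Gaussians (ApoE from
  per-class genotype frequencies with rising ε4 load), 24 noise
  predictors, missingness mimicking sparser imaging follow-up (25% MRI,
  55% PiB-PET), and a diagnosis column that matches the CDR category with
  probability 0.86 (mismatches move to an adjacent category), which makes
  the diagnosis–CDR Pearson correlation come out near 0.8.
* `default_ground_truth_network` is a nine-node discrete network:
  age → {GM, CSF, PiB}, ApoE → PiB, PiB → {GM, CSF}, GM → CSF,
  {GM, CSF, PiB} → CDR, CDR → {MMSE, LMDR, LMIR}, LMDR → LMIR. CPTs come
  from an ordinal location family (child states on [−1, 1], parents shift
  the location, a spread parameter τ sets the strength). Cognitive links
  default stronger (weight 0.9, τ 0.5) than biomarker links (weight 0.7,
  τ 0.65), so learned arc strengths and subset AUCs reproduce the
  qualitative ordering that severity couples most tightly to the
  cognitive assessments. The defaults were set so the generator is
  neither degenerate (posterior AUC saturating at 1) nor unrecoverable;
  with them, BIC hill climbing at n = 5 000 recovers ~93% of the skeleton
  with ≤1 false edge (median over 10 seeds).

One master seed is split into named substreams per stage and per feature,
so adding a stage never shifts another stage's draws.

What the synthetic experiments show: every algorithmic component behaves
correctly against independent oracles, the pipeline leaks nothing into
the test set, and the qualitative orderings (cognition > predisposing
factors; combined imaging > single markers) emerge when the generating
process has them. What they do not show: that real cohort data satisfies
the generator's assumptions (class-conditional Gaussians, faithfulness of
the dependency structure, missingness independent of severity), nor that
the specific AUC/MCA levels printed here transfer to any real cohort.

## Numerical notes and limitations

* CPT estimation error is bounded by parent-row support: rows whose
  parent configuration has probability ~1e-4 receive only tens of samples
  at n = 10⁵ and cannot be estimated to 0.02 absolute; the parameter-
  recovery check therefore uses a fully identifiable chain where every
  parent row is well populated. This is an identifiability fact, not an
  estimator defect — errors track binomial sampling error throughout.
* Hill climbing is deterministic given data order (moves enumerated in
  sorted node order, first-maximum wins); random restarts are available
  but default to 0.
* The G² arc-strength test conditions on the child's other parents; a
  marginal-test variant would give different p-values for multi-parent
  children.
* Degenerate inputs raise typed errors rather than returning defaults:
  constant features and single-class targets (discretization), zero
  variance (correlation), singleton classes (SMOTE), cyclic structures
  and inconsistent constraints (learning).
* Log-likelihood loss with smoothing 0 can be infinite on validation
  records containing unseen configurations; the CV loop therefore
  evaluates smoothed fits (smoothing 1).
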