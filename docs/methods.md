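# Methods

This note records the statistical procedures implemented in `neuroaudit`,
the assumptions behind them, the defaults and why they were chosen, and
what the synthetic-data tests do and do not establish.

## Data model

The unit of analysis is the *instance*: one derived feature vector
x ∈ ℝ^D with a categorical target y, annotated with subject, session,
optional trial, and a within-(subject, session) time index. Instances from
the same subject are not statistically independent — subject-specific
feature structure ("fingerprints") and temporal autocorrelation induce
dependence that standard i.i.d. cross-validation ignores. The
`SampleTable` container enforces: strictly increasing time within each
(subject, session) (time-blocked splits need a total order, so duplicate
timestamps are rejected rather than tie-broken), non-missing subject and
session annotations, and an explicit label code/name mapping. Trials are
optional; operations that need them fail fast rather than inferring them.

## Splitting schemes and the questions they answer

A validation split is a proxy for a prospective experiment. The package
maps:

| question | proxy experiment | scheme |
|---|---|---|
| (a) | more instances from the same subjects/sessions | instance K-fold |
| (b) | the same subjects return for a new session | session group K-fold |
| (c) | entirely new subjects, same site | subject group K-fold |
| (d) | a new site/center | not assessable from single-source data |

plus two temporal designs: time K-fold (each (subject, session) cut into
K contiguous, near-equal blocks; fold j evaluates block j everywhere) and
the segment three-fold (within-session trial tertiles — first, middle,
last trials — evaluated pooled across sessions), which respects
block-label structure when consecutive instances share a trial.

Conventions:

- **Group balancing.** Groups are assigned to folds greedily,
  largest-first into the currently smallest fold (by instance count), with
  a seeded shuffle breaking size ties. This matches the greedy used by
  scikit-learn's `GroupKFold` (used as an independent oracle in the test
  suite) while adding seed-deterministic tie-breaks.
- **Session level is subject-aware.** When grouping by session, each
  subject's sessions are placed into distinct folds while unused folds
  remain, so with S ≥ k sessions per subject every subject contributes
  train *and* eval data to every fold through different sessions — the
  semantics of a split-by-session design. Plain greedy cannot guarantee
  this; subject- and trial-level splits use the plain greedy.
- **Remainders** in time and segment splits go to the earliest blocks
  (deterministic, order-preserving).
- **Stratification** of instance K-fold is opt-in, off by default.
- **Leave-one-group-out** is group K-fold with k = number of groups, not a
  separate scheme.
- `no_validation` (train = eval = everything) is constructible only as a
  flagged diagnostic; reports annotate it as bad practice.

Every constructed assignment passes a universal structural checker:
pairwise-disjoint eval sets covering the eligible indices, train/eval
disjointness per fold, group-to-fold functionality, time contiguity.

## Null controls

All controls conserve the feature matrix and time structure exactly; only
labels change.

- **Group-constant random labels**: each subject (or session) draws one
  label; balanced assignment (class counts across groups differ by ≤ 1) is
  the default so the optimal population accuracy is exactly 1/C.
  Unbalanced i.i.d. assignment is available.
- **Cross-subject sequence permutation**: subject j receives subject k's
  full label sequence in time order, with the subject→donor map a
  *derangement* (self-assignment would weaken the null). Donor longer than
  recipient → truncate; shorter → recycle from the donor's start with a
  logged warning. Both choices preserve the temporal label structure,
  which is the property this control exists to keep. A `min_instances`
  filter (default 1; 2000 is the documented preset for sleep-scale data)
  restricts to subjects with enough data.
- **Uniform instance shuffle**: the unstructured baseline.

The permutation test computes the observed cross-fold mean metric on true
labels, re-randomises labels `n_perm` times under the *same* scheme and
model, and reports p = (1 + #{null ≥ observed}) / (n_perm + 1) — the
add-one convention avoids p = 0 and keeps the test valid. Which structure
the null keeps determines the hypothesis; the audit uses the grouping
level of the scientific question.

## Reference classifier

A single-hidden-layer ReLU network (presets: 10 units, 256 units),
cross-entropy loss, Adam, a **fixed epoch budget and no early stopping** —
early stopping would itself consume a validation split and confound the
demonstrations. The exact training hyperparameters of published
demonstrations of this kind are generally unreported; the defaults here
(200 epochs, step 1e-3, batch 32) were chosen once to reach the
zero-training-error regime on desk-scale data and are not tuned per
experiment. Any scikit-learn-style classifier can be plugged in instead.

`run_scheme` refits from scratch per fold; feature standardisation (on by
default) estimates mean/scale on the fold's training rows only —
normalisation statistics computed on all data are themselves leakage. An
instrumentation test poisons eval rows and asserts the fitted weights are
bit-identical. Eval folds containing a class absent from training are
scored normally for accuracy, with a note; balanced accuracy drops absent
classes with a warning; AUC on a single-class eval fold is undefined and
recorded as NaN (excluded from the aggregate, noted).

## Chance levels and the corrected resampled t-test

- Theoretical chance = max class prior (1/C uniform). The **analytic
  bound** is the smallest a/n with P(X ≥ a) ≤ α for X ~ Binomial(n, p₀):
  the least accuracy on n eval instances that is significantly above
  chance. It is non-increasing in n and converges to the theoretical
  level; at n = 100, C = 2, α = 0.05 it is 0.59.
- Cross-validation folds share training data, so fold-wise metric
  differences are positively correlated and the naive paired t-test is
  anti-conservative. With the fold correlation approximated as ρ = 1/k,
  the corrected variance of the mean difference is
  Var(d̄) = σ_d²·(1/k + ρ(k−1)/k), t = d̄/SE with df = k − 1, CI from t
  quantiles. The classical test/train-ratio correction (c = n₂/n₁) is
  available as `rho_mode="test_train_ratio"`; the two are reported
  side-by-side in audits when they disagree materially. With the
  correction zeroed the procedure reduces exactly to the one-sample
  t-test (oracle-checked to 1e-10). Zero-variance differences are an
  error, not a p-value.
- `ttest_from_summary` inverts a published (mean, 95% CI, df) triple back
  to (SE, t, p), assuming t quantiles — with df = 4 this reproduces
  published worked values (e.g. d̄ = 0.064, CI [0.013, 0.115] → p ≈ 0.025),
  which is why t rather than normal quantiles is the default.

## Synthetic generator

x = δ·μ(y) + φ·u_subject + ψ·v_session + ε.

- μ(y), u, v are fixed random unit-RMS directions in **disjoint coordinate
  blocks** (≈ D/3 each): the label signal is exactly orthogonal to
  fingerprint and session structure, so δ and φ control separable
  mechanisms. Real data entangle them; separability is what makes
  controlled tests possible. (Gram–Schmidt against every subject direction
  is impossible once M > D, which it typically is.)
- ε is AR(1) within each session with coefficient a and stationary sd σ —
  the simplest noise model that reproduces temporal memorisation effects.
- Labels: `state` — a sticky C-state Markov chain (stay probability
  p_stay, default 0.9, sleep-stage-like); `trait` — one label per subject,
  balanced; `session_trait` — one label per session. With δ = 0 the trait
  scheme *is* the random-label control, exact by construction.
- Defaults (16 subjects × 3 sessions × 40 instances, D = 24, φ = 3 vs
  unit noise) emulate a desk-scale session-structured EEG-like study in
  which identity dominates the feature variance, as it does in real
  electrophysiology features. The generator does not attempt spectral
  realism, electrode structure or raw waveforms; a green test on this data
  establishes that the *evaluation machinery* behaves as claimed, not that
  any particular real dataset would yield the same numbers.

`verify_structure` reports empirical lag-1 autocorrelation, state
stickiness and between/within-subject separation for any generated table.

## The audit battery and its flags

`ValidationAudit.fit()` runs: the question-matched scheme, no-validation,
instance K-fold, time K-fold (when every (subject, session) has ≥ k
instances), subject/session identity probes under the instance split
(probing an identity under folds grouped by that same identity is
rejected as impossible by construction), the random-by-group control at
the question's grouping level, the analytic chance bound at the matched
scheme's median eval-fold size, and the corrected t-test for the
instance-vs-matched contrast.

Flags (no published numeric thresholds exist for "significant
discrepancy", so each flag records the numbers it compared and the
sub-criteria are reported individually rather than collapsed to one
boolean):

1. `leakage_suspected` — instance-split mean exceeds the matched scheme's
   mean + fold sd; also reported: mean±sd interval non-overlap and
   corrected-t p < 0.05.
2. `identity_memorization` — instance-split performance on group-constant
   random labels exceeds the analytic chance bound.
3. `no_generalization_evidence` — the matched scheme does not beat the
   analytic chance bound.

Flags 2 + 3 together are summarised as "memorization without
generalization". Results serialise losslessly to JSON (seeds and versions
echoed, so deterministic components regenerate bit-identically) and render
to a markdown table with fold standard deviations in parentheses.

The reporting checklist (38 items, five categories: data/split
definition, parameter and hyperparameter selection, performance metrics,
scientific conclusions, future use) ships as versioned JSON;
`checklist_validate` enforces one of four answers per item and names
missing items.

## Acceptance quantities and their expected behaviour

`scripts/acceptance.py` regenerates, from scratch at every run: the
subject group 5-fold accuracy of the 10-unit reference net under the
random-label control — each of 20 subjects draws one label from a random
number generator, *independently* of its fingerprint-rich features — over
20 fresh cohorts (binary and five-class, reported in %), and the mean
rank-based AUC of random scores against balanced binary labels
(n = 10,000, 50 replicates). The per-subject instance count (50) and
feature dimension (16) are desk-scale choices fixed before measurement.

The label assignment in this control is deliberately i.i.d. rather than
balanced: with i.i.d. labels each held-out subject's label is independent
of the trained model, so the expected accuracy is *exactly* 1/C for any
classifier. Balanced (without-replacement) assignment — the default for
the audit's own null control, where a known 1/C optimum is wanted —
instead anti-correlates the evaluation fold's class composition with the
training set's, which biases group-CV accuracy on null labels a few
points *below* 1/C at small M (an ideal proportional-assignment
classifier scores E[Σ_c f_eval,c·f_train,c] ≈ 0.474 binary / 0.158
five-class at M = 20, k = 5). Published random-label rows show the same
wobble around 1/C. The statistical tests in `tests/test_acceptance.py`
assert these quantities at the package's stated tolerances over 30 fixed
seeds.

## Known limitations

- The generator's fingerprint geometry (disjoint blocks, Gaussian blobs)
  is far simpler than real subject variability; probe accuracies saturate
  lower when many subjects share a low-dimensional fingerprint block.
- Multiclass AUC is deliberately not a default metric (accuracy is used
  for multiclass tasks); a macro one-vs-rest AUC can be computed from the
  returned per-instance scores if needed.
- Regression targets, sign-flip permutation schemes, exhaustive
  permutation enumeration, precision-recall/F1/calibration metrics, and
  confidence intervals for cross-validated AUC are out of scope.
- The corrected t-test's ρ = 1/k is an approximation, not an estimate; at
  k = 5 it is mildly more liberal than the test/train-ratio variant.
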