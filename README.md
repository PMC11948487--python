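# neuroaudit

Validation audits for machine learning on hierarchical neural and
biomedical data.

## The problem

Feature tables from multi-subject electrophysiology (EEG, LFP,
polysomnography) are hierarchical: instances are nested in trials, trials
in sessions, sessions in subjects, and the features carry strong
subject-specific *fingerprints* — identity is often easier to read out of
the data than the target of interest. When cross-validation splits
instances at random, every evaluation fold contains instances of subjects
the model was trained on, and a classifier can score nearly perfectly by
memorising who is who, even when the labels are pure noise. The estimated
performance then answers the wrong scientific question, or no question at
all.

`neuroaudit` implements the evaluation machinery for diagnosing this:

- **Splitting schemes matched to questions** — instance K-fold ("new
  instances from the same subjects"), session/subject group K-fold ("a new
  session" / "entirely new subjects"), contiguous time K-fold,
  within-session trial tertiles, nested CV for unbiased model selection,
  and the deliberately bad no-validation baseline as an overfitting
  diagnostic. Every scheme is checked for disjointness, coverage, group
  integrity and time contiguity.
- **Null controls** — group-constant random labels (every instance of a
  subject/session gets the same random label), cross-subject label-sequence
  permutation (a derangement preserving temporal label structure), uniform
  shuffles, and a permutation test over any scheme/model/metric with the
  add-one p-value convention.
- **Identity probes** — classifiers trained to predict subject or session
  identity, quantifying how much leakage material the features contain.
- **Statistics** — accuracy, balanced accuracy, rank-based AUC; analytic
  chance levels with finite-sample binomial significance bounds; and the
  corrected resampled t-test for comparing procedures across shared
  cross-validation folds, with fold correlation ρ approximated as 1/k:

  Var(d̄) = σ_d² · (1/k + ρ·(k−1)/k),  t = d̄ / SE,  df = k − 1.

- **A synthetic generator** for hierarchical tables
  x = δ·μ(y) + φ·u_subject + ψ·v_session + ε, with AR(1) noise, sticky
  Markov state labels or subject/session-constant trait labels — so every
  phenomenon above is reproducible without any dataset download.
- **An audit orchestrator** (`ValidationAudit` / `AuditResults`,
  statsmodels-style model/results) that runs the whole battery, raises
  traceable flags, and renders reports plus a 38-item machine-readable
  reporting checklist.

## Worked example

Twenty-ish subjects with strong fingerprints, one random binary label per
subject (constant over all of a subject's instances), **zero**
label-feature signal — the canonical leakage trap:

```python
from neuroaudit import ClassifierSpec, SyntheticConfig, ValidationAudit, generate

table = generate(SyntheticConfig(
    n_subjects=10, n_sessions=1, n_per_session=30, n_features=10,
    n_classes=2, label_scheme="trait", effect_size=0.0,
    fingerprint_strength=3.0, session_strength=0.0, seed=0,
))
audit = ValidationAudit(
    table=table, question="c",          # "does this generalise to new subjects?"
    classifier=ClassifierSpec(hidden_units=64, epochs=300, seed=0),
    metric="accuracy", k=5, seed=0,
)
results = audit.fit()
print(results.summary())
```

```
         Validation audit — question (c): new subjects, same site
=========================================================================
                              accuracy   subject-ID probe random-by-group
-------------------------------------------------------------------------
no_validation [diagnostic]   0.963 (N/A)              N/A             N/A
instance_kfold             0.683 (0.049)    0.727 (0.038)   0.883 (0.026)
group_kfold[subject]       0.347 (0.132)              N/A   0.650 (0.122)
time_kfold                 0.660 (0.084)              N/A             N/A
-------------------------------------------------------------------------
```

Reading the table: evaluating on training data looks near-perfect (0.963)
— pure overfitting capacity. The instance split still reports 0.683 on
labels that are *random*, and 0.883 on the explicit random-by-group
control, because the net can identify subjects (probe: 0.727 vs 0.1
chance). The subject-grouped split — the only one that matches question
(c) — collapses to chance (0.347 with large fold spread; the analytic
bound says accuracy must exceed 0.617 on 60 eval instances to beat chance
at α = 0.05). The corrected resampled t-test puts the instance-vs-subject
gap at d̄ = 0.337 [0.115, 0.558], p = 0.013, and the audit raises
`leakage_suspected`, `identity_memorization` and
`no_generalization_evidence` — the "memorization without generalization"
pattern.

A thin CLI wraps the same library:

```sh
neuroaudit simulate --config world.yaml --out table.csv
neuroaudit split --scheme group --level subject --k 5 --seed 0 --in table.csv --out folds.json
neuroaudit audit --in table.csv --question c --out-dir report/
neuroaudit checklist --responses answers.yaml --out checklist.md
```

## Acceptance script

`scripts/acceptance.py` regenerates the package's reference quantities
from scratch — the subject-grouped cross-validation accuracy of the
reference classifier under random subject-constant labels drawn
independently of the features (binary and five-class, averaged over 20
fresh synthetic cohorts), and the expected rank-based AUC of
label-independent scores — and writes them to JSON:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

All randomness derives from `--seed`. Runtime is a couple of minutes on
one CPU.

See `docs/methods.md` for the underlying model, the generator's
assumptions, and numerical conventions.
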