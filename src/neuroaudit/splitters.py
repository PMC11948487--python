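"""Cross-validation splitting schemes keyed to scientific questions.

Each constructor returns a :class:`FoldAssignment` — an ordered list of
(train, eval) index sets realising one scheme:

``no_validation``
    train = eval = everything; a deliberate bad practice kept only as a
    diagnostic of a model's capacity to overfit.
``instance_kfold``
    random partition of instances; answers "new instances from the same
    subject, same session" and nothing stronger.
``group_kfold``
    whole subjects / sessions / trials assigned to folds; answers "new
    session" or "new subject" depending on the level.
``time_kfold``
    contiguous temporal blocks within each (subject, session); probes
    robustness to chronological structure.
``segment_3fold``
    within-session trial tertiles (first / middle / last trials), evaluated
    pooled across sessions and subjects.
``nested``
    an inner assignment built inside each outer training set, for unbiased
    model selection.

A universal structural checker (:func:`check_assignment`) asserts the
contracts every scheme must honour: disjoint eval sets covering the eligible
indices, train/eval disjointness, group integrity and time contiguity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

from .exceptions import ArgumentError, SchemaError
from .table import SampleTable

__all__ = [
    "FoldAssignment",
    "NestedAssignment",
    "make_no_validation",
    "make_instance_kfold",
    "make_group_kfold",
    "make_time_kfold",
    "make_segment_3fold",
    "make_nested",
    "make_assignment",
    "check_assignment",
]


@dataclass
class FoldAssignment:
    """An ordered list of (train, eval) index arrays realising one scheme."""

    scheme: str
    k: int
    folds: list  # list of (train_idx, eval_idx) ndarray pairs
    level: str | None = None
    seed: int | None = None
    diagnostic_only: bool = False
    eligible: np.ndarray | None = None  # indices the scheme partitions
    notes: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.folds = [
            (np.asarray(tr, dtype=int), np.asarray(ev, dtype=int)) for tr, ev in self.folds
        ]
        if self.eligible is None:
            self.eligible = np.unique(np.concatenate([ev for _, ev in self.folds]))
        else:
            self.eligible = np.asarray(self.eligible, dtype=int)

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "level": self.level,
            "k": self.k,
            "seed": self.seed,
            "diagnostic_only": self.diagnostic_only,
            "folds": {
                str(i): {"train": tr.tolist(), "eval": ev.tolist()}
                for i, (tr, ev) in enumerate(self.folds)
            },
            "notes": list(self.notes),
        }


@dataclass
class NestedAssignment:
    """Outer assignment plus one inner assignment per outer training set."""

    outer: FoldAssignment
    inner: list  # one FoldAssignment per outer fold, indices in table coordinates


def make_no_validation(table: SampleTable) -> FoldAssignment:
    """Evaluate on the training data itself (diagnostic only).

    This is the textbook bad practice: an over-parameterised model will
    report a near-perfect score regardless of whether any generalisable
    signal exists.  The assignment is flagged so downstream reports annotate
    it as inappropriate for performance claims.
    """
    idx = np.arange(table.n_instances)
    return FoldAssignment(
        scheme="no_validation",
        k=1,
        folds=[(idx, idx)],
        diagnostic_only=True,
        notes=["no-validation: inappropriate, diagnostic only"],
    )


def make_instance_kfold(
    table: SampleTable, k: int, seed: int = 0, stratified: bool = False
) -> FoldAssignment:
    """Random K-fold over individual instances (question (a) scheme)."""
    n = table.n_instances
    if k < 2:
        raise ArgumentError("instance K-fold requires k >= 2")
    if k > n:
        raise ArgumentError(f"k={k} exceeds N={n}")
    cls = StratifiedKFold if stratified else KFold
    splitter = cls(n_splits=k, shuffle=True, random_state=seed)
    folds = [
        (tr, ev) for tr, ev in splitter.split(np.zeros((n, 1)), table.labels)
    ]
    return FoldAssignment(scheme="instance_kfold", k=k, folds=folds, seed=seed)


def make_group_kfold(table: SampleTable, level: str, k: int, seed: int = 0) -> FoldAssignment:
    """Group K-fold at subject, session or trial level.

    Entire groups go to a single fold's eval set, so evaluation is always on
    unseen groups.  Fold sizes are balanced greedily: groups are taken
    largest-first (seeded shuffle breaks size ties) and each is assigned to
    the fold currently holding the fewest instances.  At the session level
    the greedy is additionally subject-aware: a subject's sessions are
    placed in distinct folds whenever folds remain unused by that subject,
    so with S sessions per subject and k <= S every subject contributes to
    every fold's train *and* eval through different sessions.
    """
    if k < 2:
        raise ArgumentError("group K-fold requires k >= 2")
    groups = table.groups(level)  # may raise SchemaError for missing trial_id
    if len(groups) < k:
        raise ArgumentError(
            f"only {len(groups)} distinct groups at level {level!r}; need >= k={k}"
        )
    rng = np.random.default_rng(seed)
    keys = sorted(groups)
    rng.shuffle(keys)  # seeded tie-break among equal-sized groups
    keys.sort(key=lambda g: -len(groups[g]))  # stable: ties keep shuffled order
    fold_sizes = np.zeros(k, dtype=int)
    fold_groups: list[list] = [[] for _ in range(k)]
    if level == "session":
        by_subject: dict = {}
        for g in keys:
            by_subject.setdefault(g.split("//")[0], []).append(g)
        subjects = sorted(
            by_subject, key=lambda s: -sum(len(groups[g]) for g in by_subject[s])
        )
        for subj in subjects:
            used: set = set()
            for g in by_subject[subj]:  # already largest-first
                candidates = [j for j in range(k) if j not in used] or list(range(k))
                j = min(candidates, key=lambda j: fold_sizes[j])
                fold_groups[j].append(g)
                fold_sizes[j] += len(groups[g])
                used.add(j)
    else:
        for g in keys:
            j = int(np.argmin(fold_sizes))
            fold_groups[j].append(g)
            fold_sizes[j] += len(groups[g])
    all_idx = np.arange(table.n_instances)
    folds = []
    for j in range(k):
        ev = np.sort(np.concatenate([groups[g] for g in fold_groups[j]]))
        tr = np.setdiff1d(all_idx, ev)
        folds.append((tr, ev))
    return FoldAssignment(scheme="group_kfold", level=level, k=k, folds=folds, seed=seed)


def make_time_kfold(table: SampleTable, k: int) -> FoldAssignment:
    """Contiguous time blocks within each (subject, session).

    Instances of every (subject, session) are sorted by time_index and cut
    into k contiguous, near-equal blocks (remainders to the earliest
    blocks); fold j evaluates the union of block j over all groups.
    Deterministic — no randomness is involved.
    """
    if k < 2:
        raise ArgumentError("time K-fold requires k >= 2")
    groups = table.groups("session")
    for key, idx in groups.items():
        if len(idx) < k:
            raise ArgumentError(
                f"(subject, session)={key} has only {len(idx)} instances; need >= k={k}"
            )
    blocks: list[list] = [[] for _ in range(k)]
    for key in sorted(groups):
        idx = groups[key]
        ordered = idx[np.argsort(table.time_index[idx], kind="stable")]
        for j, block in enumerate(np.array_split(ordered, k)):
            blocks[j].append(block)
    all_idx = np.arange(table.n_instances)
    folds = []
    for j in range(k):
        ev = np.sort(np.concatenate(blocks[j]))
        folds.append((np.setdiff1d(all_idx, ev), ev))
    return FoldAssignment(scheme="time_kfold", k=k, folds=folds)


def make_segment_3fold(table: SampleTable) -> FoldAssignment:
    """Within-session trial tertiles: first / middle / last trials.

    Within each (subject, session), trials are ordered by their first
    time_index and cut into three tertiles (remainders to the earliest);
    fold j evaluates tertile j pooled across all sessions and subjects and
    trains on the other two.  Deterministic.
    """
    if table.trial_id is None:
        raise SchemaError("segment 3-fold requires trial_id")
    k = 3
    trial_groups = table.groups("trial")
    sess_of = {t: "//".join(t.split("//")[:2]) for t in trial_groups}
    sessions: dict = {}
    for t, sess in sess_of.items():
        sessions.setdefault(sess, []).append(t)
    tertiles: list[list] = [[] for _ in range(k)]
    for sess in sorted(sessions):
        trials = sessions[sess]
        if len(trials) < k:
            raise ArgumentError(
                f"(subject, session)={sess} has only {len(trials)} trials; "
                f"segment 3-fold needs >= {k}"
            )
        trials.sort(key=lambda t: int(table.time_index[trial_groups[t]].min()))
        for j, part in enumerate(np.array_split(np.arange(len(trials)), k)):
            for ti in part:
                tertiles[j].append(trial_groups[trials[ti]])
    all_idx = np.arange(table.n_instances)
    folds = []
    for j in range(k):
        ev = np.sort(np.concatenate(tertiles[j]))
        folds.append((np.setdiff1d(all_idx, ev), ev))
    return FoldAssignment(scheme="segment_3fold", k=k, level="trial", folds=folds)


def make_assignment(table: SampleTable, spec: dict) -> FoldAssignment:
    """Build an assignment from a plain spec dict (the config interface).

    Keys: ``scheme`` plus scheme-specific ``k``, ``level``, ``seed``,
    ``stratified``.
    """
    scheme = spec["scheme"]
    if scheme in ("none", "no_validation"):
        return make_no_validation(table)
    if scheme in ("instance", "instance_kfold"):
        return make_instance_kfold(
            table, k=spec.get("k", 5), seed=spec.get("seed", 0),
            stratified=spec.get("stratified", False),
        )
    if scheme in ("group", "group_kfold"):
        return make_group_kfold(
            table, level=spec.get("level", "subject"), k=spec.get("k", 5),
            seed=spec.get("seed", 0),
        )
    if scheme in ("time", "time_kfold"):
        return make_time_kfold(table, k=spec.get("k", 5))
    if scheme in ("segment3", "segment_3fold"):
        return make_segment_3fold(table)
    raise ArgumentError(f"unknown scheme {scheme!r}")


def make_nested(table: SampleTable, outer_spec: dict, inner_spec: dict) -> NestedAssignment:
    """Nested assignment: an inner CV inside each outer training set.

    The inner assignment is built only from the outer fold's training
    indices, so inner eval sets never touch the outer eval set; selecting a
    model by inner score and reporting the outer-eval score keeps the outer
    estimate unbiased by the selection.
    """
    outer = make_assignment(table, outer_spec)
    inners = []
    for i, (tr, _ev) in enumerate(outer.folds):
        sub = table.subset(tr)
        try:
            inner_local = make_assignment(sub, inner_spec)
        except (ArgumentError, SchemaError) as exc:
            raise ArgumentError(
                f"inner scheme infeasible on outer fold {i}: {exc}"
            ) from exc
        # map local (subset) indices back to table coordinates
        folds = [(tr[itr], tr[iev]) for itr, iev in inner_local.folds]
        inners.append(
            FoldAssignment(
                scheme=inner_local.scheme, k=inner_local.k, folds=folds,
                level=inner_local.level, seed=inner_local.seed,
                eligible=tr,
            )
        )
    return NestedAssignment(outer=outer, inner=inners)


def check_assignment(table: SampleTable, fa: FoldAssignment) -> None:
    """Assert the structural contracts of a fold assignment.

    Raises AssertionError on: overlapping eval sets, eval sets not covering
    the eligible indices, a fold's train and eval intersecting (except
    no_validation), a group split across folds (group schemes), or a
    non-contiguous eval block in time (time scheme).
    """
    if fa.scheme == "no_validation":
        assert fa.k == 1 and len(fa.folds) == 1
        return
    evals = [ev for _, ev in fa.folds]
    concat = np.concatenate(evals)
    assert len(concat) == len(np.unique(concat)), "eval sets overlap"
    assert np.array_equal(np.sort(concat), np.sort(fa.eligible)), "eval sets do not cover eligible indices"
    for tr, ev in fa.folds:
        assert len(np.intersect1d(tr, ev)) == 0, "train and eval intersect"
    if fa.scheme == "group_kfold":
        keys = table.group_keys(fa.level)
        for tr, ev in fa.folds:
            assert not (set(keys[tr]) & set(keys[ev])), "group appears in both train and eval"
    if fa.scheme in ("time_kfold", "segment_3fold"):
        level = "session"
        groups = table.groups(level)
        for _, ev in fa.folds:
            ev_set = set(ev.tolist())
            for idx in groups.values():
                ordered = idx[np.argsort(table.time_index[idx], kind="stable")]
                inside = np.asarray([i in ev_set for i in ordered])
                if inside.any():
                    first, last = np.flatnonzero(inside)[[0, -1]]
                    assert inside[first : last + 1].all(), "eval block not contiguous in time"
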