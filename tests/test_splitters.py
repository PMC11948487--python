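import numpy as np
import pytest
from sklearn.model_selection import GroupKFold

from neuroaudit import (
    SampleTable,
    check_assignment,
    make_group_kfold,
    make_instance_kfold,
    make_nested,
    make_no_validation,
    make_segment_3fold,
    make_time_kfold,
)
from neuroaudit.exceptions import ArgumentError, SchemaError

from conftest import random_small_table


def one_subject_table(n, trial_size=None):
    trial = None
    if trial_size:
        trial = (np.arange(n) // trial_size).astype(str)
    return SampleTable(
        features=np.random.default_rng(0).standard_normal((n, 2)),
        labels=np.arange(n) % 2,
        label_names=("a", "b"),
        subject_id=np.full(n, "s0"),
        session_id=np.full(n, "x"),
        time_index=np.arange(n),
        trial_id=trial,
    )


def subjects_table(sizes):
    subj = np.concatenate([[f"s{i}"] * k for i, k in enumerate(sizes)])
    n = len(subj)
    times = np.concatenate([np.arange(k) for k in sizes])
    return SampleTable(
        features=np.zeros((n, 1)),
        labels=np.arange(n) % 2,
        label_names=("a", "b"),
        subject_id=subj,
        session_id=np.full(n, "x"),
        time_index=times,
    )


# ---------------------------------------------------------------- schemes
def test_no_validation_is_identity_fold():
    t = one_subject_table(5)
    fa = make_no_validation(t)
    assert fa.k == 1 and fa.diagnostic_only
    tr, ev = fa.folds[0]
    assert np.array_equal(tr, np.arange(5)) and np.array_equal(ev, np.arange(5))
    assert any("diagnostic" in n for n in fa.notes)
    # no randomness: applying twice gives the identical assignment
    fa2 = make_no_validation(t)
    assert np.array_equal(fa2.folds[0][1], ev)


def test_instance_kfold_partition_and_determinism():
    t = one_subject_table(10)
    fa = make_instance_kfold(t, k=5, seed=3)
    assert sorted(len(ev) for _, ev in fa.folds) == [2] * 5
    check_assignment(t, fa)
    fb = make_instance_kfold(t, k=5, seed=3)
    for (_, e1), (_, e2) in zip(fa.folds, fb.folds):
        assert np.array_equal(e1, e2)
    with pytest.raises(ArgumentError):
        make_instance_kfold(t, k=11)


def test_instance_kfold_large_n_equal_sizes():
    """N divisible by k gives exactly equal eval folds (58135 = 5 x 11627)."""
    t = one_subject_table(58135)
    fa = make_instance_kfold(t, k=5, seed=0)
    assert [len(ev) for _, ev in fa.folds] == [11627] * 5


def test_instance_kfold_stratified_balance():
    t = one_subject_table(20)
    fa = make_instance_kfold(t, k=4, seed=1, stratified=True)
    for _, ev in fa.folds:
        counts = np.bincount(t.labels[ev], minlength=2)
        assert abs(counts[0] - counts[1]) <= 1


def test_group_kfold_six_subjects_three_folds():
    t = subjects_table([4] * 6)
    fa = make_group_kfold(t, "subject", k=3, seed=0)
    check_assignment(t, fa)
    for _, ev in fa.folds:
        assert len(set(t.subject_id[ev])) == 2


def test_group_kfold_greedy_balance_against_sklearn():
    """Greedy largest-group-first balancing matches sklearn's GroupKFold
    instance totals on unequal groups: (100,60,40,40,30,30) -> 100/90/110."""
    sizes = [100, 60, 40, 40, 30, 30]
    t = subjects_table(sizes)
    fa = make_group_kfold(t, "subject", k=3, seed=0)
    ours = sorted(len(ev) for _, ev in fa.folds)
    g = np.repeat(np.arange(6), sizes)
    oracle = sorted(
        len(te) for _, te in GroupKFold(n_splits=3).split(np.zeros((len(g), 1)), groups=g)
    )
    assert ours == oracle == [90, 100, 110]


def test_group_kfold_session_level_spans_folds(session_table):
    """With 3 sessions per subject and k=3, every subject contributes to
    every fold's train and eval via distinct sessions."""
    fa = make_group_kfold(session_table, "session", k=3, seed=5)
    check_assignment(session_table, fa)
    for tr, ev in fa.folds:
        for s in np.unique(session_table.subject_id):
            assert s in set(session_table.subject_id[ev])
            assert s in set(session_table.subject_id[tr])


def test_group_kfold_errors(tiny_table):
    with pytest.raises(ArgumentError, match="subject"):
        make_group_kfold(tiny_table, "subject", k=3)
    with pytest.raises(SchemaError, match="trial"):
        make_group_kfold(tiny_table, "trial", k=2)


def test_time_kfold_blocks():
    t = one_subject_table(10)
    fa = make_time_kfold(t, k=5)
    blocks = [ev.tolist() for _, ev in fa.folds]
    assert blocks == [[0, 1], [2, 3], [4, 5], [6, 7], [8, 9]]


def test_time_kfold_remainder_to_earliest():
    t = one_subject_table(11)
    fa = make_time_kfold(t, k=5)
    assert [len(ev) for _, ev in fa.folds] == [3, 2, 2, 2, 2]


def test_time_kfold_blocks_ordered_in_time(session_table):
    """Within a subject, all of eval block j precedes eval block j+1."""
    fa = make_time_kfold(session_table, k=3)
    check_assignment(session_table, fa)
    for key, idx in session_table.groups("session").items():
        prev_max = -1
        for _, ev in fa.folds:
            mine = np.intersect1d(ev, idx)
            times = session_table.time_index[mine]
            assert times.min() > prev_max
            prev_max = times.max()


def test_time_kfold_too_few_instances_names_subject():
    t = one_subject_table(3)
    with pytest.raises(ArgumentError, match="s0"):
        make_time_kfold(t, k=5)


def test_segment_3fold_tertiles():
    # 15 trials of 2 instances -> tertiles of 5 trials
    t = one_subject_table(30, trial_size=2)
    fa = make_segment_3fold(t)
    check_assignment(t, fa)
    for _, ev in fa.folds:
        assert len({t.trial_id[i] for i in ev}) == 5
    # 3 trials -> one per fold
    t3 = one_subject_table(9, trial_size=3)
    fa3 = make_segment_3fold(t3)
    assert all(len({t3.trial_id[i] for i in ev}) == 1 for _, ev in fa3.folds)
    # 7 trials -> (3, 2, 2) under remainder-to-earliest
    t7 = one_subject_table(7, trial_size=1)
    fa7 = make_segment_3fold(t7)
    assert [len({t7.trial_id[i] for i in ev}) for _, ev in fa7.folds] == [3, 2, 2]


def test_segment_3fold_requires_trials():
    with pytest.raises(SchemaError, match="trial"):
        make_segment_3fold(one_subject_table(9))


def test_nested_containment_and_partition():
    t = subjects_table([3] * 10)
    nested = make_nested(
        t,
        {"scheme": "group", "level": "subject", "k": 5, "seed": 0},
        {"scheme": "group", "level": "subject", "k": 4, "seed": 1},
    )
    for (otr, oev), inner in zip(nested.outer.folds, nested.inner):
        outer_train_subjects = set(t.subject_id[otr])
        assert len(outer_train_subjects) == 8
        inner_evals = []
        for itr, iev in inner.folds:
            assert set(t.subject_id[iev]) <= outer_train_subjects
            assert len(np.intersect1d(iev, oev)) == 0
            inner_evals.append(iev)
        assert np.array_equal(np.sort(np.concatenate(inner_evals)), np.sort(otr))


def test_nested_infeasible_inner_names_fold():
    t = subjects_table([3] * 4)
    with pytest.raises(ArgumentError, match="outer fold"):
        make_nested(
            t,
            {"scheme": "group", "level": "subject", "k": 2, "seed": 0},
            {"scheme": "group", "level": "subject", "k": 4, "seed": 0},
        )


def test_group_to_fold_map_is_function():
    """Brute force: each group id appears in exactly one fold's eval set."""
    rng = np.random.default_rng(21)
    for _ in range(20):
        t = random_small_table(rng)
        for level in ("subject", "session"):
            n_groups = len(t.groups(level))
            k = min(2 + int(rng.integers(2)), n_groups)
            if k < 2:
                continue
            fa = make_group_kfold(t, level, k=k, seed=int(rng.integers(100)))
            seen = {}
            for j, (_, ev) in enumerate(fa.folds):
                for g in set(t.group_keys(level)[ev]):
                    assert g not in seen
                    seen[g] = j
            assert len(seen) == n_groups
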