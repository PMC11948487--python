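import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression

from neuroaudit import (
    NullSpec,
    SampleTable,
    SyntheticConfig,
    assign_random_labels_by_group,
    generate,
    permutation_test,
    permute_label_sequences_across_subjects,
    shuffle_instances,
)
from neuroaudit.exceptions import ArgumentError


def subjects_table(sizes, labels=None):
    subj = np.concatenate([[f"s{i}"] * k for i, k in enumerate(sizes)])
    n = len(subj)
    return SampleTable(
        features=np.random.default_rng(0).standard_normal((n, 2)),
        labels=np.asarray(labels) if labels is not None else np.arange(n) % 2,
        label_names=("W", "R"),
        subject_id=subj,
        session_id=np.full(n, "x"),
        time_index=np.concatenate([np.arange(k) for k in sizes]),
    )


# ------------------------------------------------- random labels by group
def test_random_by_subject_balanced_binary():
    t = subjects_table([3, 3, 3, 3])
    out = assign_random_labels_by_group(t, "subject", n_classes=2, balanced=True, seed=0)
    per_subject = {s: set(out.labels[idx]) for s, idx in out.groups("subject").items()}
    assert all(len(v) == 1 for v in per_subject.values())  # group-constant
    classes = [v.pop() for v in per_subject.values()]
    assert sorted(np.bincount(classes, minlength=2)) == [2, 2]
    assert np.array_equal(out.features, t.features)  # features conserved


def test_random_by_subject_five_classes_sixteen_subjects():
    """The multiclass random-by-subject control: 16 subjects, 5 classes."""
    t = subjects_table([4] * 16)
    out = assign_random_labels_by_group(t, "subject", n_classes=5, balanced=True, seed=1)
    per_subject = {s: set(out.labels[idx]) for s, idx in out.groups("subject").items()}
    assert all(len(v) == 1 for v in per_subject.values())
    counts = np.bincount([v.pop() for v in per_subject.values()], minlength=5)
    assert counts.max() - counts.min() <= 1


def test_random_by_session_within_subject_variation():
    cfg = SyntheticConfig(n_subjects=3, n_sessions=4, n_per_session=5, seed=2)
    t = generate(cfg)
    out = assign_random_labels_by_group(t, "session", n_classes=2, balanced=True, seed=3)
    for idx in out.groups("session").values():
        assert len(set(out.labels[idx])) == 1
    # with 12 sessions and 2 classes some subject must carry both labels
    per_subject_classes = [
        len(set(out.labels[idx])) for idx in out.groups("subject").values()
    ]
    assert max(per_subject_classes) > 1


def test_random_by_group_too_few_groups():
    t = subjects_table([3, 3])
    with pytest.raises(ArgumentError):
        assign_random_labels_by_group(t, "subject", n_classes=5, balanced=True)


# --------------------------------------------- cross-subject sequence swap
def test_two_subjects_swap():
    """The only derangement on 2 elements is the swap."""
    t = subjects_table([4, 4], labels=[0, 0, 1, 1, 1, 1, 0, 0])
    out = permute_label_sequences_across_subjects(t, seed=0)
    g = out.groups("subject")
    assert out.labels[g["s0"]].tolist() == [1, 1, 0, 0]
    assert out.labels[g["s1"]].tolist() == [0, 0, 1, 1]


def test_truncation_rule():
    """A 5-instance recipient of donor sequence (W,W,R,R,R,W,W) gets the
    first five labels (W,W,R,R,R)."""
    t = subjects_table([5, 7], labels=[0] * 5 + [0, 0, 1, 1, 1, 0, 0])
    out = permute_label_sequences_across_subjects(t, seed=0)
    g = out.groups("subject")
    assert out.labels[g["s0"]].tolist() == [0, 0, 1, 1, 1]


def test_derangement_and_structure_preserved():
    rng = np.random.default_rng(4)
    sizes = [10, 12, 11, 10, 13]
    labels = rng.integers(0, 2, sum(sizes))
    t = subjects_table(sizes, labels=labels)
    out = permute_label_sequences_across_subjects(t, seed=9)
    # features and time order untouched
    assert np.array_equal(out.features, t.features)
    assert np.array_equal(out.time_index, t.time_index)
    # no subject keeps its own sequence (label coincidence over >= 10
    # random binary draws is negligible at this fixed seed)
    g_in, g_out = t.groups("subject"), out.groups("subject")
    for s in g_in:
        assert not np.array_equal(out.labels[g_out[s]], t.labels[g_in[s]])


def test_run_length_structure_transfers():
    """The recipient's label run-length sequence equals the donor's, up to
    truncation (fixed seed, 2 subjects -> swap)."""

    def runs(x):
        x = np.asarray(x)
        breaks = np.flatnonzero(np.diff(x) != 0)
        return np.diff(np.r_[0, breaks + 1, len(x)]).tolist()

    donor_seq = [0, 0, 0, 1, 1, 0, 1, 1, 1, 1]
    t = subjects_table([10, 10], labels=donor_seq + donor_seq[::-1])
    out = permute_label_sequences_across_subjects(t, seed=0)
    g = out.groups("subject")
    assert runs(out.labels[g["s0"]]) == runs(donor_seq[::-1])
    assert runs(out.labels[g["s1"]]) == runs(donor_seq)


def test_min_instances_filters_subjects():
    t = subjects_table([3, 20, 20])
    out = permute_label_sequences_across_subjects(t, min_instances=10, seed=0)
    assert set(out.subject_id) == {"s1", "s2"}
    with pytest.raises(ArgumentError):
        permute_label_sequences_across_subjects(t, min_instances=21)


# ------------------------------------------------------------- shuffling
def test_shuffle_conserves_counts_and_is_deterministic():
    t = subjects_table([6, 6])
    a = shuffle_instances(t, seed=5)
    b = shuffle_instances(t, seed=5)
    assert np.array_equal(a.labels, b.labels)
    assert np.bincount(a.labels).tolist() == np.bincount(t.labels).tolist()
    assert np.array_equal(a.features, t.features)


# ------------------------------------------------------ permutation test
def fast_model():
    return LogisticRegression(max_iter=200)


def test_permutation_test_add_one_convention():
    """Strong real signal: the observed statistic beats all permutations and
    p attains its minimum (n_perm + 1)^-1."""
    cfg = SyntheticConfig(
        n_subjects=4, n_sessions=1, n_per_session=20, n_features=6,
        label_scheme="state", effect_size=4.0, fingerprint_strength=0.0,
        session_strength=0.0, ar_coefficient=0.0, p_stay=0.5, seed=6,
    )
    t = generate(cfg)
    res = permutation_test(
        t,
        scheme={"scheme": "instance", "k": 3, "seed": 0},
        model=fast_model(),
        metric="accuracy",
        null=NullSpec(kind="shuffle_instances"),
        n_perm=19,
        seed=1,
    )
    assert res.observed > res.null_values.max()
    assert res.p == pytest.approx(1 / 20)


def test_permutation_test_null_data_p_not_small():
    """With no label-feature association the observed statistic sits inside
    the null distribution and p is not extreme."""
    cfg = SyntheticConfig(
        n_subjects=4, n_sessions=1, n_per_session=20, n_features=4,
        label_scheme="state", effect_size=0.0, fingerprint_strength=0.0,
        session_strength=0.0, ar_coefficient=0.0, p_stay=0.5, seed=7,
    )
    t = generate(cfg)
    res = permutation_test(
        t,
        scheme={"scheme": "instance", "k": 3, "seed": 0},
        model=fast_model(),
        metric="accuracy",
        null=NullSpec(kind="shuffle_instances"),
        n_perm=39,
        seed=2,
    )
    assert res.p > 0.05


def test_permutation_test_requires_enough_permutations(tiny_table):
    with pytest.raises(ArgumentError):
        permutation_test(
            tiny_table, {"scheme": "instance", "k": 2, "seed": 0}, fast_model(),
            "accuracy", NullSpec(kind="shuffle_instances"), n_perm=5, seed=0,
        )
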