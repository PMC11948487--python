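"""Label-randomisation null controls and the permutation test built on them.

A null control replaces the labels of a table while conserving the feature
matrix and time structure exactly.  Which structure the randomisation keeps
determines what the control can detect:

``assign_random_labels_by_group``
    every instance of a subject (or session) receives the same random
    label.  Any above-chance instance-split performance on such labels can
    only come from the classifier memorising group identity — the
    subject-fingerprint failure mode.
``permute_label_sequences_across_subjects``
    each subject receives another subject's full label *sequence* in time
    order (a derangement: nobody keeps their own).  The label-feature link
    is broken but the temporal label structure is preserved, so residual
    performance isolates temporal memorisation.
``shuffle_instances``
    uniform label permutation over all instances; the unstructured baseline.

:func:`permutation_test` turns any of these into a significance test: the
observed statistic on true labels is compared with the statistic under
``n_perm`` independent re-randomisations evaluated under the *same*
splitting scheme, with the add-one p-value convention
p = (1 + #{null >= observed}) / (n_perm + 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .exceptions import ArgumentError
from .model import run_scheme
from .splitters import make_assignment
from .table import SampleTable

logger = logging.getLogger(__name__)

__all__ = [
    "NullSpec",
    "NullResult",
    "assign_random_labels_by_group",
    "permute_label_sequences_across_subjects",
    "shuffle_instances",
    "apply_null",
    "permutation_test",
]


@dataclass
class NullSpec:
    """Which label randomisation to apply, and its parameters."""

    kind: str  # random_by_group | permute_sequences_across_subjects | shuffle_instances
    level: str = "subject"  # for random_by_group
    n_classes: int = 2
    balanced: bool = True
    min_instances: int = 1  # for sequence permutation; 2000 emulates sleep-scale data
    seed: int = 0

    def __post_init__(self) -> None:
        known = (
            "random_by_group",
            "permute_sequences_across_subjects",
            "shuffle_instances",
        )
        if self.kind not in known:
            raise ArgumentError(f"unknown null kind {self.kind!r}")
        if self.n_classes < 2:
            raise ArgumentError("n_classes must be >= 2")
        if self.min_instances < 1:
            raise ArgumentError("min_instances must be >= 1")


@dataclass
class NullResult:
    observed: float
    null_values: np.ndarray
    p: float
    spec: NullSpec
    scheme: dict

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"permutation test ({self.spec.kind}): observed {self.observed:.3f}, "
            f"null mean {float(np.mean(self.null_values)):.3f}, p={self.p:.4f}"
        )

    def to_dict(self) -> dict:
        return {
            "observed": self.observed,
            "null_values": np.asarray(self.null_values).tolist(),
            "p": self.p,
            "null_kind": self.spec.kind,
            "scheme": self.scheme,
        }


def _generic_names(n_classes: int) -> tuple:
    return tuple(f"class_{c}" for c in range(n_classes))


def assign_random_labels_by_group(
    table: SampleTable,
    level: str = "subject",
    n_classes: int = 2,
    balanced: bool = True,
    seed: int = 0,
) -> SampleTable:
    """Give every instance of a group the same random label.

    With ``balanced`` (default) class counts over groups differ by at most
    one, so the optimal population-level accuracy is exactly 1/C; with
    ``balanced=False`` each group draws its label iid uniform.  Features are
    untouched; the original labels remain available on the input table.
    """
    groups = table.groups(level)
    if level not in ("subject", "session"):
        raise ArgumentError("random_by_group level must be 'subject' or 'session'")
    if balanced and len(groups) < n_classes:
        raise ArgumentError(
            f"balanced assignment needs >= {n_classes} groups at level {level!r}; "
            f"found {len(groups)}"
        )
    rng = np.random.default_rng(seed)
    keys = sorted(groups)
    if balanced:
        pool = np.resize(np.arange(n_classes), len(keys))
        rng.shuffle(keys)
        group_label = dict(zip(keys, pool))
    else:
        group_label = {k: int(rng.integers(n_classes)) for k in keys}
    labels = np.empty(table.n_instances, dtype=int)
    for k, idx in groups.items():
        labels[idx] = group_label[k]
    return table.with_labels(labels, _generic_names(n_classes))


def _derangement(n: int, rng) -> np.ndarray:
    """Uniform random derangement by rejection; n=2 has exactly one."""
    if n < 2:
        raise ArgumentError("derangement needs >= 2 elements")
    while True:
        perm = rng.permutation(n)
        if not np.any(perm == np.arange(n)):
            return perm


def permute_label_sequences_across_subjects(
    table: SampleTable, min_instances: int = 1, seed: int = 0
) -> SampleTable:
    """Swap whole label sequences between subjects, keeping time order.

    Only subjects with at least ``min_instances`` instances are retained
    (published sleep-scale analyses restrict to subjects with over 2000
    instances; the threshold is configurable).  The subject-to-donor map is
    a derangement.  Each recipient receives the donor's label sequence in
    donor time order, truncated to the recipient's length; a donor shorter
    than its recipient is recycled from the start with a logged warning.
    Feature rows and time order are unchanged.
    """
    groups = table.groups("subject")
    eligible = [s for s in sorted(groups) if len(groups[s]) >= min_instances]
    if len(eligible) < 2:
        raise ArgumentError(
            f"need >= 2 subjects with >= {min_instances} instances; found {len(eligible)}"
        )
    sub = table.subset(
        np.sort(np.concatenate([groups[s] for s in eligible]))
    )
    groups = sub.groups("subject")
    rng = np.random.default_rng(seed)
    donors = dict(zip(eligible, (eligible[j] for j in _derangement(len(eligible), rng))))
    labels = sub.labels.copy()
    for recip, donor in donors.items():
        r_idx = groups[recip]
        d_idx = groups[donor]
        r_order = r_idx[np.argsort(sub.time_index[r_idx], kind="stable")]
        d_order = d_idx[np.argsort(sub.time_index[d_idx], kind="stable")]
        seq = sub.labels[d_order]
        if len(seq) < len(r_order):
            logger.warning(
                "donor %s (%d instances) shorter than recipient %s (%d); recycling",
                donor, len(seq), recip, len(r_order),
            )
            seq = np.resize(seq, len(r_order))
        labels[r_order] = seq[: len(r_order)]
    return sub.with_labels(labels)


def shuffle_instances(table: SampleTable, seed: int = 0) -> SampleTable:
    """Uniform label permutation over all instances."""
    if table.n_instances < 2:
        raise ArgumentError("need at least 2 instances to shuffle")
    rng = np.random.default_rng(seed)
    return table.with_labels(table.labels[rng.permutation(table.n_instances)])


def apply_null(table: SampleTable, null: NullSpec, seed: int | None = None) -> SampleTable:
    """Apply a null spec (optionally overriding its seed)."""
    s = null.seed if seed is None else seed
    if null.kind == "random_by_group":
        return assign_random_labels_by_group(
            table, level=null.level, n_classes=null.n_classes,
            balanced=null.balanced, seed=s,
        )
    if null.kind == "permute_sequences_across_subjects":
        return permute_label_sequences_across_subjects(
            table, min_instances=null.min_instances, seed=s
        )
    return shuffle_instances(table, seed=s)


def permutation_test(
    table: SampleTable,
    scheme: dict,
    model,
    metric: str,
    null: NullSpec,
    n_perm: int = 99,
    seed: int = 0,
) -> NullResult:
    """Permutation test of a cross-validated performance statistic.

    The observed statistic is the cross-fold mean metric on the true
    labels; the null distribution re-randomises the labels ``n_perm`` times
    under ``null`` and re-runs the *same* splitting scheme and model each
    time.  Which structure the null keeps (instances, sessions, subjects)
    determines which hypothesis is being tested; choose it to match the
    grouping of the scientific question.
    """
    if n_perm < 19:
        raise ArgumentError("n_perm must be >= 19 for a minimally useful p-value")
    assignment = make_assignment(table, scheme)
    observed = run_scheme(table, assignment, model, metric=metric).mean
    rng = np.random.default_rng(seed)
    null_vals = np.empty(n_perm)
    for b in range(n_perm):
        child = int(rng.integers(2 ** 31 - 1))
        null_table = apply_null(table, null, seed=child)
        null_assignment = (
            assignment
            if null_table.n_instances == table.n_instances
            else make_assignment(null_table, scheme)
        )
        null_vals[b] = run_scheme(null_table, null_assignment, model, metric=metric).mean
    p = float((1 + np.sum(null_vals >= observed)) / (n_perm + 1))
    return NullResult(
        observed=float(observed), null_values=null_vals, p=p, spec=null, scheme=dict(scheme)
    )
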