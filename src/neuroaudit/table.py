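"""Hierarchical sample tables.

The central container is :class:`SampleTable`: an N x D matrix of derived
features together with per-row hierarchical annotations — subject, session,
optional trial, a within-(subject, session) time index, and a categorical
label.  Rows are *instances* (e.g. one epoched window of neural features);
instances are nested in trials, trials in sessions, sessions in subjects.
This is the structure under which naive instance-level cross-validation
leaks subject identity into the evaluation set, which is the failure mode
the rest of the package diagnoses.

Labels are stored as integer codes with an explicit code-to-name mapping so
reports can print the original class names.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .exceptions import SchemaError, TableValidationError

__all__ = ["SampleTable", "load_table", "save_table", "summarize"]

_SCHEMA_VERSION = "1"
_ANNOTATION_COLUMNS = ("subject_id", "session_id", "trial_id", "time_index", "label")


@dataclass
class SampleTable:
    """Feature matrix plus hierarchical annotations.

    Parameters
    ----------
    features : ndarray, shape (N, D)
        Derived feature vectors, one row per instance.
    labels : ndarray of int, shape (N,)
        Integer label codes indexing into ``label_names``.
    label_names : tuple of str
        Code-to-name mapping; ``label_names[labels[i]]`` is row *i*'s class.
    subject_id, session_id : ndarray of str, shape (N,)
        Hierarchy annotations; sessions are nested within subjects.
    time_index : ndarray of int, shape (N,)
        Within-(subject, session) temporal order; strictly increasing within
        each (subject, session) pair, 0-based by convention.
    trial_id : ndarray of str or None
        Optional trial annotation nested within session.
    """

    features: np.ndarray
    labels: np.ndarray
    label_names: tuple
    subject_id: np.ndarray
    session_id: np.ndarray
    time_index: np.ndarray
    trial_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.label_names = tuple(str(n) for n in self.label_names)
        self.subject_id = np.asarray(self.subject_id, dtype=str)
        self.session_id = np.asarray(self.session_id, dtype=str)
        self.time_index = np.asarray(self.time_index, dtype=int)
        if self.trial_id is not None:
            self.trial_id = np.asarray(self.trial_id, dtype=str)
        self.validate()

    # -- basic geometry ----------------------------------------------------
    @property
    def n_instances(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def n_subjects(self) -> int:
        return len(np.unique(self.subject_id))

    @property
    def n_classes(self) -> int:
        return len(self.label_names)

    def validate(self) -> None:
        if self.features.ndim != 2:
            raise TableValidationError("features must be a 2-D matrix")
        n = self.features.shape[0]
        if self.features.shape[1] < 1:
            raise TableValidationError("need at least one feature column (D >= 1)")
        for name in ("labels", "subject_id", "session_id", "time_index"):
            arr = getattr(self, name)
            if len(arr) != n:
                raise TableValidationError(
                    f"length of {name} ({len(arr)}) does not match N={n}"
                )
        if self.trial_id is not None and len(self.trial_id) != n:
            raise TableValidationError("length of trial_id does not match N")
        if n and (self.labels.min() < 0 or self.labels.max() >= len(self.label_names)):
            raise TableValidationError("label codes outside label_names range")
        if n and self.time_index.min() < 0:
            raise TableValidationError("time_index must be non-negative")
        # strict monotonicity of time within each (subject, session)
        for key, idx in self.groups("session").items():
            t = self.time_index[idx]
            order = np.argsort(t, kind="stable")
            if np.any(np.diff(t[order]) <= 0):
                bad = idx[order][np.flatnonzero(np.diff(t[order]) <= 0)[0] + 1]
                raise TableValidationError(
                    f"time_index not strictly increasing within (subject, session)="
                    f"{key}; first offending row {bad}"
                )

    # -- grouping helpers --------------------------------------------------
    def group_keys(self, level: str) -> np.ndarray:
        """Per-row group key at ``level`` ('subject', 'session' or 'trial')."""
        if level == "subject":
            return self.subject_id
        if level == "session":
            return np.char.add(np.char.add(self.subject_id, "//"), self.session_id)
        if level == "trial":
            if self.trial_id is None:
                raise SchemaError("table has no trial_id; cannot group by trial")
            sess = np.char.add(np.char.add(self.subject_id, "//"), self.session_id)
            return np.char.add(np.char.add(sess, "//"), self.trial_id)
        raise SchemaError(f"unknown grouping level {level!r}")

    def groups(self, level: str) -> dict:
        """Map group key -> row indices (row order preserved)."""
        keys = self.group_keys(level)
        out: dict = {}
        for i, k in enumerate(keys):
            out.setdefault(k, []).append(i)
        return {k: np.asarray(v) for k, v in out.items()}

    def subset(self, indices) -> "SampleTable":
        """Row subset (row order follows ``indices``); label map retained."""
        idx = np.asarray(indices)
        return SampleTable(
            features=self.features[idx],
            labels=self.labels[idx],
            label_names=self.label_names,
            subject_id=self.subject_id[idx],
            session_id=self.session_id[idx],
            time_index=self.time_index[idx],
            trial_id=None if self.trial_id is None else self.trial_id[idx],
        )

    def with_labels(self, labels, label_names=None) -> "SampleTable":
        """Copy of the table with replaced labels; features untouched."""
        return SampleTable(
            features=self.features,
            labels=np.asarray(labels, dtype=int),
            label_names=tuple(label_names) if label_names is not None else self.label_names,
            subject_id=self.subject_id,
            session_id=self.session_id,
            time_index=self.time_index,
            trial_id=self.trial_id,
        )

    # -- interchange -------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        d = {
            "subject_id": self.subject_id,
            "session_id": self.session_id,
            "trial_id": self.trial_id if self.trial_id is not None else [""] * self.n_instances,
            "time_index": self.time_index,
            "label": [self.label_names[c] for c in self.labels],
        }
        for j in range(self.n_features):
            d[f"feature_{j}"] = self.features[:, j]
        return pd.DataFrame(d)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SampleTable":
        for col in ("subject_id", "session_id", "time_index", "label"):
            if col not in df.columns:
                raise SchemaError(f"missing required column {col!r}")
        feat_cols = [c for c in df.columns if str(c).startswith("feature_")]
        if not feat_cols:
            raise SchemaError("no feature_* columns found")
        feat_cols.sort(key=lambda c: int(str(c).split("_", 1)[1]))
        labels_raw = df["label"].astype(str).to_numpy()
        names = tuple(sorted(set(labels_raw)))
        code = {n: i for i, n in enumerate(names)}
        trial = None
        if "trial_id" in df.columns:
            t = df["trial_id"].fillna("").astype(str).to_numpy()
            if np.any(t != ""):
                trial = t
        return cls(
            features=df[feat_cols].to_numpy(dtype=float),
            labels=np.array([code[v] for v in labels_raw]),
            label_names=names,
            subject_id=df["subject_id"].astype(str).to_numpy(),
            session_id=df["session_id"].astype(str).to_numpy(),
            time_index=df["time_index"].to_numpy(dtype=int),
            trial_id=trial,
        )

    def equals(self, other: "SampleTable") -> bool:
        if (self.trial_id is None) != (other.trial_id is None):
            return False
        return (
            np.allclose(self.features, other.features)
            and np.array_equal(self.labels, other.labels)
            and self.label_names == other.label_names
            and np.array_equal(self.subject_id, other.subject_id)
            and np.array_equal(self.session_id, other.session_id)
            and np.array_equal(self.time_index, other.time_index)
            and (self.trial_id is None or np.array_equal(self.trial_id, other.trial_id))
        )


def load_table(path, format: str | None = None) -> SampleTable:
    """Read a :class:`SampleTable` from CSV or HDF5.

    ``format`` defaults to the file suffix (``.csv`` / ``.h5`` / ``.hdf5``).
    Row order is preserved from the file.
    """
    path = Path(path)
    fmt = format or ("hdf5" if path.suffix in (".h5", ".hdf5") else "csv")
    if fmt == "csv":
        return SampleTable.from_frame(pd.read_csv(path))
    if fmt == "hdf5":
        with h5py.File(path, "r") as f:
            for name in ("features", "labels", "subject_id", "session_id", "time_index"):
                if name not in f:
                    raise SchemaError(f"missing required dataset {name!r}")
            trial = f["trial_id"][:].astype(str) if "trial_id" in f else None
            return SampleTable(
                features=f["features"][:],
                labels=f["labels"][:],
                label_names=tuple(json.loads(f.attrs["label_names"])),
                subject_id=f["subject_id"][:].astype(str),
                session_id=f["session_id"][:].astype(str),
                time_index=f["time_index"][:],
                trial_id=trial,
            )
    raise SchemaError(f"unknown format {fmt!r}")


def save_table(table: SampleTable, path, format: str | None = None) -> None:
    """Write a table to CSV or HDF5 so that ``load_table`` round-trips it."""
    path = Path(path)
    fmt = format or ("hdf5" if path.suffix in (".h5", ".hdf5") else "csv")
    if fmt == "csv":
        table.to_frame().to_csv(path, index=False)
        return
    if fmt == "hdf5":
        str_dt = h5py.string_dtype("utf-8")
        with h5py.File(path, "w") as f:
            f.attrs["schema_version"] = _SCHEMA_VERSION
            f.attrs["label_names"] = json.dumps(list(table.label_names))
            f.create_dataset("features", data=table.features)
            f.create_dataset("labels", data=table.labels)
            f.create_dataset("subject_id", data=table.subject_id.astype(object), dtype=str_dt)
            f.create_dataset("session_id", data=table.session_id.astype(object), dtype=str_dt)
            f.create_dataset("time_index", data=table.time_index)
            if table.trial_id is not None:
                f.create_dataset("trial_id", data=table.trial_id.astype(object), dtype=str_dt)
        return
    raise SchemaError(f"unknown format {fmt!r}")


def summarize(table: SampleTable) -> dict:
    """Exact counts at every level of the hierarchy.

    Returns a dict with N, D, M, class counts, sessions per subject and
    instance counts per subject and per (subject, session) group.  Counts are
    invariant under row permutation of the table.
    """
    subj_groups = table.groups("subject")
    sess_groups = table.groups("session")
    class_counts = {
        name: int(np.sum(table.labels == code))
        for code, name in enumerate(table.label_names)
    }
    sessions_per_subject = {
        s: len({k for k in sess_groups if k.split("//")[0] == s}) for s in subj_groups
    }
    out = {
        "n_instances": table.n_instances,
        "n_features": table.n_features,
        "n_subjects": table.n_subjects,
        "n_sessions": len(sess_groups),
        "n_classes": table.n_classes,
        "class_counts": class_counts,
        "sessions_per_subject": sessions_per_subject,
        "instances_per_subject": {k: len(v) for k, v in sorted(subj_groups.items())},
        "instances_per_session": {k: len(v) for k, v in sorted(sess_groups.items())},
    }
    if table.trial_id is not None:
        out["n_trials"] = len(table.groups("trial"))
    return out
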