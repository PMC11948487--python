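"""The reference classifier and the fold runner.

The reference model is a deliberately ordinary multi-layer perceptron with a
single hidden layer of ReLU units (presets: 10 units for small binary
problems, 256 for larger multiclass ones), trained with a fixed epoch
budget and no early stopping — early stopping would itself consume a
validation split and muddy the demonstrations.  The point is not predictive
optimality: over-parameterised networks routinely drive training error to
zero while generalising, which is exactly the regime in which evaluating on
training data (or on leaked instances) reports near-perfect, meaningless
scores.

:func:`run_scheme` evaluates any sklearn-style classifier over a
:class:`~neuroaudit.splitters.FoldAssignment`, refitting from scratch per
fold.  Feature standardisation is estimated on each fold's training rows
only and applied to its evaluation rows — normalisation statistics computed
on all data are themselves a leak.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import clone
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .exceptions import ArgumentError
from .metrics import compute_metric
from .splitters import FoldAssignment
from .table import SampleTable

__all__ = ["ClassifierSpec", "FoldScores", "build_estimator", "fit", "run_scheme"]


@dataclass
class ClassifierSpec:
    """One-hidden-layer ReLU network trained with a fixed epoch budget.

    Parameters
    ----------
    hidden_units : int
        Width of the single hidden layer (presets 10 and 256).
    epochs : int
        Fixed number of passes over the training data; no early stopping.
    step_size : float
        Adam step size.
    batch_size : int or "full"
        Minibatch size; "full" uses the whole training set per step, which
        makes the fit invariant to training-row order.
    seed : int
        Initialisation / shuffling seed; identical seeds give identical fits.
    """

    hidden_units: int = 10
    epochs: int = 200
    step_size: float = 1e-3
    batch_size: int | str = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_units < 1:
            raise ArgumentError("hidden_units must be >= 1")
        if self.epochs < 1:
            raise ArgumentError("epochs must be >= 1")


def build_estimator(spec: ClassifierSpec):
    """Materialise the spec as an sklearn estimator."""
    batch = spec.batch_size
    return MLPClassifier(
        hidden_layer_sizes=(spec.hidden_units,),
        activation="relu",
        solver="adam",
        learning_rate_init=spec.step_size,
        batch_size=(2 ** 31 - 1) if batch == "full" else batch,
        max_iter=spec.epochs,
        n_iter_no_change=spec.epochs + 1,  # disable early stopping
        tol=0.0,
        alpha=0.0,
        random_state=spec.seed,
    )


def _as_estimator(model, seed: int | None = None):
    if isinstance(model, ClassifierSpec):
        if seed is not None:
            model = ClassifierSpec(
                hidden_units=model.hidden_units, epochs=model.epochs,
                step_size=model.step_size, batch_size=model.batch_size, seed=seed,
            )
        return build_estimator(model)
    est = clone(model)
    if seed is not None and "random_state" in est.get_params():
        est.set_params(random_state=seed)
    return est


def fit(spec, features, labels, seed: int | None = None):
    """Fit the reference model (or any sklearn classifier) on raw arrays.

    Deterministic given (spec, data, seed).  Raises if the training labels
    contain a single class — a classifier cannot be trained on one class,
    and silently returning a constant predictor would hide fold-design
    errors.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ArgumentError("training labels contain a single class")
    est = _as_estimator(spec, seed)
    if isinstance(spec, ClassifierSpec) and spec.batch_size == "full":
        est.set_params(batch_size=len(labels))
    with warnings.catch_warnings():
        # a fixed epoch budget is deliberate; "not converged" is expected
        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(np.asarray(features, dtype=float), labels)
    return est


@dataclass
class FoldScores:
    """Per-fold fitted models, eval scores and the cross-fold aggregate."""

    scheme: str
    metric: str
    fold_values: np.ndarray
    models: list = field(repr=False, default_factory=list)
    eval_scores: list = field(repr=False, default_factory=list)  # per fold: per-instance class scores
    eval_indices: list = field(repr=False, default_factory=list)
    diagnostic_only: bool = False
    notes: list = field(default_factory=list)

    @property
    def mean(self) -> float:
        return float(np.nanmean(self.fold_values))

    @property
    def sd(self) -> float:
        defined = self.fold_values[~np.isnan(self.fold_values)]
        if len(defined) < 2:
            return float("nan")
        return float(np.std(defined, ddof=1))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        sd = "N/A" if np.isnan(self.sd) else f"{self.sd:.3f}"
        return f"{self.scheme}: {self.metric} {self.mean:.3f} ({sd})"


def run_scheme(
    table: SampleTable,
    assignment: FoldAssignment,
    spec,
    metric: str = "accuracy",
    standardize: bool = True,
) -> FoldScores:
    """Refit-per-fold evaluation of a classifier under a fold assignment.

    The model (and the feature standardiser, when enabled) sees only the
    fold's training rows; the metric is computed only on the fold's eval
    rows.  Folds whose training labels collapse to one class are a design
    error and raise.
    """
    values, models, scores_all, notes = [], [], [], list(assignment.notes)
    for tr, ev in assignment.folds:
        est = _as_estimator(spec)
        if isinstance(spec, ClassifierSpec) and spec.batch_size == "full":
            est.set_params(batch_size=len(tr))
        if standardize:
            est = Pipeline([("scale", StandardScaler()), ("clf", est)])
        y_tr = table.labels[tr]
        if len(np.unique(y_tr)) < 2:
            raise ArgumentError("a fold's training labels contain a single class")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            est.fit(table.features[tr], y_tr)
        y_ev = table.labels[ev]
        missing = np.setdiff1d(np.unique(y_ev), np.unique(y_tr))
        if missing.size:
            notes.append(
                f"eval fold contains classes absent from training: {missing.tolist()}"
            )
        pred = est.predict(table.features[ev])
        proba = est.predict_proba(table.features[ev])
        if metric == "auc":
            if len(np.unique(y_ev)) < 2:
                # AUC is undefined on a single-class eval fold (can happen
                # under group splits of group-constant labels); record NaN
                notes.append("AUC undefined on single-class eval fold; recorded NaN")
                values.append(np.nan)
            else:
                pos = est.classes_[-1]
                col = int(np.flatnonzero(est.classes_ == pos)[0])
                values.append(compute_metric("auc", y_ev, scores=proba[:, col]))
        else:
            values.append(compute_metric(metric, y_ev, predicted=pred))
        models.append(est)
        scores_all.append(proba)
    return FoldScores(
        scheme=assignment.scheme,
        metric=metric,
        fold_values=np.asarray(values, dtype=float),
        models=models,
        eval_scores=scores_all,
        eval_indices=[ev for _, ev in assignment.folds],
        diagnostic_only=assignment.diagnostic_only,
        notes=notes,
    )
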