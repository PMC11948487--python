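"""The audit battery: a model/results pair over a sample table.

:class:`ValidationAudit` is constructed from a :class:`SampleTable` and a
scientific question:

* **a** — predict targets on new instances from the same subjects
  (matched scheme: instance K-fold);
* **b** — predict targets on a new session from the same subjects
  (matched scheme: session group K-fold);
* **c** — predict targets on entirely new subjects
  (matched scheme: subject group K-fold).

(A fourth level — new recording site/center — cannot be assessed from
single-source data and is reported as such rather than omitted.)

``fit()`` runs the question-matched scheme plus a diagnostic battery
(no-validation, instance K-fold, time K-fold where time structure exists),
identity probes, a group-constant random-label control at the question's
grouping level, analytic chance levels, and the corrected resampled t-test
for the instance-vs-matched contrast.  It returns an
:class:`AuditResults` carrying the numbers, the flags and a ``summary()``
table.

Flags (each traceable to a recorded numeric comparison):

* ``leakage_suspected`` — instance-split performance exceeds the matched
  scheme's upper confidence limit; sub-criteria (mean±sd interval
  non-overlap, corrected-t p < 0.05) are reported individually;
* ``identity_memorization`` — instance-split performance on group-constant
  *random* labels exceeds the analytic chance bound: the classifier can
  recover labels that carry no information, by memorising group identity;
* ``no_generalization_evidence`` — the question-matched scheme does not
  beat its analytic chance bound.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from statsmodels.iolib.table import SimpleTable

from . import __version__ as _version
from .exceptions import ArgumentError
from .metrics import ChanceEstimate, chance_level, corrected_ttest
from .model import ClassifierSpec, FoldScores, run_scheme
from .nulls import NullSpec, apply_null
from .splitters import make_assignment
from .table import SampleTable, summarize

__all__ = ["ValidationAudit", "AuditResults", "identity_probe", "QUESTION_SCHEMES"]

QUESTION_SCHEMES = {
    "a": {"scheme": "instance_kfold", "question": "new instances, same subjects"},
    "b": {"scheme": "group_kfold", "level": "session", "question": "new session, same subjects"},
    "c": {"scheme": "group_kfold", "level": "subject", "question": "new subjects, same site"},
}


def identity_probe(
    table: SampleTable,
    target: str,
    scheme: dict,
    spec=None,
    metric: str = "accuracy",
) -> FoldScores:
    """Train a classifier to predict subject or session identity.

    Quantifies how strongly identity is encoded in the features — the raw
    material of leakage.  Probing an identity under a grouping scheme that
    holds that same identity out is impossible by construction (every eval
    group is a class never seen in training) and is rejected.
    """
    if target not in ("subject", "session"):
        raise ArgumentError("probe target must be 'subject' or 'session'")
    if scheme.get("scheme") in ("group", "group_kfold") and scheme.get("level") == target:
        raise ArgumentError(
            f"cannot probe {target} identity under {target}-grouped folds: every "
            "eval group is a class absent from training; the task is impossible "
            "by construction"
        )
    keys = table.group_keys(target)
    names = tuple(sorted(set(keys)))
    code = {k: i for i, k in enumerate(names)}
    probe_table = table.with_labels(
        np.array([code[k] for k in keys]), names
    )
    if spec is None:
        spec = ClassifierSpec(hidden_units=256)
    assignment = make_assignment(probe_table, scheme)
    fs = run_scheme(probe_table, assignment, spec, metric=metric)
    fs.notes.append(f"identity probe: target={target}, chance=1/{len(names)}")
    return fs


@dataclass
class ValidationAudit:
    """Audit model: a table, a question, and the battery configuration.

    Parameters
    ----------
    table : SampleTable
        The data under audit.
    question : {"a", "b", "c"}
        Scientific question the study claims to answer; fixes the matched
        splitting scheme.
    classifier : ClassifierSpec or sklearn classifier
        Reference model for every battery entry.
    metric : str
        accuracy | balanced_accuracy | auc.
    k : int
        Fold count for K-fold schemes.
    seed : int
        Master seed; every stochastic component derives from it and is
        echoed in the results for bit reproducibility.
    """

    table: SampleTable
    question: str = "c"
    classifier: object = field(default_factory=ClassifierSpec)
    metric: str = "accuracy"
    k: int = 5
    seed: int = 0
    alpha: float = 0.05
    run_time_scheme: bool = True
    run_probes: bool = True

    def __post_init__(self) -> None:
        if self.question not in QUESTION_SCHEMES:
            raise ArgumentError("question must be one of 'a', 'b', 'c'")
        self._check_feasible()

    def _check_feasible(self) -> None:
        t = self.table
        missing = []
        if self.question == "b":
            spst = summarize(t)["sessions_per_subject"]
            if min(spst.values()) < 2:
                missing.append("question (b) requires multiple sessions per subject")
            if len(t.groups("session")) < self.k:
                missing.append(f"question (b) requires >= k={self.k} sessions")
        if self.question == "c" and t.n_subjects < self.k:
            missing.append(f"question (c) requires >= k={self.k} subjects")
        if t.n_instances < self.k:
            missing.append(f"table has fewer than k={self.k} instances")
        if missing:
            raise ArgumentError("; ".join(missing))

    @classmethod
    def from_dataframe(cls, df, **kwargs) -> "ValidationAudit":
        """Build the audit from a tidy DataFrame (see SampleTable.from_frame)."""
        return cls(table=SampleTable.from_frame(df), **kwargs)

    # ------------------------------------------------------------------
    def fit(self) -> "AuditResults":
        """Run the full battery and return the results object."""
        t = self.table
        q = self.question
        matched_spec = dict(QUESTION_SCHEMES[q])
        matched_spec.pop("question")
        matched_spec.update(k=self.k, seed=self.seed)

        scheme_specs = {"no_validation": {"scheme": "no_validation"}}
        scheme_specs["instance_kfold"] = {
            "scheme": "instance_kfold", "k": self.k, "seed": self.seed,
        }
        matched_name = (
            "instance_kfold" if q == "a" else f"group_kfold[{matched_spec['level']}]"
        )
        if q != "a":
            scheme_specs[matched_name] = matched_spec
        if self.run_time_scheme:
            min_group = min(len(v) for v in t.groups("session").values())
            if min_group >= self.k:
                scheme_specs["time_kfold"] = {"scheme": "time_kfold", "k": self.k}

        scores: dict = {}
        for name, spec in scheme_specs.items():
            assignment = make_assignment(t, spec)
            scores[name] = run_scheme(t, assignment, self.classifier, metric=self.metric)

        # identity probes under the instance split (never under a grouping
        # that holds the probed identity out)
        probes: dict = {}
        if self.run_probes:
            probe_spec = {"scheme": "instance_kfold", "k": self.k, "seed": self.seed}
            probes["subject"] = identity_probe(
                t, "subject", probe_spec, spec=self.classifier, metric="accuracy"
            )
            if len(t.groups("session")) > t.n_subjects:
                probes["session"] = identity_probe(
                    t, "session", probe_spec, spec=self.classifier, metric="accuracy"
                )

        # group-constant random-label control at the question's grouping level
        null_level = {"a": None, "b": "session", "c": "subject"}[q]
        null_scores: dict = {}
        if null_level is not None:
            null = NullSpec(
                kind="random_by_group", level=null_level,
                n_classes=t.n_classes, balanced=True, seed=self.seed,
            )
            null_table = apply_null(t, null)
            for name in ("instance_kfold", matched_name):
                assignment = make_assignment(t, scheme_specs[name])
                null_scores[name] = run_scheme(
                    null_table, assignment, self.classifier, metric=self.metric
                )

        # chance level on the matched scheme's typical eval-fold size
        matched = scores[matched_name]
        eval_n = int(np.median([len(ev) for ev in matched.eval_indices]))
        priors = np.bincount(t.labels, minlength=t.n_classes) / t.n_instances
        chance = chance_level(eval_n, priors, alpha=self.alpha)

        # pairwise corrected resampled t-tests between schemes sharing a
        # fold count (the instance-vs-matched contrast is the headline one)
        pairwise: dict = {}
        names = [n for n in scores if n != "no_validation"]
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                fa, fb = scores[a].fold_values, scores[b].fold_values
                if len(fa) != len(fb):
                    continue
                diffs = fa - fb
                if np.std(diffs, ddof=1) > 0:
                    pairwise[f"{a} - {b}"] = corrected_ttest(diffs, rho_mode="one_over_k")
        ttest = pairwise.get(f"instance_kfold - {matched_name}")

        flags = self._flags(scores, null_scores, matched_name, chance, ttest)
        return AuditResults(
            model=self,
            scores=scores,
            probes=probes,
            null_scores=null_scores,
            chance=chance,
            ttest=ttest,
            pairwise_ttests=pairwise,
            flags=flags,
            matched_scheme=matched_name,
        )

    def _flags(self, scores, null_scores, matched_name, chance, ttest) -> dict:
        flags: dict = {}
        inst = scores["instance_kfold"]
        matched = scores[matched_name]
        if matched_name != "instance_kfold":
            upper = matched.mean + matched.sd
            interval_sep = (inst.mean - inst.sd) > (matched.mean + matched.sd)
            t_sig = bool(ttest is not None and ttest.p < 0.05 and ttest.mean_diff > 0)
            flags["leakage_suspected"] = {
                "raised": bool(inst.mean > upper),
                "instance_mean": inst.mean,
                "matched_upper": float(upper),
                "interval_nonoverlap": bool(interval_sep),
                "corrected_t_significant": t_sig,
            }
        if null_scores:
            null_inst = null_scores["instance_kfold"]
            flags["identity_memorization"] = {
                "raised": bool(null_inst.mean > chance.analytic_bound),
                "instance_mean_on_random_labels": null_inst.mean,
                "chance_bound": chance.analytic_bound,
            }
        flags["no_generalization_evidence"] = {
            "raised": bool(matched.mean <= chance.analytic_bound),
            "matched_mean": matched.mean,
            "chance_bound": chance.analytic_bound,
        }
        raised = [k for k, v in flags.items() if v["raised"]]
        if {"identity_memorization", "no_generalization_evidence"} <= set(raised):
            flags["pattern"] = "memorization without generalization"
        return flags


@dataclass
class AuditResults:
    """Everything the audit measured, plus provenance to regenerate it."""

    model: ValidationAudit
    scores: dict
    probes: dict
    null_scores: dict
    chance: ChanceEstimate
    ttest: object
    flags: dict
    matched_scheme: str
    pairwise_ttests: dict = field(default_factory=dict)

    # ------------------------------------------------------------------
    def summary(self) -> SimpleTable:
        """Cross-scheme performance table (fold sd in parentheses)."""
        rows, data = [], []
        targets = [self.model.metric] + [f"{p}-ID probe" for p in self.probes] + (
            ["random-by-group"] if self.null_scores else []
        )
        for name, fs in self.scores.items():
            label = name + (" [diagnostic]" if fs.diagnostic_only else "")
            row = [self._cell(fs)]
            for p in self.probes:
                row.append(self._cell(self.probes[p]) if name == "instance_kfold" else "N/A")
            if self.null_scores:
                row.append(
                    self._cell(self.null_scores[name]) if name in self.null_scores else "N/A"
                )
            rows.append(label)
            data.append(row)
        title = (
            f"Validation audit — question ({self.model.question}): "
            f"{QUESTION_SCHEMES[self.model.question]['question']}"
        )
        return SimpleTable(data, headers=targets, stubs=rows, title=title)

    @staticmethod
    def _cell(fs: FoldScores) -> str:
        sd = "N/A" if np.isnan(fs.sd) else f"{fs.sd:.3f}"
        return f"{fs.mean:.3f} ({sd})"

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        def fs_dict(fs: FoldScores) -> dict:
            return {
                "scheme": fs.scheme,
                "metric": fs.metric,
                "fold_values": fs.fold_values.tolist(),
                "mean": fs.mean,
                "sd": None if np.isnan(fs.sd) else fs.sd,
                "diagnostic_only": fs.diagnostic_only,
                "notes": list(fs.notes),
            }

        out = {
            "provenance": {
                "package_version": _version,
                "question": self.model.question,
                "metric": self.model.metric,
                "k": self.model.k,
                "seed": self.model.seed,
                "alpha": self.model.alpha,
                "n_instances": self.model.table.n_instances,
                "n_subjects": self.model.table.n_subjects,
            },
            "question_map": {
                q: v["question"] for q, v in QUESTION_SCHEMES.items()
            },
            "external_validity": "new center/site: not assessable from single-source data",
            "matched_scheme": self.matched_scheme,
            "schemes": {k: fs_dict(v) for k, v in self.scores.items()},
            "probes": {k: fs_dict(v) for k, v in self.probes.items()},
            "null_controls": {k: fs_dict(v) for k, v in self.null_scores.items()},
            "chance": {
                "theoretical": self.chance.theoretical,
                "analytic_bound": self.chance.analytic_bound,
                "n": self.chance.n,
                "alpha": self.chance.alpha,
            },
            "flags": self.flags,
        }
        def tt_dict(tt) -> dict:
            return {
                "mean_diff": tt.mean_diff, "se": tt.se, "t": tt.t,
                "df": tt.df, "p": tt.p, "ci": [tt.ci_low, tt.ci_high],
            }

        if self.ttest is not None:
            out["corrected_ttest"] = {
                "contrast": f"instance_kfold - {self.matched_scheme}",
                **tt_dict(self.ttest),
            }
        out["pairwise_ttests"] = {k: tt_dict(v) for k, v in self.pairwise_ttests.items()}
        return out

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)

    def render_markdown(self) -> str:
        """Markdown report mirroring the cross-scheme table layout."""
        d = self.to_dict()
        lines = [
            "# Validation audit report",
            "",
            f"Question ({self.model.question}): "
            f"{QUESTION_SCHEMES[self.model.question]['question']}  ",
            f"Metric: {self.model.metric}; k = {self.model.k}; seed = {self.model.seed}",
            "",
            "| Validation procedure | " + " | ".join(
                [self.model.metric]
                + [f"{p}-ID probe" for p in self.probes]
                + (["random-by-group"] if self.null_scores else [])
            ) + " |",
        ]
        ncols = 1 + len(self.probes) + (1 if self.null_scores else 0)
        lines.append("|---" * (ncols + 1) + "|")
        for name, fs in self.scores.items():
            label = name + (" *(diagnostic only — bad practice)*" if fs.diagnostic_only else "")
            cells = [self._cell(fs)]
            for p in self.probes:
                cells.append(self._cell(self.probes[p]) if name == "instance_kfold" else "N/A")
            if self.null_scores:
                cells.append(
                    self._cell(self.null_scores[name]) if name in self.null_scores else "N/A"
                )
            lines.append(f"| {label} | " + " | ".join(cells) + " |")
        lines += [
            "",
            f"Chance: theoretical {self.chance.theoretical:.3f}; significance bound "
            f"{self.chance.analytic_bound:.3f} (alpha={self.chance.alpha}, n={self.chance.n})",
            "",
        ]
        if self.ttest is not None:
            tt = d["corrected_ttest"]
            lines.append(
                f"Corrected resampled t-test ({tt['contrast']}): mean diff "
                f"{tt['mean_diff']:.3f} [95% CI: {tt['ci'][0]:.3f}, {tt['ci'][1]:.3f}], "
                f"p = {tt['p']:.3f}"
            )
            lines.append("")
        lines.append("## Flags")
        for k, v in self.flags.items():
            if k == "pattern":
                lines.append(f"- **pattern**: {v}")
            else:
                lines.append(f"- {k}: {'RAISED' if v['raised'] else 'clear'} ({v})")
        lines.append("")
        lines.append(f"External validity: {d['external_validity']}")
        return "\n".join(lines)
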