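"""Machine-readable reporting checklist.

The checklist (38 items in five categories — data and split definition,
parameter/hyperparameter selection, performance metrics, scientific
conclusions, and future use of results) ships as a versioned JSON data
file so wording updates never require code changes.  Every item takes one
of four answers: yes / no / unclear / n-a.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

from .exceptions import ArgumentError

__all__ = [
    "ChecklistResponse",
    "load_checklist",
    "checklist_validate",
    "render_checklist",
]

_ANSWERS = ("yes", "no", "unclear", "n/a")


@dataclass
class ChecklistResponse:
    item_id: str
    answer: str
    note: str = ""

    def __post_init__(self) -> None:
        a = self.answer.strip().lower()
        if a in ("n-a", "na"):
            a = "n/a"
        if a not in _ANSWERS:
            raise ArgumentError(
                f"answer must be one of {_ANSWERS}; got {self.answer!r}"
            )
        self.answer = a


def load_checklist() -> dict:
    """Load the bundled checklist schema."""
    with resources.files("neuroaudit.data").joinpath("checklist.json").open() as f:
        return json.load(f)


def _all_items(schema: dict) -> dict:
    return {
        item["id"]: (cat, item)
        for cat in schema["categories"]
        for item in cat["items"]
    }


def checklist_validate(responses, schema: dict | None = None) -> dict:
    """Check a list of responses for unknown ids and completeness.

    Returns {"complete": bool, "missing": [...], "n_items": int,
    "responses": {item_id: ChecklistResponse}}.
    """
    schema = schema or load_checklist()
    items = _all_items(schema)
    seen: dict = {}
    for r in responses:
        if not isinstance(r, ChecklistResponse):
            r = ChecklistResponse(**r)
        if r.item_id not in items:
            raise ArgumentError(f"unknown checklist item id {r.item_id!r}")
        seen[r.item_id] = r
    missing = [i for i in items if i not in seen]
    return {
        "complete": not missing,
        "missing": missing,
        "n_items": len(items),
        "responses": seen,
    }


def render_checklist(responses=None, schema: dict | None = None) -> str:
    """Render the checklist as markdown, one section per category.

    With ``responses`` the chosen answer is marked; without, an empty
    answer grid is produced.
    """
    schema = schema or load_checklist()
    answered = {}
    if responses:
        answered = checklist_validate(responses, schema)["responses"]
    lines = [f"# {schema['title']}", ""]
    for cat in schema["categories"]:
        lines.append(f"## {cat['name']}")
        if cat.get("note"):
            lines.append(f"*{cat['note']}*")
        lines.append("")
        lines.append("| Item | Question | " + " | ".join(a.capitalize() for a in _ANSWERS) + " |")
        lines.append("|---|---|" + "---|" * len(_ANSWERS))
        for item in cat["items"]:
            r = answered.get(item["id"])
            marks = [
                "x" if (r is not None and r.answer == a) else " " for a in _ANSWERS
            ]
            lines.append(
                f"| {item['id']} | {item['text']} | " + " | ".join(marks) + " |"
            )
            if r is not None and r.note:
                lines.append(f"| | note: {r.note} | | | | |")
        lines.append("")
    return "\n".join(lines)
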