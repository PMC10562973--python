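"""Branching electronic questionnaire definitions and patient response sets.

A questionnaire is an ordered list of items (single-choice, multi-choice,
numeric, free-text) plus branch rules: answering a trigger item with one of
its trigger options reveals further detail items.  Items never revealed by
any branch are "top-level" and always visible; revealed items may themselves
trigger deeper branches, so the branch graph is a DAG of arbitrary finite
depth (the packaged preadmission instrument uses at most two levels).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Any, Mapping, Optional, Sequence

import yaml

ITEM_KINDS = ("single_choice", "multi_choice", "numeric", "free_text")
CHOICE_KINDS = ("single_choice", "multi_choice")


class DefinitionMismatchError(ValueError):
    """A response set refers to a different questionnaire than the one given."""


class InvalidDefinitionError(ValueError):
    """The questionnaire definition violates its structural invariants."""


@dataclass(frozen=True)
class NumericRange:
    min: float
    max: float
    unit: str = ""


@dataclass(frozen=True)
class QuestionItem:
    id: str
    prompt: str
    kind: str
    options: tuple[str, ...] = ()
    numeric_range: Optional[NumericRange] = None


@dataclass(frozen=True)
class BranchRule:
    trigger_item: str
    trigger_options: tuple[str, ...]
    revealed_items: tuple[str, ...]


@dataclass(frozen=True)
class QuestionnaireDef:
    id: str
    title: str
    items: tuple[QuestionItem, ...]
    branches: tuple[BranchRule, ...] = ()

    def item_map(self) -> dict[str, QuestionItem]:
        return {it.id: it for it in self.items}

    def revealed_ids(self) -> set[str]:
        out: set[str] = set()
        for br in self.branches:
            out.update(br.revealed_items)
        return out

    def top_level_items(self) -> tuple[QuestionItem, ...]:
        hidden = self.revealed_ids()
        return tuple(it for it in self.items if it.id not in hidden)


@dataclass
class ResponseSet:
    questionnaire_id: str
    answers: dict[str, Any] = field(default_factory=dict)
    answered_by: str = "self"
    completed_at: Optional[str] = None

    def __eq__(self, other: object) -> bool:  # multi-choice order-insensitive
        if not isinstance(other, ResponseSet):
            return NotImplemented

        def norm(a: Mapping[str, Any]) -> dict[str, Any]:
            return {
                k: tuple(sorted(v)) if isinstance(v, (list, tuple, set)) else v
                for k, v in a.items()
            }

        return (
            self.questionnaire_id == other.questionnaire_id
            and norm(self.answers) == norm(other.answers)
            and self.answered_by == other.answered_by
            and self.completed_at == other.completed_at
        )


# ---------------------------------------------------------------------------
# validation

def validate_definition(qdef: QuestionnaireDef) -> list[str]:
    """Check every structural invariant; return human-readable issues.

    An empty list means the definition is valid.  Issues name the offending
    item or branch so fixture authors can locate them.
    """
    issues: list[str] = []
    seen: set[str] = set()
    for it in qdef.items:
        if it.id in seen:
            issues.append(f"duplicate item id {it.id!r}")
        seen.add(it.id)
        if it.kind not in ITEM_KINDS:
            issues.append(f"item {it.id!r}: unknown kind {it.kind!r}")
        if it.kind in CHOICE_KINDS and len(it.options) < 2:
            issues.append(f"item {it.id!r}: choice item needs >=2 options")
        if it.kind not in CHOICE_KINDS and it.options:
            issues.append(f"item {it.id!r}: non-choice item must not have options")
        if it.kind == "numeric":
            if it.numeric_range is None:
                issues.append(f"item {it.id!r}: numeric item needs a numeric_range")
            elif it.numeric_range.min > it.numeric_range.max:
                issues.append(f"item {it.id!r}: numeric_range min > max")

    ids = {it.id for it in qdef.items}
    items = qdef.item_map()
    for i, br in enumerate(qdef.branches):
        label = f"branch[{i}] (trigger {br.trigger_item!r})"
        if br.trigger_item not in ids:
            issues.append(f"{label}: unknown trigger item {br.trigger_item!r}")
        else:
            trig = items[br.trigger_item]
            if trig.kind not in CHOICE_KINDS:
                issues.append(f"{label}: trigger item is not a choice item")
            else:
                for opt in br.trigger_options:
                    if opt not in trig.options:
                        issues.append(f"{label}: trigger option {opt!r} not an option of {br.trigger_item!r}")
        if not br.revealed_items:
            issues.append(f"{label}: revealed_items is empty")
        for tid in br.revealed_items:
            if tid not in ids:
                issues.append(f"{label}: reveals unknown item {tid!r}")

    # cycle check on the reveal graph (trigger -> revealed)
    graph: dict[str, set[str]] = {i: set() for i in ids}
    for br in qdef.branches:
        if br.trigger_item in graph:
            graph[br.trigger_item].update(t for t in br.revealed_items if t in ids)
    state: dict[str, int] = {}

    def dfs(node: str, path: list[str]) -> None:
        state[node] = 1
        for nxt in graph[node]:
            if state.get(nxt) == 1:
                issues.append(f"branch cycle involving item {nxt!r} (via {' -> '.join(path + [node, nxt])})")
            elif state.get(nxt) is None:
                dfs(nxt, path + [node])
        state[node] = 2

    for node in graph:
        if state.get(node) is None:
            dfs(node, [])
    return issues


# ---------------------------------------------------------------------------
# visibility

def _branch_active(br: BranchRule, answer: Any) -> bool:
    if answer is None:
        return False
    if isinstance(answer, (list, tuple, set)):
        return any(a in br.trigger_options for a in answer)
    return answer in br.trigger_options


def _visible_ids(qdef: QuestionnaireDef, answers: Mapping[str, Any]) -> set[str]:
    """Fixpoint of top-level items plus items revealed by answers on
    already-visible trigger items (answers on hidden items never reveal)."""
    visible = {it.id for it in qdef.top_level_items()}
    changed = True
    while changed:
        changed = False
        for br in qdef.branches:
            if br.trigger_item in visible and _branch_active(br, answers.get(br.trigger_item)):
                for tid in br.revealed_items:
                    if tid not in visible:
                        visible.add(tid)
                        changed = True
    return visible


def visible_items(qdef: QuestionnaireDef, partial: ResponseSet) -> list[QuestionItem]:
    """Items currently presented to the patient, in definition order."""
    if partial.questionnaire_id != qdef.id:
        raise DefinitionMismatchError(
            f"response is for questionnaire {partial.questionnaire_id!r}, not {qdef.id!r}"
        )
    vis = _visible_ids(qdef, partial.answers)
    return [it for it in qdef.items if it.id in vis]


# ---------------------------------------------------------------------------
# path enumeration

def _activation_signatures(item: QuestionItem, rules: Sequence[int],
                           branches: Sequence[BranchRule]) -> list[frozenset[int]]:
    """Distinct sets of this item's branch rules that some answer activates."""
    sigs: set[frozenset[int]] = set()
    if item.kind == "single_choice":
        for opt in item.options:
            sigs.add(frozenset(i for i in rules if opt in branches[i].trigger_options))
    elif item.kind == "multi_choice":
        # any selected option activates; a complete answer selects at least
        # one option, so signatures are unions over nonempty selections
        per_opt = [frozenset(i for i in rules if opt in branches[i].trigger_options)
                   for opt in item.options]
        per_opt = list({s for s in per_opt})
        for r in range(1, len(per_opt) + 1):
            for combo in itertools.combinations(per_opt, r):
                sigs.add(frozenset().union(*combo))
    else:  # numeric / free_text items cannot trigger branches
        sigs.add(frozenset())
    return sorted(sigs, key=lambda s: sorted(s))


def enumerate_answer_paths(qdef: QuestionnaireDef) -> tuple[int, int]:
    """(min, max) number of items visible over all complete answer paths.

    Exhaustive search over the distinct branch-activation patterns of every
    trigger item reachable along the path; exact for any DAG-shaped
    definition (the graphs in practice are small).
    """
    issues = validate_definition(qdef)
    if issues:
        raise InvalidDefinitionError("; ".join(issues))

    branches = qdef.branches
    items = qdef.item_map()
    rules_by_item: dict[str, list[int]] = {}
    for i, br in enumerate(branches):
        rules_by_item.setdefault(br.trigger_item, []).append(i)
    sig_by_item = {
        iid: _activation_signatures(items[iid], idxs, branches)
        for iid, idxs in rules_by_item.items()
    }
    top = {it.id for it in qdef.top_level_items()}

    best = [len(qdef.items) + 1, -1]  # min, max

    def visible_for(chosen: dict[str, frozenset[int]]) -> set[str]:
        vis = set(top)
        changed = True
        while changed:
            changed = False
            for iid, sig in chosen.items():
                if iid not in vis:
                    continue
                for ridx in sig:
                    for tid in branches[ridx].revealed_items:
                        if tid not in vis:
                            vis.add(tid)
                            changed = True
        return vis

    def search(chosen: dict[str, frozenset[int]]) -> None:
        vis = visible_for(chosen)
        pending = [iid for iid in sig_by_item if iid in vis and iid not in chosen]
        if not pending:
            n = len(vis)
            best[0] = min(best[0], n)
            best[1] = max(best[1], n)
            return
        iid = pending[0]
        for sig in sig_by_item[iid]:
            chosen[iid] = sig
            search(chosen)
            del chosen[iid]

    search({})
    return best[0], best[1]


# ---------------------------------------------------------------------------
# response validation

def _answer_type_issue(item: QuestionItem, value: Any) -> Optional[str]:
    if item.kind == "single_choice":
        if not isinstance(value, str) or value not in item.options:
            return f"item {item.id!r}: {value!r} is not one of its options"
    elif item.kind == "multi_choice":
        if not isinstance(value, (list, tuple, set)) or not value:
            return f"item {item.id!r}: multi-choice answer must be a nonempty selection"
        else:
            bad = [v for v in value if v not in item.options]
            if bad:
                return f"item {item.id!r}: {bad!r} are not options"
    elif item.kind == "numeric":
        if isinstance(value, bool) or not isinstance(value, (int, float)):
            return f"item {item.id!r}: numeric answer expected, got {value!r}"
        rng = item.numeric_range
        if rng is not None and not (rng.min <= float(value) <= rng.max):
            return (f"item {item.id!r}: {value} outside range "
                    f"[{rng.min}, {rng.max}] {rng.unit}".rstrip())
    elif item.kind == "free_text":
        if not isinstance(value, str):
            return f"item {item.id!r}: free-text answer must be a string"
    return None


def validate_response(qdef: QuestionnaireDef, resp: ResponseSet) -> list[str]:
    """Consistency plus completeness: every visible item must be answered,
    no hidden item may carry an answer, every answer must type-check."""
    issues: list[str] = []
    if resp.questionnaire_id != qdef.id:
        issues.append(
            f"response questionnaire id {resp.questionnaire_id!r} != {qdef.id!r}")
        return issues
    items = qdef.item_map()
    for iid, value in resp.answers.items():
        if iid not in items:
            issues.append(f"answer for unknown item {iid!r}")
            continue
        issue = _answer_type_issue(items[iid], value)
        if issue:
            issues.append(issue)
    well_typed = {iid: v for iid, v in resp.answers.items()
                  if iid in items and _answer_type_issue(items[iid], v) is None}
    vis = _visible_ids(qdef, well_typed)
    for iid in resp.answers:
        if iid in items and iid not in vis:
            issues.append(f"answer present for hidden item {iid!r}")
    for iid in vis:
        if iid not in resp.answers:
            issues.append(f"visible item {iid!r} is unanswered")
    return issues


# ---------------------------------------------------------------------------
# serialization (YAML definition files)

def questionnaire_from_dict(data: Mapping[str, Any]) -> QuestionnaireDef:
    items = []
    for d in data.get("items", []):
        rng = None
        if d.get("range") is not None:
            r = d["range"]
            rng = NumericRange(float(r["min"]), float(r["max"]), str(r.get("unit", "")))
        items.append(QuestionItem(
            id=str(d["id"]), prompt=str(d.get("prompt", "")), kind=str(d["kind"]),
            options=tuple(str(o) for o in d.get("options", []) or []),
            numeric_range=rng))
    branches = tuple(
        BranchRule(trigger_item=str(b["trigger"]),
                   trigger_options=tuple(str(o) for o in b["when"]),
                   revealed_items=tuple(str(t) for t in b["reveal"]))
        for b in data.get("branches", []) or [])
    return QuestionnaireDef(id=str(data["id"]), title=str(data.get("title", "")),
                            items=tuple(items), branches=branches)


def load_questionnaire(path) -> QuestionnaireDef:
    with open(path, "r", encoding="utf-8") as fh:
        return questionnaire_from_dict(yaml.safe_load(fh))
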