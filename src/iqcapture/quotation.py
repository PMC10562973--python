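"""Intelligent Quotation: rule-based mapping of questionnaire answers into
the nursing patient profile.

Five rule kinds are supported:

* **quote** — copy an answer verbatim into a profile field (numbers are
  formatted with their unit-free decimal representation);
* **term_map** — convert a patient-facing expression into the clinical term
  used by the nursing record ("I can do it myself" -> "Independent");
* **aggregate** — combine several answers into one field value, optionally
  generating a comment sentence from the contributing answers;
* **calculate** — derive a clinical indicator (daily pure-alcohol grams,
  alcohol units, smoking duration) from numeric answers;
* **interview_stub** — open an empty text box per selected option so the
  nurse can fill in details during the focused interview.

Unmapped options never guess a term: the field is left for manual entry and
the rule is recorded as skipped, matching the workflow in which the nurse
reviews and, if necessary, corrects the quoted data.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Any, Mapping, Optional, Union

import yaml

from .profile import FieldValue, ProfileDocument, ProfileTemplate, TemplateMismatchError
from .questionnaire import QuestionnaireDef, ResponseSet

#: ethanol density factor (g/mL) used by the drinking-habit calculation
ETHANOL_DENSITY = 0.8
#: alcohol fraction of beer used by the packaged ruleset
BEER_ALCOHOL_FRACTION = 0.05
#: one Japanese standard drink ("unit") equals 20 g of pure ethanol
GRAMS_PER_UNIT = 20.0


class RulesetError(ValueError):
    """The mapping configuration is inconsistent with the schemas it binds."""


# ---------------------------------------------------------------------------
# rule types

@dataclass(frozen=True)
class QuoteRule:
    source_item: str
    target_field: str

    def source_items(self) -> tuple[str, ...]:
        return (self.source_item,)

    def target_refs(self) -> tuple[str, ...]:
        return (self.target_field,)


@dataclass(frozen=True)
class TermMapRule:
    source_item: str
    mapping: Mapping[str, str]
    target_field: str

    def source_items(self) -> tuple[str, ...]:
        return (self.source_item,)

    def target_refs(self) -> tuple[str, ...]:
        return (self.target_field,)


@dataclass(frozen=True)
class AggregateCase:
    match: Mapping[str, str]  # item id -> required option
    value: str


@dataclass(frozen=True)
class AggregateRule:
    sources: tuple[str, ...]
    combine: tuple[AggregateCase, ...]
    target_field: str
    comment_field: Optional[str] = None
    comment_template: Optional[str] = None
    required: tuple[str, ...] = ()  # sources that must be answered; default: first

    def source_items(self) -> tuple[str, ...]:
        return self.sources

    def target_refs(self) -> tuple[str, ...]:
        refs = [self.target_field]
        if self.comment_field:
            refs.append(self.comment_field)
        return tuple(refs)


@dataclass(frozen=True)
class CalculateRule:
    calc: str  # pure_alcohol | alcohol_units | smoking_duration
    sources: Mapping[str, str]  # role -> item id
    target_field: str
    parameters: Mapping[str, float] = field(default_factory=dict)

    def source_items(self) -> tuple[str, ...]:
        return tuple(self.sources.values())

    def target_refs(self) -> tuple[str, ...]:
        return (self.target_field,)


@dataclass(frozen=True)
class InterviewStubRule:
    source_item: str
    option_to_stub: Mapping[str, str]  # option -> text_entry field ref

    def source_items(self) -> tuple[str, ...]:
        return (self.source_item,)

    def target_refs(self) -> tuple[str, ...]:
        return tuple(self.option_to_stub.values())


Rule = Union[QuoteRule, TermMapRule, AggregateRule, CalculateRule, InterviewStubRule]


@dataclass(frozen=True)
class MappingRuleSet:
    rules: tuple[Rule, ...]


@dataclass
class QuotationResult:
    document: ProfileDocument
    filled_fields: int
    stub_fields: int
    skipped_rules: list[tuple[Rule, str]]


# ---------------------------------------------------------------------------
# ruleset validation

def validate_ruleset(ruleset: MappingRuleSet, qdef: QuestionnaireDef,
                     template: ProfileTemplate) -> list[str]:
    issues: list[str] = []
    items = qdef.item_map()
    fmap = template.field_map()
    non_stub_targets: dict[str, int] = {}
    for i, rule in enumerate(ruleset.rules):
        label = f"rule[{i}] ({type(rule).__name__})"
        for iid in rule.source_items():
            if iid not in items:
                issues.append(f"{label}: unknown source item {iid!r}")
        for ref in rule.target_refs():
            if ref not in fmap:
                issues.append(f"{label}: unknown target field {ref!r}")
        if not isinstance(rule, InterviewStubRule):
            for ref in rule.target_refs():
                non_stub_targets[ref] = non_stub_targets.get(ref, 0) + 1
        if isinstance(rule, TermMapRule):
            src = items.get(rule.source_item)
            tgt = fmap.get(rule.target_field)
            if src is not None:
                for opt in rule.mapping:
                    if opt not in src.options:
                        issues.append(f"{label}: mapping key {opt!r} not an option of {rule.source_item!r}")
            if tgt is not None and tgt[1].kind != "text_entry":
                for term in rule.mapping.values():
                    if term not in tgt[1].options:
                        issues.append(f"{label}: mapped term {term!r} not an option of {rule.target_field!r}")
        if isinstance(rule, InterviewStubRule):
            src = items.get(rule.source_item)
            if src is not None and src.kind != "multi_choice":
                issues.append(f"{label}: stub source must be multi_choice")
            for opt, ref in rule.option_to_stub.items():
                if src is not None and opt not in src.options:
                    issues.append(f"{label}: stub option {opt!r} not an option of {rule.source_item!r}")
                tgt = fmap.get(ref)
                if tgt is not None and tgt[1].kind != "text_entry":
                    issues.append(f"{label}: stub target {ref!r} is not text_entry")
        if isinstance(rule, CalculateRule):
            if rule.calc not in ("pure_alcohol", "alcohol_units", "smoking_duration"):
                issues.append(f"{label}: unknown calculation {rule.calc!r}")
            for name, v in rule.parameters.items():
                if v <= 0:
                    issues.append(f"{label}: parameter {name!r} must be positive")
        if isinstance(rule, AggregateRule) and rule.comment_template and not rule.comment_field:
            issues.append(f"{label}: comment_template without comment_field")
    for ref, n in non_stub_targets.items():
        if n > 1:
            issues.append(f"field {ref!r} targeted by {n} non-stub rules")
    return issues


# ---------------------------------------------------------------------------
# primitive operations

_NO_VALUE = object()


def map_term(answer_option: str, rule: TermMapRule):
    """Clinical term for a patient expression, or ``None`` when the option is
    not in the rule's mapping (the field is then left for manual entry)."""
    return rule.mapping.get(answer_option)


def calc_pure_alcohol_grams(volume_ml: float, cans: float,
                            alcohol_fraction: float = BEER_ALCOHOL_FRACTION) -> float:
    """Daily pure alcohol in grams: volume × cans × 0.8 × alcohol fraction."""
    if volume_ml < 0 or cans < 0 or not (0 <= alcohol_fraction <= 1):
        raise ValueError("volume, cans must be >=0 and fraction in [0,1]")
    return volume_ml * cans * ETHANOL_DENSITY * alcohol_fraction


def grams_to_units(grams: float) -> float:
    """Japanese standard-drink units: 20 g of pure alcohol per unit."""
    if grams < 0:
        raise ValueError("grams must be >= 0")
    return grams / GRAMS_PER_UNIT


def calc_smoking_duration(start_age: float, quit_age: Optional[float] = None,
                          current_age: Optional[float] = None) -> Optional[float]:
    """Years smoked: quit − start for ex-smokers, current − start for current
    smokers; ``None`` when there is no smoking history to compute from."""
    if start_age is None:
        return None
    if start_age < 0:
        raise ValueError("ages must be >= 0")
    if quit_age is not None:
        if quit_age < start_age:
            raise ValueError("quit age before start age")
        return quit_age - start_age
    if current_age is not None:
        if current_age < start_age:
            raise ValueError("current age before start age")
        return current_age - start_age
    return None


def _fmt_number(x: float) -> str:
    return f"{x:g}"


def _answer_text(value: Any) -> str:
    if isinstance(value, (list, tuple, set)):
        return ", ".join(str(v) for v in value)
    if isinstance(value, float):
        return _fmt_number(value)
    return str(value)


def aggregate_answers(rule: AggregateRule, resp: ResponseSet):
    """(combined field value, comment text or None), or (None, reason) when a
    required source answer is missing.

    The combine specification is an ordered case list; the first case whose
    per-item option requirements are all met by the answers wins.  The comment
    template is instantiated with the contributing answers ({item_id}
    placeholders) and produced only when all referenced answers exist.
    """
    required = rule.required or rule.sources[:1]
    for iid in required:
        if iid not in resp.answers:
            return None, f"missing answer for {iid!r}"
    value = None
    for case in rule.combine:
        ok = True
        for iid, opt in case.match.items():
            ans = resp.answers.get(iid)
            if isinstance(ans, (list, tuple, set)):
                ok = opt in ans
            else:
                ok = ans == opt
            if not ok:
                break
        if ok:
            value = case.value
            break
    if value is None:
        return None, "no combine case matched the answers"
    comment = None
    if rule.comment_field and rule.comment_template:
        try:
            comment = rule.comment_template.format(
                **{iid: _answer_text(resp.answers[iid])
                   for iid in rule.sources if iid in resp.answers})
        except (KeyError, IndexError):
            comment = None  # a placeholder's answer is absent: no comment
    return value, comment


def make_interview_stubs(rule: InterviewStubRule, resp: ResponseSet
                         ) -> tuple[list[tuple[str, FieldValue]], list[str]]:
    """One empty stub text field per selected option that has a stub mapping;
    selected options without a mapping are reported back."""
    selected = resp.answers.get(rule.source_item)
    if selected is None:
        return [], []
    if not isinstance(selected, (list, tuple, set)):
        selected = [selected]
    stubs: list[tuple[str, FieldValue]] = []
    unmapped: list[str] = []
    for opt in selected:
        ref = rule.option_to_stub.get(opt)
        if ref is None:
            unmapped.append(opt)
        else:
            stubs.append((ref, FieldValue(content="", provenance="questionnaire", stub=True)))
    return stubs, unmapped


# ---------------------------------------------------------------------------
# whole-ruleset application

def _apply_calculate(rule: CalculateRule, resp: ResponseSet):
    """Value string for the target text field, or (None, reason)."""
    a = resp.answers
    if rule.calc in ("pure_alcohol", "alcohol_units"):
        vol_item = rule.sources.get("volume")
        cans_item = rule.sources.get("cans")
        if vol_item not in a or cans_item not in a:
            return None, "missing drinking-amount answers"
        frac = rule.parameters.get("alcohol_fraction", BEER_ALCOHOL_FRACTION)
        grams = calc_pure_alcohol_grams(float(a[vol_item]), float(a[cans_item]), frac)
        if rule.calc == "pure_alcohol":
            # presentation: integer grams, half-up
            return str(int(grams + 0.5)), None
        per_unit = rule.parameters.get("grams_per_unit", GRAMS_PER_UNIT)
        return f"{grams / per_unit:.1f}", None
    if rule.calc == "smoking_duration":
        status_item = rule.sources.get("status")
        start_item = rule.sources.get("start_age")
        quit_item = rule.sources.get("quit_age")
        if start_item not in a:
            return None, "no smoking history answered"
        start = float(a[start_item])
        quit_age = float(a[quit_item]) if quit_item in a else None
        current_age = resp.answers.get("__current_age__")
        dur = calc_smoking_duration(start, quit_age,
                                    float(current_age) if current_age is not None else None)
        if dur is None:
            return None, "duration not computable without quit age or current age"
        return _fmt_number(dur), None
    return None, f"unknown calculation {rule.calc!r}"


def apply_ruleset(resp: ResponseSet, ruleset: MappingRuleSet,
                  template: ProfileTemplate, qdef: Optional[QuestionnaireDef] = None,
                  current_age: Optional[float] = None) -> QuotationResult:
    """Apply every rule in order to an (empty) profile document.

    Deterministic: the same response, ruleset and template always produce the
    same document.  All produced values carry provenance ``questionnaire``;
    fields no rule fires for are left untouched for manual entry.  When a
    questionnaire definition is given the ruleset is validated against it
    first and a schema mismatch raises before any document is built.
    """
    if qdef is not None:
        issues = validate_ruleset(ruleset, qdef, template)
        if issues:
            raise RulesetError("; ".join(issues))
    fmap = template.field_map()
    for rule in ruleset.rules:
        for ref in rule.target_refs():
            if ref not in fmap:
                raise TemplateMismatchError(f"rule targets unknown field {ref!r}")

    resp = copy.deepcopy(resp)
    if current_age is not None:
        resp.answers["__current_age__"] = current_age

    doc = ProfileDocument(template_id=template.id, values={})
    skipped: list[tuple[Rule, str]] = []
    n_stub = 0

    def put(ref: str, content, stub: bool = False) -> None:
        f = fmap[ref][1]
        if f.kind == "multi_choice" and not isinstance(content, list):
            content = list(content) if isinstance(content, (tuple, set)) else [content]
        doc.values[ref] = FieldValue(content=content, provenance="questionnaire", stub=stub)

    for rule in ruleset.rules:
        if isinstance(rule, QuoteRule):
            if rule.source_item not in resp.answers:
                skipped.append((rule, f"missing answer for {rule.source_item!r}"))
                continue
            ans = resp.answers[rule.source_item]
            f = fmap[rule.target_field][1]
            if f.kind == "text_entry":
                put(rule.target_field, _answer_text(ans))
            elif f.kind == "multi_choice":
                legal = [a for a in (ans if isinstance(ans, (list, tuple, set)) else [ans])
                         if a in f.options]
                if not legal:
                    skipped.append((rule, f"no selected option is legal for {rule.target_field!r}"))
                    continue
                put(rule.target_field, list(legal))
            else:
                if ans not in f.options:
                    skipped.append((rule, f"answer {ans!r} not a legal option of {rule.target_field!r}"))
                    continue
                put(rule.target_field, ans)
        elif isinstance(rule, TermMapRule):
            if rule.source_item not in resp.answers:
                skipped.append((rule, f"missing answer for {rule.source_item!r}"))
                continue
            ans = resp.answers[rule.source_item]
            if isinstance(ans, (list, tuple, set)):
                terms = [map_term(a, rule) for a in ans]
                mapped = [t for t in terms if t is not None]
                unmapped = [a for a, t in zip(ans, terms) if t is None]
                if unmapped:
                    skipped.append((rule, f"options {unmapped!r} have no term mapping"))
                if mapped:
                    put(rule.target_field, mapped)
            else:
                term = map_term(ans, rule)
                if term is None:
                    skipped.append((rule, f"option {ans!r} has no term mapping"))
                    continue
                put(rule.target_field, term)
        elif isinstance(rule, AggregateRule):
            value, extra = aggregate_answers(rule, resp)
            if value is None:
                skipped.append((rule, extra or "aggregate produced no value"))
                continue
            put(rule.target_field, value)
            if rule.comment_field and extra:
                put(rule.comment_field, extra)
        elif isinstance(rule, CalculateRule):
            try:
                value, reason = _apply_calculate(rule, resp)
            except ValueError as exc:
                # implausible patient answers (e.g. quit age before start age)
                # are left for the nurse to resolve manually
                value, reason = None, f"implausible answers: {exc}"
            if value is None:
                skipped.append((rule, reason or "calculation not applicable"))
                continue
            put(rule.target_field, value)
        elif isinstance(rule, InterviewStubRule):
            if rule.source_item not in resp.answers:
                skipped.append((rule, f"missing answer for {rule.source_item!r}"))
                continue
            stubs, unmapped = make_interview_stubs(rule, resp)
            if unmapped:
                skipped.append((rule, f"selected options {unmapped!r} have no stub mapping"))
            for ref, fv in stubs:
                if ref not in doc.values:
                    doc.values[ref] = fv
                    n_stub += 1
        else:  # pragma: no cover - closed union
            raise TypeError(f"unknown rule type {type(rule).__name__}")

    filled = sum(1 for v in doc.values.values()
                 if v.provenance == "questionnaire" and not v.stub)
    return QuotationResult(document=doc, filled_fields=filled,
                           stub_fields=n_stub, skipped_rules=skipped)


# ---------------------------------------------------------------------------
# serialization

def ruleset_from_dict(data: Mapping[str, Any]) -> MappingRuleSet:
    rules: list[Rule] = []
    for d in data.get("rules", []):
        kind = d["kind"]
        if kind == "quote":
            rules.append(QuoteRule(source_item=str(d["source"]), target_field=str(d["target"])))
        elif kind == "term_map":
            rules.append(TermMapRule(source_item=str(d["source"]),
                                     mapping={str(k): str(v) for k, v in d["mapping"].items()},
                                     target_field=str(d["target"])))
        elif kind == "aggregate":
            combine = tuple(AggregateCase(match={str(k): str(v) for k, v in c["match"].items()},
                                          value=str(c["value"]))
                            for c in d["combine"])
            rules.append(AggregateRule(sources=tuple(str(s) for s in d["sources"]),
                                       combine=combine, target_field=str(d["target"]),
                                       comment_field=d.get("comment_field"),
                                       comment_template=d.get("comment_template"),
                                       required=tuple(d.get("required", []) or [])))
        elif kind == "calculate":
            rules.append(CalculateRule(calc=str(d["calc"]),
                                       sources={str(k): str(v) for k, v in d["sources"].items()},
                                       target_field=str(d["target"]),
                                       parameters={str(k): float(v)
                                                   for k, v in (d.get("parameters") or {}).items()}))
        elif kind == "interview_stub":
            rules.append(InterviewStubRule(source_item=str(d["source"]),
                                           option_to_stub={str(k): str(v)
                                                           for k, v in d["stubs"].items()}))
        else:
            raise RulesetError(f"unknown rule kind {kind!r}")
    return MappingRuleSet(rules=tuple(rules))


def load_ruleset(path) -> MappingRuleSet:
    with open(path, "r", encoding="utf-8") as fh:
        return ruleset_from_dict(yaml.safe_load(fh))
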