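"""The inpatient nursing assessment document ("patient profile").

The profile is a comprehensive admission assessment organised by Gordon's
eleven functional health patterns; the packaged template carries 77 sections,
each a small form of single-choice, multi-choice and text-entry fields.
Filled documents track per-field provenance: a value either came from the
quotation engine (``questionnaire``) or was typed by a nurse (``manual``).
Interview stubs are empty text boxes opened by the engine for the nurse to
complete during the focused bedside interview.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping, Optional, Union

import yaml

FIELD_KINDS = ("single_choice", "multi_choice", "text_entry")
PROVENANCES = ("questionnaire", "manual")


class TemplateMismatchError(ValueError):
    """Document refers to fields that its template does not define."""


@dataclass(frozen=True)
class FormField:
    id: str
    kind: str
    options: tuple[str, ...] = ()


@dataclass(frozen=True)
class ProfileSection:
    id: str
    pattern: str
    title: str
    fields: tuple[FormField, ...]


@dataclass(frozen=True)
class ProfileTemplate:
    id: str
    patterns: tuple[str, ...]
    sections: tuple[ProfileSection, ...]

    def field_map(self) -> dict[str, tuple[ProfileSection, FormField]]:
        """Map ``section_id.field_id`` -> (section, field)."""
        out: dict[str, tuple[ProfileSection, FormField]] = {}
        for sec in self.sections:
            for f in sec.fields:
                out[f"{sec.id}.{f.id}"] = (sec, f)
        return out


@dataclass
class FieldValue:
    content: Union[str, list[str]]
    provenance: str = "manual"
    stub: bool = False


@dataclass
class ProfileDocument:
    template_id: str
    values: dict[str, FieldValue] = field(default_factory=dict)
    created_for: Optional[str] = None


def validate_template(template: ProfileTemplate) -> list[str]:
    issues: list[str] = []
    seen_sec: set[str] = set()
    for sec in template.sections:
        if sec.id in seen_sec:
            issues.append(f"duplicate section id {sec.id!r}")
        seen_sec.add(sec.id)
        if sec.pattern not in template.patterns:
            issues.append(f"section {sec.id!r}: unknown pattern {sec.pattern!r}")
        if not sec.fields:
            issues.append(f"section {sec.id!r}: has no fields")
        seen_f: set[str] = set()
        for f in sec.fields:
            if f.id in seen_f:
                issues.append(f"section {sec.id!r}: duplicate field id {f.id!r}")
            seen_f.add(f.id)
            if f.kind not in FIELD_KINDS:
                issues.append(f"field {sec.id}.{f.id}: unknown kind {f.kind!r}")
            if f.kind in ("single_choice", "multi_choice") and len(f.options) < 2:
                issues.append(f"field {sec.id}.{f.id}: choice field needs >=2 options")
    return issues


def validate_document(doc: ProfileDocument, template: ProfileTemplate) -> list[str]:
    issues: list[str] = []
    if doc.template_id != template.id:
        issues.append(f"document template id {doc.template_id!r} != {template.id!r}")
        return issues
    fmap = template.field_map()
    for ref, val in doc.values.items():
        if ref not in fmap:
            issues.append(f"value for unknown field {ref!r}")
            continue
        _, f = fmap[ref]
        if val.provenance not in PROVENANCES:
            issues.append(f"field {ref!r}: unknown provenance {val.provenance!r}")
        if val.stub:
            if f.kind != "text_entry":
                issues.append(f"field {ref!r}: stub on non-text field")
            elif val.content:
                issues.append(f"field {ref!r}: stub must have empty content")
        if f.kind == "single_choice":
            if not isinstance(val.content, str) or val.content not in f.options:
                issues.append(f"field {ref!r}: {val.content!r} not a legal option")
        elif f.kind == "multi_choice":
            if not isinstance(val.content, list) or any(c not in f.options for c in val.content):
                issues.append(f"field {ref!r}: {val.content!r} not a legal selection")
        else:
            if not isinstance(val.content, str):
                issues.append(f"field {ref!r}: text content must be a string")
    return issues


def registered_counts(doc: ProfileDocument, template: ProfileTemplate) -> tuple[int, int, int]:
    """(filled single-choice fields, filled multi-choice fields, total
    characters over nonempty text entries).  Stubs count as unfilled;
    character counting is over code points, whitespace included."""
    issues = validate_document(doc, template)
    if issues:
        raise TemplateMismatchError("; ".join(issues))
    fmap = template.field_map()
    n_single = n_multi = char_sum = 0
    for ref, val in doc.values.items():
        _, f = fmap[ref]
        if f.kind == "single_choice" and val.content:
            n_single += 1
        elif f.kind == "multi_choice" and val.content:
            n_multi += 1
        elif f.kind == "text_entry" and not val.stub and val.content:
            char_sum += len(val.content)
    return n_single, n_multi, char_sum


def coverage_report(template: ProfileTemplate, ruleset) -> tuple[int, int, int, int]:
    """(sections_total, sections_quoted, patterns_total, patterns_quoted).

    A section is "quoted" when at least one rule in the mapping configuration
    targets one of its fields (interview-stub targets count: the stub rule is
    part of the quotation set-up even though the nurse types the detail)."""
    fmap = template.field_map()
    targets: set[str] = set()
    for rule in ruleset.rules:
        for ref in rule.target_refs():
            if ref not in fmap:
                raise TemplateMismatchError(f"rule targets unknown field {ref!r}")
            targets.add(ref)
    quoted_sections = {fmap[ref][0].id for ref in targets}
    quoted_patterns = {fmap[ref][0].pattern for ref in targets}
    return (len(template.sections), len(quoted_sections),
            len(template.patterns), len(quoted_patterns))


# ---------------------------------------------------------------------------
# serialization

def template_from_dict(data: Mapping[str, Any]) -> ProfileTemplate:
    sections = []
    for s in data.get("sections", []):
        fields = tuple(
            FormField(id=str(f["id"]), kind=str(f["kind"]),
                      options=tuple(str(o) for o in f.get("options", []) or []))
            for f in s.get("fields", []))
        sections.append(ProfileSection(id=str(s["id"]), pattern=str(s["pattern"]),
                                       title=str(s.get("title", "")), fields=fields))
    return ProfileTemplate(id=str(data["id"]),
                           patterns=tuple(str(p) for p in data.get("patterns", [])),
                           sections=tuple(sections))


def load_template(path) -> ProfileTemplate:
    with open(path, "r", encoding="utf-8") as fh:
        return template_from_dict(yaml.safe_load(fh))
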