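"""Loaders for the packaged fixtures: the preadmission questionnaire, the
77-section profile template, and the quotation mapping configuration."""

from __future__ import annotations

from importlib import resources

import yaml

from .profile import ProfileTemplate, template_from_dict
from .questionnaire import QuestionnaireDef, questionnaire_from_dict
from .quotation import MappingRuleSet, ruleset_from_dict


def fixture_text(name: str) -> str:
    return (resources.files("iqcapture") / "fixtures" / name).read_text(encoding="utf-8")


def load_preadmission() -> QuestionnaireDef:
    return questionnaire_from_dict(yaml.safe_load(fixture_text("preadmission.yaml")))


def load_profile_template() -> ProfileTemplate:
    return template_from_dict(yaml.safe_load(fixture_text("profile_template.yaml")))


def load_mapping_rules() -> MappingRuleSet:
    return ruleset_from_dict(yaml.safe_load(fixture_text("mapping_rules.yaml")))
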