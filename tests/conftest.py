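import random

import pytest

from iqcapture.datasets import (load_mapping_rules, load_preadmission,
                                load_profile_template)
from iqcapture.questionnaire import QuestionnaireDef, ResponseSet, visible_items


@pytest.fixture(scope="session")
def qdef() -> QuestionnaireDef:
    return load_preadmission()


@pytest.fixture(scope="session")
def template():
    return load_profile_template()


@pytest.fixture(scope="session")
def ruleset():
    return load_mapping_rules()


def random_complete_response(qdef: QuestionnaireDef, rng: random.Random,
                             answered_by: str = "self") -> ResponseSet:
    """A complete, valid response: answer every visible item until the
    visible set is fully answered (branch answers reveal more items)."""
    resp = ResponseSet(questionnaire_id=qdef.id, answers={},
                       answered_by=answered_by)
    while True:
        pending = [it for it in visible_items(qdef, resp)
                   if it.id not in resp.answers]
        if not pending:
            return resp
        for item in pending:
            if item.kind == "single_choice":
                resp.answers[item.id] = rng.choice(item.options)
            elif item.kind == "multi_choice":
                k = rng.randint(1, len(item.options))
                resp.answers[item.id] = rng.sample(list(item.options), k)
            elif item.kind == "numeric":
                lo, hi = item.numeric_range.min, item.numeric_range.max
                val = round(rng.uniform(lo, hi), 1)
                resp.answers[item.id] = val
            else:
                resp.answers[item.id] = f"text-{rng.randint(0, 999)}"


def full_branch_response(qdef: QuestionnaireDef) -> ResponseSet:
    """The maximal answer path: every branch-opening option selected, so all
    53 items of the packaged questionnaire are visible and answered."""
    triggering: dict[str, set[str]] = {}
    for br in qdef.branches:
        triggering.setdefault(br.trigger_item, set()).update(br.trigger_options)
    resp = ResponseSet(questionnaire_id=qdef.id, answers={})
    while True:
        pending = [it for it in visible_items(qdef, resp)
                   if it.id not in resp.answers]
        if not pending:
            return resp
        for item in pending:
            trig = triggering.get(item.id, set())
            if item.kind == "single_choice":
                # prefer an option that opens the *largest* reveal set
                best, best_n = item.options[0], -1
                for opt in item.options:
                    n = sum(len(br.revealed_items) for br in qdef.branches
                            if br.trigger_item == item.id and opt in br.trigger_options)
                    if n > best_n:
                        best, best_n = opt, n
                resp.answers[item.id] = best
            elif item.kind == "multi_choice":
                chosen = [o for o in item.options if o in trig] or [item.options[0]]
                resp.answers[item.id] = chosen
            elif item.kind == "numeric":
                lo = item.numeric_range.min
                resp.answers[item.id] = min(item.numeric_range.max, lo + 1)
            else:
                resp.answers[item.id] = "detail"
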