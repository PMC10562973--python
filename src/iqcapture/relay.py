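"""Two-zone capture relay for questionnaire responses.

Emulates the capture architecture of an on-premise hospital information
system (HIS): sessions are issued as opaque tokens embedded in URLs / QR
payloads; the *inside* store keeps the token-to-patient binding, while the
*outside* store (reachable from the internet) holds the token only — never
any patient identifier.  Answered outside payloads are pulled inward by a
one-way transfer that purges the outside copy; registration re-attaches the
patient identity from the inside table and freezes the response as XML in an
EMR template store.

No real networking is involved; the direction contract (nothing ever flows
from the inside store to the outside store) is enforced by the API surface
itself.
"""

from __future__ import annotations

import datetime as _dt
import json
import random
import secrets
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from typing import Any, Optional

from .questionnaire import QuestionnaireDef, ResponseSet, validate_response


class UnknownTokenError(KeyError):
    pass


class RelayError(ValueError):
    pass


class RegistrationRefused(RelayError):
    def __init__(self, issues: list[str]):
        super().__init__("registration refused: " + "; ".join(issues))
        self.issues = issues


# ---------------------------------------------------------------------------
# XML response payloads

def response_to_xml(resp: ResponseSet) -> str:
    root = ET.Element("response", {
        "schema": "iqcapture-response-1",
        "questionnaire": resp.questionnaire_id,
        "answered_by": resp.answered_by,
    })
    if resp.completed_at:
        root.set("completed_at", resp.completed_at)
    for iid in sorted(resp.answers):
        ans = ET.SubElement(root, "answer", {"item": iid})
        value = resp.answers[iid]
        values = value if isinstance(value, (list, tuple, set)) else [value]
        for v in values:
            el = ET.SubElement(ans, "value")
            if isinstance(v, bool):
                raise RelayError(f"boolean answers are not part of the schema ({iid!r})")
            if isinstance(v, (int, float)):
                el.set("type", "number")
                el.text = repr(v)
            else:
                el.text = str(v)
        if isinstance(value, (list, tuple, set)):
            ans.set("multi", "true")
    return ET.tostring(root, encoding="unicode")


def response_from_xml(payload: str) -> ResponseSet:
    root = ET.fromstring(payload)
    if root.tag != "response":
        raise RelayError("not a response payload")
    answers: dict[str, Any] = {}
    for ans in root.findall("answer"):
        iid = ans.get("item")
        vals: list[Any] = []
        for el in ans.findall("value"):
            text = el.text or ""
            if el.get("type") == "number":
                num = float(text)
                vals.append(int(num) if num.is_integer() and "." not in text else num)
            else:
                vals.append(text)
        answers[iid] = vals if ans.get("multi") == "true" else vals[0]
    return ResponseSet(
        questionnaire_id=root.get("questionnaire", ""),
        answers=answers,
        answered_by=root.get("answered_by", "self"),
        completed_at=root.get("completed_at"),
    )


# ---------------------------------------------------------------------------
# stores

@dataclass
class SessionToken:
    token: str
    questionnaire_id: str
    mode: str  # inside | outside
    issued_at: str


@dataclass
class UrlRecord:
    token: str
    patient_id: str
    questionnaire_id: str
    status: str = "issued"  # issued | answered | registered


@dataclass
class OutsideUrlRecord:
    # deliberately has NO patient field: the outside zone never learns identity
    token: str
    questionnaire_id: str
    status: str = "issued"


@dataclass
class EmrTemplateRecord:
    patient_id: str
    questionnaire_id: str
    payload: str  # XML
    registered_at: str


@dataclass
class InsideStore:
    records: dict[str, UrlRecord] = field(default_factory=dict)
    payloads: dict[str, str] = field(default_factory=dict)

    def serialize(self) -> str:
        return json.dumps({"records": {t: vars(r) for t, r in self.records.items()},
                           "payloads": self.payloads}, sort_keys=True)


@dataclass
class OutsideStore:
    records: dict[str, OutsideUrlRecord] = field(default_factory=dict)
    payloads: dict[str, str] = field(default_factory=dict)

    def serialize(self) -> str:
        """Full serialization of everything the outside zone holds; used by the
        privacy tests to assert no patient identifier ever appears here."""
        return json.dumps({"records": {t: vars(r) for t, r in self.records.items()},
                           "payloads": self.payloads}, sort_keys=True)


@dataclass
class IssuedSession:
    session: SessionToken
    url: str
    qr_payload: str


class CaptureRelay:
    """Session issuance, submission, one-way transfer and EMR registration.

    ``rng`` (a ``random.Random``) makes token generation reproducible in
    simulations; by default tokens come from the OS entropy pool.  Tokens are
    128-bit URL-safe strings and contain no patient information.
    """

    BASE_URL = "https://questionnaire.example/q/"

    def __init__(self, questionnaires: dict[str, QuestionnaireDef],
                 rng: Optional[random.Random] = None,
                 overwrite_resubmission: bool = True):
        self.questionnaires = dict(questionnaires)
        self._rng = rng
        self.overwrite_resubmission = overwrite_resubmission
        self.inside = InsideStore()
        self.outside = OutsideStore()
        self.emr: dict[str, EmrTemplateRecord] = {}
        self.quarantine: dict[str, str] = {}
        self.audit_log: list[str] = []
        self._answered_tokens: set[str] = set()

    # -- helpers
    def _now(self) -> str:
        return _dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds")

    def _new_token(self) -> str:
        while True:
            if self._rng is not None:
                tok = self._rng.getrandbits(128).to_bytes(16, "big").hex()
            else:
                tok = secrets.token_hex(16)
            if tok not in self.inside.records:
                return tok

    def _audit(self, line: str) -> None:
        self.audit_log.append(f"{self._now()} {line}")

    # -- operations
    def issue_session(self, patient_id: str, questionnaire_id: str,
                      mode: str = "inside") -> IssuedSession:
        if questionnaire_id not in self.questionnaires:
            raise RelayError(f"unknown questionnaire {questionnaire_id!r}")
        if mode not in ("inside", "outside"):
            raise RelayError(f"unknown mode {mode!r}")
        token = self._new_token()
        self.inside.records[token] = UrlRecord(token=token, patient_id=patient_id,
                                               questionnaire_id=questionnaire_id)
        if mode == "outside":
            self.outside.records[token] = OutsideUrlRecord(token=token,
                                                           questionnaire_id=questionnaire_id)
        url = self.BASE_URL + token
        self._audit(f"issue token={token} mode={mode} questionnaire={questionnaire_id}")
        return IssuedSession(
            session=SessionToken(token=token, questionnaire_id=questionnaire_id,
                                 mode=mode, issued_at=self._now()),
            url=url, qr_payload=url)

    def submit_response(self, token: str, resp: ResponseSet) -> None:
        """Accept a payload into the store matching the token's zone.

        Outside-mode tokens are only known to the outside store, so an
        internet submission can never land directly inside; inside-mode
        submissions go straight to the inside store.
        """
        if token in self.outside.records:
            store_records, payloads, zone = self.outside.records, self.outside.payloads, "outside"
        elif token in self.inside.records:
            store_records, payloads, zone = self.inside.records, self.inside.payloads, "inside"
        else:
            raise UnknownTokenError(token)
        rec = store_records[token]
        # the inside URL table is authoritative for session state: once a
        # payload is registered it is frozen, whichever zone resubmits
        inside_rec = self.inside.records.get(token)
        if rec.status == "registered" or (inside_rec is not None
                                          and inside_rec.status == "registered"):
            raise RelayError("session already registered; payload frozen")
        if rec.status == "answered" and not self.overwrite_resubmission:
            raise RelayError("session already answered")
        qdef = self.questionnaires[rec.questionnaire_id]
        if resp.questionnaire_id != qdef.id:
            raise RelayError("response is for a different questionnaire")
        payloads[token] = response_to_xml(resp)
        rec.status = "answered"
        self._answered_tokens.add(token)
        self._audit(f"submit token={token} zone={zone}")

    def transfer_and_purge(self) -> int:
        """Copy every answered outside payload inward, then delete it outside.

        Outside tokens with no inside binding are quarantined with an audit
        entry.  After this call the outside store retains no response data.
        """
        moved = 0
        for token in list(self.outside.payloads):
            payload = self.outside.payloads.pop(token)
            inside_rec = self.inside.records.get(token)
            if inside_rec is None:
                self.quarantine[token] = payload
                self._audit(f"quarantine token={token} reason=no-inside-binding")
                continue
            self.inside.payloads[token] = payload
            inside_rec.status = "answered"
            out_rec = self.outside.records.get(token)
            if out_rec is not None:
                out_rec.status = "answered"
            moved += 1
            self._audit(f"transfer token={token}")
        return moved

    def register_to_emr(self, token: str) -> EmrTemplateRecord:
        rec = self.inside.records.get(token)
        if rec is None:
            raise UnknownTokenError(token)
        if rec.status != "answered" or token not in self.inside.payloads:
            raise RelayError("no answered payload held inside for this token")
        payload = self.inside.payloads[token]
        resp = response_from_xml(payload)
        issues = validate_response(self.questionnaires[rec.questionnaire_id], resp)
        if issues:
            raise RegistrationRefused(issues)
        emr_rec = EmrTemplateRecord(patient_id=rec.patient_id,
                                    questionnaire_id=rec.questionnaire_id,
                                    payload=payload, registered_at=self._now())
        self.emr[token] = emr_rec
        rec.status = "registered"
        self._audit(f"register token={token}")
        return emr_rec

    # -- bookkeeping used by the conservation property
    def counts(self) -> dict[str, int]:
        """Session accounting: every token ever answered is, at any point,
        exactly one of pending (payload awaiting transfer or registration),
        registered, or quarantined.  Counted over distinct tokens."""
        registered = {t for t, r in self.inside.records.items()
                      if r.status == "registered"}
        pending = ({t for t in self.inside.payloads
                    if self.inside.records[t].status == "answered"}
                   | set(self.outside.payloads)) - registered
        quarantined = set(self.quarantine) - registered - pending
        return {"answered": len(self._answered_tokens), "pending": len(pending),
                "registered": len(registered), "quarantined": len(quarantined)}
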