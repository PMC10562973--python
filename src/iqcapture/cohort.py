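"""Synthetic admission cohorts and EMR operation logs.

Generates admission cases split into questionnaire *use* / *no-use* groups
with ward, ADL, and documentation-volume structure, plus per-case EMR
operation-log events (open_profile / save / logout) whose episode durations
sum to a per-stratum lognormal input time.  Defaults reproduce the study
conditions of a ~2400-case scheduled-admission cohort: use fraction 1326/2425,
group-wise internal-medicine ward fractions 0.46 / 0.25, independent-ADL
(bedriddenness rank J) fractions 0.84 / 0.74, and input-time medians 9.4 /
10.1 minutes with lognormal dispersion chosen so the quartile brackets match
the reported interquartile ranges.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

GROUPS = ("use", "no_use")
WARDS = ("internal_medicine", "surgery")
RANKS = ("J", "A", "B", "C")

#: lognormal sigma from an interquartile ratio: ln(Q3/Q1) / (2 * 0.6745)
def sigma_from_iqr(q1: float, q3: float) -> float:
    return math.log(q3 / q1) / (2 * 0.674489750196082)


@dataclass(frozen=True)
class LogNormalSpec:
    """Lognormal in median/sigma form: X = median * exp(sigma * Z)."""
    median: float
    sigma: float

    def __post_init__(self):
        if self.median <= 0 or self.sigma < 0:
            raise ValueError("median must be > 0 and sigma >= 0")


@dataclass
class CohortConfig:
    n_cases: int = 2425
    p_use: float = 1326 / 2425
    p_internal_medicine: Mapping[str, float] = field(
        default_factory=lambda: {"use": 0.46, "no_use": 0.25})
    p_independent_adl: Mapping[str, float] = field(
        default_factory=lambda: {"use": 0.84, "no_use": 0.74})
    # per-stratum input-time model; the most specific key wins:
    # (group, ward, adl) > (group, ward) > (group,)
    input_time_model: Mapping[tuple, LogNormalSpec] = field(default_factory=lambda: {
        ("use",): LogNormalSpec(9.4, sigma_from_iqr(6.2, 15.0)),
        ("no_use",): LogNormalSpec(10.1, sigma_from_iqr(6.6, 16.7)),
    })
    # editing-episode counts: 1 + Poisson(extra_episodes_mean)
    extra_episodes_mean: float = 1.5
    # probability that one episode is left unterminated (no save; closed by a
    # later logout), exercising the sessionizer's truncation handling
    truncated_rate: float = 0.02
    # documentation volume per group: medians of registered item counts and
    # character sums
    singles_median: Mapping[str, float] = field(
        default_factory=lambda: {"use": 56, "no_use": 56})
    multis_median: Mapping[str, float] = field(
        default_factory=lambda: {"use": 16, "no_use": 15})
    chars_median: Mapping[str, float] = field(
        default_factory=lambda: {"use": 237, "no_use": 208})
    chars_dispersion: float = 3.0  # negative-binomial shape (smaller = wider)
    seed: int = 0
    admission_start: str = "2022-08-01"

    def validate(self) -> list[str]:
        issues = []
        if self.n_cases < 1:
            issues.append("n_cases must be >= 1")
        probs = [("p_use", self.p_use)]
        probs += [(f"p_internal_medicine[{g}]", self.p_internal_medicine[g]) for g in GROUPS]
        probs += [(f"p_independent_adl[{g}]", self.p_independent_adl[g]) for g in GROUPS]
        for name, p in probs:
            if not (0 <= p <= 1):
                issues.append(f"{name} must be in [0, 1]")
        if not (0 <= self.truncated_rate <= 1):
            issues.append("truncated_rate must be in [0, 1]")
        if self.extra_episodes_mean < 0:
            issues.append("extra_episodes_mean must be >= 0")
        return issues

    def input_time_spec(self, group: str, ward: str, adl_independent: bool) -> LogNormalSpec:
        adl = "independent" if adl_independent else "dependent"
        for key in ((group, ward, adl), (group, ward), (group,)):
            if key in self.input_time_model:
                return self.input_time_model[key]
        raise KeyError(f"no input-time model for group {group!r}")


def config_from_dict(data: Mapping) -> CohortConfig:
    """Build a CohortConfig from a YAML-friendly mapping.  Stratum keys for
    ``input_time_model`` are '/'-joined strings (e.g. ``use`` or
    ``use/internal_medicine/dependent``) mapping to {median, sigma}."""
    data = dict(data)
    itm = data.get("input_time_model")
    if itm:
        parsed = {}
        for k, v in itm.items():
            key = tuple(str(k).split("/")) if isinstance(k, str) else tuple(k)
            parsed[key] = (v if isinstance(v, LogNormalSpec)
                           else LogNormalSpec(float(v["median"]), float(v["sigma"])))
        data["input_time_model"] = parsed
    return CohortConfig(**data)


@dataclass
class AdmissionCase:
    case_id: str
    group: str
    ward: str
    bedriddenness_rank: str
    age: int
    sex: str
    cognitive_impairment: bool
    prolonged_stay: bool
    admission_date: str
    n_single: int
    n_multi: int
    char_sum: int

    @property
    def adl_independent(self) -> bool:
        # bedriddenness rank J defines independent ADL; A/B/C are dependent
        return self.bedriddenness_rank == "J"


@dataclass(frozen=True)
class OperationLogEvent:
    case_id: str
    timestamp: str  # ISO 8601
    action: str  # open_profile | save | logout


def _median_int(rng: np.random.Generator, median: float, dispersion: float) -> int:
    """Negative-binomial draw whose median is approximately ``median``.

    Uses the Wilson-Hilferty gamma-median approximation
    median/mean ~ (1 - 1/(9r))^3 to choose the mean; adequate for the
    character-count scales used here."""
    r = dispersion
    mean = median / (1 - 1 / (9 * r)) ** 3
    p = r / (r + mean)
    return int(rng.negative_binomial(r, p))


def generate_cohort(config: CohortConfig) -> list[AdmissionCase]:
    """Reproducible synthetic admission cases; marginal group, ward and ADL
    proportions converge to the configured values."""
    issues = config.validate()
    if issues:
        raise ValueError("; ".join(issues))
    rng = np.random.default_rng(config.seed)
    start = _dt.date.fromisoformat(config.admission_start)
    cases: list[AdmissionCase] = []
    for i in range(config.n_cases):
        group = "use" if rng.random() < config.p_use else "no_use"
        ward = ("internal_medicine" if rng.random() < config.p_internal_medicine[group]
                else "surgery")
        if rng.random() < config.p_independent_adl[group]:
            rank = "J"
        else:
            rank = str(rng.choice(["A", "B", "C"], p=[0.5, 0.3, 0.2]))
        age = int(np.clip(rng.normal(57, 20), 18, 95))
        sex = "male" if rng.random() < (0.46 if group == "use" else 0.45) else "female"
        cog = bool(rng.random() < (0.069 if group == "use" else 0.076))
        prolonged = bool(rng.random() < (0.54 if group == "use" else 0.52))
        n_single = max(0, int(rng.normal(config.singles_median[group], 9)))
        n_multi = max(0, int(rng.normal(config.multis_median[group], 5)))
        chars = _median_int(rng, config.chars_median[group], config.chars_dispersion)
        admission = start + _dt.timedelta(days=int(rng.integers(0, 150)))
        cases.append(AdmissionCase(
            case_id=f"case{i:05d}", group=group, ward=ward, bedriddenness_rank=rank,
            age=age, sex=sex, cognitive_impairment=cog, prolonged_stay=prolonged,
            admission_date=admission.isoformat(),
            n_single=n_single, n_multi=n_multi, char_sum=chars))
    return cases


def generate_operation_log(case: AdmissionCase, config: CohortConfig,
                           rng: Optional[np.random.Generator] = None
                           ) -> list[OperationLogEvent]:
    """Operation-log events for one case: 1+ open/save episodes on the
    admission day and the following day whose durations sum to a draw from
    the case's stratum input-time distribution.  With probability
    ``truncated_rate`` one episode omits its save and is closed by a later
    logout (to be flagged as truncated by the sessionizer)."""
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, int(case.case_id[4:])]))
    spec = config.input_time_spec(case.group, case.ward, case.adl_independent)
    total = spec.median * math.exp(spec.sigma * rng.standard_normal())
    n_ep = 1 + int(rng.poisson(config.extra_episodes_mean))
    shares = rng.dirichlet(np.full(n_ep, 2.0))
    durations = total * shares

    day0 = _dt.datetime.fromisoformat(case.admission_date + "T00:00:00")
    t = day0 + _dt.timedelta(minutes=float(rng.uniform(9 * 60, 18 * 60)))
    truncate_idx = -1
    if rng.random() < config.truncated_rate:
        truncate_idx = int(rng.integers(0, n_ep))
    events: list[OperationLogEvent] = []

    def emit(action: str, when: _dt.datetime) -> None:
        events.append(OperationLogEvent(case.case_id, when.isoformat(), action))

    for k, dur in enumerate(durations):
        emit("open_profile", t)
        end = t + _dt.timedelta(minutes=float(dur))
        if k == truncate_idx:
            # nurse walked away: no save; the next logout closes the episode
            emit("logout", end)
        else:
            emit("save", end)
            if rng.random() < 0.3:
                emit("logout", end + _dt.timedelta(seconds=30))
        gap = float(rng.exponential(45))
        t = end + _dt.timedelta(minutes=2 + gap)
        # keep the remaining episodes inside the two-day inclusion window
        limit = day0 + _dt.timedelta(days=1, hours=21)
        if t > limit:
            t = limit - _dt.timedelta(minutes=float(sum(durations[k + 1:])) + 5 * n_ep)
            t = max(t, end + _dt.timedelta(minutes=1))
    return events


def generate_logs(cases: Sequence[AdmissionCase], config: CohortConfig
                  ) -> list[OperationLogEvent]:
    events: list[OperationLogEvent] = []
    for case in cases:
        events.extend(generate_operation_log(case, config))
    return events


# ---------------------------------------------------------------------------
# CSV interfaces

def cases_to_frame(cases: Iterable[AdmissionCase]) -> pd.DataFrame:
    return pd.DataFrame([vars(c) for c in cases])


def events_to_frame(events: Iterable[OperationLogEvent]) -> pd.DataFrame:
    return pd.DataFrame([vars(e) for e in events])


def cases_from_frame(df: pd.DataFrame) -> list[AdmissionCase]:
    return [AdmissionCase(
        case_id=str(r.case_id), group=str(r.group), ward=str(r.ward),
        bedriddenness_rank=str(r.bedriddenness_rank), age=int(r.age), sex=str(r.sex),
        cognitive_impairment=bool(r.cognitive_impairment),
        prolonged_stay=bool(r.prolonged_stay), admission_date=str(r.admission_date),
        n_single=int(r.n_single), n_multi=int(r.n_multi), char_sum=int(r.char_sum))
        for r in df.itertuples()]


def events_from_frame(df: pd.DataFrame) -> list[OperationLogEvent]:
    return [OperationLogEvent(str(r.case_id), str(r.timestamp), str(r.action))
            for r in df.itertuples()]
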