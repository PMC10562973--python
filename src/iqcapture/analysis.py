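"""Documentation-time analysis on EMR operation logs.

Pipeline: sessionize per-case operation-log events into total profile input
time (sum of open→save/logout episode durations on the admission day and the
following day), exclude outliers above mean + 3·SD (single pass, sample SD),
then compare the questionnaire use / no-use groups overall and stratified by
admission ward and by patient ADL.  Continuous variables are summarised as
median (IQR) and tested with the Wilcoxon rank-sum test (exact enumeration
for small samples, tie-corrected normal approximation otherwise); categorical
variables use the Pearson chi-square test without continuity correction, and
ordered proportions the Cochran-Armitage trend test.  All tests are
two-sided and unadjusted.
"""

from __future__ import annotations

import datetime as _dt
import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import AdmissionCase, OperationLogEvent


@dataclass
class InputTimeRecord:
    case_id: str
    total_minutes: float
    n_episodes: int
    truncated: bool = False


@dataclass
class SessionizationError:
    case_id: str
    reason: str


@dataclass
class GroupComparison:
    variable: str
    summaries: dict[str, str]
    test: str
    statistic: float
    p_value: float


# ---------------------------------------------------------------------------
# sessionization

def sessionize_input_time(events: Sequence[OperationLogEvent],
                          admission_dates: Optional[Mapping[str, str]] = None,
                          window_days: int = 2
                          ) -> tuple[list[InputTimeRecord], list[SessionizationError]]:
    """Per-case total input time from open/save/logout events.

    Episodes start at ``open_profile`` and end at the next ``save`` or
    ``logout``; an episode ended by ``logout`` without an intervening save is
    flagged truncated (the nurse walked away, the duration runs to the forced
    logout).  Only episodes opening within ``window_days`` calendar days of
    the admission date (default: admission day plus the following day) count.
    A save or logout with no open pending and no prior episode is a malformed
    sequence: the case is excluded with a reason.  Admission dates default to
    the date of the case's first event.
    """
    by_case: dict[str, list[OperationLogEvent]] = {}
    for ev in events:
        by_case.setdefault(ev.case_id, []).append(ev)

    records: list[InputTimeRecord] = []
    errors: list[SessionizationError] = []
    for case_id, evs in by_case.items():
        evs = sorted(evs, key=lambda e: e.timestamp)
        if admission_dates and case_id in admission_dates:
            day0 = _dt.date.fromisoformat(str(admission_dates[case_id])[:10])
        else:
            day0 = _dt.datetime.fromisoformat(evs[0].timestamp).date()
        last_day = day0 + _dt.timedelta(days=window_days - 1)

        open_t: Optional[_dt.datetime] = None
        total = 0.0
        n_ep = 0
        truncated = False
        malformed: Optional[str] = None
        for ev in evs:
            t = _dt.datetime.fromisoformat(ev.timestamp)
            if ev.action == "open_profile":
                if open_t is not None:
                    malformed = "open_profile while an episode was already open"
                    break
                open_t = t
            elif ev.action in ("save", "logout"):
                if open_t is None:
                    if ev.action == "save":
                        malformed = "save with no open episode"
                        break
                    continue  # stray logout after a closed episode
                if day0 <= open_t.date() <= last_day:
                    total += (t - open_t).total_seconds() / 60.0
                    n_ep += 1
                    if ev.action == "logout":
                        # episode never saved; forced shut by the logout
                        truncated = True
                open_t = None
            else:
                malformed = f"unknown action {ev.action!r}"
                break
        if malformed:
            errors.append(SessionizationError(case_id, malformed))
            continue
        if n_ep >= 1:
            records.append(InputTimeRecord(case_id=case_id, total_minutes=total,
                                           n_episodes=n_ep, truncated=truncated))
    return records, errors


# ---------------------------------------------------------------------------
# outlier exclusion

def exclude_outliers_mean3sd(records: Sequence[InputTimeRecord]
                             ) -> tuple[list[InputTimeRecord], list[InputTimeRecord]]:
    """Exclude records with input time strictly above mean + 3·SD.

    The threshold is computed once over all records (sample SD, n−1
    denominator), not iteratively.  With fewer than two records no exclusion
    is possible and a warning is emitted.
    """
    records = list(records)
    if len(records) < 2:
        warnings.warn("fewer than 2 records: outlier exclusion skipped")
        return records, []
    times = np.array([r.total_minutes for r in records], dtype=float)
    threshold = times.mean() + 3 * times.std(ddof=1)
    kept = [r for r in records if r.total_minutes <= threshold]
    excluded = [r for r in records if r.total_minutes > threshold]
    return kept, excluded


# ---------------------------------------------------------------------------
# statistical tests

def _midranks(values: np.ndarray) -> np.ndarray:
    return stats.rankdata(values, method="average")


def rank_sum_test(x: Sequence[float], y: Sequence[float],
                  exact_limit: int = 12) -> tuple[float, float]:
    """Wilcoxon rank-sum test, two-sided.  Returns (W, p) where W is the
    rank sum of the first sample.

    For small samples (combined n ≤ ``exact_limit``) the p-value is exact:
    all C(n, n1) assignments of the pooled midranks are enumerated and the
    p-value is the fraction with |W − E[W]| at least as large as observed.
    Larger samples use the tie-corrected normal approximation without
    continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    n1, n = len(x), len(pooled)
    ranks = _midranks(pooled)
    w_obs = float(ranks[:n1].sum())
    mu = n1 * (n + 1) / 2.0

    if n <= exact_limit:
        dev = abs(w_obs - mu)
        count = 0
        total = 0
        for combo in itertools.combinations(range(n), n1):
            w = ranks[list(combo)].sum()
            total += 1
            if abs(w - mu) >= dev - 1e-12:
                count += 1
        return w_obs, count / total

    n2 = n - n1
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts).sum())) / ((n) * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var == 0:
        return w_obs, 1.0
    z = (w_obs - mu) / math.sqrt(var)
    p = 2 * stats.norm.sf(abs(z))
    return w_obs, min(1.0, p)


def chi_square_test(table) -> tuple[float, float]:
    """Pearson chi-square on a contingency table, no continuity correction."""
    table = np.asarray(table, dtype=float)
    if table.sum() == 0 or (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        raise ValueError("table has an empty row or column")
    res = stats.chi2_contingency(table, correction=False)
    expected = res.expected_freq
    if (expected < 5).any():
        warnings.warn("some expected cell counts are below 5; "
                      "the chi-square approximation may be poor")
    return float(res.statistic), float(res.pvalue)


def cochran_armitage_trend(successes: Sequence[float], totals: Sequence[float],
                           scores: Optional[Sequence[float]] = None
                           ) -> tuple[float, float]:
    """Cochran-Armitage test for a trend in proportions over ordered strata.

    Returns (z, p) with z the standardized linear trend statistic; z = 0 when
    the proportions are exactly flat.  Default scores are 0, 1, 2, ...
    """
    r = np.asarray(successes, dtype=float)
    n = np.asarray(totals, dtype=float)
    if len(r) != len(n) or len(r) < 2:
        raise ValueError("need >=2 ordered strata with matching lengths")
    if (n <= 0).any() or (r < 0).any() or (r > n).any():
        raise ValueError("invalid counts")
    s = np.arange(len(n), dtype=float) if scores is None else np.asarray(scores, dtype=float)
    N = n.sum()
    p_hat = r.sum() / N
    t_stat = float((s * (r - n * p_hat)).sum())
    var = p_hat * (1 - p_hat) * float((n * s ** 2).sum() - (n * s).sum() ** 2 / N)
    if var == 0 or t_stat == 0:
        return 0.0 if t_stat == 0 else math.inf, 1.0 if t_stat == 0 else 0.0
    z = t_stat / math.sqrt(var)
    return z, min(1.0, 2 * stats.norm.sf(abs(z)))


def _median_iqr(values: Sequence[float]) -> str:
    v = np.asarray(values, dtype=float)
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return f"{med:.1f} ({q1:.1f}-{q3:.1f})"


def compare_groups(data, variable_kind: str, variable: str = "",
                   group_names: Sequence[str] = ("use", "no_use")) -> GroupComparison:
    """Two-group comparison in the reporting style of the evaluation tables.

    ``variable_kind`` selects the test: ``continuous`` (data: mapping group →
    values; Wilcoxon rank-sum, median (IQR) summaries), ``categorical``
    (data: contingency table, groups × categories; Pearson chi-square, n (%)
    summaries), or ``trend`` (data: (successes, totals) over ordered strata;
    Cochran-Armitage).
    """
    if variable_kind == "continuous":
        g1, g2 = group_names
        x, y = np.asarray(data[g1], float), np.asarray(data[g2], float)
        if len(x) == 0 or len(y) == 0:
            raise ValueError("empty group")
        stat, p = rank_sum_test(x, y)
        return GroupComparison(variable=variable,
                               summaries={g1: _median_iqr(x), g2: _median_iqr(y)},
                               test="Wilcoxon rank-sum", statistic=stat, p_value=p)
    if variable_kind == "categorical":
        table = np.asarray(data, dtype=float)
        stat, p = chi_square_test(table)
        row_sums = table.sum(axis=1)
        summaries = {str(group_names[i]) if i < len(group_names) else f"group{i}":
                     " / ".join(f"{int(c)} ({100 * c / row_sums[i]:.0f}%)" for c in row)
                     for i, row in enumerate(table)}
        return GroupComparison(variable=variable, summaries=summaries,
                               test="Pearson chi-square", statistic=stat, p_value=p)
    if variable_kind == "trend":
        successes, totals = data
        stat, p = cochran_armitage_trend(successes, totals)
        summaries = {f"stratum{i}": f"{int(r)}/{int(n)}"
                     for i, (r, n) in enumerate(zip(successes, totals))}
        return GroupComparison(variable=variable, summaries=summaries,
                               test="Cochran-Armitage trend", statistic=stat, p_value=p)
    raise ValueError(f"unknown variable kind {variable_kind!r}")


# ---------------------------------------------------------------------------
# stratified tables

_ROW_VARS = ("input_time", "single_choice_items", "multi_choice_items", "characters")


def _case_value(case: AdmissionCase, var: str, time_by_case: Mapping[str, float]):
    if var == "input_time":
        return time_by_case.get(case.case_id)
    if var == "single_choice_items":
        return case.n_single
    if var == "multi_choice_items":
        return case.n_multi
    if var == "characters":
        return case.char_sum
    raise KeyError(var)


def stratified_analysis(cases: Sequence[AdmissionCase],
                        records: Sequence[InputTimeRecord]) -> dict[str, pd.DataFrame]:
    """Use vs no-use comparison tables: overall, by admission ward, and by
    patient ADL.  Rows are input time, single-choice items, multi-choice
    items and character sums; every cell is median (IQR) with a Wilcoxon
    rank-sum p-value per row.  Deterministic given the inputs."""
    case_by_id = {c.case_id: c for c in cases}
    unjoinable = [r.case_id for r in records if r.case_id not in case_by_id]
    if unjoinable:
        raise ValueError(f"records with no matching case: {unjoinable}")
    time_by_case = {r.case_id: r.total_minutes for r in records}
    included = [case_by_id[r.case_id] for r in records]

    def strata(case: AdmissionCase) -> list[str]:
        return ["overall", f"ward:{case.ward}",
                "adl:independent" if case.adl_independent else "adl:dependent"]

    tables: dict[str, pd.DataFrame] = {}
    names = ["overall", "ward:internal_medicine", "ward:surgery",
             "adl:independent", "adl:dependent"]
    for name in names:
        sub = [c for c in included if name in strata(c)]
        rows = []
        for var in _ROW_VARS:
            data = {g: [_case_value(c, var, time_by_case) for c in sub if c.group == g]
                    for g in ("use", "no_use")}
            if not data["use"] or not data["no_use"]:
                raise ValueError(f"empty group in stratum {name!r}")
            cmp = compare_groups(data, "continuous", variable=var)
            rows.append({"variable": var, "use": cmp.summaries["use"],
                         "no_use": cmp.summaries["no_use"], "test": cmp.test,
                         "statistic": cmp.statistic, "p_value": cmp.p_value})
        tables[name] = pd.DataFrame(rows)
    return tables


def report_text(tables: Mapping[str, pd.DataFrame]) -> str:
    parts = []
    for name, df in tables.items():
        parts.append(f"== {name} ==")
        parts.append(df.to_string(index=False,
                                  formatters={"p_value": lambda p: f"{p:.3g}",
                                              "statistic": lambda s: f"{s:.1f}"}))
        parts.append("")
    return "\n".join(parts)
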