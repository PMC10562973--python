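import datetime as dt
import itertools
import math
import random

import numpy as np
import pytest
from scipy import stats

from iqcapture.cohort import (CohortConfig, OperationLogEvent, generate_cohort,
                              generate_logs)
from iqcapture.analysis import (InputTimeRecord, chi_square_test,
                                cochran_armitage_trend, compare_groups,
                                exclude_outliers_mean3sd, rank_sum_test,
                                sessionize_input_time, stratified_analysis)


def ev(case, minutes, action, day="2022-08-01"):
    t = dt.datetime.fromisoformat(day + "T09:00:00") + dt.timedelta(minutes=minutes)
    return OperationLogEvent(case, t.isoformat(), action)


# ---------------------------------------------------------------------------
# sessionization

def test_two_episodes_sum_to_total():
    events = [ev("c1", 0, "open_profile"), ev("c1", 5.0, "save"),
              ev("c1", 60, "open_profile"), ev("c1", 64.4, "save")]
    records, errors = sessionize_input_time(events)
    assert errors == []
    assert len(records) == 1
    assert records[0].total_minutes == pytest.approx(9.4)
    assert records[0].n_episodes == 2
    assert not records[0].truncated


def test_episode_outside_window_is_ignored():
    events = [ev("c1", 0, "open_profile"), ev("c1", 5, "save"),
              ev("c1", 0, "open_profile", day="2022-08-05"),
              ev("c1", 7, "save", day="2022-08-05")]
    records, _ = sessionize_input_time(events, {"c1": "2022-08-01"})
    assert records[0].total_minutes == pytest.approx(5)
    assert records[0].n_episodes == 1


def test_case_with_no_events_in_window_is_absent():
    events = [ev("c1", 0, "open_profile", day="2022-08-09"),
              ev("c1", 4, "save", day="2022-08-09")]
    records, errors = sessionize_input_time(events, {"c1": "2022-08-01"})
    assert records == [] and errors == []


def test_unterminated_episode_closed_at_logout_and_flagged():
    events = [ev("c1", 0, "open_profile"), ev("c1", 6, "logout")]
    records, _ = sessionize_input_time(events)
    assert records[0].truncated
    assert records[0].total_minutes == pytest.approx(6)


def test_save_without_open_is_malformed():
    records, errors = sessionize_input_time([ev("c1", 0, "save")])
    assert records == []
    assert len(errors) == 1 and "save" in errors[0].reason


def test_sessionization_invariant_to_non_reordering_jitter():
    events = [ev("c1", 0, "open_profile"), ev("c1", 5, "save"),
              ev("c1", 30, "open_profile"), ev("c1", 34.4, "save")]
    jittered = [OperationLogEvent(e.case_id,
                                  (dt.datetime.fromisoformat(e.timestamp)
                                   + dt.timedelta(seconds=10)).isoformat(),
                                  e.action) for e in events]
    a, _ = sessionize_input_time(events)
    b, _ = sessionize_input_time(jittered)
    assert a[0].total_minutes == pytest.approx(b[0].total_minutes)
    assert a[0].n_episodes == b[0].n_episodes


def oracle_pairing(events, admission_dates):
    """Independent sessionizer: explicit scan pairing each open with the
    next save/logout, then windowing on the open's date."""
    out = {}
    by_case = {}
    for e in sorted(events, key=lambda e: (e.case_id, e.timestamp)):
        by_case.setdefault(e.case_id, []).append(e)
    for case, evs in by_case.items():
        day0 = dt.date.fromisoformat(str(admission_dates[case])[:10])
        total, n, i = 0.0, 0, 0
        while i < len(evs):
            if evs[i].action == "open_profile":
                j = i + 1
                while j < len(evs) and evs[j].action == "open_profile":
                    j += 1
                if j < len(evs):
                    t0 = dt.datetime.fromisoformat(evs[i].timestamp)
                    t1 = dt.datetime.fromisoformat(evs[j].timestamp)
                    if day0 <= t0.date() <= day0 + dt.timedelta(days=1):
                        total += (t1 - t0).total_seconds() / 60
                        n += 1
                i = j + 1
            else:
                i += 1
        if n:
            out[case] = (round(total, 9), n)
    return out


def test_sessionizer_matches_oracle_on_generated_logs():
    cfg = CohortConfig(n_cases=400, seed=8, truncated_rate=0.1)
    cases = generate_cohort(cfg)
    admission = {c.case_id: c.admission_date for c in cases}
    events = generate_logs(cases, cfg)
    records, errors = sessionize_input_time(events, admission)
    assert errors == []
    mine = {r.case_id: (round(r.total_minutes, 9), r.n_episodes) for r in records}
    assert mine == oracle_pairing(events, admission)


# ---------------------------------------------------------------------------
# outlier exclusion

def test_constant_times_exclude_nothing():
    recs = [InputTimeRecord(f"c{i}", 10.0, 1) for i in range(5)]
    kept, excluded = exclude_outliers_mean3sd(recs)
    assert excluded == [] and len(kept) == 5


def test_exclusion_matches_hand_arithmetic():
    times = [10, 10, 10, 10, 300]
    recs = [InputTimeRecord(f"c{i}", t, 1) for i, t in enumerate(times)]
    kept, excluded = exclude_outliers_mean3sd(recs)
    mean = sum(times) / 5
    sd = math.sqrt(sum((t - mean) ** 2 for t in times) / 4)
    manual_excluded = [t for t in times if t > mean + 3 * sd]
    assert [r.total_minutes for r in excluded] == manual_excluded
    assert sorted(kept + excluded, key=lambda r: r.case_id) == recs


def test_exclusion_partitions_input():
    rng = np.random.default_rng(0)
    recs = [InputTimeRecord(f"c{i}", float(t), 1)
            for i, t in enumerate(rng.lognormal(2.3, 0.8, 500))]
    kept, excluded = exclude_outliers_mean3sd(recs)
    assert len(kept) + len(excluded) == 500
    assert {r.case_id for r in kept} | {r.case_id for r in excluded} == \
        {r.case_id for r in recs}
    assert {r.case_id for r in kept} & {r.case_id for r in excluded} == set()


def test_no_exclusion_when_max_below_threshold():
    recs = [InputTimeRecord(f"c{i}", float(t), 1)
            for i, t in enumerate([8, 9, 10, 11, 12])]
    kept, excluded = exclude_outliers_mean3sd(recs)
    assert excluded == []


def test_single_record_warns_and_keeps():
    with pytest.warns(UserWarning):
        kept, excluded = exclude_outliers_mean3sd([InputTimeRecord("c0", 5.0, 1)])
    assert len(kept) == 1 and excluded == []


# ---------------------------------------------------------------------------
# rank-sum test

def exact_permutation_p(x, y):
    """Exhaustive two-sided permutation oracle over all rank assignments."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1, n = len(x), len(pooled)
    mu = n1 * (n + 1) / 2
    w_obs = ranks[:n1].sum()
    dev = abs(w_obs - mu)
    hits = total = 0
    for combo in itertools.combinations(range(n), n1):
        total += 1
        if abs(ranks[list(combo)].sum() - mu) >= dev - 1e-12:
            hits += 1
    return hits / total


@pytest.mark.parametrize("seed", range(8))
def test_small_sample_p_equals_exact_enumeration(seed):
    rng = np.random.default_rng(seed)
    n1 = int(rng.integers(2, 6))
    n2 = int(rng.integers(2, 11 - n1))
    x = np.round(rng.normal(0, 1, n1), 1)
    y = np.round(rng.normal(0.5, 1, n2), 1)  # rounding induces ties
    _, p = rank_sum_test(x, y)
    assert p == pytest.approx(exact_permutation_p(x, y), abs=1e-12)


def test_identical_large_groups_give_p_near_one():
    x = np.arange(100, dtype=float)
    _, p = rank_sum_test(x, x)
    assert p > 0.95


def test_large_sample_matches_scipy_normal_approximation():
    rng = np.random.default_rng(3)
    x = rng.lognormal(2.2, 0.6, 300)
    y = rng.lognormal(2.3, 0.6, 250)
    _, p = rank_sum_test(x, y)
    ref = stats.mannwhitneyu(x, y, use_continuity=False, method="asymptotic").pvalue
    assert p == pytest.approx(ref, rel=1e-10)


def test_tied_data_matches_scipy_with_tie_correction():
    rng = np.random.default_rng(4)
    x = rng.integers(0, 6, 80).astype(float)
    y = rng.integers(1, 7, 90).astype(float)
    _, p = rank_sum_test(x, y)
    ref = stats.mannwhitneyu(x, y, use_continuity=False, method="asymptotic").pvalue
    assert p == pytest.approx(ref, rel=1e-10)


# ---------------------------------------------------------------------------
# chi-square and trend

def test_chi_square_matches_scipy_without_correction():
    table = [[30, 70], [45, 55]]
    stat, p = chi_square_test(table)
    ref = stats.chi2_contingency(np.array(table), correction=False)
    assert stat == pytest.approx(ref.statistic)
    assert p == pytest.approx(ref.pvalue)


def test_chi_square_empty_row_raises():
    with pytest.raises(ValueError):
        chi_square_test([[0, 0], [5, 5]])


def test_flat_proportions_give_zero_trend():
    z, p = cochran_armitage_trend([10, 20, 30], [100, 200, 300])
    assert z == 0.0 and p == 1.0


def test_trend_matches_independent_oracles():
    successes = [12, 25, 40]
    totals = [100, 100, 100]
    z, p = cochran_armitage_trend(successes, totals)
    # frozen from R prop.trend.test(c(12,25,40), c(100,100,100)):
    # X-squared = 20.5462698736, p = 5.820710346e-06
    assert z ** 2 == pytest.approx(20.5462698736, rel=1e-9)
    assert p == pytest.approx(5.820710346e-06, rel=1e-6)
    # statsmodels' linear-by-linear association uses the hypergeometric
    # (N-1) variance; the two z-scores differ by exactly sqrt((N-1)/N)
    from statsmodels.stats.contingency_tables import Table
    N = sum(totals)
    table = np.array([successes, [n - r for r, n in zip(successes, totals)]]).T
    lbl = Table(table).test_ordinal_association()
    assert abs(z) * math.sqrt((N - 1) / N) == pytest.approx(abs(float(lbl.zscore)),
                                                            rel=1e-8)


def test_compare_groups_dispatch():
    cont = compare_groups({"use": [1, 2, 3, 4], "no_use": [2, 3, 4, 5]},
                          "continuous", variable="input_time")
    assert cont.test == "Wilcoxon rank-sum" and "(" in cont.summaries["use"]
    cat = compare_groups([[30, 70], [45, 55]], "categorical", variable="ward")
    assert cat.test == "Pearson chi-square"
    tr = compare_groups(([5, 10, 20], [50, 50, 50]), "trend", variable="proxy by age")
    assert tr.test == "Cochran-Armitage trend"
    with pytest.raises(ValueError):
        compare_groups({"use": [], "no_use": [1.0]}, "continuous")


# ---------------------------------------------------------------------------
# stratified analysis

def _small_pipeline(seed=0, n=600, **kw):
    cfg = CohortConfig(n_cases=n, seed=seed, **kw)
    cases = generate_cohort(cfg)
    events = generate_logs(cases, cfg)
    records, _ = sessionize_input_time(events,
                                       {c.case_id: c.admission_date for c in cases})
    kept, _ = exclude_outliers_mean3sd(records)
    return cases, kept


def test_table_layout_covers_variables_and_strata():
    cases, kept = _small_pipeline()
    tables = stratified_analysis(cases, kept)
    assert set(tables) == {"overall", "ward:internal_medicine", "ward:surgery",
                           "adl:independent", "adl:dependent"}
    for df in tables.values():
        assert list(df["variable"]) == ["input_time", "single_choice_items",
                                        "multi_choice_items", "characters"]
        assert {"use", "no_use", "p_value"} <= set(df.columns)


def test_identical_group_distributions_give_large_p():
    from iqcapture.cohort import LogNormalSpec
    cases, kept = _small_pipeline(
        seed=1, n=800,
        input_time_model={("use",): LogNormalSpec(10.0, 0.6),
                          ("no_use",): LogNormalSpec(10.0, 0.6)},
        singles_median={"use": 56, "no_use": 56},
        multis_median={"use": 15, "no_use": 15},
        chars_median={"use": 220, "no_use": 220})
    tables = stratified_analysis(cases, kept)
    assert (tables["overall"]["p_value"] > 0.01).all()


def test_unjoinable_record_raises():
    cases, kept = _small_pipeline()
    kept.append(InputTimeRecord("ghost", 5.0, 1))
    with pytest.raises(ValueError, match="ghost"):
        stratified_analysis(cases, kept)


def test_pipeline_is_deterministic():
    from iqcapture.analysis import report_text
    a = stratified_analysis(*_small_pipeline(seed=7, n=400))
    b = stratified_analysis(*_small_pipeline(seed=7, n=400))
    assert report_text(a) == report_text(b)
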