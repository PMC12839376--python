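"""Cohort statistics: exact intervals, correlations, tables, strata."""

import math

import numpy as np
import pandas as pd
import pytest

from ddinet.cohort import Cohort, Patient
from ddinet.knowledge import KnowledgeBase, Severity
from ddinet.network import build_network
from ddinet.profiles import (
    PatientProfile,
    interactions_long_frame,
    profile_cohort,
)
from ddinet.simulate import GeneratorConfig, generate
from ddinet.stats import (
    clopper_pearson,
    drug_frequency_table,
    drug_severity_breakdown,
    pair_frequency_table,
    pearson_r,
    proportion_estimate,
    stratify,
    summarize_cohort,
)


# --- Clopper-Pearson -------------------------------------------------------

def _binom_tail_ge(n, x, p):
    """P(X >= x) for X ~ Binomial(n, p), from the exact pmf."""
    return sum(math.comb(n, k) * p**k * (1 - p) ** (n - k) for k in range(x, n + 1))


def _binom_tail_le(n, x, p):
    return sum(math.comb(n, k) * p**k * (1 - p) ** (n - k) for k in range(0, x + 1))


def _bisect(f, target, lo=0.0, hi=1.0, iters=80):
    """Solve f(p) = target for the monotone-increasing f on [lo, hi]."""
    for _ in range(iters):
        mid = (lo + hi) / 2
        if f(mid) < target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def cp_oracle(x, n, level=0.95):
    """Clopper-Pearson interval by bisection on binomial tails."""
    alpha = 1 - level
    lo = 0.0 if x == 0 else _bisect(lambda p: _binom_tail_ge(n, x, p), alpha / 2)
    hi = 1.0 if x == n else _bisect(
        lambda p: 1 - _binom_tail_le(n, x, p), 1 - alpha / 2)
    return 100 * lo, 100 * hi


@pytest.mark.parametrize("x, n", [
    (0, 10), (10, 10), (5, 10), (1, 30), (123, 250), (246, 250), (299, 300)])
def test_clopper_pearson_matches_binomial_tail_bisection(x, n):
    got = clopper_pearson(x, n)
    want = cp_oracle(x, n)
    assert got[0] == pytest.approx(want[0], abs=1e-9 * 100)
    assert got[1] == pytest.approx(want[1], abs=1e-9 * 100)


def test_clopper_pearson_boundaries_and_errors():
    assert clopper_pearson(0, 10)[0] == 0.0
    assert clopper_pearson(10, 10)[1] == 100.0
    with pytest.raises(ValueError):
        clopper_pearson(5, 0)
    with pytest.raises(ValueError):
        clopper_pearson(11, 10)


def test_clopper_pearson_brackets_half():
    lo, hi = clopper_pearson(5, 10)
    assert lo < 50 < hi
    # exact symmetry of the beta quantiles at x = n/2
    assert lo == pytest.approx(100 - hi, abs=1e-9)


def test_proportion_estimate_invariants():
    est = proportion_estimate(183, 250)
    assert 0 <= est.ci_low <= est.pct <= est.ci_high <= 100
    assert est.pct == pytest.approx(73.2)


# --- Pearson r -------------------------------------------------------------

def test_pearson_perfect_linearity():
    assert pearson_r([1, 2, 3], [2, 4, 6]).r == pytest.approx(1.0)
    assert pearson_r([1, 2, 3], [6, 4, 2]).r == pytest.approx(-1.0)


def test_pearson_matches_textbook_formula():
    rng = np.random.default_rng(42)
    x = rng.normal(size=100)
    y = 0.5 * x + rng.normal(size=100)
    got = pearson_r(x, y).r
    # independent evaluation: cov / (sx * sy) from raw sums
    xm, ym = x - x.mean(), y - y.mean()
    want = (xm * ym).sum() / math.sqrt((xm**2).sum() * (ym**2).sum())
    assert got == pytest.approx(want, abs=1e-12)
    assert abs(got) <= 1


def test_pearson_constant_input_is_absent_with_warning():
    with pytest.warns(UserWarning, match="constant"):
        result = pearson_r([1, 1, 1], [1, 2, 3])
    assert result.r is None
    with pytest.raises(ValueError):
        pearson_r([1], [2])


# --- summarize_cohort ------------------------------------------------------

def _profile(pid, n_meds, interactions):
    return PatientProfile(patient_id=pid, n_medications=n_meds,
                          interactions=interactions)


def test_summarize_three_patient_example():
    p1 = _profile("P1", 3, [])
    p2 = _profile("P2", 4, [(("a", "b"), Severity.MAJOR),
                            (("a", "c"), Severity.MINOR)])
    p3 = _profile("P3", 6, [(("a", "b"), Severity.MAJOR),
                            (("a", "c"), Severity.MAJOR),
                            (("a", "d"), Severity.MAJOR),
                            (("b", "c"), Severity.MODERATE),
                            (("b", "d"), Severity.MODERATE)])
    s = summarize_cohort([p1, p2, p3])
    assert s.total_interactions == 7
    assert s.prevalence_any.successes == 2 and s.prevalence_any.n == 3
    assert s.prevalence_any_major.successes == 2
    assert {k: v["count"] for k, v in s.risk_distribution.items()} == {
        "low": 1, "moderate": 1, "high": 1}
    assert sum(v["pct"] for v in s.severity_distribution.values()) == (
        pytest.approx(100.0, abs=0.1))
    assert sum(v["count"] for v in s.risk_distribution.values()) == s.n_patients


def test_summarize_all_zero_cohort():
    s = summarize_cohort([_profile(f"P{i}", 2, []) for i in range(4)])
    assert s.prevalence_any.successes == 0
    assert s.severity_distribution == {}
    assert s.total_interactions == 0
    assert s.correlation_meds_vs_total.r is None


def test_summary_totals_match_long_table_recount():
    """Cohort totals re-derived from the long-format interaction table."""
    bundle = generate(GeneratorConfig(seed=3, n_patients=50))
    profiles = profile_cohort(bundle.cohort, bundle.kb)
    s = summarize_cohort(profiles)
    long = interactions_long_frame(profiles)
    assert s.total_interactions == len(long)
    recount = long["severity"].value_counts().to_dict()
    assert {k: v["count"] for k, v in s.severity_distribution.items()} == recount
    assert s.prevalence_any.successes == long["patient_id"].nunique()


# --- frequency tables ------------------------------------------------------

def _long(rows):
    return pd.DataFrame(rows, columns=["patient_id", "drug_a", "drug_b",
                                       "severity"])


def test_drug_frequency_positional_count():
    long = _long([("P1", "a", "b", "minor"), ("P1", "a", "c", "major")])
    table = drug_frequency_table(long)
    assert dict(zip(table["drug"], table["count"])) == {"a": 2, "b": 1, "c": 1}
    assert table["count"].sum() == 2 * len(long)
    assert table.iloc[0]["drug"] == "a"  # ranked by count desc


def test_drug_frequency_empty():
    assert drug_frequency_table(_long([])).empty


def test_drug_frequency_top1_matches_recount_and_sum_invariant():
    bundle = generate(GeneratorConfig(seed=5, n_patients=60))
    profiles = profile_cohort(bundle.cohort, bundle.kb)
    long = interactions_long_frame(profiles)
    table = drug_frequency_table(long, bundle.cohort)
    assert table["count"].sum() == 2 * len(long)
    counts: dict[str, int] = {}
    for row in long.itertuples(index=False):
        counts[row.drug_a] = counts.get(row.drug_a, 0) + 1
        counts[row.drug_b] = counts.get(row.drug_b, 0) + 1
    best = min(sorted(counts), key=lambda d: (-counts[d], d))
    assert table.iloc[0]["drug"] == best
    assert (table["male"] + table["female"]).sum() == 2 * len(long)


def test_mf_ratio_absent_when_no_female_count():
    patients = [
        Patient(id="P1", age=60, sex="male", medications=("a", "b")),
        Patient(id="P2", age=70, sex="female", medications=("c", "d")),
    ]
    cohort = Cohort(patients=patients)
    long = _long([("P1", "a", "b", "minor"), ("P2", "c", "d", "minor")])
    table = drug_frequency_table(long, cohort).set_index("drug")
    assert np.isnan(table.loc["a", "mf_ratio"])  # no female appearances
    assert np.isnan(table.loc["c", "mf_ratio"]) == False  # noqa: E712


def test_pair_frequency_counts_patients_per_pair():
    long = _long([("P1", "a", "b", "minor"), ("P2", "a", "b", "minor"),
                  ("P2", "b", "c", "major")])
    table = pair_frequency_table(long)
    assert len(table) == 2  # unique canonical pairs
    top = table.iloc[0]
    assert (top["drug_a"], top["drug_b"], top["count"]) == ("a", "b", 2)


def test_pair_count_equals_network_edge_count():
    bundle = generate(GeneratorConfig(seed=7, n_patients=40))
    profiles = profile_cohort(bundle.cohort, bundle.kb)
    long = interactions_long_frame(profiles)
    g = build_network(profiles)
    assert len(pair_frequency_table(long)) == g.n_edges


def test_drug_severity_breakdown_rows_sum():
    bundle = generate(GeneratorConfig(seed=9, n_patients=40))
    profiles = profile_cohort(bundle.cohort, bundle.kb)
    long = interactions_long_frame(profiles)
    cross = drug_severity_breakdown(long, top=15)
    assert len(cross) <= 15
    sev_cols = [c for c in cross.columns
                if c in {"minor", "moderate", "major", "unknown"}]
    assert (cross[sev_cols].sum(axis=1) == cross["total"]).all()


# --- stratification --------------------------------------------------------

def _mini_cohort():
    patients = [
        Patient(id="P1", age=45, sex="male", medications=("a", "b")),
        Patient(id="P2", age=70, sex="male", medications=("a", "b")),
        Patient(id="P3", age=83, sex="female", medications=("a", "b")),
    ]
    kb = KnowledgeBase.from_records([("a", "b", "major")])
    cohort = Cohort(patients=patients)
    return cohort, profile_cohort(cohort, kb)


def test_stratify_partition_conservation():
    cohort, profiles = _mini_cohort()
    total = summarize_cohort(profiles).total_interactions
    for by in ("sex", "age_group", "both"):
        strata = stratify(cohort, profiles, by=by)
        assert sum(s.total_interactions for s in strata.values()) == total
        assert sum(s.n_patients for s in strata.values()) == len(cohort)


def test_single_stratum_equals_cohort_summary():
    patients = [Patient(id=f"P{i}", age=60, sex="male", medications=("a", "b"))
                for i in range(3)]
    kb = KnowledgeBase.from_records([("a", "b", "minor")])
    cohort = Cohort(patients=patients)
    profiles = profile_cohort(cohort, kb)
    strata = stratify(cohort, profiles, by="sex")
    assert list(strata) == ["male"]
    assert strata["male"].to_dict() == summarize_cohort(profiles).to_dict()


def test_stratify_synthetic_age_bins_resum():
    bundle = generate(GeneratorConfig(seed=11, n_patients=80))
    profiles = profile_cohort(bundle.cohort, bundle.kb)
    strata = stratify(bundle.cohort, profiles, by="age_group")
    global_summary = summarize_cohort(profiles)
    assert sum(s.total_interactions for s in strata.values()) == (
        global_summary.total_interactions)
    for sev in ("minor", "moderate", "major"):
        per_bin = sum(s.severity_distribution.get(sev, {"count": 0})["count"]
                      for s in strata.values())
        want = global_summary.severity_distribution.get(sev, {"count": 0})["count"]
        assert per_bin == want


def test_frequency_tables_invariant_to_patient_order():
    bundle = generate(GeneratorConfig(seed=13, n_patients=30))
    profiles = profile_cohort(bundle.cohort, bundle.kb)
    long = interactions_long_frame(profiles)
    reversed_long = interactions_long_frame(list(reversed(profiles)))
    pd.testing.assert_frame_equal(
        drug_frequency_table(long), drug_frequency_table(reversed_long))
    pd.testing.assert_frame_equal(
        pair_frequency_table(long), pair_frequency_table(reversed_long))
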