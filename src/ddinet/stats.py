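"""Cohort-level descriptive statistics.

Aggregates per-patient interaction profiles into the descriptive surface
of a polypharmacy DDI study: prevalences with exact Clopper–Pearson
intervals, the event-level severity distribution, per-drug and per-pair
frequency tables, burden/risk category distributions, Pearson
correlations, and sex/age stratifications.  Deliberately no inferential
testing — this layer enumerates and describes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .cohort import Cohort, age_group, AGE_GROUP_LABELS
from .knowledge import Severity
from .profiles import PatientProfile

__all__ = [
    "ProportionEstimate",
    "CorrelationResult",
    "CohortSummary",
    "clopper_pearson",
    "proportion_estimate",
    "pearson_r",
    "summarize_cohort",
    "drug_frequency_table",
    "pair_frequency_table",
    "drug_severity_breakdown",
    "stratify",
]


def clopper_pearson(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper–Pearson) binomial confidence interval, in percent.

    Computed from Beta-distribution quantiles:

        lower = BetaInv(alpha/2;     x,     n - x + 1)
        upper = BetaInv(1 - alpha/2; x + 1, n - x)

    with the conventional boundary values lower = 0 when x = 0 and
    upper = 100 when x = n.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= successes <= n:
        raise ValueError(f"successes {successes} outside [0, {n}]")
    if not 0 < level < 1:
        raise ValueError("confidence level must be in (0, 1)")
    alpha = 1.0 - level
    lower = 0.0 if successes == 0 else float(
        _sps.beta.ppf(alpha / 2, successes, n - successes + 1))
    upper = 1.0 if successes == n else float(
        _sps.beta.ppf(1 - alpha / 2, successes + 1, n - successes))
    return 100.0 * lower, 100.0 * upper


@dataclass(frozen=True)
class ProportionEstimate:
    """A cohort proportion with its exact confidence interval (percent)."""

    successes: int
    n: int
    level: float = 0.95
    pct: float = field(init=False)
    ci_low: float = field(init=False)
    ci_high: float = field(init=False)

    def __post_init__(self) -> None:
        lo, hi = clopper_pearson(self.successes, self.n, self.level)
        object.__setattr__(self, "pct", 100.0 * self.successes / self.n)
        object.__setattr__(self, "ci_low", lo)
        object.__setattr__(self, "ci_high", hi)

    def to_dict(self) -> dict:
        return {
            "successes": self.successes,
            "n": self.n,
            "pct": round(self.pct, 1),
            "ci_low": round(self.ci_low, 1),
            "ci_high": round(self.ci_high, 1),
            "level": self.level,
        }


def proportion_estimate(successes: int, n: int, level: float = 0.95) -> ProportionEstimate:
    """Convenience constructor for :class:`ProportionEstimate`."""
    return ProportionEstimate(successes, n, level)


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson product-moment correlation; ``r is None`` when undefined."""

    r: Optional[float]
    n: int

    def to_dict(self) -> dict:
        return {"r": None if self.r is None else round(self.r, 3), "n": self.n}


def pearson_r(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson correlation of two equal-length numeric sequences.

    Returns an absent coefficient (with a warning) when either variable
    is constant, rather than a spurious value.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    if xa.size < 2:
        raise ValueError("need at least two observations")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        warnings.warn("Pearson r undefined for constant input", stacklevel=2)
        return CorrelationResult(r=None, n=int(xa.size))
    r = float(np.corrcoef(xa, ya)[0, 1])
    return CorrelationResult(r=r, n=int(xa.size))


def _dist(counts: Mapping[str, int], denom: int) -> dict[str, dict]:
    return {
        key: {"count": int(cnt), "pct": (100.0 * cnt / denom) if denom else 0.0}
        for key, cnt in counts.items()
    }


@dataclass
class CohortSummary:
    """Machine-readable cohort aggregate (counts kept at full precision;
    percentages rounded only on export)."""

    n_patients: int
    total_interactions: int
    severity_distribution: dict[str, dict]
    prevalence_any: ProportionEstimate
    prevalence_any_major: ProportionEstimate
    prevalence_by_severity: dict[str, ProportionEstimate]
    risk_distribution: dict[str, dict]
    medication_burden_distribution: dict[str, dict]
    interaction_burden_distribution: dict[str, dict]
    per_patient: dict[str, float]
    correlation_meds_vs_total: CorrelationResult
    correlation_total_vs_major: CorrelationResult

    def to_dict(self) -> dict:
        def round_dist(d: dict) -> dict:
            return {k: {"count": v["count"], "pct": round(v["pct"], 1)}
                    for k, v in d.items()}

        return {
            "n_patients": self.n_patients,
            "total_interactions": self.total_interactions,
            "severity_distribution": round_dist(self.severity_distribution),
            "prevalence_any": self.prevalence_any.to_dict(),
            "prevalence_any_major": self.prevalence_any_major.to_dict(),
            "prevalence_by_severity": {
                k: v.to_dict() for k, v in self.prevalence_by_severity.items()
            },
            "risk_distribution": round_dist(self.risk_distribution),
            "medication_burden_distribution": round_dist(
                self.medication_burden_distribution),
            "interaction_burden_distribution": round_dist(
                self.interaction_burden_distribution),
            "per_patient": {k: round(v, 2) for k, v in self.per_patient.items()},
            "correlation_meds_vs_total": self.correlation_meds_vs_total.to_dict(),
            "correlation_total_vs_major": self.correlation_total_vs_major.to_dict(),
        }


def summarize_cohort(profiles: Sequence[PatientProfile],
                     level: float = 0.95) -> CohortSummary:
    """Aggregate patient profiles into a :class:`CohortSummary`.

    Severity distribution is event-level (over all interactions);
    prevalences and category distributions are patient-level.
    """
    if not profiles:
        raise ValueError("need at least one patient profile")
    n = len(profiles)
    totals = np.array([p.total_interactions for p in profiles])
    majors = np.array([p.major_count for p in profiles])
    meds = np.array([p.n_medications for p in profiles])

    sev_counts: dict[str, int] = {}
    for p in profiles:
        for sev, cnt in p.counts.items():
            if cnt:
                sev_counts[sev.value] = sev_counts.get(sev.value, 0) + cnt
    total_events = int(totals.sum())

    by_sev = {
        sev.value: proportion_estimate(
            int(sum(1 for p in profiles if p.counts[sev] > 0)), n, level)
        for sev in Severity
        if any(p.counts[sev] > 0 for p in profiles)
    }

    def _cat_counts(values: Iterable[str], order: Sequence[str]) -> dict[str, int]:
        counts = {label: 0 for label in order}
        for v in values:
            counts[v] += 1
        return counts

    risk = _cat_counts((p.risk_category for p in profiles), ("low", "moderate", "high"))
    med_burden = _cat_counts((p.burden_category for p in profiles),
                             ("low", "medium", "high"))
    int_burden = _cat_counts((p.interaction_burden_category for p in profiles),
                             ("low", "medium", "high"))

    if n >= 2:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            corr_mt = pearson_r(meds, totals)
            corr_tm = pearson_r(totals, majors)
    else:  # single-patient stratum: correlation undefined
        corr_mt = corr_tm = CorrelationResult(r=None, n=n)

    return CohortSummary(
        n_patients=n,
        total_interactions=total_events,
        severity_distribution=_dist(sev_counts, total_events),
        prevalence_any=proportion_estimate(int((totals > 0).sum()), n, level),
        prevalence_any_major=proportion_estimate(int((majors > 0).sum()), n, level),
        prevalence_by_severity=by_sev,
        risk_distribution=_dist(risk, n),
        medication_burden_distribution=_dist(med_burden, n),
        interaction_burden_distribution=_dist(int_burden, n),
        per_patient={
            "mean_medications": float(meds.mean()),
            "mean_total": float(totals.mean()),
            "median_total": float(np.median(totals)),
            "max_total": float(totals.max()),
            "mean_major": float(majors.mean()),
            "median_major": float(np.median(majors)),
            "max_major": float(majors.max()),
        },
        correlation_meds_vs_total=corr_mt,
        correlation_total_vs_major=corr_tm,
    )


def _patient_attrs(cohort: Cohort) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [p.id for p in cohort],
            "sex": [p.sex for p in cohort],
            "age_group": [p.age_group for p in cohort],
        }
    )


def drug_frequency_table(interactions: pd.DataFrame,
                         cohort: Optional[Cohort] = None) -> pd.DataFrame:
    """Per-drug interaction frequency from the long-format table.

    Every interaction row contributes one appearance to each of its two
    drugs, so the column sum equals twice the number of interactions.
    Ranking is count-descending with lexicographic tie-break.  When a
    cohort is supplied, per-sex and per-age-group appearance counts and
    the male/female ratio are added (ratio absent when the female count
    is zero).
    """
    if interactions.empty:
        return pd.DataFrame(columns=["drug", "count"])
    melted = interactions.melt(
        id_vars=[c for c in ("patient_id", "severity") if c in interactions.columns],
        value_vars=["drug_a", "drug_b"], value_name="drug",
    )
    table = (
        melted.groupby("drug").size().rename("count").reset_index()
    )
    if cohort is not None:
        attrs = _patient_attrs(cohort)
        merged = melted.merge(attrs, on="patient_id", how="left")
        for sex in ("male", "female"):
            counts = (
                merged[merged["sex"] == sex].groupby("drug").size().rename(sex)
            )
            table = table.merge(counts, on="drug", how="left")
            table[sex] = table[sex].fillna(0).astype(int)
        table["mf_ratio"] = np.where(
            table["female"] > 0, table["male"] / table["female"], np.nan
        ).round(2)
        for grp in AGE_GROUP_LABELS:
            counts = (
                merged[merged["age_group"] == grp].groupby("drug").size().rename(grp)
            )
            table = table.merge(counts, on="drug", how="left")
            table[grp] = table[grp].fillna(0).astype(int)
    return (
        table.sort_values(["count", "drug"], ascending=[False, True])
        .reset_index(drop=True)
    )


def pair_frequency_table(interactions: pd.DataFrame) -> pd.DataFrame:
    """Per-pair frequency: one entry per distinct canonical pair, count =
    number of patient-level occurrences of that pair."""
    if interactions.empty:
        return pd.DataFrame(columns=["drug_a", "drug_b", "severity", "count"])
    table = (
        interactions.groupby(["drug_a", "drug_b", "severity"])
        .size().rename("count").reset_index()
    )
    return (
        table.sort_values(["count", "drug_a", "drug_b"], ascending=[False, True, True])
        .reset_index(drop=True)
    )


def drug_severity_breakdown(interactions: pd.DataFrame, top: int = 15) -> pd.DataFrame:
    """Severity cross-tabulation for the *top* most frequently
    interacting drugs (selection by total count, lexicographic
    tie-break).  Counts plus row-percentage columns."""
    freq = drug_frequency_table(interactions)
    if freq.empty:
        return pd.DataFrame()
    chosen = freq.head(top)["drug"].tolist()
    melted = interactions.melt(
        id_vars=["severity"], value_vars=["drug_a", "drug_b"], value_name="drug"
    )
    melted = melted[melted["drug"].isin(chosen)]
    cross = (
        melted.groupby(["drug", "severity"]).size().unstack(fill_value=0)
    )
    cross = cross.reindex(chosen)
    totals = cross.sum(axis=1)
    for col in list(cross.columns):
        cross[f"{col}_pct"] = (100.0 * cross[col] / totals).round(1)
    cross.insert(0, "total", totals)
    return cross.reset_index()


def stratify(cohort: Cohort, profiles: Sequence[PatientProfile],
             by: str = "sex") -> dict[str, CohortSummary]:
    """Per-stratum summaries, partitioning the cohort by ``sex``,
    ``age_group`` or ``both``.  Strata counts re-aggregate exactly to the
    cohort totals (empty strata are omitted)."""
    if by not in {"sex", "age_group", "both"}:
        raise ValueError("by must be 'sex', 'age_group' or 'both'")
    prof_by_id = {p.patient_id: p for p in profiles}

    def key(p) -> str:
        if by == "sex":
            return p.sex
        if by == "age_group":
            return age_group(p.age)
        return f"{p.sex}|{age_group(p.age)}"

    groups: dict[str, list[PatientProfile]] = {}
    for patient in cohort:
        prof = prof_by_id.get(patient.id)
        if prof is None:
            continue
        groups.setdefault(key(patient), []).append(prof)
    return {label: summarize_cohort(profs) for label, profs in sorted(groups.items())}


def severity_distribution_frame(summary: CohortSummary) -> pd.DataFrame:
    """Tidy severity distribution table for export."""
    rows = [
        {"severity": sev, "count": v["count"], "pct": round(v["pct"], 1)}
        for sev, v in sorted(summary.severity_distribution.items())
    ]
    return pd.DataFrame(rows, columns=["severity", "count", "pct"])


def risk_distribution_frame(summary: CohortSummary) -> pd.DataFrame:
    rows = [
        {"risk_category": cat, "count": v["count"], "pct": round(v["pct"], 1)}
        for cat, v in summary.risk_distribution.items()
    ]
    return pd.DataFrame(rows, columns=["risk_category", "count", "pct"])
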