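"""Per-patient interaction profiling.

For each patient, every unordered pair among their n medications — there
are n(n-1)/2 of them — is screened once against the knowledge base.  The
matches, their severity counts, and three categorical measures derive
from that screen:

* medication burden:   low 1–5 drugs, medium 6–10, high >= 11
* interaction burden:  low 0–10 interactions, medium 11–30, high >= 31
* major-interaction risk: low 0 major, moderate 1–2, high >= 3
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .cohort import Patient
from .knowledge import KnowledgeBase, Severity, canonical_pair

__all__ = [
    "PatientProfile",
    "enumerate_pairs",
    "profile_patient",
    "profile_cohort",
    "medication_burden_category",
    "interaction_burden_category",
    "risk_category",
    "profiles_to_frame",
    "interactions_long_frame",
]


def enumerate_pairs(medications: Iterable[str]) -> list[tuple[str, str]]:
    """All unordered pairs of a medication set, canonically ordered.

    A set of n drugs yields exactly n(n-1)/2 pairs; no self-pairs, no
    duplicates.
    """
    meds = sorted(set(medications))
    return [canonical_pair(a, b) for a, b in itertools.combinations(meds, 2)]


def medication_burden_category(n: int) -> str:
    """Medication-count burden: 1–5 low, 6–10 medium, >=11 high."""
    if n < 1:
        raise ValueError("medication count must be >= 1")
    if n <= 5:
        return "low"
    return "medium" if n <= 10 else "high"


def interaction_burden_category(total: int) -> str:
    """Interaction-count burden: 0–10 low, 11–30 medium, >=31 high."""
    if total < 0:
        raise ValueError("interaction count must be >= 0")
    if total <= 10:
        return "low"
    return "medium" if total <= 30 else "high"


def risk_category(major: int) -> str:
    """Major-interaction risk: 0 low, 1–2 moderate, >=3 high."""
    if major < 0:
        raise ValueError("major-interaction count must be >= 0")
    if major == 0:
        return "low"
    return "moderate" if major <= 2 else "high"


@dataclass
class PatientProfile:
    """One patient's screened interactions and derived measures."""

    patient_id: str
    n_medications: int
    interactions: list[tuple[tuple[str, str], Severity]] = field(default_factory=list)

    @property
    def candidate_pairs(self) -> int:
        return self.n_medications * (self.n_medications - 1) // 2

    @property
    def counts(self) -> dict[Severity, int]:
        out = {s: 0 for s in Severity}
        for _, sev in self.interactions:
            out[sev] += 1
        return out

    @property
    def total_interactions(self) -> int:
        return len(self.interactions)

    @property
    def major_count(self) -> int:
        return self.counts[Severity.MAJOR]

    @property
    def major_pct_of_total(self) -> Optional[float]:
        """Major interactions as % of the patient's total; ``None`` (not
        zero) for patients with no interactions, so means over patients
        with >= 1 interaction stay well-defined."""
        if self.total_interactions == 0:
            return None
        return 100.0 * self.major_count / self.total_interactions

    @property
    def burden_category(self) -> str:
        return medication_burden_category(self.n_medications)

    @property
    def interaction_burden_category(self) -> str:
        return interaction_burden_category(self.total_interactions)

    @property
    def risk_category(self) -> str:
        return risk_category(self.major_count)


def profile_patient(patient: Patient, kb: KnowledgeBase) -> PatientProfile:
    """Screen every candidate pair of *patient* against *kb* once.

    Each unordered pair contributes at most one interaction per patient;
    the interaction list is sorted canonically.
    """
    interactions = []
    for pair in enumerate_pairs(patient.medications):
        sev = kb.records.get(pair)
        if sev is not None:
            interactions.append((pair, sev))
    interactions.sort(key=lambda item: item[0])
    return PatientProfile(
        patient_id=patient.id,
        n_medications=patient.n_medications,
        interactions=interactions,
    )


def profile_cohort(patients: Iterable[Patient], kb: KnowledgeBase) -> list[PatientProfile]:
    """Profile every patient in input order."""
    return [profile_patient(p, kb) for p in patients]


def profiles_to_frame(profiles: Iterable[PatientProfile]) -> pd.DataFrame:
    """One row per patient with all scalar profile fields."""
    rows = []
    for p in profiles:
        counts = p.counts
        rows.append(
            {
                "patient_id": p.patient_id,
                "n_medications": p.n_medications,
                "candidate_pairs": p.candidate_pairs,
                "total_interactions": p.total_interactions,
                "minor_count": counts[Severity.MINOR],
                "moderate_count": counts[Severity.MODERATE],
                "major_count": counts[Severity.MAJOR],
                "unknown_count": counts[Severity.UNKNOWN],
                "major_pct_of_total": (
                    round(p.major_pct_of_total, 1)
                    if p.major_pct_of_total is not None else None
                ),
                "burden_category": p.burden_category,
                "interaction_burden_category": p.interaction_burden_category,
                "risk_category": p.risk_category,
            }
        )
    return pd.DataFrame(rows)


def interactions_long_frame(profiles: Iterable[PatientProfile]) -> pd.DataFrame:
    """Long-format interaction table: patient_id, drug_a, drug_b, severity.

    One row per (patient, interacting pair) — the detailed interactions
    dataset every cohort-level frequency table is recomputed from.
    """
    rows = [
        {"patient_id": p.patient_id, "drug_a": a, "drug_b": b, "severity": sev.value}
        for p in profiles
        for (a, b), sev in p.interactions
    ]
    return pd.DataFrame(rows, columns=["patient_id", "drug_a", "drug_b", "severity"])
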