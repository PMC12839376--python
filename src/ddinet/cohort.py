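"""Patient cohort ingestion and validation.

Reads one-row-per-patient CSV files (id, age, sex, residence, primary
diagnosis, semicolon-delimited medication list) and applies the study's
inclusion rules: adults (>= 18 years) carrying at least two distinct
pharmacologically active agents.  Rows failing a rule are excluded and
itemised with a reason; in strict mode any exclusion aborts the load.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .errors import FormatError, ValidationError
from .knowledge import canonicalize_drug

logger = logging.getLogger(__name__)

__all__ = [
    "Patient",
    "Cohort",
    "ExclusionReport",
    "load_cohort",
    "write_cohort",
    "parse_medications",
    "age_group",
    "AGE_GROUP_LABELS",
]

_SEX_ALIASES = {"m": "male", "male": "male", "f": "female", "female": "female"}
_RESIDENCE_VALUES = {"urban", "rural"}

#: Four-bin age scheme: half-open bins [18,50), [50,65), [65,80), [80,inf).
AGE_GROUP_LABELS = ("<50", "50–65", "65–80", ">80")
_AGE_CUTS = (50, 65, 80)


@dataclass(frozen=True)
class Patient:
    """One admitted patient with a de-duplicated medication set."""

    id: str
    age: int
    sex: str
    medications: tuple[str, ...]
    residence: Optional[str] = None
    diagnosis: Optional[str] = None

    def __post_init__(self) -> None:
        if self.age < 18:
            raise ValidationError(f"patient {self.id}: age {self.age} under 18")
        meds = tuple(sorted({canonicalize_drug(m, f"patient {self.id}")
                             for m in self.medications}))
        if len(meds) < 2:
            raise ValidationError(
                f"patient {self.id}: fewer than two agents after de-duplication"
            )
        object.__setattr__(self, "medications", meds)

    @property
    def n_medications(self) -> int:
        return len(self.medications)

    @property
    def age_group(self) -> str:
        return age_group(self.age)


@dataclass
class Cohort:
    """Validated patient collection plus load provenance."""

    patients: list[Patient]
    source: str = "<memory>"
    loaded_at: Optional[str] = None

    def __post_init__(self) -> None:
        ids = [p.id for p in self.patients]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate patient id(s): {dupes}")

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self):
        return iter(self.patients)

    def to_frame(self) -> pd.DataFrame:
        """One row per patient in the cohort CSV column layout."""
        return pd.DataFrame(
            {
                "patient_id": [p.id for p in self.patients],
                "age": [p.age for p in self.patients],
                "sex": [p.sex for p in self.patients],
                "residence": [p.residence or "" for p in self.patients],
                "diagnosis": [p.diagnosis or "" for p in self.patients],
                "medications": ["; ".join(p.medications) for p in self.patients],
            }
        )


@dataclass
class ExclusionReport:
    """Per-row accounting of the inclusion screen."""

    n_input: int = 0
    excluded: list[tuple[int, str, str]] = field(default_factory=list)  # (row, id, reason)
    warnings: list[str] = field(default_factory=list)

    @property
    def n_excluded(self) -> int:
        return len(self.excluded)

    @property
    def n_accepted(self) -> int:
        return self.n_input - self.n_excluded


def parse_medications(raw: str, context: str = "") -> tuple[str, ...]:
    """Split a semicolon-delimited medication list, canonicalize, and
    de-duplicate (set semantics: one count per drug per patient)."""
    items = [part for part in str(raw).split(";") if part.strip()]
    return tuple(sorted({canonicalize_drug(m, context) for m in items}))


_REQUIRED = ("patient_id", "age", "sex", "residence", "diagnosis", "medications")


def load_cohort(path: str | Path, strict: bool = False) -> tuple[Cohort, ExclusionReport]:
    """Load and screen a cohort CSV.

    Returns the accepted :class:`Cohort` and an :class:`ExclusionReport`
    itemising every rejected row with its reason.  In strict mode the
    first exclusion (or unknown sex value) raises instead.
    """
    path = Path(path)
    table = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED if c not in table.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")

    report = ExclusionReport(n_input=len(table))
    patients: list[Patient] = []
    for idx, row in table.iterrows():
        rownum = int(idx) + 2
        pid = str(row["patient_id"]).strip()
        reason = None
        try:
            if not pid:
                reason = "missing patient id"
                raise ValidationError(reason)
            try:
                age = int(str(row["age"]).strip())
            except ValueError:
                reason = f"unparsable age '{row['age']}'"
                raise ValidationError(reason) from None
            if age < 18:
                reason = "under 18"
                raise ValidationError(reason)

            sex_raw = str(row["sex"]).strip().lower()
            sex = _SEX_ALIASES.get(sex_raw)
            if sex is None:
                if strict:
                    raise ValidationError(
                        f"{path.name} row {rownum}: unknown sex value '{sex_raw}'"
                    )
                sex = "other/unknown"
                report.warnings.append(
                    f"row {rownum} ({pid}): sex '{sex_raw}' mapped to other/unknown"
                )

            raw_meds = str(row["medications"])
            if not raw_meds.strip():
                reason = "incomplete or missing medication record"
                raise ValidationError(reason)
            meds = parse_medications(raw_meds, f"row {rownum}")
            n_raw = len([p for p in raw_meds.split(";") if p.strip()])
            if len(meds) < n_raw:
                report.warnings.append(
                    f"row {rownum} ({pid}): {n_raw - len(meds)} duplicate "
                    "medication(s) collapsed"
                )
            if len(meds) < 2:
                reason = "fewer than two agents"
                raise ValidationError(reason)

            residence = str(row["residence"]).strip().lower() or None
            if residence is not None and residence not in _RESIDENCE_VALUES:
                report.warnings.append(
                    f"row {rownum} ({pid}): residence '{residence}' not recognised"
                )
                residence = None
            diagnosis = str(row["diagnosis"]).strip() or None
            patients.append(
                Patient(id=pid, age=age, sex=sex, medications=meds,
                        residence=residence, diagnosis=diagnosis)
            )
        except ValidationError as exc:
            if reason is None:
                raise  # structural problem (e.g. strict sex), not an exclusion
            if strict:
                raise ValidationError(
                    f"{path.name} row {rownum} ({pid or '?'}): {reason}"
                ) from exc
            report.excluded.append((rownum, pid or "?", reason))

    cohort = Cohort(
        patients=patients,
        source=str(path),
        loaded_at=_dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds"),
    )
    logger.info(
        "loaded %d patients from %s (%d excluded of %d rows)",
        len(cohort), path, report.n_excluded, report.n_input,
    )
    return cohort, report


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write the cohort back out in the standard CSV layout."""
    cohort.to_frame().to_csv(path, index=False)


def age_group(age: int, cuts: Sequence[int] = _AGE_CUTS,
              labels: Sequence[str] = AGE_GROUP_LABELS) -> str:
    """Assign an adult age to its (half-open) bin.

    Default scheme: [18,50) -> "<50", [50,65) -> "50–65", [65,80) ->
    "65–80", [80,inf) -> ">80".  Custom cut points may be supplied with
    ``len(labels) == len(cuts) + 1``.
    """
    if age < 18:
        raise ValidationError(f"age {age} below adult minimum of 18")
    if len(labels) != len(cuts) + 1:
        raise ValueError("need exactly one more label than cut points")
    for cut, label in zip(cuts, labels):
        if age < cut:
            return label
    return labels[-1]
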