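"""Severity-annotated drug-drug interaction knowledge base.

A knowledge base (KB) is a local table of interacting drug pairs, each
carrying one of four severity labels (``minor``, ``moderate``, ``major``,
``unknown``), standing in for an online interaction checker.  Pairs are
unordered and stored under a canonical (lexicographic) key, so ``(A, B)``
and ``(B, A)`` are the same record.  The KB is closed-world: a pair that
is not listed means "no documented interaction", which is distinct from a
listed pair whose severity is undetermined (``unknown``).
"""

from __future__ import annotations

import enum
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "Severity",
    "SEVERITY_WEIGHTS",
    "canonicalize_drug",
    "canonical_pair",
    "severity_weight",
    "InteractionRecord",
    "KnowledgeBase",
    "load_knowledge_base",
    "write_knowledge_base",
]


class Severity(str, enum.Enum):
    """Clinical severity of a documented drug-drug interaction.

    ``minor < moderate < major`` is the clinical ordering; ``unknown`` is
    a listed-but-undetermined severity and is never ranked clinically.
    """

    MINOR = "minor"
    MODERATE = "moderate"
    MAJOR = "major"
    UNKNOWN = "unknown"

    @property
    def weight(self) -> float:
        """Numeric edge weight used by the network layer."""
        return SEVERITY_WEIGHTS[self]

    @property
    def clinical_rank(self) -> int:
        """1 (minor) .. 3 (major).  Raises for ``unknown``, which has no
        position on the clinical scale."""
        if self is Severity.UNKNOWN:
            raise ValidationError("'unknown' severity has no clinical rank")
        return {Severity.MINOR: 1, Severity.MODERATE: 2, Severity.MAJOR: 3}[self]


#: Fixed severity -> edge-weight mapping used throughout the package.
SEVERITY_WEIGHTS: dict[Severity, float] = {
    Severity.MINOR: 1.0,
    Severity.MODERATE: 2.0,
    Severity.MAJOR: 3.0,
    Severity.UNKNOWN: 0.5,
}

_WS = re.compile(r"\s+")


def canonicalize_drug(name: str, context: str = "") -> str:
    """Normalise a raw drug name to its canonical form.

    Lower-cases, trims surrounding whitespace and collapses internal runs
    of whitespace to single spaces.  Idempotent.  Raises
    :class:`ValidationError` for empty/blank input; *context* (e.g. a row
    reference) is included in the message to name the offending record.
    """
    canonical = _WS.sub(" ", str(name).strip()).lower()
    if not canonical:
        where = f" ({context})" if context else ""
        raise ValidationError(f"empty or blank drug name{where}")
    return canonical


def canonical_pair(a: str, b: str, context: str = "") -> tuple[str, str]:
    """Canonicalize both names and order them lexicographically.

    Raises :class:`ValidationError` if the two names canonicalize to the
    same drug (self-interactions are undefined).
    """
    ca, cb = canonicalize_drug(a, context), canonicalize_drug(b, context)
    if ca == cb:
        where = f" ({context})" if context else ""
        raise ValidationError(f"self-pair for drug '{ca}'{where}")
    return (ca, cb) if ca < cb else (cb, ca)


def severity_weight(severity: Severity | str) -> float:
    """Map a severity label to its fixed numeric weight
    (major=3, moderate=2, minor=1, unknown=0.5)."""
    return Severity(severity).weight


@dataclass(frozen=True)
class InteractionRecord:
    """One unordered interacting drug pair with its severity."""

    pair: tuple[str, str]
    severity: Severity

    def __post_init__(self) -> None:
        a, b = self.pair
        object.__setattr__(self, "pair", canonical_pair(a, b))
        object.__setattr__(self, "severity", Severity(self.severity))


@dataclass
class KnowledgeBase:
    """Collection of interaction records keyed by canonical pair.

    At most one record exists per unordered pair.  Lookup of a pair that
    is not listed returns ``None`` ("no interaction"), never
    ``Severity.UNKNOWN``.
    """

    records: dict[tuple[str, str], Severity] = field(default_factory=dict)

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str, Severity | str]]
    ) -> "KnowledgeBase":
        """Build a KB from ``(drug_a, drug_b, severity)`` triples.

        Duplicate pairs with agreeing severities collapse silently;
        conflicting duplicates raise with both severities named.
        """
        kb = cls()
        for a, b, sev in records:
            kb.add(a, b, sev)
        return kb

    def add(self, a: str, b: str, severity: Severity | str, context: str = "") -> None:
        pair = canonical_pair(a, b, context)
        try:
            sev = Severity(severity)
        except ValueError:
            allowed = ", ".join(s.value for s in Severity)
            where = f" ({context})" if context else ""
            raise ValidationError(
                f"unknown severity label '{severity}'{where}; allowed: {allowed}"
            ) from None
        existing = self.records.get(pair)
        if existing is not None and existing is not sev:
            raise ValidationError(
                f"conflicting duplicate for pair {pair}: "
                f"'{existing.value}' vs '{sev.value}'"
            )
        self.records[pair] = sev

    def lookup(self, a: str, b: str) -> Optional[Severity]:
        """Severity of the interaction between *a* and *b*, or ``None``
        when the pair is not listed.  Symmetric in its arguments."""
        return self.records.get(canonical_pair(a, b))

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return canonical_pair(*pair) in self.records

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[InteractionRecord]:
        for pair in sorted(self.records):
            yield InteractionRecord(pair, self.records[pair])

    @property
    def drugs(self) -> set[str]:
        """All drug names appearing in at least one record."""
        return {d for pair in self.records for d in pair}

    def to_frame(self) -> pd.DataFrame:
        """Canonical tabular form: drug_a, drug_b, severity (sorted)."""
        rows = [(a, b, sev.value) for (a, b), sev in sorted(self.records.items())]
        return pd.DataFrame(rows, columns=["drug_a", "drug_b", "severity"])


_KB_COLUMNS = ("drug_a", "drug_b", "severity")


def _separator_for(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".tsv":
        return "\t"
    if suffix == ".csv":
        return ","
    raise FormatError(
        f"unsupported knowledge-base extension '{suffix}' for {path}; use .tsv or .csv"
    )


def load_knowledge_base(path: str | Path) -> KnowledgeBase:
    """Read a knowledge base from a delimited file.

    The delimiter is inferred from the extension (``.tsv`` / ``.csv``)
    and the header must contain the columns ``drug_a``, ``drug_b`` and
    ``severity``.  Names are canonicalized and pairs canonically ordered
    on load; validation failures name the offending row.
    """
    path = Path(path)
    sep = _separator_for(path)
    table = pd.read_csv(path, sep=sep, dtype=str)
    missing = [c for c in _KB_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    kb = KnowledgeBase()
    for idx, row in table.iterrows():
        context = f"{path.name} row {int(idx) + 2}"  # +2: header + 1-based
        kb.add(row["drug_a"], row["drug_b"], str(row["severity"]).strip().lower(),
               context=context)
    logger.info("loaded %d interaction records from %s", len(kb), path)
    return kb


def write_knowledge_base(kb: KnowledgeBase, path: str | Path) -> None:
    """Write the canonical record set; delimiter follows the extension.

    ``load_knowledge_base(write_knowledge_base(kb))`` reproduces the
    record set exactly."""
    path = Path(path)
    kb.to_frame().to_csv(path, sep=_separator_for(path), index=False)
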