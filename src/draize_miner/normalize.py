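"""Mapping free-text irritation verdicts to standard GHS categories.

REACH dossiers report eye-irritation conclusions in natural language
("category 1", "corrosive", "cat. I", "highly irritating", ...).  A
synonym table maps the normalized verdict string to a category; anything
without a high-confidence (exact) match stays UNKNOWN.  Low coverage is
expected behavior, not failure: dossier prose is not standardized.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .model import IrritationCategory, SubstanceRecord, severity_rank

__all__ = [
    "SynonymTable",
    "DEFAULT_SYNONYMS",
    "CANONICAL_VERDICT",
    "normalize_text",
    "normalize_verdict",
    "mode_category",
    "coverage",
]

_PUNCT_RE = re.compile(r"[^\w\s]")
_WS_RE = re.compile(r"\s+")


def normalize_text(text: str) -> str:
    """Lowercase, strip punctuation, collapse whitespace."""
    return _WS_RE.sub(" ", _PUNCT_RE.sub(" ", text.lower())).strip()


@dataclass
class SynonymTable:
    """Exact-match lookup from normalized verdict pattern to category.

    Matching is deterministic by design: no fuzzy matching, no partial
    matches.  Patterns are normalized on insertion; a pattern may map to
    only one category.
    """

    entries: dict[str, IrritationCategory] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def add(self, pattern: str, category: IrritationCategory,
            note: str = "") -> None:
        key = normalize_text(pattern)
        if not key:
            raise ValueError("empty pattern")
        existing = self.entries.get(key)
        if existing is not None and existing is not category:
            raise ValueError(
                f"pattern {key!r} already maps to {existing.value}")
        self.entries[key] = category
        if note:
            self.provenance[key] = note

    def lookup(self, text: str) -> IrritationCategory:
        return self.entries.get(normalize_text(text), IrritationCategory.UNKNOWN)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SynonymTable":
        """Load a (pattern, category[, note]) CSV; header row optional."""
        table = cls()
        with open(path, newline="", encoding="utf-8") as fh:
            for row in csv.reader(fh):
                if not row or row[0].strip().lower() == "pattern":
                    continue
                pattern, category = row[0], row[1].strip().upper()
                note = row[2] if len(row) > 2 else ""
                table.add(pattern, IrritationCategory(category), note)
        return table

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["pattern", "category", "note"])
            for key, cat in sorted(self.entries.items()):
                writer.writerow([key, cat.value, self.provenance.get(key, "")])


def _default_table() -> SynonymTable:
    t = SynonymTable()
    spellings = {
        IrritationCategory.TYPE1: [
            "category 1", "cat 1", "cat i", "category i", "type 1",
            "corrosive", "corrosion", "serious damage", "serious eye damage",
            "irreversible damage", "irreversible effects", "highly irritating",
            "severely irritating", "h318",
        ],
        IrritationCategory.TYPE2A: [
            "category 2", "category 2a", "cat 2", "cat 2a", "cat ii",
            "type 2", "type 2a", "irritating", "irritant", "eye irritation",
            "moderately irritating", "h319",
        ],
        IrritationCategory.TYPE2B: [
            "category 2b", "cat 2b", "type 2b", "mildly irritating",
            "mild irritant", "slightly irritating", "h320",
        ],
        IrritationCategory.NON_IRRITANT: [
            "not irritating", "non irritating", "non irritant", "nonirritant",
            "no classification", "not classified", "no irritation",
            "not an irritant", "negative",
        ],
    }
    for cat, words in spellings.items():
        for w in words:
            t.add(w, cat, "default table")
    return t


#: Default synonym table.  The spellings cover the common ways dossiers
#: phrase each category; replace or extend it for a different corpus.
DEFAULT_SYNONYMS: SynonymTable = _default_table()

#: Canonical spelling emitted by the synthetic generator for each category;
#: each is guaranteed to round-trip through :data:`DEFAULT_SYNONYMS`.
CANONICAL_VERDICT: dict[IrritationCategory, str] = {
    IrritationCategory.TYPE1: "category 1",
    IrritationCategory.TYPE2A: "category 2a",
    IrritationCategory.TYPE2B: "category 2b",
    IrritationCategory.NON_IRRITANT: "not irritating",
}


def normalize_verdict(text: str,
                      table: Optional[SynonymTable] = None) -> IrritationCategory:
    """Map one free-text verdict to a category; UNKNOWN when unmatched."""
    return (table or DEFAULT_SYNONYMS).lookup(text)


def mode_category(record: SubstanceRecord,
                  table: Optional[SynonymTable] = None,
                  tie_break: str = "severe") -> IrritationCategory:
    """Most frequent mapped category across a substance's studies.

    UNKNOWN verdicts are excluded from the vote; a substance with no
    mappable verdict returns UNKNOWN.  Ties go to the more severe
    category by default (conservative hazard assignment); pass
    ``tie_break="mild"`` for the opposite convention.
    """
    if tie_break not in ("severe", "mild"):
        raise ValueError("tie_break must be 'severe' or 'mild'")
    votes: dict[IrritationCategory, int] = {}
    for study in record.studies:
        cat = normalize_verdict(study.verdict_text, table)
        if cat is not IrritationCategory.UNKNOWN:
            votes[cat] = votes.get(cat, 0) + 1
    if not votes:
        return IrritationCategory.UNKNOWN
    sign = 1 if tie_break == "severe" else -1
    return max(votes, key=lambda c: (votes[c], sign * -severity_rank(c)))


def coverage(records: Sequence[SubstanceRecord],
             table: Optional[SynonymTable] = None) -> float:
    """Fraction of substances whose mode category could be extracted.

    Mirrors the mapping-coverage statistic of text analysis over dossier
    verdicts; low values are informative, not errors.
    """
    if not records:
        return float("nan")
    mapped = sum(
        mode_category(r, table) is not IrritationCategory.UNKNOWN
        for r in records
    )
    return mapped / len(records)
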