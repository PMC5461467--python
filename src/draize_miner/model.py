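"""Core data model for Draize eye-irritation dossier collections.

A collection is a list of :class:`SubstanceRecord`, one per substance,
each holding the substance's Draize studies, its GHS hazard statements,
an optional binary substructure fingerprint, and the eye-irritation
category reported in the dossier's classification-and-labeling section.

The UN GHS eye categories are:

* Type 1   -- serious, irreversible eye damage (persists >= 21 days)
* Type 2A  -- reversible eye irritation
* Type 2B  -- mild eye irritation, fully reversible within 7 days
* non-irritant

corresponding to hazard statements H318, H319 and H320 respectively.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional

import numpy as np

__all__ = [
    "IrritationCategory",
    "HazardStatus",
    "Guideline",
    "Reversibility",
    "NOT_REVERSED",
    "ENDPOINTS",
    "ENDPOINT_RANGES",
    "SEVERITY_ORDER",
    "DraizeStudy",
    "Fingerprint",
    "SubstanceRecord",
    "Violation",
    "validate_record",
]


class IrritationCategory(str, Enum):
    """UN GHS eye irritation category."""

    TYPE1 = "TYPE1"
    TYPE2A = "TYPE2A"
    TYPE2B = "TYPE2B"
    NON_IRRITANT = "NON_IRRITANT"
    UNKNOWN = "UNKNOWN"


#: Categories ordered from most to least severe.  ``UNKNOWN`` never
#: participates in metrics and is deliberately absent.
SEVERITY_ORDER: tuple[IrritationCategory, ...] = (
    IrritationCategory.TYPE1,
    IrritationCategory.TYPE2A,
    IrritationCategory.TYPE2B,
    IrritationCategory.NON_IRRITANT,
)


class HazardStatus(str, Enum):
    POSITIVE = "POSITIVE"
    NEGATIVE = "NEGATIVE"
    UNKNOWN = "UNKNOWN"


class Guideline(str, Enum):
    """Eye-test study guideline.

    TG 405 is the in vivo rabbit (Draize) test; read-across entries are
    TG 405 results transferred from similar substances.  TG 437 (bovine
    cornea) and TG 438 (isolated chicken eye) are organotypic partial
    replacements.
    """

    TG405_INVIVO = "TG405_INVIVO"
    TG405_READACROSS = "TG405_READACROSS"
    TG437 = "TG437"
    TG438 = "TG438"
    OTHER = "OTHER"


#: Guidelines that count as a Draize (TG 405) result.
DRAIZE_GUIDELINES = frozenset(
    {Guideline.TG405_INVIVO, Guideline.TG405_READACROSS}
)

#: Guidelines considered eye-test studies at all.
EYE_GUIDELINES = frozenset(
    {
        Guideline.TG405_INVIVO,
        Guideline.TG405_READACROSS,
        Guideline.TG437,
        Guideline.TG438,
    }
)


class Reversibility(str, Enum):
    """Longest-reversal-period bucket across all endpoints and studies."""

    REVERSED_7D = "REVERSED_7D"
    REVERSED_21D = "REVERSED_21D"
    IRREVERSIBLE = "IRREVERSIBLE"


#: Sentinel for an endpoint effect that had not reversed by the end of the
#: 21-day observation window ("persists >= 21 days").  Distinct from a
#: missing observation, which is simply absent from the map.
NOT_REVERSED = "NOT_REVERSED"

#: The four Draize ocular endpoints and the score range each may take.
ENDPOINT_RANGES: dict[str, tuple[float, float]] = {
    "cornea": (0.0, 4.0),       # degree of opacity and ulceration
    "iris": (0.0, 2.0),         # swelling, hyperaemia
    "conjunctivae": (0.0, 3.0), # redness, vessel discernibility
    "chemosis": (0.0, 4.0),     # lid/conjunctival swelling
}
ENDPOINTS: tuple[str, ...] = tuple(ENDPOINT_RANGES)

_HCODE_RE = re.compile(r"^H\d{3}$")


@dataclass
class DraizeStudy:
    """One eye-test study for a substance.

    Scores are study-level values (means over the animals in the study
    are admissible, hence floats).  ``reversibility_days`` maps endpoint
    name to the number of days until the effect reversed, or
    :data:`NOT_REVERSED` if it persisted past the 21-day window; endpoints
    with no reversibility observation are absent.  ``reliability`` is the
    Klimisch reliability score (1-4, 1-2 = reliable) or ``None`` when not
    reported.
    """

    study_num: int
    cornea: Optional[float] = None
    iris: Optional[float] = None
    conjunctivae: Optional[float] = None
    chemosis: Optional[float] = None
    reversibility_days: dict[str, object] = field(default_factory=dict)
    verdict_text: str = ""
    reliability: Optional[int] = None
    guideline: Guideline = Guideline.TG405_INVIVO

    def score(self, endpoint: str) -> Optional[float]:
        if endpoint not in ENDPOINT_RANGES:
            raise KeyError(f"unknown Draize endpoint {endpoint!r}")
        return getattr(self, endpoint)


class Fingerprint:
    """Fixed-length binary substructure fingerprint.

    The default length of 881 matches PubChem's 2D substructure keys.
    """

    __slots__ = ("bits",)

    def __init__(self, bits: Iterable[int] | np.ndarray):
        arr = np.asarray(list(bits) if not isinstance(bits, np.ndarray) else bits)
        if arr.ndim != 1:
            raise ValueError("fingerprint bits must be one-dimensional")
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("fingerprint bits must be 0/1")
        self.bits = arr.astype(np.uint8)

    def __len__(self) -> int:
        return int(self.bits.shape[0])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Fingerprint):
            return NotImplemented
        return len(self) == len(other) and bool((self.bits == other.bits).all())

    def __hash__(self):  # pragma: no cover - containers use eq only
        return hash(self.bits.tobytes())

    def __repr__(self) -> str:
        return f"Fingerprint(len={len(self)}, popcount={self.popcount})"

    @property
    def popcount(self) -> int:
        return int(self.bits.sum())

    # -- codecs ---------------------------------------------------------
    def to_bitstring(self) -> str:
        return "".join("1" if b else "0" for b in self.bits)

    def to_hex(self) -> str:
        """Hex codec: bits are packed big-endian, padded to a whole byte."""
        return np.packbits(self.bits).tobytes().hex()

    @classmethod
    def from_bitstring(cls, s: str, length: Optional[int] = None) -> "Fingerprint":
        if set(s) - {"0", "1"}:
            raise ValueError("bit string may contain only '0' and '1'")
        if length is not None and len(s) != length:
            raise ValueError(f"expected {length} bits, got {len(s)}")
        return cls(np.frombuffer(s.encode(), dtype=np.uint8) - ord("0"))

    @classmethod
    def from_hex(cls, s: str, length: int) -> "Fingerprint":
        raw = bytes.fromhex(s)
        bits = np.unpackbits(np.frombuffer(raw, dtype=np.uint8))
        if bits.shape[0] < length or bits.shape[0] - length >= 8:
            raise ValueError(
                f"hex payload holds {bits.shape[0]} bits, cannot decode {length}"
            )
        if bits[length:].any():
            raise ValueError("nonzero padding bits in hex fingerprint")
        return cls(bits[:length])


@dataclass
class SubstanceRecord:
    """One substance: identifier, eye studies, hazards, fingerprint.

    ``hazards`` maps GHS H-code to status; codes absent from the map are
    UNKNOWN by convention, and explicit UNKNOWN entries are normalized
    away on construction so that absence and UNKNOWN compare equal.
    ``dossier_category`` is the eye category from the dossier's
    classification-and-labeling section (H318/H319/H320), when present.
    """

    id: str
    studies: list[DraizeStudy] = field(default_factory=list)
    hazards: dict[str, HazardStatus] = field(default_factory=dict)
    fingerprint: Optional[Fingerprint] = None
    dossier_category: IrritationCategory = IrritationCategory.UNKNOWN

    def __post_init__(self) -> None:
        self.hazards = {
            code: status
            for code, status in self.hazards.items()
            if status is not HazardStatus.UNKNOWN
        }

    def hazard_status(self, code: str) -> HazardStatus:
        return self.hazards.get(code, HazardStatus.UNKNOWN)


@dataclass
class Violation:
    """One validation finding for a record.

    ``fatal`` violations exclude the record from a collection read under
    the default policy; non-fatal ones are reported as warnings.
    """

    record_id: str
    field: str
    message: str
    fatal: bool = False

    def __str__(self) -> str:
        kind = "error" if self.fatal else "warning"
        return f"[{kind}] {self.record_id}: {self.field}: {self.message}"


def validate_record(record: SubstanceRecord, strict: bool = False) -> list[Violation]:
    """Check all invariants of a record; return the full list of findings.

    Validation is total: a record either returns an empty list or every
    violated invariant appears, each with a machine-readable field path.
    Out-of-range endpoint scores are warnings by default (dossiers do
    contain incorrect inputs) and fatal only under ``strict``.
    """
    out: list[Violation] = []
    if not record.id:
        out.append(Violation(record.id, "id", "empty substance id", fatal=True))
    seen_nums: set[int] = set()
    for study in record.studies:
        where = f"studies[{study.study_num}]"
        if study.study_num <= 0:
            out.append(Violation(record.id, where + ".study_num",
                                 "study_num must be a positive integer", fatal=True))
        if study.study_num in seen_nums:
            out.append(Violation(record.id, where + ".study_num",
                                 "duplicate study_num within record", fatal=True))
        seen_nums.add(study.study_num)
        for ep, (lo, hi) in ENDPOINT_RANGES.items():
            score = study.score(ep)
            if score is None:
                continue
            if score < lo or score > hi:
                out.append(Violation(
                    record.id, f"{where}.{ep}",
                    f"score {score} outside Draize range [{lo}, {hi}]",
                    fatal=strict))
        for ep, days in study.reversibility_days.items():
            if ep not in ENDPOINT_RANGES:
                out.append(Violation(record.id, f"{where}.reversibility_days",
                                     f"unknown endpoint {ep!r}", fatal=True))
            elif days != NOT_REVERSED and (not isinstance(days, int) or days < 0):
                out.append(Violation(record.id, f"{where}.reversibility_days.{ep}",
                                     f"days must be a non-negative integer or "
                                     f"{NOT_REVERSED!r}, got {days!r}", fatal=True))
        if study.reliability is not None and study.reliability not in (1, 2, 3, 4):
            out.append(Violation(record.id, where + ".reliability",
                                 f"Klimisch score must be 1-4, got {study.reliability}",
                                 fatal=True))
    for code in record.hazards:
        if not _HCODE_RE.match(code):
            out.append(Violation(record.id, f"hazards.{code}",
                                 "H-code must match H### pattern", fatal=True))
    if record.fingerprint is not None and record.fingerprint.popcount == 0:
        out.append(Violation(record.id, "fingerprint",
                             "all-zero fingerprint unusable for similarity",
                             fatal=False))
    return out


def severity_rank(category: IrritationCategory) -> int:
    """Rank with 0 = most severe; raises for UNKNOWN."""
    return SEVERITY_ORDER.index(category)
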