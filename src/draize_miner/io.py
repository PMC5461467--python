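"""Reading and writing dossier collections.

JSON is the canonical on-disk form; CSV is a flattened convenience view
with one row per study plus one substance-level row per substance
(RFC 4180, UTF-8, header row).  Fingerprints are accepted as 0/1 bit
strings or hex; the two codecs are mutually inverse.
"""

from __future__ import annotations

import csv
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .model import (
    EYE_GUIDELINES,
    NOT_REVERSED,
    DraizeStudy,
    Fingerprint,
    Guideline,
    HazardStatus,
    IrritationCategory,
    SubstanceRecord,
    Violation,
    validate_record,
)

__all__ = [
    "ParseError",
    "ValidationReport",
    "read_collection",
    "read_collection_with_report",
    "write_collection",
    "filter_eye_studies",
]

log = logging.getLogger(__name__)

FORMAT_NAME = "draize-miner-collection"
FORMAT_VERSION = 1

_CSV_COLUMNS = [
    "row_type", "id", "dossier_category", "hazards", "fingerprint",
    "study_num", "cornea", "iris", "conjunctivae", "chemosis",
    "rev_cornea", "rev_iris", "rev_conjunctivae", "rev_chemosis",
    "verdict_text", "reliability", "guideline",
]

_HEX_FP_RE = re.compile(r"^hex:(\d+):([0-9a-fA-F]+)$")


class ParseError(ValueError):
    """Malformed collection file; the message names the record or line."""


@dataclass
class ValidationReport:
    """Everything the validator found while reading a collection."""

    violations: list[Violation] = field(default_factory=list)
    excluded_ids: list[str] = field(default_factory=list)

    def extend(self, vs: Iterable[Violation]) -> None:
        self.violations.extend(vs)

    @property
    def n_fatal(self) -> int:
        return sum(v.fatal for v in self.violations)


def _infer_format(path: Path, format: Optional[str]) -> str:
    if format is not None:
        if format not in ("json", "csv"):
            raise ValueError(f"unknown format {format!r}")
        return format
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("json", "csv"):
        return suffix
    raise ValueError(f"cannot infer format from {path.name!r}; pass format=")


# --------------------------------------------------------------------------
# fingerprint codecs
# --------------------------------------------------------------------------

def decode_fingerprint(text: str, length: Optional[int] = None) -> Fingerprint:
    """Decode a fingerprint from a 0/1 bit string or ``hex:<len>:<payload>``.

    A bare hex payload is also accepted when ``length`` is given.
    """
    m = _HEX_FP_RE.match(text)
    if m:
        return Fingerprint.from_hex(m.group(2), int(m.group(1)))
    if set(text) <= {"0", "1"} and (length is None or len(text) == length):
        return Fingerprint.from_bitstring(text, length)
    if length is not None:
        return Fingerprint.from_hex(text, length)
    raise ParseError(f"cannot decode fingerprint {text[:20]!r}...")


def encode_fingerprint(fp: Fingerprint, codec: str = "bits") -> str:
    if codec == "bits":
        return fp.to_bitstring()
    if codec == "hex":
        return f"hex:{len(fp)}:{fp.to_hex()}"
    raise ValueError(f"unknown fingerprint codec {codec!r}")


# --------------------------------------------------------------------------
# JSON
# --------------------------------------------------------------------------

def _study_to_dict(s: DraizeStudy) -> dict:
    d: dict = {"study_num": s.study_num}
    for ep in ("cornea", "iris", "conjunctivae", "chemosis"):
        val = getattr(s, ep)
        if val is not None:
            d[ep] = val
    if s.reversibility_days:
        d["reversibility_days"] = dict(s.reversibility_days)
    if s.verdict_text:
        d["verdict_text"] = s.verdict_text
    if s.reliability is not None:
        d["reliability"] = s.reliability
    d["guideline"] = s.guideline.value
    return d


def _study_from_dict(d: dict, where: str) -> DraizeStudy:
    try:
        rev = {
            ep: (days if days == NOT_REVERSED else int(days))
            for ep, days in d.get("reversibility_days", {}).items()
        }
        return DraizeStudy(
            study_num=int(d["study_num"]),
            cornea=_opt_float(d.get("cornea")),
            iris=_opt_float(d.get("iris")),
            conjunctivae=_opt_float(d.get("conjunctivae")),
            chemosis=_opt_float(d.get("chemosis")),
            reversibility_days=rev,
            verdict_text=d.get("verdict_text", ""),
            reliability=(int(d["reliability"]) if d.get("reliability") is not None
                         else None),
            guideline=Guideline(d.get("guideline", "TG405_INVIVO")),
        )
    except (KeyError, ValueError, TypeError) as exc:
        raise ParseError(f"{where}: malformed study: {exc}") from exc


def _opt_float(v):
    return None if v is None else float(v)


def _record_to_dict(r: SubstanceRecord) -> dict:
    d: dict = {"id": r.id}
    if r.dossier_category is not IrritationCategory.UNKNOWN:
        d["dossier_category"] = r.dossier_category.value
    if r.hazards:
        d["hazards"] = {code: st.value for code, st in sorted(r.hazards.items())}
    if r.fingerprint is not None:
        d["fingerprint"] = {"bits": r.fingerprint.to_bitstring()}
    d["studies"] = [_study_to_dict(s) for s in r.studies]
    return d


def _record_from_dict(d: dict, where: str) -> SubstanceRecord:
    if "id" not in d:
        raise ParseError(f"{where}: record missing 'id'")
    rid = str(d["id"])
    fp = None
    fpd = d.get("fingerprint")
    if fpd is not None:
        try:
            if "bits" in fpd:
                fp = Fingerprint.from_bitstring(fpd["bits"])
            elif "hex" in fpd:
                fp = Fingerprint.from_hex(fpd["hex"], int(fpd["length"]))
            else:
                raise ValueError("fingerprint needs 'bits' or 'hex'+'length'")
        except (ValueError, KeyError) as exc:
            raise ParseError(f"{where} ({rid}): bad fingerprint: {exc}") from exc
    try:
        hazards = {code: HazardStatus(st) for code, st in d.get("hazards", {}).items()}
        cat = IrritationCategory(d.get("dossier_category", "UNKNOWN"))
    except ValueError as exc:
        raise ParseError(f"{where} ({rid}): {exc}") from exc
    studies = [
        _study_from_dict(sd, f"{where} ({rid}) study {i}")
        for i, sd in enumerate(d.get("studies", []))
    ]
    return SubstanceRecord(id=rid, studies=studies, hazards=hazards,
                           fingerprint=fp, dossier_category=cat)


# --------------------------------------------------------------------------
# CSV
# --------------------------------------------------------------------------

def _encode_hazards(hazards: dict[str, HazardStatus]) -> str:
    # UNKNOWN entries are never stored; absence restores them on read.
    marks = {HazardStatus.POSITIVE: "+", HazardStatus.NEGATIVE: "-"}
    return ";".join(f"{code}:{marks[st]}" for code, st in sorted(hazards.items()))


def _decode_hazards(text: str, where: str) -> dict[str, HazardStatus]:
    if not text:
        return {}
    out: dict[str, HazardStatus] = {}
    for item in text.split(";"):
        try:
            code, mark = item.split(":")
        except ValueError as exc:
            raise ParseError(f"{where}: bad hazard entry {item!r}") from exc
        if mark == "+":
            out[code] = HazardStatus.POSITIVE
        elif mark == "-":
            out[code] = HazardStatus.NEGATIVE
        else:
            raise ParseError(f"{where}: hazard mark must be + or -, got {mark!r}")
    return out


def _records_to_csv_rows(records: Sequence[SubstanceRecord]) -> Iterable[list]:
    yield _CSV_COLUMNS
    for r in records:
        cat = ("" if r.dossier_category is IrritationCategory.UNKNOWN
               else r.dossier_category.value)
        fp = "" if r.fingerprint is None else encode_fingerprint(r.fingerprint)
        yield (["substance", r.id, cat, _encode_hazards(r.hazards), fp]
               + [""] * 12)
        for s in r.studies:
            row = ["study", r.id, "", "", "", s.study_num]
            for ep in ("cornea", "iris", "conjunctivae", "chemosis"):
                v = getattr(s, ep)
                row.append("" if v is None else repr(v))
            for ep in ("cornea", "iris", "conjunctivae", "chemosis"):
                d = s.reversibility_days.get(ep)
                row.append("" if d is None else str(d))
            row += [s.verdict_text,
                    "" if s.reliability is None else str(s.reliability),
                    s.guideline.value]
            yield row


def _records_from_csv(path: Path) -> list[SubstanceRecord]:
    records: dict[str, SubstanceRecord] = {}
    order: list[str] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            return []
        if header != _CSV_COLUMNS:
            raise ParseError(f"{path.name}: unexpected CSV header")
        for lineno, row in enumerate(reader, start=2):
            where = f"{path.name}:{lineno}"
            if len(row) != len(_CSV_COLUMNS):
                raise ParseError(f"{where}: expected {len(_CSV_COLUMNS)} fields")
            d = dict(zip(_CSV_COLUMNS, row))
            rid = d["id"]
            if d["row_type"] == "substance":
                fp = (decode_fingerprint(d["fingerprint"])
                      if d["fingerprint"] else None)
                cat = (IrritationCategory(d["dossier_category"])
                       if d["dossier_category"] else IrritationCategory.UNKNOWN)
                rec = SubstanceRecord(
                    id=rid, hazards=_decode_hazards(d["hazards"], where),
                    fingerprint=fp, dossier_category=cat)
                if rid not in records:
                    order.append(rid)
                    records[rid] = rec
                else:
                    raise ParseError(f"{where}: duplicate substance row for {rid!r}")
            elif d["row_type"] == "study":
                if rid not in records:
                    raise ParseError(f"{where}: study row before substance row "
                                     f"for {rid!r}")
                rev: dict[str, object] = {}
                for ep in ("cornea", "iris", "conjunctivae", "chemosis"):
                    val = d[f"rev_{ep}"]
                    if val:
                        rev[ep] = val if val == NOT_REVERSED else int(val)
                try:
                    study = DraizeStudy(
                        study_num=int(d["study_num"]),
                        cornea=_opt_float(d["cornea"] or None),
                        iris=_opt_float(d["iris"] or None),
                        conjunctivae=_opt_float(d["conjunctivae"] or None),
                        chemosis=_opt_float(d["chemosis"] or None),
                        reversibility_days=rev,
                        verdict_text=d["verdict_text"],
                        reliability=int(d["reliability"]) if d["reliability"] else None,
                        guideline=Guideline(d["guideline"]),
                    )
                except (ValueError, TypeError) as exc:
                    raise ParseError(f"{where}: {exc}") from exc
                records[rid].studies.append(study)
            else:
                raise ParseError(f"{where}: row_type must be 'substance' or "
                                 f"'study', got {d['row_type']!r}")
    return [records[rid] for rid in order]


# --------------------------------------------------------------------------
# public API
# --------------------------------------------------------------------------

def read_collection_with_report(
    path: str | Path,
    format: Optional[str] = None,
    strict: bool = False,
) -> tuple[list[SubstanceRecord], ValidationReport]:
    """Read a collection and return (records, validation report).

    Records with fatal violations (including duplicate ids) are excluded
    from the returned list and recorded in the report.  Under ``strict``,
    out-of-range endpoint scores are fatal rather than warnings.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if path.stat().st_size == 0:
        return [], ValidationReport()
    if fmt == "json":
        try:
            with open(path, encoding="utf-8") as fh:
                doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ParseError(f"{path.name}: invalid JSON at line {exc.lineno}: "
                             f"{exc.msg}") from exc
        if not isinstance(doc, dict) or "substances" not in doc:
            raise ParseError(f"{path.name}: not a {FORMAT_NAME} document")
        raw = [
            _record_from_dict(rd, f"{path.name} record {i}")
            for i, rd in enumerate(doc["substances"])
        ]
    else:
        raw = _records_from_csv(path)

    report = ValidationReport()
    seen: set[str] = set()
    records: list[SubstanceRecord] = []
    for rec in raw:
        violations = validate_record(rec, strict=strict)
        if rec.id in seen:
            violations.append(Violation(rec.id, "id", "duplicate substance id",
                                        fatal=True))
        seen.add(rec.id)
        report.extend(violations)
        if any(v.fatal for v in violations):
            report.excluded_ids.append(rec.id)
            log.warning("excluding record %s: %d fatal violation(s)",
                        rec.id, sum(v.fatal for v in violations))
        else:
            records.append(rec)
    return records, report


def violations_warnings(report: ValidationReport) -> list[Violation]:
    return [v for v in report.violations if not v.fatal]


def read_collection(path: str | Path, format: Optional[str] = None,
                    strict: bool = False) -> list[SubstanceRecord]:
    records, _ = read_collection_with_report(path, format=format, strict=strict)
    return records


def write_collection(records: Sequence[SubstanceRecord], path: str | Path,
                     format: Optional[str] = None) -> None:
    """Write a collection; ``read_collection`` restores it field-for-field."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "json":
        doc = {
            "format": FORMAT_NAME,
            "version": FORMAT_VERSION,
            "substances": [_record_to_dict(r) for r in records],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=1)
            fh.write("\n")
    else:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            for row in _records_to_csv_rows(records):
                writer.writerow(row)


def filter_eye_studies(
    records: Sequence[SubstanceRecord],
    require_reliability: bool = True,
    guidelines: frozenset = EYE_GUIDELINES,
) -> list[SubstanceRecord]:
    """Apply the study-inclusion filter used throughout the analyses.

    Keeps studies whose guideline is one of the recognized eye-test
    guidelines and, when ``require_reliability`` is set, whose Klimisch
    reliability score is 1 or 2.  Substances are never dropped: a
    substance whose studies are all filtered out is returned with an
    empty study list so it still participates in hazard-only analyses.
    """
    out: list[SubstanceRecord] = []
    for rec in records:
        kept = [
            s for s in rec.studies
            if s.guideline in guidelines
            and (not require_reliability or s.reliability in (1, 2))
        ]
        out.append(SubstanceRecord(
            id=rec.id, studies=kept, hazards=dict(rec.hazards),
            fingerprint=rec.fingerprint, dossier_category=rec.dossier_category))
    return out
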