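"""Predicting Draize eye outcomes from other GHS hazard classifications.

A substance is labeled "irritant" if positive for any of H318, H319 or
H320 and "non-irritant" otherwise.  Single hazards are screened for
positive/negative predictive value against that label, and all
3-hazard combinations are searched exhaustively: for every triplet, the
substances with definite values for all three hazards form a dataset on
which an information-gain decision tree is fitted and scored.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd

from .model import HazardStatus, SubstanceRecord
from .tree import TreeNode, fit_tree, predict

__all__ = [
    "IRRITANT",
    "NON_IRRITANT_LABEL",
    "EYE_HAZARD_CODES",
    "BinaryMetrics",
    "HazardScreenRow",
    "TripletResult",
    "irritant_label",
    "screen_single_hazards",
    "enumerate_triplets",
    "triplet_count",
    "triplet_search",
    "tree_truth_table",
    "describe_truth_table",
]

log = logging.getLogger(__name__)

#: The three GHS eye hazard statements defining the irritant label.
EYE_HAZARD_CODES = ("H318", "H319", "H320")

IRRITANT = "IRRITANT"
NON_IRRITANT_LABEL = "NON_IRRITANT"
UNKNOWN_LABEL = "UNKNOWN"

#: Hazard-statement text for codes that commonly appear in screens.
HAZARD_DESCRIPTIONS = {
    "H290": "May be corrosive to metals",
    "H301": "Toxic if swallowed",
    "H302": "Harmful if swallowed",
    "H311": "Toxic in contact with skin",
    "H312": "Harmful in contact with skin",
    "H314": "Causes severe skin burns and eye damage",
    "H315": "Causes skin irritation",
    "H317": "May cause an allergic skin reaction",
    "H330": "Fatal if inhaled",
    "H331": "Toxic if inhaled",
    "H332": "Harmful if inhaled",
    "H334": "May cause allergy or asthma symptoms if inhaled",
    "H335": "May cause respiratory irritation",
    "H336": "May cause drowsiness or dizziness",
    "H341": "Suspected of causing genetic defects",
    "H412": "Harmful to aquatic life with long lasting effects",
}


@dataclass
class BinaryMetrics:
    """Confusion counts and the derived predictive-value metrics.

    A ratio whose denominator is zero is left ``None`` and its name
    recorded in ``undefined`` -- never silently reported as 0.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    ppv: Optional[float] = None
    npv: Optional[float] = None
    sensitivity: Optional[float] = None
    specificity: Optional[float] = None
    bac: Optional[float] = None
    undefined: list[str] = field(default_factory=list)

    @classmethod
    def from_counts(cls, tp: int, fp: int, tn: int, fn: int) -> "BinaryMetrics":
        m = cls(tp=tp, fp=fp, tn=tn, fn=fn)
        ratios = {
            "ppv": (tp, tp + fp),
            "npv": (tn, tn + fn),
            "sensitivity": (tp, tp + fn),
            "specificity": (tn, tn + fp),
        }
        for name, (num, den) in ratios.items():
            if den > 0:
                setattr(m, name, num / den)
            else:
                m.undefined.append(name)
        if m.sensitivity is not None and m.specificity is not None:
            m.bac = (m.sensitivity + m.specificity) / 2.0
        else:
            m.undefined.append("bac")
        return m

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class HazardScreenRow:
    code: str
    metrics: BinaryMetrics
    total: int
    description: str = ""


def irritant_label(record: SubstanceRecord, strict: bool = False) -> str:
    """Binary eye-irritant label from the H318/H319/H320 statements.

    Any positive among the three gives IRRITANT; everything else is
    NON_IRRITANT ("otherwise"), which deliberately treats missing
    classification as negative -- the operational choice this screening
    design rests on, with its known caveat that unclassified substances
    may simply be unassessed.  Under ``strict``, a substance whose three
    eye statements are all UNKNOWN returns UNKNOWN instead.
    """
    statuses = [record.hazard_status(c) for c in EYE_HAZARD_CODES]
    if HazardStatus.POSITIVE in statuses:
        return IRRITANT
    if strict and all(s is HazardStatus.UNKNOWN for s in statuses):
        return UNKNOWN_LABEL
    return NON_IRRITANT_LABEL


def screen_single_hazards(
    records: Sequence[SubstanceRecord],
    min_pos: int = 100,
    min_neg: int = 100,
    strict_label: bool = False,
    descriptions: Optional[dict] = None,
) -> list[HazardScreenRow]:
    """Predictive-value screen of every individual hazard.

    For each hazard code appearing in the collection, the dataset is
    restricted to substances with a definite (positive/negative) value
    for both the hazard and the irritant label; hazards making fewer
    than ``min_pos`` positive predictions (TP+FP) or ``min_neg``
    negative predictions (TN+FN) are omitted.  Rows are sorted by code.
    """
    descriptions = {**HAZARD_DESCRIPTIONS, **(descriptions or {})}
    labels = [irritant_label(r, strict=strict_label) for r in records]
    codes = sorted({
        code for r in records for code in r.hazards
        if code not in EYE_HAZARD_CODES
    })
    rows: list[HazardScreenRow] = []
    for code in codes:
        tp = fp = tn = fn = 0
        for record, label in zip(records, labels):
            status = record.hazard_status(code)
            if status is HazardStatus.UNKNOWN or label == UNKNOWN_LABEL:
                continue
            if status is HazardStatus.POSITIVE:
                if label == IRRITANT:
                    tp += 1
                else:
                    fp += 1
            else:
                if label == IRRITANT:
                    fn += 1
                else:
                    tn += 1
        if tp + fp < min_pos or tn + fn < min_neg:
            continue
        metrics = BinaryMetrics.from_counts(tp, fp, tn, fn)
        rows.append(HazardScreenRow(code=code, metrics=metrics,
                                    total=metrics.total,
                                    description=descriptions.get(code, "")))
    return rows


def screen_to_frame(rows: Sequence[HazardScreenRow]) -> pd.DataFrame:
    return pd.DataFrame([
        {"Hazard": r.code, "PPV": r.metrics.ppv, "TP+FP": r.metrics.tp + r.metrics.fp,
         "NPV": r.metrics.npv, "TN+FN": r.metrics.tn + r.metrics.fn,
         "BAC": r.metrics.bac, "Total": r.total, "Description": r.description}
        for r in rows
    ])


def enumerate_triplets(hazard_codes: Sequence[str]) -> Iterator[tuple[str, str, str]]:
    """Every unordered 3-subset of the codes, exactly once, sorted."""
    codes = sorted(set(hazard_codes))
    if len(codes) < 3:
        raise ValueError(f"need at least 3 hazard codes, got {len(codes)}")
    return itertools.combinations(codes, 3)


def triplet_count(n: int) -> int:
    """C(n, 3) = n(n-1)(n-2)/6."""
    return math.comb(n, 3)


@dataclass
class TripletResult:
    codes: tuple[str, str, str]
    tree: TreeNode
    metrics: BinaryMetrics
    truth_table: tuple[str, ...]
    n_substances: int

    @property
    def rule(self) -> str:
        return describe_truth_table(self.codes, self.truth_table)


def _status_matrix(records: Sequence[SubstanceRecord],
                   codes: Sequence[str]) -> np.ndarray:
    """n_substances x n_codes matrix with 1=positive, 0=negative, -1=unknown."""
    value = {HazardStatus.POSITIVE: 1, HazardStatus.NEGATIVE: 0,
             HazardStatus.UNKNOWN: -1}
    return np.array([[value[r.hazard_status(c)] for c in codes]
                     for r in records], dtype=np.int8)


def tree_truth_table(tree: TreeNode, codes: Sequence[str]) -> tuple[str, ...]:
    """Canonical truth table of a tree over binary (0/1) attributes.

    Entry ``i`` is the prediction for the assignment whose bits, most
    significant first, follow the order of ``codes``.  Cells never seen
    in training are answered by majority descent.
    """
    k = len(codes)
    out = []
    for cell in range(2 ** k):
        bits = [(cell >> (k - 1 - j)) & 1 for j in range(k)]
        row = dict(zip(codes, (float(b) for b in bits)))
        out.append(predict(tree, row, missing="majority"))
    return tuple(out)


def describe_truth_table(codes: Sequence[str],
                         table: Sequence[str]) -> str:
    """Human-readable boolean rule equivalent to a 3-attribute truth table.

    Recognizes constants and OR/AND combinations of positive literals;
    anything else is rendered as an explicit minterm disjunction.
    """
    k = len(codes)
    pos = [i for i, lab in enumerate(table) if lab == IRRITANT]
    if not pos:
        return "never irritant"
    if len(pos) == 2 ** k:
        return "always irritant"

    def cell_bits(cell: int) -> tuple[int, ...]:
        return tuple((cell >> (k - 1 - j)) & 1 for j in range(k))

    # OR over every non-empty subset of literals
    for r in range(1, k + 1):
        for subset in itertools.combinations(range(k), r):
            if all((any(cell_bits(c)[j] for j in subset)) == (lab == IRRITANT)
                   for c, lab in enumerate(table)):
                return " or ".join(codes[j] for j in subset)
    for r in range(2, k + 1):
        for subset in itertools.combinations(range(k), r):
            if all((all(cell_bits(c)[j] for j in subset)) == (lab == IRRITANT)
                   for c, lab in enumerate(table)):
                return " and ".join(codes[j] for j in subset)
    minterms = []
    for c in pos:
        bits = cell_bits(c)
        minterms.append("(" + " and ".join(
            codes[j] if bits[j] else f"not {codes[j]}" for j in range(k)) + ")")
    return " or ".join(minterms)


def triplet_search(
    records: Sequence[SubstanceRecord],
    hazard_codes: Sequence[str],
    ranking: str = "bac",
    top_k: int = 10,
    min_leaf: float = 1.0,
    strict_label: bool = False,
    min_substances: int = 1,
) -> list[TripletResult]:
    """Exhaustive decision-tree search over all 3-hazard combinations.

    For every triplet, the dataset is the set of substances with
    definite values for all three hazards; a tree is fitted on the three
    binary attributes against the irritant label and its training
    metrics computed.  Results are ranked by ``ranking`` (``bac``,
    ``ppv`` or ``npv``) descending, ties broken by triplet order.

    The per-triplet fit works on the 8-cell contingency table (each
    attribute assignment with its label counts as a weighted row), which
    is exactly equivalent to fitting on the expanded dataset.
    """
    if ranking not in ("bac", "ppv", "npv"):
        raise ValueError("ranking must be 'bac', 'ppv' or 'npv'")
    codes = sorted(set(hazard_codes))
    S = _status_matrix(records, codes)
    labels = np.array([irritant_label(r, strict=strict_label) for r in records],
                      dtype=object)
    usable = labels != UNKNOWN_LABEL
    y_pos = labels == IRRITANT

    cell_bits16 = np.array(
        [[float((cell >> 2) & 1), float((cell >> 1) & 1), float(cell & 1)]
         for cell in range(8)] * 2)
    ys16 = np.array([IRRITANT] * 8 + [NON_IRRITANT_LABEL] * 8, dtype=object)

    results: list[TripletResult] = []
    n_searched = 0
    for trip in enumerate_triplets(codes):
        n_searched += 1
        ia, ib, ic = (codes.index(c) for c in trip)
        sub = S[:, (ia, ib, ic)]
        mask = usable & (sub >= 0).all(axis=1)
        n_sub = int(mask.sum())
        if n_sub < min_substances:
            log.info("triplet %s skipped: %d usable substances", trip, n_sub)
            continue
        cells = sub[mask] @ np.array([4, 2, 1])
        pos = y_pos[mask]
        pos_counts = np.bincount(cells[pos], minlength=8)
        neg_counts = np.bincount(cells[~pos], minlength=8)
        weights = np.concatenate([pos_counts, neg_counts]).astype(float)
        keep = weights > 0
        frame = pd.DataFrame(
            {"a": cell_bits16[keep, 0], "b": cell_bits16[keep, 1],
             "c": cell_bits16[keep, 2]})
        tree = fit_tree(frame, ys16[keep],
                        attributes=["a", "b", "c"], min_leaf=min_leaf,
                        sample_weight=weights[keep])
        tree = _rename_attributes(tree, dict(zip(["a", "b", "c"], trip)))
        table = tree_truth_table(tree, trip)
        tp = int(sum(pos_counts[c] for c in range(8) if table[c] == IRRITANT))
        fn = int(sum(pos_counts[c] for c in range(8) if table[c] != IRRITANT))
        fp = int(sum(neg_counts[c] for c in range(8) if table[c] == IRRITANT))
        tn = int(sum(neg_counts[c] for c in range(8) if table[c] != IRRITANT))
        metrics = BinaryMetrics.from_counts(tp, fp, tn, fn)
        results.append(TripletResult(codes=trip, tree=tree, metrics=metrics,
                                     truth_table=table, n_substances=n_sub))
    expected = triplet_count(len(codes))
    if n_searched != expected:
        raise AssertionError(
            f"triplet audit failed: searched {n_searched}, expected {expected}")

    def key(res: TripletResult):
        val = getattr(res.metrics, ranking)
        return (-(val if val is not None else -1.0), res.codes)

    results.sort(key=key)
    return results[:top_k]


def _rename_attributes(node: TreeNode, mapping: dict[str, str]) -> TreeNode:
    if node.attribute in mapping:
        node.attribute = mapping[node.attribute]
    for child in node.branches.values():
        _rename_attributes(child, mapping)
    return node
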