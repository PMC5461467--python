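"""Test-retest reproducibility of Draize eye-irritation categories.

Frequent retesting of the same substance makes it possible to ask: what
is the probability that a Draize test outcome agrees with another Draize
test outcome for the same chemical?  The answer is a 4x4 matrix of
conditional probabilities P(next = j | prior = i), estimated from all
substances with at least two studies whose verdicts map to a category.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import SEVERITY_ORDER, IrritationCategory, SubstanceRecord
from .normalize import SynonymTable, normalize_verdict

__all__ = ["ConditionalMatrix", "conditional_matrix", "agreement_summary"]

#: Row/column order of the matrix: Type 1, Type 2A, Type 2B, non-irritant.
CATEGORIES: tuple[IrritationCategory, ...] = SEVERITY_ORDER

PAIR_MODES = ("all_ordered", "unordered", "consecutive")


@dataclass
class ConditionalMatrix:
    """Category-transition probabilities between repeat tests.

    ``probs[i, j]`` estimates P(next test = categories[j] | prior test =
    categories[i]); rows with no pairs are NaN.  ``totals[i]`` counts the
    contributing substances with at least one study of category i (a
    substance can appear in several rows, so totals may sum to more than
    the number of substances).  ``pair_counts`` holds the raw pair
    counts the probabilities were computed from.
    """

    categories: tuple[IrritationCategory, ...]
    probs: np.ndarray
    totals: np.ndarray
    pair_counts: np.ndarray
    n_substances: int
    pair_mode: str

    def prob(self, prior: IrritationCategory,
             outcome: IrritationCategory) -> float:
        return float(self.probs[self.categories.index(prior),
                                self.categories.index(outcome)])

    def self_agreement(self, category: IrritationCategory) -> float:
        return self.prob(category, category)

    def to_frame(self, percent: bool = True, decimals: int = 1) -> pd.DataFrame:
        """Row-conditional table: one row per prior category plus Total.

        With ``percent`` (default) probabilities are formatted as
        percentages rounded to one decimal, the customary presentation
        for this matrix.
        """
        labels = [c.value for c in self.categories]
        vals = self.probs * 100.0 if percent else self.probs
        if decimals is not None:
            vals = np.round(vals, decimals)
        frame = pd.DataFrame(vals, index=labels, columns=labels)
        frame.index.name = "prior"
        frame["Total"] = self.totals
        return frame


def _study_categories(record: SubstanceRecord,
                      table: Optional[SynonymTable]) -> list[IrritationCategory]:
    cats = [normalize_verdict(s.verdict_text, table) for s in record.studies]
    return [c for c in cats if c is not IrritationCategory.UNKNOWN]


def conditional_matrix(
    records: Sequence[SubstanceRecord],
    table: Optional[SynonymTable] = None,
    pair_mode: str = "all_ordered",
) -> ConditionalMatrix:
    """Estimate the repeat-test conditional probability matrix.

    Only substances with >= 2 studies having mappable categories
    contribute.  ``pair_mode`` selects the counting unit:

    * ``all_ordered`` (default) -- every ordered pair (s, t), s != t, of
      mapped studies within a substance; a substance with n mapped
      studies contributes n*(n-1) pairs.  This makes the pair-count
      matrix symmetric by construction and every row well-defined.
    * ``unordered`` -- each unordered pair once (row-conditioning then
      reads the pair's first-listed category as prior).
    * ``consecutive`` -- directed transitions between consecutive
      studies in study_num order; the estimator of choice when repeat
      outcomes are modeled as a Markov chain, whose transition kernel it
      estimates consistently.
    """
    if pair_mode not in PAIR_MODES:
        raise ValueError(f"pair_mode must be one of {PAIR_MODES}")
    k = len(CATEGORIES)
    idx = {c: i for i, c in enumerate(CATEGORIES)}
    pair_counts = np.zeros((k, k), dtype=np.int64)
    totals = np.zeros(k, dtype=np.int64)
    n_contributing = 0
    for record in records:
        cats = _study_categories(record, table)
        if len(cats) < 2:
            continue
        n_contributing += 1
        for c in set(cats):
            totals[idx[c]] += 1
        if pair_mode == "consecutive":
            for a, b in zip(cats, cats[1:]):
                pair_counts[idx[a], idx[b]] += 1
        else:
            for i, a in enumerate(cats):
                start = i + 1 if pair_mode == "unordered" else 0
                for j in range(start, len(cats)):
                    if j == i:
                        continue
                    pair_counts[idx[a], idx[cats[j]]] += 1
    row_sums = pair_counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = pair_counts / row_sums[:, None]
    probs[row_sums == 0] = np.nan
    return ConditionalMatrix(
        categories=CATEGORIES, probs=probs, totals=totals,
        pair_counts=pair_counts, n_substances=n_contributing,
        pair_mode=pair_mode)


def agreement_summary(matrix: ConditionalMatrix) -> pd.DataFrame:
    """Per-category reproducibility summary.

    One row per prior category with its self-agreement (probability the
    repeat test returns the same category), the most likely repeat
    outcome, and the probability of a flip all the way across the scale
    (severe prior -> non-irritant outcome, and vice versa).
    """
    rows = []
    non = IrritationCategory.NON_IRRITANT
    t1 = IrritationCategory.TYPE1
    for i, cat in enumerate(matrix.categories):
        row = matrix.probs[i]
        if np.isnan(row).all():
            rows.append({"prior": cat.value, "self_agreement": np.nan,
                         "most_likely_next": None, "p_non_irritant": np.nan,
                         "p_type1": np.nan, "substances": int(matrix.totals[i])})
            continue
        rows.append({
            "prior": cat.value,
            "self_agreement": float(row[i]),
            "most_likely_next": matrix.categories[int(np.nanargmax(row))].value,
            "p_non_irritant": matrix.prob(cat, non),
            "p_type1": matrix.prob(cat, t1),
            "substances": int(matrix.totals[i]),
        })
    return pd.DataFrame(rows).set_index("prior")
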