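"""Per-substance Draize endpoint aggregation and GHS rulebook classification.

For each substance the four ocular endpoints (cornea, iris, conjunctivae,
chemosis) are summarized across all its studies into a mean and a maximum,
plus one reversibility feature taken from the study/endpoint pair with the
longest reversal period.  The rulebook then applies the UN GHS eye
criteria:

* Type 1 (serious damage): cornea >= 3, or iris > 1.5, or effects that
  persist beyond the 21-day observation window;
* Type 2 (irritant): cornea >= 1, or iris >= 1, or conjunctival
  redness >= 2, or chemosis >= 2, split into 2B when fully reversible
  within 7 days and 2A otherwise;
* non-irritant when no criterion is met.

All cut-offs are configurable through :class:`RuleThresholds`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .model import (
    ENDPOINTS,
    NOT_REVERSED,
    IrritationCategory,
    Reversibility,
    SubstanceRecord,
)

__all__ = [
    "EndpointFeatures",
    "RuleThresholds",
    "aggregate_features",
    "classify_rulebook",
    "bucket_reversal_days",
]


@dataclass
class EndpointFeatures:
    """The 9+1 feature vector for one substance.

    ``None`` marks a feature whose endpoint was never scored in any study
    (possible under the relaxed, any-available-data regime).
    ``draize_ghs_category`` is the category implied by the dossier's
    H318/H319/H320 classification-and-labeling value, when present.
    """

    substance_id: str
    cornea_mean: Optional[float] = None
    cornea_max: Optional[float] = None
    iris_mean: Optional[float] = None
    iris_max: Optional[float] = None
    conjunctivae_mean: Optional[float] = None
    conjunctivae_max: Optional[float] = None
    chemosis_mean: Optional[float] = None
    chemosis_max: Optional[float] = None
    reversibility: Optional[Reversibility] = None
    draize_ghs_category: IrritationCategory = IrritationCategory.UNKNOWN

    @property
    def complete(self) -> bool:
        """True when every endpoint feature and reversibility is present."""
        return (
            all(getattr(self, f"{ep}_mean") is not None for ep in ENDPOINTS)
            and self.reversibility is not None
        )

    def missing(self) -> list[str]:
        out = [f"{ep}_{stat}" for ep in ENDPOINTS for stat in ("mean", "max")
               if getattr(self, f"{ep}_{stat}") is None]
        if self.reversibility is None:
            out.append("reversibility")
        return out


@dataclass
class RuleThresholds:
    """Numeric cut-offs of the GHS eye-classification rules.

    Defaults follow UN GHS: cornea >= 3.0 or iris > 1.5 (or 21-day
    persistence) for category 1; cornea >= 1.0, iris >= 1.0,
    conjunctival redness >= 2.0 or chemosis >= 2.0 for category 2.  The
    7- and 21-day windows bound the reversal buckets.
    """

    cornea_cat1: float = 3.0
    iris_cat1: float = 1.5
    cornea_cat2: float = 1.0
    iris_cat2: float = 1.0
    conjunctivae_cat2: float = 2.0
    chemosis_cat2: float = 2.0
    reversal_window_short: int = 7
    reversal_window_long: int = 21

    def __post_init__(self) -> None:
        if self.cornea_cat1 < self.cornea_cat2 or self.iris_cat1 < self.iris_cat2:
            raise ValueError("category-1 thresholds must be >= category-2")
        if not 0 < self.reversal_window_short < self.reversal_window_long:
            raise ValueError("reversal windows must satisfy 0 < short < long")


def bucket_reversal_days(days: object,
                         thresholds: Optional[RuleThresholds] = None) -> Reversibility:
    """Bucket one reversal observation into the three GHS windows."""
    t = thresholds or RuleThresholds()
    if days == NOT_REVERSED:
        return Reversibility.IRREVERSIBLE
    if not isinstance(days, int):
        raise TypeError(f"reversal days must be int or NOT_REVERSED, got {days!r}")
    if days > t.reversal_window_long:
        return Reversibility.IRREVERSIBLE
    if days > t.reversal_window_short:
        return Reversibility.REVERSED_21D
    return Reversibility.REVERSED_7D


_REV_SEVERITY = {
    Reversibility.REVERSED_7D: 0,
    Reversibility.REVERSED_21D: 1,
    Reversibility.IRREVERSIBLE: 2,
}


def aggregate_features(record: SubstanceRecord,
                       thresholds: Optional[RuleThresholds] = None) -> EndpointFeatures:
    """Mean/max of every endpoint across all studies, plus reversibility.

    The reversibility feature is the bucket of the single longest
    reversal period over all endpoint/study pairs; a substance with no
    reversal observation at all gets ``None``.  Raises for a substance
    with zero studies.
    """
    if not record.studies:
        raise ValueError(f"substance {record.id!r} has no studies to aggregate")
    feats = EndpointFeatures(substance_id=record.id,
                             draize_ghs_category=record.dossier_category)
    for ep in ENDPOINTS:
        scores = [s.score(ep) for s in record.studies if s.score(ep) is not None]
        if scores:
            setattr(feats, f"{ep}_mean", sum(scores) / len(scores))
            setattr(feats, f"{ep}_max", max(scores))
    buckets = [
        bucket_reversal_days(days, thresholds)
        for s in record.studies
        for days in s.reversibility_days.values()
    ]
    if buckets:
        feats.reversibility = max(buckets, key=_REV_SEVERITY.__getitem__)
    return feats


def classify_rulebook(features: EndpointFeatures,
                      thresholds: Optional[RuleThresholds] = None,
                      severity_stat: str = "max") -> IrritationCategory:
    """Classify one substance's features by the GHS rulebook.

    ``severity_stat`` selects whether the severity tests read the per-
    endpoint maximum (default, protective) or the mean.  The rule set is
    order-independent: category 1 criteria are checked first, then any
    category 2 criterion, split by reversibility, else non-irritant.
    Raises when a required feature is missing, naming the missing ones.
    """
    if severity_stat not in ("max", "mean"):
        raise ValueError("severity_stat must be 'max' or 'mean'")
    t = thresholds or RuleThresholds()

    def sel(ep: str) -> Optional[float]:
        return getattr(features, f"{ep}_{severity_stat}")

    missing = [f"{ep}_{severity_stat}" for ep in ENDPOINTS if sel(ep) is None]
    if features.reversibility is None:
        missing.append("reversibility")
    if missing:
        raise ValueError(
            f"substance {features.substance_id!r}: cannot classify, missing "
            f"feature(s): {', '.join(missing)}")

    if (sel("cornea") >= t.cornea_cat1
            or sel("iris") > t.iris_cat1
            or features.reversibility is Reversibility.IRREVERSIBLE):
        return IrritationCategory.TYPE1
    if (sel("cornea") >= t.cornea_cat2
            or sel("iris") >= t.iris_cat2
            or sel("conjunctivae") >= t.conjunctivae_cat2
            or sel("chemosis") >= t.chemosis_cat2):
        if features.reversibility is Reversibility.REVERSED_7D:
            return IrritationCategory.TYPE2B
        return IrritationCategory.TYPE2A
    return IrritationCategory.NON_IRRITANT
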