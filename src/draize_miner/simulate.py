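"""Synthetic dossier collections with the statistical structure the
analyses assume.

The generator emulates, feature by feature, what a mined registration
corpus looks like: a long-tailed distribution of repeat Draize studies
per substance; per-category endpoint-score distributions ordered
Type 1 > 2A > 2B > non-irritant; a row-stochastic confusion kernel
governing how repeat tests disagree; hazard statements whose positivity
rates depend on irritant status; and clustered binary fingerprints built
from category-linked prototypes with independent bit flips.

Repeat-test outcomes are generated as a Markov chain over categories:
the first study reports the substance's latent category and each
subsequent study's category is drawn from the confusion kernel row of
the previous study's outcome.  Under this model the kernel is exactly
the consecutive-transition conditional matrix, so the reproducibility
estimator (``pair_mode="consecutive"``) recovers it consistently.
Setting the kernel to the identity makes every repeat identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .ghs import EndpointFeatures, RuleThresholds, classify_rulebook
from .model import (
    ENDPOINT_RANGES,
    ENDPOINTS,
    NOT_REVERSED,
    DraizeStudy,
    Fingerprint,
    Guideline,
    HazardStatus,
    IrritationCategory,
    Reversibility,
    SubstanceRecord,
)
from .normalize import CANONICAL_VERDICT

__all__ = [
    "GeneratorConfig",
    "ScoreParams",
    "HazardRates",
    "FingerprintModel",
    "DEFAULT_KERNEL",
    "DEFAULT_PREVALENCE",
    "DEFAULT_REPEAT_DISTRIBUTION",
    "DEFAULT_HAZARD_CODES",
    "generate",
    "make_rulebook_dataset",
]

CATS4 = (IrritationCategory.TYPE1, IrritationCategory.TYPE2A,
         IrritationCategory.TYPE2B, IrritationCategory.NON_IRRITANT)

#: Category prevalence: roughly one third of tested substances are eye
#: irritants, with reversible irritation (2A) the most common irritant
#: class and mild (2B) the rarest; the remainder are non-irritant.
DEFAULT_PREVALENCE: dict[IrritationCategory, float] = {
    IrritationCategory.TYPE1: 0.10,
    IrritationCategory.TYPE2A: 0.14,
    IrritationCategory.TYPE2B: 0.10,
    IrritationCategory.NON_IRRITANT: 0.66,
}

#: Repeat-test distribution: number of Draize studies per substance and
#: its probability.  The long tail (a few substances retested dozens of
#: times) mirrors the repeat structure of mined registration data.
DEFAULT_REPEAT_DISTRIBUTION: dict[int, float] = {
    k: v / 3679.0
    for k, v in {
        1: 2388, 2: 593, 3: 254, 4: 135, 5: 56, 6: 75, 7: 32, 8: 27,
        9: 1, 10: 2, 11: 2, 12: 2, 13: 38, 15: 2, 18: 1, 45: 69, 90: 2,
    }.items()
}

#: Confusion kernel: probability that a repeat test reports category j
#: (column) given a prior result of category i (row).  Rows/columns are
#: ordered Type 1, 2A, 2B, non-irritant.  Negative priors are the most
#: reproducible (~94%), severe irritants next (~73%); a severe prior
#: still carries a ~10% chance of a non-irritant repeat.  Rows are
#: normalized to sum exactly to 1.
_K = np.array([
    [0.730, 0.161, 0.004, 0.104],
    [0.042, 0.329, 0.035, 0.594],
    [0.002, 0.040, 0.155, 0.802],
    [0.011, 0.035, 0.015, 0.939],
])
DEFAULT_KERNEL: np.ndarray = _K / _K.sum(axis=1, keepdims=True)


@dataclass(frozen=True)
class ScoreParams:
    """Truncated-normal parameters for one endpoint in one category."""

    mean: float
    sd: float


#: Per-category, per-endpoint score models.  Means decrease from Type 1
#: to non-irritant on every endpoint, and each category's means are
#: consistent with the GHS rulebook (so a zero-noise draw classifies
#: back to its generating category).
DEFAULT_SCORE_MODEL: dict[IrritationCategory, dict[str, ScoreParams]] = {
    IrritationCategory.TYPE1: {
        "cornea": ScoreParams(3.0, 0.6), "iris": ScoreParams(1.2, 0.4),
        "conjunctivae": ScoreParams(2.8, 0.3), "chemosis": ScoreParams(2.8, 0.7),
    },
    IrritationCategory.TYPE2A: {
        "cornea": ScoreParams(1.5, 0.6), "iris": ScoreParams(0.8, 0.4),
        "conjunctivae": ScoreParams(2.2, 0.4), "chemosis": ScoreParams(2.0, 0.7),
    },
    IrritationCategory.TYPE2B: {
        "cornea": ScoreParams(0.5, 0.4), "iris": ScoreParams(0.3, 0.3),
        "conjunctivae": ScoreParams(2.0, 0.4), "chemosis": ScoreParams(1.5, 0.6),
    },
    IrritationCategory.NON_IRRITANT: {
        "cornea": ScoreParams(0.2, 0.3), "iris": ScoreParams(0.1, 0.2),
        "conjunctivae": ScoreParams(0.5, 0.4), "chemosis": ScoreParams(0.3, 0.4),
    },
}

#: Reversibility buckets per category.  Type 1 effects mostly persist
#: past the 21-day window; 2A reverses within 21 days, 2B within 7.
DEFAULT_REVERSIBILITY_MODEL: dict[IrritationCategory, dict[Reversibility, float]] = {
    IrritationCategory.TYPE1: {Reversibility.IRREVERSIBLE: 0.80,
                               Reversibility.REVERSED_21D: 0.20},
    IrritationCategory.TYPE2A: {Reversibility.REVERSED_21D: 0.85,
                                Reversibility.REVERSED_7D: 0.15},
    IrritationCategory.TYPE2B: {Reversibility.REVERSED_7D: 0.90,
                                Reversibility.REVERSED_21D: 0.10},
    IrritationCategory.NON_IRRITANT: {Reversibility.REVERSED_7D: 0.85,
                                      Reversibility.REVERSED_21D: 0.15},
}

#: Representative days for each reversibility bucket when materialized
#: into a study's per-endpoint reversal map.
_BUCKET_DAYS = {Reversibility.REVERSED_7D: 5,
                Reversibility.REVERSED_21D: 14,
                Reversibility.IRREVERSIBLE: NOT_REVERSED}


@dataclass(frozen=True)
class HazardRates:
    """Conditional positivity rates for one hazard statement.

    ``p_known`` is the probability the dossier reports a definite value
    at all; given known, positivity depends only on irritant status
    (conditional independence across hazards).
    """

    p_pos_irritant: float
    p_pos_non: float
    p_known: float = 0.8


def _default_hazard_model() -> dict[str, HazardRates]:
    physical = ["H200", "H201", "H202", "H203", "H204", "H205", "H206",
                "H207", "H208", "H220", "H221", "H222", "H223", "H224",
                "H225", "H226", "H228", "H229", "H230", "H231", "H232",
                "H240", "H241", "H242", "H250", "H251", "H252", "H260",
                "H261", "H270", "H271", "H272", "H280", "H281", "H290"]
    health = ["H300", "H301", "H302", "H303", "H304", "H305", "H310",
              "H311", "H312", "H314", "H315", "H317", "H330", "H331",
              "H332", "H334", "H335", "H336", "H340", "H341", "H350",
              "H351", "H360", "H361", "H362", "H370", "H371", "H372",
              "H373"]
    env = ["H400", "H410", "H411", "H412", "H413"]
    # systemic/local health hazards co-occur with eye irritation far more
    # than physical or environmental ones do
    informative = {
        "H301": HazardRates(0.08, 0.030), "H302": HazardRates(0.35, 0.080),
        "H311": HazardRates(0.07, 0.025), "H312": HazardRates(0.12, 0.020),
        "H314": HazardRates(0.30, 0.060), "H315": HazardRates(0.40, 0.080),
        "H317": HazardRates(0.25, 0.070), "H330": HazardRates(0.05, 0.020),
        "H331": HazardRates(0.10, 0.030), "H332": HazardRates(0.20, 0.080),
        "H334": HazardRates(0.06, 0.020), "H335": HazardRates(0.30, 0.050),
        "H341": HazardRates(0.05, 0.020), "H412": HazardRates(0.18, 0.100,
                                                              p_known=0.7),
        "H290": HazardRates(0.06, 0.010, p_known=0.6),
    }
    model: dict[str, HazardRates] = {}
    for code in physical:
        model[code] = informative.get(code, HazardRates(0.04, 0.03, p_known=0.6))
    for code in health:
        model[code] = informative.get(code, HazardRates(0.05, 0.04, p_known=0.8))
    for code in env:
        model[code] = informative.get(code, HazardRates(0.06, 0.05, p_known=0.7))
    assert len(model) == 69
    return model


#: The non-eye hazard statements carried by generated dossiers.  With
#: H318/H319/H320 (set from the substance's category) a collection
#: reports values for 72 GHS hazards.
DEFAULT_HAZARD_CODES: tuple[str, ...] = tuple(sorted(_default_hazard_model()))


@dataclass(frozen=True)
class FingerprintModel:
    """Category-linked prototype fingerprints with independent bit flips."""

    bit_length: int = 881
    density: float = 0.2
    flip_rate: float = 0.02
    n_prototypes: int = 4


@dataclass
class GeneratorConfig:
    """Everything that defines a synthetic dossier collection."""

    n_substances: int = 1000
    category_prevalence: dict[IrritationCategory, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCE))
    repeat_distribution: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_REPEAT_DISTRIBUTION))
    confusion_kernel: np.ndarray = field(
        default_factory=lambda: DEFAULT_KERNEL.copy())
    score_model: dict = field(default_factory=lambda: {
        c: dict(m) for c, m in DEFAULT_SCORE_MODEL.items()})
    reversibility_model: dict = field(default_factory=lambda: {
        c: dict(m) for c, m in DEFAULT_REVERSIBILITY_MODEL.items()})
    hazard_model: dict[str, HazardRates] = field(
        default_factory=_default_hazard_model)
    fingerprint_model: FingerprintModel = field(default_factory=FingerprintModel)
    p_readacross: float = 0.21  # fraction of TG 405 studies that are read-across
    reliability_probs: tuple[float, float, float] = (0.55, 0.40, 0.05)  # K1, K2, K3
    seed: int = 0

    def validate(self) -> None:
        if self.n_substances < 1:
            raise ValueError("n_substances must be >= 1")
        if abs(sum(self.category_prevalence.values()) - 1) > 1e-9:
            raise ValueError("category_prevalence must sum to 1")
        if set(self.category_prevalence) != set(CATS4):
            raise ValueError("category_prevalence must cover the 4 categories")
        rep = self.repeat_distribution
        if abs(sum(rep.values()) - 1) > 1e-9 or any(k < 1 for k in rep):
            raise ValueError("repeat_distribution must be a distribution "
                             "over counts >= 1")
        K = np.asarray(self.confusion_kernel, dtype=float)
        if K.shape != (4, 4) or not np.allclose(K.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("confusion_kernel must be 4x4 row-stochastic")
        if (K < 0).any():
            raise ValueError("confusion_kernel entries must be >= 0")
        for cat, model in self.score_model.items():
            for ep, params in model.items():
                lo, hi = ENDPOINT_RANGES[ep]
                if not lo <= params.mean <= hi or params.sd < 0:
                    raise ValueError(
                        f"score_model[{cat.value}][{ep}]: mean must lie in "
                        f"[{lo}, {hi}] and sd >= 0")
        for cat, model in self.reversibility_model.items():
            if abs(sum(model.values()) - 1) > 1e-9:
                raise ValueError(
                    f"reversibility_model[{cat.value}] must sum to 1")
        fm = self.fingerprint_model
        if not 0 <= fm.flip_rate < 0.5:
            raise ValueError("fingerprint flip_rate must lie in [0, 0.5)")
        if not 0 < fm.density < 1 or fm.bit_length < 1 or fm.n_prototypes < 1:
            raise ValueError("invalid fingerprint_model")

    # -- convenience variants ------------------------------------------
    def repeats_only(self) -> "GeneratorConfig":
        """Condition the repeat distribution on >= 2 studies.

        Single-study substances carry no information about the confusion
        kernel; a kernel-recovery experiment (the analog of filtering to
        substances with at least two Draize studies) uses this variant.
        """
        rep = {k: v for k, v in self.repeat_distribution.items() if k >= 2}
        total = sum(rep.values())
        return replace(self, repeat_distribution={k: v / total
                                                  for k, v in rep.items()})

    def zero_noise(self) -> "GeneratorConfig":
        """Degenerate configuration: identity kernel, sd-0 scores, and
        deterministic reversibility, so every repeat study is identical
        and the rulebook recovers the latent category exactly."""
        return replace(
            self,
            confusion_kernel=np.eye(4),
            score_model={c: {ep: ScoreParams(p.mean, 0.0)
                             for ep, p in m.items()}
                         for c, m in self.score_model.items()},
            reversibility_model={
                IrritationCategory.TYPE1: {Reversibility.IRREVERSIBLE: 1.0},
                IrritationCategory.TYPE2A: {Reversibility.REVERSED_21D: 1.0},
                IrritationCategory.TYPE2B: {Reversibility.REVERSED_7D: 1.0},
                IrritationCategory.NON_IRRITANT: {Reversibility.REVERSED_7D: 1.0},
            },
        )


def _substance_id(i: int) -> str:
    # EC-number-style identifier: three digit groups
    return f"{600 + i // 1000:03d}-{i % 1000:03d}-{i % 10:01d}"


def _draw_scores(rng: np.random.Generator, params: ScoreParams,
                 lo: float, hi: float, size: int) -> np.ndarray:
    if params.sd == 0:
        return np.full(size, np.clip(params.mean, lo, hi))
    a = (lo - params.mean) / params.sd
    b = (hi - params.mean) / params.sd
    draws = stats.truncnorm.rvs(a, b, loc=params.mean, scale=params.sd,
                                size=size, random_state=rng)
    return np.clip(np.round(draws, 1), lo, hi)


def generate(config: GeneratorConfig
             ) -> tuple[list[SubstanceRecord], pd.DataFrame]:
    """Generate a collection; returns (records, latent-truth sidecar).

    Deterministic given ``config.seed``.  The sidecar frame has one row
    per substance with its latent category and study count, for
    parameter-recovery tests.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_substances
    K = np.asarray(config.confusion_kernel, dtype=float)
    cat_idx = {c: i for i, c in enumerate(CATS4)}

    prev = np.array([config.category_prevalence[c] for c in CATS4])
    true_idx = rng.choice(4, size=n, p=prev / prev.sum())
    repeat_counts = np.array(sorted(config.repeat_distribution))
    repeat_probs = np.array([config.repeat_distribution[k]
                             for k in repeat_counts], dtype=float)
    n_studies = rng.choice(repeat_counts, size=n,
                           p=repeat_probs / repeat_probs.sum())

    # Markov chain of observed categories per substance
    observed: list[list[int]] = []
    for i in range(n):
        chain = [int(true_idx[i])]
        for _ in range(int(n_studies[i]) - 1):
            chain.append(int(rng.choice(4, p=K[chain[-1]])))
        observed.append(chain)

    # batch score draws per observed category and endpoint
    flat = [(i, j, c) for i, chain in enumerate(observed)
            for j, c in enumerate(chain)]
    flat_cat = np.array([c for _, _, c in flat])
    scores = {ep: np.empty(len(flat)) for ep in ENDPOINTS}
    for ci, cat in enumerate(CATS4):
        mask = flat_cat == ci
        k = int(mask.sum())
        if k == 0:
            continue
        for ep in ENDPOINTS:
            lo, hi = ENDPOINT_RANGES[ep]
            scores[ep][mask] = _draw_scores(rng, config.score_model[cat][ep],
                                            lo, hi, k)

    # reversibility bucket per study
    rev_buckets: list[Reversibility] = []
    for _, _, c in flat:
        model = config.reversibility_model[CATS4[c]]
        opts = list(model)
        probs = np.array([model[o] for o in opts], dtype=float)
        rev_buckets.append(opts[int(rng.choice(len(opts),
                                               p=probs / probs.sum()))])

    rel_probs = np.array(config.reliability_probs, dtype=float)
    reliabilities = rng.choice([1, 2, 3], size=len(flat),
                               p=rel_probs / rel_probs.sum())
    readacross = rng.random(len(flat)) < config.p_readacross

    # fingerprints: category-linked prototypes with bit flips
    fm = config.fingerprint_model
    prototypes = (rng.random((fm.n_prototypes, fm.bit_length))
                  < fm.density).astype(np.uint8)
    proto_for_sub = prototypes[true_idx % fm.n_prototypes]
    flips = rng.random((n, fm.bit_length)) < fm.flip_rate
    fp_bits = np.bitwise_xor(proto_for_sub, flips.astype(np.uint8))

    # hazards: eye statements from the latent category, the rest from
    # conditional positivity rates given irritant status
    irritant = true_idx != cat_idx[IrritationCategory.NON_IRRITANT]
    hazard_codes = sorted(config.hazard_model)
    p_pos = np.array([[config.hazard_model[c].p_pos_non,
                       config.hazard_model[c].p_pos_irritant]
                      for c in hazard_codes])
    p_known = np.array([config.hazard_model[c].p_known for c in hazard_codes])
    known = rng.random((n, len(hazard_codes))) < p_known[None, :]
    positive = rng.random((n, len(hazard_codes))) < p_pos[:, 1][None, :] * \
        irritant[:, None] + p_pos[:, 0][None, :] * (~irritant[:, None])

    eye_code_for = {IrritationCategory.TYPE1: "H318",
                    IrritationCategory.TYPE2A: "H319",
                    IrritationCategory.TYPE2B: "H320"}

    records: list[SubstanceRecord] = []
    pos_in_flat = 0
    for i in range(n):
        true_cat = CATS4[int(true_idx[i])]
        studies = []
        for j, c in enumerate(observed[i]):
            obs_cat = CATS4[c]
            days = _BUCKET_DAYS[rev_buckets[pos_in_flat]]
            studies.append(DraizeStudy(
                study_num=j + 1,
                cornea=float(scores["cornea"][pos_in_flat]),
                iris=float(scores["iris"][pos_in_flat]),
                conjunctivae=float(scores["conjunctivae"][pos_in_flat]),
                chemosis=float(scores["chemosis"][pos_in_flat]),
                reversibility_days={ep: days for ep in ENDPOINTS},
                verdict_text=CANONICAL_VERDICT[obs_cat],
                reliability=int(reliabilities[pos_in_flat]),
                guideline=(Guideline.TG405_READACROSS
                           if readacross[pos_in_flat]
                           else Guideline.TG405_INVIVO),
            ))
            pos_in_flat += 1
        hazards = {}
        for target_code in ("H318", "H319", "H320"):
            hazards[target_code] = HazardStatus.NEGATIVE
        if true_cat in eye_code_for:
            hazards[eye_code_for[true_cat]] = HazardStatus.POSITIVE
        for jc, code in enumerate(hazard_codes):
            if known[i, jc]:
                hazards[code] = (HazardStatus.POSITIVE if positive[i, jc]
                                 else HazardStatus.NEGATIVE)
        records.append(SubstanceRecord(
            id=_substance_id(i), studies=studies, hazards=hazards,
            fingerprint=Fingerprint(fp_bits[i]),
            dossier_category=true_cat))
    assert pos_in_flat == len(flat)

    truth = pd.DataFrame({
        "id": [r.id for r in records],
        "true_category": [CATS4[int(c)].value for c in true_idx],
        "n_studies": n_studies.astype(int),
    })
    return records, truth


def make_rulebook_dataset(
    n: int,
    thresholds: Optional[RuleThresholds] = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[str]]:
    """Feature table whose labels come exactly from the GHS rulebook.

    Endpoint scores are drawn on a 0.1 grid, skewed toward the low end
    of each range the way observed severity scores are (means equal
    maxima, the single-study case).  The draw is salted with pairs of
    records straddling every rulebook cut point in a *decisive* context
    -- every other feature held below its own cut-off -- so the two
    members of a pair receive different labels and a learned tree has
    the evidence needed to place each threshold.  Labels have zero
    noise: each row's label is the rulebook classification of its own
    features.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    t = thresholds or RuleThresholds()
    rng = np.random.default_rng(seed)
    rev_values = [r.value for r in Reversibility]
    cat2_cut = {"cornea": t.cornea_cat2, "iris": t.iris_cat2,
                "conjunctivae": t.conjunctivae_cat2,
                "chemosis": t.chemosis_cat2}

    def skewed(hi: float) -> float:
        # most studies score low; squash uniform draws toward zero
        return float(round(rng.uniform() ** 1.7 * hi, 1))

    def random_row() -> dict:
        row = {ep: skewed(ENDPOINT_RANGES[ep][1]) for ep in ENDPOINTS}
        row["reversibility"] = str(
            rng.choice(rev_values, p=[0.4, 0.4, 0.2]))
        return row

    def quiet_row() -> dict:
        # all endpoints below their category-2 cut-offs, effects reversible
        row = {ep: float(round(rng.uniform(0, cat2_cut[ep] - 0.1), 1))
               for ep in ENDPOINTS}
        row["reversibility"] = str(rng.choice(rev_values[:2]))
        return row

    straddle_points = [
        ("cornea", t.cornea_cat2), ("cornea", t.cornea_cat1),
        ("iris", t.iris_cat2), ("iris", round(t.iris_cat1 + 0.1, 1)),
        ("conjunctivae", t.conjunctivae_cat2), ("chemosis", t.chemosis_cat2),
    ]
    n_pairs = max(2, n // 40)
    rows: list[dict] = []
    for ep, cut in straddle_points:
        for _ in range(n_pairs):
            base = quiet_row()
            for value in (round(cut - 0.1, 1), round(cut, 1)):
                row = dict(base)
                row[ep] = value
                rows.append(row)
    while len(rows) < n:
        rows.append(random_row())
    rows = rows[:n]

    columns = {}
    for ep in ("chemosis", "iris", "cornea", "conjunctivae"):
        vals = [r[ep] for r in rows]
        columns[f"{ep}_mean"] = vals
        columns[f"{ep}_max"] = vals
    columns["reversibility"] = [r["reversibility"] for r in rows]
    frame = pd.DataFrame(columns)

    labels = []
    for r in rows:
        feats = EndpointFeatures(
            substance_id="synthetic",
            cornea_mean=r["cornea"], cornea_max=r["cornea"],
            iris_mean=r["iris"], iris_max=r["iris"],
            conjunctivae_mean=r["conjunctivae"], conjunctivae_max=r["conjunctivae"],
            chemosis_mean=r["chemosis"], chemosis_max=r["chemosis"],
            reversibility=Reversibility(r["reversibility"]))
        labels.append(classify_rulebook(feats, t).value)
    return frame, labels
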