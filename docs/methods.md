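# Methods

This note documents the models and procedures implemented in
`draize_miner`, the assumptions behind them, the defaults of the
synthetic-data generator, and the numerical choices that affect results.

## Data model

A collection is a list of substances, each with: an EC-number-style
identifier; an ordered list of eye studies (per-study scores for the
four Draize endpoints — cornea 0–4, iris 0–2, conjunctivae 0–3,
chemosis 0–4 — a per-endpoint reversal-days map, a free-text verdict, a
Klimisch reliability score and a guideline tag); a map of GHS hazard
statements to positive/negative status (absent codes are unknown); an
optional fixed-length binary fingerprint (881 bits by default, the
PubChem 2D key length); and an optional dossier-level eye category from
classification and labeling (H318/H319/H320).

Scores are stored as decimals because dossier studies commonly report
animal means. Validation is total — every record either passes or
appears in the violation report with a machine-readable field path — and
out-of-range scores are warnings by default (registration data does
contain incorrect inputs) and fatal only under strict validation. The
reversal sentinel `NOT_REVERSED` (effect persisting past the 21-day
observation window) is distinct from a missing observation. Explicit
unknown hazard statuses are normalized away on construction, so absence
and unknown are one state; the CSV form omits them and restores them on
read, making round-trips exact.

## Verdict normalization

Dossier verdicts are free text ("category 1", "cat. I", "corrosive",
"highly irritating", …). Matching is exact on the normalized string
(lower-cased, punctuation stripped, whitespace collapsed) against a
synonym table; there is deliberately no fuzzy matching, so mapping is
deterministic and unmatched verdicts stay unknown — low coverage is a
property of the corpus, not an error. The shipped default table covers
the common spellings of the four categories and is user-replaceable
(CSV). A substance's category is the mode over its studies' mapped
verdicts, with ties broken toward the more severe category
(conservative hazard assignment; configurable).

## Reproducibility estimation

Substances with at least two mappable study verdicts contribute to a
4×4 matrix of conditional probabilities P(next = j | prior = i). Three
counting units are implemented:

* `all_ordered` (default): every ordered pair of distinct studies
  within a substance. The pair-count matrix is symmetric by
  construction and every row is well-defined; this matches the
  row-conditional presentation customary for such tables. The `Total`
  column counts substances with at least one study of the row category
  (a substance can appear in several rows).
* `unordered`: each pair once.
* `consecutive`: directed transitions between consecutive studies.
  This is the estimator paired with the generator's repeat model: when
  repeat outcomes form a Markov chain with transition kernel K, the
  consecutive-transition estimate converges to K. Note that the
  all-ordered estimator does *not* converge to K under that model
  (pairs at lag ℓ follow K^ℓ), which is why the kernel-recovery
  experiment uses `consecutive`.

Probabilities are reported as percentages rounded to one decimal.

## GHS rulebook classification

Features per substance: mean and maximum of each endpoint across all
studies, and one reversibility feature from the single longest
endpoint/study reversal (≤ 7 days, ≤ 21 days, or irreversible —
i.e. > 21 days or never reversed). The rule set is order-independent:

* Type 1 if cornea ≥ 3.0, or iris > 1.5, or reversibility is
  irreversible;
* otherwise Type 2 if cornea ≥ 1.0, iris ≥ 1.0, conjunctivae ≥ 2.0 or
  chemosis ≥ 2.0 — Type 2B when effects reverse within 7 days, else
  Type 2A;
* otherwise non-irritant.

Severity tests read the per-endpoint maximum by default (protective);
the mean is a named option. The learner-facing dataset builder offers a
strict mode (complete cases only) and a relaxed mode (any available
features), plus a drop-rare-class filter for classes too sparse to
learn. Per-animal GHS clauses ("2 of 3 animals") are out of scope: the
data model carries study-level scores only.

## Decision trees

Top-down induction by maximum information gain (Shannon entropy in
bits), numeric splits at midpoints between consecutive distinct
observed values, categorical splits multiway. No gain-ratio correction,
confidence pruning or subtree raising: the trees are read as rule
statements, and training-set confusion is the default report. Defaults
`min_leaf=2` (each child of a split keeps at least two rows, weighted),
unlimited depth. Ties in gain go to the earlier attribute in
declaration order, then to the smaller threshold; leaf majorities break
ties lexicographically. Together these make fitting invariant to row
order. Optional per-row weights let the 3-hazard search fit each tree
from its 8-cell contingency table, which is exactly equivalent to
fitting on the expanded dataset and makes the exhaustive search of all
C(72,3) = 59,640 combinations run in about a millisecond per model.

## Hazard screening

The binary eye label is irritant if any of H318/H319/H320 is positive
and non-irritant otherwise. The "otherwise" convention treats
unclassified substances as negative — the operational choice this kind
of screen rests on, with the known caveat that an unclassified
substance may simply be unassessed; a strict mode that returns unknown
instead is provided. Single-hazard rows are computed on substances with
definite values for both the hazard and the label, and rows making
fewer than 100 positive or 100 negative predictions are dropped.
Triplet search ranks by balanced accuracy by default (PPV and NPV are
options) and reports each tree's truth table reduced to a boolean rule.
No multiple-testing correction is applied over the 59,640 models; the
search is descriptive, and its training-set metrics on small subsets
are optimistic.

## Read-across

Tanimoto similarity |a∧b| / |a∨b| over equal-length fingerprints;
all-zero fingerprints are rejected as undefined. Classification is
leave-one-out 1-NN: a substance is predicted by the label of its most
similar *other* substance among those with similarity ≥ T, ties going
to the smallest substance id. Substances with no qualifying neighbor
are excluded from the metrics and counted separately, so the sweep's
substance count is non-increasing in T by construction. The positive
class for sensitivity is irritant. The similarity graph is exported as
an edge list (and optionally GraphML) for external force-directed
layout; rendering is out of scope.

## Synthetic-data generator

The generator emulates the structure of a mined registration corpus;
its defaults are the package's study conditions.

* **Prevalence**: Type 1 10%, Type 2A 14%, Type 2B 10%, non-irritant
  66% — about one third irritants, reversible irritation the most
  common irritant class.
* **Repeat counts**: a fixed long-tailed distribution (mode 1 study,
  ~65% singletons, a small mass at 45–90 repeats) reflecting how often
  substances are retested.
* **Repeat outcomes**: a Markov chain over categories. The first study
  reports the substance's latent category; each later study's category
  is drawn from the confusion kernel row of the previous outcome. The
  default kernel has ~94% self-agreement for non-irritant priors, ~73%
  for severe irritants, and ~10% severe→non-irritant flips. An
  identity kernel makes every repeat identical.
* **Scores**: truncated normals per category and endpoint, means
  ordered Type 1 > 2A > 2B > non-irritant on every endpoint and chosen
  consistent with the rulebook, so a zero-noise draw classifies back to
  its generating category (the `zero_noise()` configuration makes this
  exact end to end).
* **Reversibility**: per-category distributions over the three buckets
  (Type 1 mostly irreversible, 2A within 21 days, 2B within 7).
* **Hazards**: H318/H319/H320 follow the latent category; the other 69
  codes of the 72-hazard vocabulary are conditionally independent given
  irritant status, with a subset of health hazards (H302, H314, H315,
  H317, H335, …) given elevated positive rates among irritants.
* **Fingerprints**: one random prototype per category (density 0.2)
  with independent per-bit flips (2% default). Within-prototype
  Tanimoto similarity (~0.85 at the default flip rate) far exceeds
  between-prototype similarity (~0.1), giving the clustered structure
  read-across assumes.

What the generator does **not** emulate: real chemistry (fingerprints
are abstract prototypes, not molecules), correlated hazard panels,
laboratory- or year-level effects, per-animal variation, and verdict
text diversity (generated verdicts use one canonical spelling per
category). Consequently, passing recovery tests demonstrates the
correctness and calibration of the estimators and learners, not the
field performance of read-across or hazard screens on real substances.

## Experiment designs used in the acceptance checks

* **Kernel recovery**: 2,000 substances, repeat distribution
  conditioned on ≥ 2 studies (single-study substances carry no
  information about the kernel — the same inclusion criterion a
  repeat-test analysis applies), starting categories uniform over the
  four classes (a balanced design equalizes the information per matrix
  row), consecutive-pair estimator, no reliability filtering (dropping
  studies would splice chains and mix lag-2 transitions into the
  estimate). Typical maximum elementwise error ≈ 0.015–0.025.
* **Rulebook recovery**: 391 zero-label-noise feature rows; scores on a
  0.1 grid skewed low (u^1.7 × range) as observed severity scores are,
  salted with pairs straddling every rulebook cut point in a decisive
  context (all other endpoints below their own cut-offs) so the two
  pair members receive different labels. The learned tree reaches 100%
  training accuracy — labels are a deterministic function of the
  features — and places its cornea and conjunctivae cuts at the grid
  midpoints 0.95/2.95 and 1.95, i.e. within 0.05 of the rulebook values.
* **Read-across**: two-prototype collections (binary label = cluster)
  at 2% flip rate keep between-cluster similarity far below the 0.7
  threshold, so leave-one-out 1-NN is near-perfect; the threshold sweep
  is checked for exact coverage monotonicity.
* **Triplet search**: with the label constructed as an exact
  disjunction of two hazards, any triplet containing both reaches
  balanced accuracy 1.0 and the fitted tree's truth table equals the
  disjunction.

Problem sizes (2,000 substances for reproducibility experiments, 391
for rulebook recovery, 929–1,500 for the screening and read-across
stages) were chosen to keep sampling error comfortably inside the
assertion tolerances while the full suite runs in a few seconds.

## Numerical choices and degenerate inputs

Probabilities in the conditional matrix are NaN for rows with no pairs
rather than silently zero. Undefined binary-metric ratios
(zero denominators) are `None` and recorded by name in an `undefined`
list. Threshold comparisons in the similarity sweep use a 1e-12
tolerance so grid thresholds equal to attained similarities are
inclusive. Entropy uses base-2 logarithms; information-gain ties use a
1e-12 comparison margin. Fingerprint hex encoding pads to whole bytes
and rejects nonzero padding on decode. The empty collection, empty
study lists, single-study substances, and all-unknown hazard panels are
all defined, tested cases rather than errors wherever a sensible value
exists.

## Known limitations

The tree learner's training-set metrics overstate generalization; no
cross-validation is built in beyond what a caller assembles. The
hazard screen's "otherwise = negative" label construction biases both
predictive values when unclassified substances are in fact positives.
The verdict normalizer is exact-match and English-only by design. The
generator's conditional-independence assumption for hazards understates
the redundancy present in real hazard panels.
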