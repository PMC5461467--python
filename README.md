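# draize-miner

Tools for mining and modeling rabbit-eye-irritation (Draize, OECD TG 405)
study data of the kind found in chemical registration dossiers: free-text
verdict normalization, UN GHS category classification from endpoint
scores, test–retest reproducibility, decision-tree modeling, hazard
predictive-value screening, and Tanimoto-similarity read-across.

It is written for computational toxicologists and cheminformaticians who
work with dossier-style datasets — one record per substance, each with
repeated Draize studies (cornea, iris, conjunctivae and chemosis scores
plus reversibility), GHS hazard statements, and an optional binary
substructure fingerprint. Because curated registration extractions are
generally not redistributable, the package ships a synthetic-data
generator that reproduces the statistical structure such corpora have
(long-tailed retest counts, category-ordered score distributions, a
repeat-test confusion kernel, hazard co-occurrence, clustered
fingerprints), so every stage of the pipeline is testable end to end
against known latent truth.

## The statistics at the core

**Test–retest reproducibility.** For repeat-tested substances the
package estimates the conditional probability that a further Draize test
reproduces a prior category,

    P(T2 = j | T1 = i) = P(T2 = j ∩ T1 = i) / P(T1 = i),

as a 4×4 row-stochastic matrix over the GHS eye categories
(Type 1 = serious damage / H318, Type 2A = irritant / H319,
Type 2B = mild irritant / H320, non-irritant). Three pair-counting
conventions are available: all ordered within-substance pairs (default),
unordered pairs, and directed consecutive transitions — the estimator of
choice when repeats are modeled as a Markov chain.

**GHS rulebook.** Per substance, endpoint means and maxima over all
studies plus the longest reversal period feed the UN GHS eye criteria:
cornea ≥ 3, iris > 1.5 or effects persisting ≥ 21 days give Type 1;
cornea ≥ 1, iris ≥ 1, conjunctival redness ≥ 2 or chemosis ≥ 2 give
Type 2, split 2B/2A by 7-day reversibility; otherwise non-irritant. All
cut-offs are configurable.

**Decision trees.** A plain Quinlan-style learner: each node takes the
attribute (and midpoint cut, for numeric attributes) with maximal
information gain ΔH = H(parent) − Σ (n_k/n) H(child_k), with entropy in
bits. No pruning or gain-ratio correction — the trees are meant to
expose the rules in the data.

**Hazard screens.** Substances are labeled irritant if positive for any
of H318/H319/H320. Every other hazard is scored by PPV, NPV,
sensitivity, specificity and balanced accuracy BAC = (sens + spec)/2;
all C(n,3) three-hazard combinations are searched exhaustively, fitting
one decision tree per combination and canonicalizing it to its boolean
truth table (e.g. "H335 or H302 or H314").

**Read-across.** Chemical similarity is the Jaccard/Tanimoto coefficient
|a ∧ b| / |a ∨ b| over 881-bit substructure fingerprints. Each substance
is predicted leave-one-out by its most similar neighbor with similarity
≥ T; sweeping T trades coverage (substances with a qualifying neighbor)
against accuracy.

## Worked example

```python
from draize_miner import GeneratorConfig, generate, conditional_matrix, filter_eye_studies
from draize_miner.pipeline import build_endpoint_dataset
from draize_miner.tree import fit_tree, confusion

records, truth = generate(GeneratorConfig(n_substances=1000, seed=0))
records = filter_eye_studies(records)          # Klimisch 1-2 eye studies
print(conditional_matrix(records, pair_mode="consecutive").to_frame())
```

```
              TYPE1  TYPE2A  TYPE2B  NON_IRRITANT  Total
prior
TYPE1          74.7    18.1     0.0           7.2     40
TYPE2A          3.9    40.6     1.6          53.9     81
TYPE2B          0.0     6.4     6.4          87.2     43
NON_IRRITANT    0.8     3.3     1.5          94.4    294
```

Rows are the prior test's category, cells the percentage of repeat tests
returning each category, and Total the number of repeat-tested
substances contributing to the row. Read: a prior non-irritant result is
reproduced 94.4% of the time, a prior severe irritant 74.7% of the time,
and 7.2% of repeats after a severe-irritant result come back
non-irritant — the pattern injected by the generator's confusion kernel.

```python
X, y = build_endpoint_dataset(records, drop_rare_below=10)
tree = fit_tree(X, y, min_leaf=2)
print(confusion(tree, X, y).to_frame())
```

```
actual        NON_IRRITANT  TYPE1  TYPE2A  TYPE2B
predicted
NON_IRRITANT           698      1       2       3
TYPE1                    0     81       3       0
TYPE2A                   0      0     116       3
TYPE2B                   1      0       1      67
```

The learned endpoint tree recovers the GHS logic from noisy scores
(training accuracy 98.6% here; rows are predictions, columns the
mode-verdict classes).

The same pipeline is available from the shell:

```sh
draize-miner simulate --n 1000 --seed 0 --out collection.json
draize-miner repro --input collection.json --out table3.csv
draize-miner hazard-scan --input collection.json --triplets 10 --out table5.csv
draize-miner knn --input collection.json --out table6.csv
draize-miner run --simulate-n 1000 --seed 0 --out-dir out/
```

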