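"""Hazard predictive-value screen and 3-hazard combination search."""

import numpy as np
import pytest

from draize_miner.hazards import (
    IRRITANT,
    NON_IRRITANT_LABEL,
    BinaryMetrics,
    describe_truth_table,
    enumerate_triplets,
    irritant_label,
    screen_single_hazards,
    triplet_count,
    triplet_search,
)
from draize_miner.model import HazardStatus, SubstanceRecord

P, N = HazardStatus.POSITIVE, HazardStatus.NEGATIVE


def _rec(i, **hazards):
    return SubstanceRecord(id=f"S{i:05d}", hazards=hazards)


def test_irritant_label_rules():
    assert irritant_label(_rec(0, H319=P)) == IRRITANT
    assert irritant_label(_rec(1, H318=N, H319=N, H320=N)) == NON_IRRITANT_LABEL
    # the "otherwise" convention: nothing reported still counts negative...
    assert irritant_label(_rec(2)) == NON_IRRITANT_LABEL
    # ...unless strict mode is asked for
    assert irritant_label(_rec(3), strict=True) == "UNKNOWN"
    assert irritant_label(_rec(4, H318=N), strict=True) == NON_IRRITANT_LABEL


def test_binary_metrics_identities_and_undefined():
    m = BinaryMetrics.from_counts(tp=30, fp=10, tn=50, fn=10)
    assert m.ppv == pytest.approx(0.75)
    assert m.npv == pytest.approx(50 / 60)
    assert m.sensitivity == pytest.approx(0.75)
    assert m.specificity == pytest.approx(50 / 60)
    assert m.bac == pytest.approx((m.sensitivity + m.specificity) / 2, abs=1e-12)
    assert m.total == 100 and not m.undefined
    degenerate = BinaryMetrics.from_counts(tp=0, fp=0, tn=5, fn=5)
    assert degenerate.ppv is None and "ppv" in degenerate.undefined


def _screen_records(n_pos_pred, n_neg_pred):
    """Hazard HX positive for the first n_pos_pred substances (all
    irritant), negative for the next n_neg_pred (all non-irritant)."""
    records = []
    for i in range(n_pos_pred):
        records.append(_rec(i, HX=P, H319=P))
    for i in range(n_neg_pred):
        records.append(_rec(n_pos_pred + i, HX=N, H319=N))
    return records


def test_screen_min_prediction_filter_boundary():
    # 99 positive predictions: filtered out; 100: retained
    assert screen_single_hazards(_screen_records(99, 150)) == []
    rows = screen_single_hazards(_screen_records(100, 150))
    assert [r.code for r in rows] == ["HX"]
    assert rows[0].total == 250


def test_perfect_hazard_scores_one():
    rows = screen_single_hazards(_screen_records(120, 130))
    m = rows[0].metrics
    assert m.ppv == m.npv == m.bac == 1.0
    assert m.tp + m.fp + m.tn + m.fn == rows[0].total


def test_independent_hazard_near_chance():
    """A hazard independent of the label: PPV tracks prevalence and BAC
    sits at one half, up to sampling error at n=5,000."""
    rng = np.random.default_rng(0)
    records = []
    for i in range(5000):
        irritant = rng.random() < 0.35
        hz = {"H319": P if irritant else N, "HX": P if rng.random() < 0.4 else N}
        records.append(SubstanceRecord(id=f"S{i}", hazards=hz))
    m = screen_single_hazards(records)[0].metrics
    assert m.ppv == pytest.approx(0.35, abs=0.03)
    assert m.bac == pytest.approx(0.5, abs=0.03)


@pytest.mark.parametrize("n,expected", [(3, 1), (5, 10), (72, 59640)])
def test_triplet_counts(n, expected):
    codes = [f"H{300 + i}" for i in range(n)]
    subsets = list(enumerate_triplets(codes))
    assert len(subsets) == triplet_count(n) == expected
    assert len(set(subsets)) == len(subsets)  # each subset exactly once


def test_enumerate_requires_three():
    with pytest.raises(ValueError):
        enumerate_triplets(["H300", "H301"])


def _or_dataset(seed=0, n=400):
    rng = np.random.default_rng(seed)
    codes = ["H301", "H302", "H311", "H314", "H315", "H335"]
    records = []
    for i in range(n):
        vals = rng.random(len(codes)) < 0.4
        hz = {c: (P if v else N) for c, v in zip(codes, vals)}
        hz["H319"] = P if (vals[1] or vals[3]) else N  # H302 or H314
        records.append(SubstanceRecord(id=f"S{i:04d}", hazards=hz))
    return records, codes


def test_triplet_search_recovers_disjunction():
    records, codes = _or_dataset()
    results = triplet_search(records, codes, top_k=4)
    top = results[0]
    assert {"H302", "H314"} <= set(top.codes)
    assert top.metrics.bac == 1.0
    assert top.rule == "H302 or H314"
    # the truth table is exactly the disjunction over the triplet's bits
    k = 3
    for cell, label in enumerate(top.truth_table):
        bits = {top.codes[j]: (cell >> (k - 1 - j)) & 1 for j in range(k)}
        want = IRRITANT if (bits["H302"] or bits["H314"]) else NON_IRRITANT_LABEL
        assert label == want


def test_triplet_search_exact_count_single_output():
    records, _ = _or_dataset(n=60)
    results = triplet_search(records, ["H302", "H314", "H315"], top_k=10)
    assert len(results) == 1  # C(3,3)


def test_triplet_metrics_conserve_subset_size():
    records, codes = _or_dataset(n=200)
    for res in triplet_search(records, codes, top_k=20):
        assert res.metrics.total == res.n_substances


def test_triplet_search_null_hazards_near_chance():
    rng = np.random.default_rng(1)
    codes = ["H301", "H302", "H311", "H314"]
    records = []
    for i in range(3000):
        hz = {c: (P if rng.random() < 0.4 else N) for c in codes}
        hz["H319"] = P if rng.random() < 0.35 else N  # independent label
        records.append(SubstanceRecord(id=f"S{i}", hazards=hz))
    top = triplet_search(records, codes, top_k=1)[0]
    assert top.metrics.bac == pytest.approx(0.5, abs=0.04)


def test_describe_truth_table_shapes():
    codes = ("A", "B", "C")
    always = tuple([IRRITANT] * 8)
    assert describe_truth_table(codes, always) == "always irritant"
    never = tuple([NON_IRRITANT_LABEL] * 8)
    assert describe_truth_table(codes, never) == "never irritant"
    conj = tuple(IRRITANT if (c >> 2) & 1 and (c >> 1) & 1 else NON_IRRITANT_LABEL
                 for c in range(8))
    assert describe_truth_table(codes, conj) == "A and B"
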