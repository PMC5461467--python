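"""Tanimoto similarity, leave-one-out 1-NN read-across, similarity graph."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from draize_miner.hazards import IRRITANT, NON_IRRITANT_LABEL
from draize_miner.model import Fingerprint, SubstanceRecord
from draize_miner.similarity import (
    knn1_classify,
    similarity_edges,
    tanimoto,
    tanimoto_matrix,
    threshold_sweep,
)
from draize_miner.simulate import CATS4, FingerprintModel, GeneratorConfig, generate


def fp(*on_bits, length=16):
    bits = np.zeros(length, dtype=np.uint8)
    bits[list(on_bits)] = 1
    return Fingerprint(bits)


def test_tanimoto_examples():
    assert tanimoto(fp(1, 2, 3), fp(1, 2, 3)) == 1.0
    assert tanimoto(fp(1, 2), fp(5, 6)) == 0.0
    assert tanimoto(fp(1, 2, 3), fp(2, 3, 4)) == 0.5  # 2 shared / 4 union


def test_tanimoto_errors():
    with pytest.raises(ValueError, match="length"):
        tanimoto(fp(1), fp(1, length=8))
    with pytest.raises(ValueError, match="all-zero"):
        tanimoto(fp(length=16), fp(length=16))


@settings(max_examples=60, deadline=None, derandomize=True)
@given(a=st.lists(st.integers(0, 1), min_size=12, max_size=12),
       b=st.lists(st.integers(0, 1), min_size=12, max_size=12))
def test_tanimoto_symmetry_and_range(a, b):
    if sum(a) == 0 or sum(b) == 0:
        return
    fa, fb = Fingerprint(np.array(a)), Fingerprint(np.array(b))
    s = tanimoto(fa, fb)
    assert 0.0 <= s <= 1.0
    assert s == tanimoto(fb, fa)
    assert tanimoto(fa, fa) == 1.0


def test_matrix_agrees_with_pairwise():
    rng = np.random.default_rng(0)
    fps = [Fingerprint((rng.random(40) < 0.3).astype(np.uint8) | base)
           for base in (np.eye(40, dtype=np.uint8)[i] for i in range(12))]
    M = tanimoto_matrix(fps)
    for i in range(12):
        for j in range(12):
            assert M[i, j] == pytest.approx(tanimoto(fps[i], fps[j]))


def _labeled(fps, labels):
    return ([SubstanceRecord(id=f"S{i:03d}", fingerprint=f)
             for i, f in enumerate(fps)], list(labels))


def test_adversarial_identical_pair_is_always_wrong():
    records, labels = _labeled([fp(1, 2, 3), fp(1, 2, 3)],
                               [IRRITANT, NON_IRRITANT_LABEL])
    preds, row = knn1_classify(records, 0.9, labels=labels)
    assert preds == [NON_IRRITANT_LABEL, IRRITANT]
    assert row.sensitivity == 0.0 and row.specificity == 0.0


def test_no_neighbors_at_full_similarity():
    records, labels = _labeled([fp(1), fp(2), fp(3)], [IRRITANT] * 3)
    _, row = knn1_classify(records, 1.0, labels=labels)
    assert row.n_substances == 0 and row.n_no_neighbor == 3
    assert row.bac is None


def test_nearest_neighbor_matches_brute_force():
    """Oracle equivalence: the 1-NN choice agrees with an independent
    all-pairs scan, including the smallest-id tie rule."""
    rng = np.random.default_rng(3)
    n, L = 120, 64
    fps = [Fingerprint((rng.random(L) < 0.25).astype(np.uint8)
                       | np.eye(L, dtype=np.uint8)[i % L])
           for i in range(n)]
    labels = [IRRITANT if rng.random() < 0.4 else NON_IRRITANT_LABEL
              for _ in range(n)]
    records, labels = _labeled(fps, labels)
    T = 0.2
    preds, _ = knn1_classify(records, T, labels=labels)
    for i in range(n):
        best_j, best_s = None, -1.0
        for j in range(n):
            if j == i:
                continue
            s = tanimoto(fps[i], fps[j])
            if s < T:
                continue
            if s > best_s + 1e-12 or (abs(s - best_s) <= 1e-12
                                      and records[j].id < records[best_j].id):
                best_j, best_s = j, s
        expected = labels[best_j] if best_j is not None else None
        assert preds[i] == expected


def _clustered(n=200, flip=0.02, seed=0):
    # two prototype clusters; the binary label is the cluster
    prevalence = {CATS4[0]: 0.5, CATS4[1]: 0.0, CATS4[2]: 0.0, CATS4[3]: 0.5}
    config = GeneratorConfig(
        n_substances=n, seed=seed, category_prevalence=prevalence,
        fingerprint_model=FingerprintModel(flip_rate=flip))
    return generate(config)[0]


def test_clustered_generator_high_bac():
    records = _clustered()
    _, row = knn1_classify(records, 0.7)
    assert row.bac is not None and row.bac >= 0.95


def test_sweep_monotone_and_bac_identity():
    records = _clustered(n=150, flip=0.05, seed=2)
    thresholds = [round(0.7 + 0.025 * i, 3) for i in range(12)]
    rows = threshold_sweep(records, thresholds)
    assert len(rows) == 12
    for prev, cur in zip(rows, rows[1:]):
        assert cur.n_substances <= prev.n_substances
    for row in rows:
        assert row.n_substances == row.tp_fn + row.tn_fp
        if row.bac is not None:
            assert row.bac == pytest.approx(
                (row.sensitivity + row.specificity) / 2, abs=1e-12)


def test_sweep_requires_sorted_thresholds():
    records = _clustered(n=20)
    with pytest.raises(ValueError):
        threshold_sweep(records, [0.9, 0.7])


def test_edges_triangle_and_empty():
    records, _ = _labeled([fp(1, 2), fp(1, 2), fp(1, 2)], [IRRITANT] * 3)
    edges, degrees = similarity_edges(records, 1.0)
    assert len(edges) == 3  # complete graph on identical fingerprints
    assert set(degrees.values()) == {2}
    records, _ = _labeled([fp(1), fp(2), fp(3)], [IRRITANT] * 3)
    edges, degrees = similarity_edges(records, 1.0)
    assert edges == [] and set(degrees.values()) == {0}


def test_graphml_export(tmp_path):
    nx = pytest.importorskip("networkx")
    from draize_miner.similarity import export_graphml

    records = _clustered(n=30, seed=6)
    path = tmp_path / "sim.graphml"
    export_graphml(records, 0.7, path)
    g = nx.read_graphml(path)
    assert g.number_of_nodes() == 30
    edges, _ = similarity_edges(records, 0.7)
    assert g.number_of_edges() == len(edges)


def test_edges_cluster_structure():
    records = _clustered(n=80, seed=5)
    edges, _ = similarity_edges(records, 0.7)
    by_cat = {r.id: r.dossier_category for r in records}
    within = [e for e in edges if by_cat[e[0]] == by_cat[e[1]]]
    assert len(within) == len(edges)  # no cross-cluster edges at 0.7
    assert len(edges) > 0
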