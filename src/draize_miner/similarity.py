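"""Tanimoto chemical similarity, thresholded 1-NN read-across, and the
similarity graph.

Substances carry fixed-length binary substructure fingerprints (881 bits
by default, the PubChem 2D key length).  Similarity between two
fingerprints is the Jaccard (Tanimoto) coefficient |a AND b| / |a OR b|.
Read-across is evaluated leave-one-out: each substance is predicted by
the binary irritant label of its most similar other substance, counting
only neighbors with similarity >= T; substances with no qualifying
neighbor at T are excluded from the metrics and tallied separately.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .hazards import IRRITANT, NON_IRRITANT_LABEL
from .model import Fingerprint, IrritationCategory, SubstanceRecord
from .normalize import SynonymTable, mode_category

__all__ = [
    "tanimoto",
    "tanimoto_matrix",
    "binary_irritant_labels",
    "SweepRow",
    "knn1_classify",
    "threshold_sweep",
    "similarity_edges",
]


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Jaccard (Tanimoto) similarity of two equal-length fingerprints."""
    if len(a) != len(b):
        raise ValueError(f"fingerprint length mismatch: {len(a)} vs {len(b)}")
    inter = int(np.bitwise_and(a.bits, b.bits).sum())
    union = int(np.bitwise_or(a.bits, b.bits).sum())
    if union == 0:
        raise ValueError("Tanimoto undefined for two all-zero fingerprints")
    return inter / union


def tanimoto_matrix(fingerprints: Sequence[Fingerprint]) -> np.ndarray:
    """All-pairs similarity matrix (float64, symmetric, unit diagonal)."""
    if not fingerprints:
        return np.zeros((0, 0))
    lengths = {len(fp) for fp in fingerprints}
    if len(lengths) != 1:
        raise ValueError(f"inconsistent fingerprint lengths: {sorted(lengths)}")
    F = np.stack([fp.bits for fp in fingerprints]).astype(np.float64)
    pop = F.sum(axis=1)
    if (pop == 0).any():
        bad = int(np.argmax(pop == 0))
        raise ValueError(f"all-zero fingerprint at position {bad}")
    inter = F @ F.T
    union = pop[:, None] + pop[None, :] - inter
    return inter / union


def binary_irritant_labels(
    records: Sequence[SubstanceRecord],
    table: Optional[SynonymTable] = None,
) -> list[str]:
    """Irritant / non-irritant label for the read-across sweep.

    Irritant means eye category Type 1, 2A or 2B.  The dossier
    classification-and-labeling category is used when present; otherwise
    the mode of the substance's mapped study verdicts.  Substances whose
    category cannot be determined get ``"UNKNOWN"`` and are dropped by
    the sweep.
    """
    irritant_cats = {IrritationCategory.TYPE1, IrritationCategory.TYPE2A,
                     IrritationCategory.TYPE2B}
    out = []
    for r in records:
        cat = r.dossier_category
        if cat is IrritationCategory.UNKNOWN:
            cat = mode_category(r, table)
        if cat is IrritationCategory.UNKNOWN:
            out.append("UNKNOWN")
        else:
            out.append(IRRITANT if cat in irritant_cats else NON_IRRITANT_LABEL)
    return out


@dataclass
class SweepRow:
    """One row of the similarity-threshold sweep.

    ``n_substances`` counts the substances with at least one neighbor at
    similarity >= T (= tp_fn + tn_fp); ``n_no_neighbor`` the excluded
    remainder.  Sensitivity's positive class is irritant.  Undefined
    metrics (empty class) are ``None``.
    """

    threshold: float
    n_substances: int
    n_no_neighbor: int
    sensitivity: Optional[float]
    specificity: Optional[float]
    bac: Optional[float]
    tp_fn: int
    tn_fp: int


def _neighbor_predict(sim: np.ndarray, ids: Sequence[str], labels: Sequence[str],
                      threshold: float) -> list[Optional[int]]:
    """Index of the 1-NN for each row at the threshold, or None.

    Self-similarity is always excluded (leave-one-out).  Ties among
    equally similar neighbors go to the smallest substance id.
    """
    n = sim.shape[0]
    out: list[Optional[int]] = []
    order_key = np.array([str(i) for i in ids], dtype=object)
    for i in range(n):
        row = sim[i].copy()
        row[i] = -np.inf
        eligible = np.flatnonzero(row >= threshold - 1e-12)
        if eligible.size == 0:
            out.append(None)
            continue
        best_sim = row[eligible].max()
        tied = eligible[row[eligible] >= best_sim - 1e-12]
        out.append(int(tied[np.argsort(order_key[tied], kind="stable")[0]]))
    return out


def knn1_classify(
    records: Sequence[SubstanceRecord],
    threshold: float,
    labels: Optional[Sequence[str]] = None,
    sim: Optional[np.ndarray] = None,
) -> tuple[list[Optional[str]], SweepRow]:
    """Leave-one-out 1-nearest-neighbor read-across at one threshold.

    Returns per-substance predictions (None when the substance has no
    qualifying neighbor) and the metrics row.  ``labels`` defaults to
    :func:`binary_irritant_labels`; a precomputed similarity matrix can
    be passed to amortize sweeps.
    """
    with_fp = [r for r in records if r.fingerprint is not None]
    if len(with_fp) < 2:
        raise ValueError("need at least 2 records with fingerprints")
    if labels is None:
        labels = binary_irritant_labels(with_fp)
    elif len(labels) != len(with_fp):
        raise ValueError("labels length must match records with fingerprints")
    if sim is None:
        sim = tanimoto_matrix([r.fingerprint for r in with_fp])
    ids = [r.id for r in with_fp]
    nn = _neighbor_predict(sim, ids, labels, threshold)
    preds: list[Optional[str]] = [labels[j] if j is not None else None for j in nn]

    tp = fp = tn = fn = n_no_neighbor = 0
    for pred, actual in zip(preds, labels):
        if actual == "UNKNOWN":
            continue
        if pred is None:
            n_no_neighbor += 1
            continue
        if actual == IRRITANT:
            if pred == IRRITANT:
                tp += 1
            else:
                fn += 1
        else:
            if pred == IRRITANT:
                fp += 1
            else:
                tn += 1
    sens = tp / (tp + fn) if tp + fn else None
    spec = tn / (tn + fp) if tn + fp else None
    bac = (sens + spec) / 2 if sens is not None and spec is not None else None
    row = SweepRow(threshold=threshold, n_substances=tp + fn + tn + fp,
                   n_no_neighbor=n_no_neighbor, sensitivity=sens,
                   specificity=spec, bac=bac, tp_fn=tp + fn, tn_fp=tn + fp)
    return preds, row


def threshold_sweep(
    records: Sequence[SubstanceRecord],
    thresholds: Sequence[float],
    labels: Optional[Sequence[str]] = None,
) -> list[SweepRow]:
    """Evaluate the 1-NN read-across over an ascending threshold grid."""
    thresholds = list(thresholds)
    if thresholds != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    with_fp = [r for r in records if r.fingerprint is not None]
    if len(with_fp) < 2:
        raise ValueError("need at least 2 records with fingerprints")
    sim = tanimoto_matrix([r.fingerprint for r in with_fp])
    if labels is None:
        labels = binary_irritant_labels(with_fp)
    return [knn1_classify(with_fp, t, labels=labels, sim=sim)[1]
            for t in thresholds]


def sweep_to_frame(rows: Sequence[SweepRow]) -> pd.DataFrame:
    return pd.DataFrame([
        {"T": r.threshold, "Substances": r.n_substances,
         "Sensitivity": r.sensitivity, "TP+FN": r.tp_fn,
         "Specificity": r.specificity, "TN+FP": r.tn_fp, "BAC": r.bac}
        for r in rows
    ])


def similarity_edges(
    records: Sequence[SubstanceRecord],
    threshold: float,
) -> tuple[list[tuple[str, str, float]], dict[str, int]]:
    """Undirected similarity-graph edge list at a minimum similarity.

    Each unordered pair with similarity >= T appears once as
    (id_a, id_b, similarity) with id_a < id_b; the second return value
    is the node-degree table (nodes with no edges have degree 0).  The
    edge list is suitable for external force-directed layout tools.
    """
    with_fp = [r for r in records if r.fingerprint is not None]
    ids = [r.id for r in with_fp]
    degrees = {rid: 0 for rid in ids}
    edges: list[tuple[str, str, float]] = []
    if len(with_fp) >= 2:
        sim = tanimoto_matrix([r.fingerprint for r in with_fp])
        n = len(ids)
        for i in range(n):
            for j in range(i + 1, n):
                if sim[i, j] >= threshold - 1e-12:
                    a, b = sorted((ids[i], ids[j]))
                    edges.append((a, b, float(sim[i, j])))
                    degrees[ids[i]] += 1
                    degrees[ids[j]] += 1
    return edges, degrees


def export_graphml(records: Sequence[SubstanceRecord], threshold: float,
                   path) -> None:
    """Write the similarity graph as GraphML for external layout tools.

    Nodes carry the substance's irritant label and degree; edges carry
    the similarity.  Requires the optional networkx dependency.
    """
    import networkx as nx

    with_fp = [r for r in records if r.fingerprint is not None]
    labels = dict(zip((r.id for r in with_fp), binary_irritant_labels(with_fp)))
    edges, degrees = similarity_edges(records, threshold)
    g = nx.Graph()
    for rid, degree in degrees.items():
        g.add_node(rid, label=labels[rid], degree=degree)
    for a, b, s in edges:
        g.add_edge(a, b, similarity=s)
    nx.write_graphml(g, path)
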