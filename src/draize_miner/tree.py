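"""Top-down information-gain decision trees.

A deliberately plain Quinlan-style learner: at every node the attribute
(and, for numeric attributes, the cut point) with the greatest reduction
in Shannon entropy is chosen; recursion stops at purity, a minimum leaf
size, a depth limit, or zero gain.  No gain-ratio correction, confidence
pruning or subtree raising -- the point of the learner is to expose the
predictive rules in the data, not to squeeze out generalization error.

Numeric splits test ``value <= threshold`` with thresholds at midpoints
between consecutive distinct observed values; categorical attributes
split multiway on their values.  Ties in gain are broken by attribute
declaration order, then by the smaller threshold, which makes fitting
invariant to row shuffling.  Optional ``sample_weight`` lets callers fit
from pre-aggregated contingency rows.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TreeNode",
    "ConfusionMatrix",
    "entropy",
    "best_split",
    "fit_tree",
    "predict",
    "predict_frame",
    "confusion",
    "render",
]

_EPS = 1e-12


def entropy(class_counts: Mapping[object, float]) -> float:
    """Shannon entropy in bits of a class-count map; 0 for pure nodes."""
    total = float(sum(class_counts.values()))
    if total <= 0:
        raise ValueError("entropy undefined for empty count map")
    h = 0.0
    for c in class_counts.values():
        if c < 0:
            raise ValueError("class counts must be non-negative")
        if c > 0:
            p = c / total
            h -= p * math.log2(p)
    return h


@dataclass
class TreeNode:
    """A split or leaf node.

    ``branches`` is keyed ``"le"``/``"gt"`` for numeric splits and by the
    attribute's (string) values for categorical splits.  ``class_counts``
    holds the training class distribution at the node, so any node can
    act as a majority-vote leaf when descent cannot continue.
    """

    kind: str  # "SPLIT_NUMERIC" | "SPLIT_CATEGORICAL" | "LEAF"
    class_counts: dict[str, float]
    attribute: Optional[str] = None
    threshold: Optional[float] = None
    branches: dict[str, "TreeNode"] = field(default_factory=dict)

    @property
    def leaf_class(self) -> str:
        """Majority class; ties go to the lexicographically first label."""
        best = max(self.class_counts.values())
        return min(l for l, c in self.class_counts.items() if c == best)

    @property
    def n_leaves(self) -> int:
        if self.kind == "LEAF":
            return 1
        return sum(child.n_leaves for child in self.branches.values())

    def depth(self) -> int:
        if self.kind == "LEAF":
            return 0
        return 1 + max(child.depth() for child in self.branches.values())

    def thresholds_for(self, attribute_prefix: str) -> list[float]:
        """All numeric cut points in the tree on attributes whose name
        starts with ``attribute_prefix``."""
        out = []
        if self.kind == "SPLIT_NUMERIC" and self.attribute.startswith(
                attribute_prefix):
            out.append(float(self.threshold))
        for child in self.branches.values():
            out.extend(child.thresholds_for(attribute_prefix))
        return out

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        d: dict = {"kind": self.kind, "class_counts": dict(self.class_counts)}
        if self.kind != "LEAF":
            d["attribute"] = self.attribute
            if self.kind == "SPLIT_NUMERIC":
                d["threshold"] = self.threshold
            d["branches"] = {k: v.to_dict() for k, v in self.branches.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TreeNode":
        node = cls(kind=d["kind"], class_counts=dict(d["class_counts"]),
                   attribute=d.get("attribute"), threshold=d.get("threshold"))
        node.branches = {k: cls.from_dict(v)
                         for k, v in d.get("branches", {}).items()}
        return node

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TreeNode":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class SplitChoice:
    attribute: str
    kind: str  # as TreeNode.kind
    gain: float
    threshold: Optional[float] = None


def _counts(y: np.ndarray, w: np.ndarray, labels: Sequence[str]) -> dict[str, float]:
    return {lab: float(w[y == lab].sum()) for lab in labels
            if (y == lab).any()}


def _weighted_entropy_partition(parts: Iterable[dict[str, float]],
                                total: float) -> float:
    h = 0.0
    for counts in parts:
        sub = sum(counts.values())
        if sub > 0:
            h += (sub / total) * entropy(counts)
    return h


def _prepare_columns(X: pd.DataFrame,
                     attributes: Sequence[str]) -> dict[str, np.ndarray]:
    """One numpy column per attribute: float for numeric, str otherwise."""
    cols: dict[str, np.ndarray] = {}
    for attr in attributes:
        col = X[attr].to_numpy()
        if np.issubdtype(col.dtype, np.number):
            cols[attr] = col.astype(float)
        else:
            cols[attr] = np.asarray([str(v) for v in col], dtype=object)
    return cols


def _best_split_arrays(cols: dict[str, np.ndarray], y: np.ndarray,
                       w: np.ndarray, min_leaf: float) -> Optional[SplitChoice]:
    labels = sorted(set(y))
    if len(labels) < 2:
        return None
    total = float(w.sum())
    parent_h = entropy(_counts(y, w, labels))
    best: Optional[SplitChoice] = None
    for attr, col in cols.items():
        if col.dtype == object:
            values = sorted(set(col))
            if len(values) < 2:
                continue
            parts = [_counts(y[col == v], w[col == v], labels) for v in values]
            if any(sum(p.values()) < min_leaf for p in parts):
                continue
            gain = parent_h - _weighted_entropy_partition(parts, total)
            if gain > _EPS and (best is None or gain > best.gain + _EPS):
                best = SplitChoice(attribute=attr, kind="SPLIT_CATEGORICAL",
                                   gain=gain)
        else:
            cand = _best_numeric(col, y, w, labels, parent_h, total, min_leaf)
            if cand is not None and (best is None or cand[0] > best.gain + _EPS):
                best = SplitChoice(attribute=attr, kind="SPLIT_NUMERIC",
                                   gain=cand[0], threshold=cand[1])
    return best


def best_split(
    X: pd.DataFrame,
    y: Sequence[str],
    attributes: Optional[Sequence[str]] = None,
    sample_weight: Optional[Sequence[float]] = None,
    min_leaf: float = 1.0,
) -> Optional[SplitChoice]:
    """Exhaustively search all attributes and cut points for maximum gain.

    Returns ``None`` when no candidate split has positive information
    gain or satisfies the ``min_leaf`` constraint on every child.
    """
    attributes = list(attributes) if attributes is not None else list(X.columns)
    y = np.asarray([str(v) for v in y], dtype=object)
    if len(y) == 0:
        raise ValueError("best_split on empty dataset")
    w = (np.ones(len(y)) if sample_weight is None
         else np.asarray(sample_weight, dtype=float))
    return _best_split_arrays(_prepare_columns(X, attributes), y, w, min_leaf)


def _best_numeric(col, y, w, labels, parent_h, total, min_leaf):
    order = np.argsort(col, kind="stable")
    col, y, w = col[order], y[order], w[order]
    lab_idx = {lab: i for i, lab in enumerate(labels)}
    onehot = np.zeros((len(y), len(labels)))
    onehot[np.arange(len(y)), [lab_idx[v] for v in y]] = 1.0
    onehot *= w[:, None]
    cum = np.cumsum(onehot, axis=0)
    cum_w = np.cumsum(w)
    # boundaries between distinct consecutive values, ascending
    best_gain, best_thr = None, None
    for i in range(len(col) - 1):
        if col[i + 1] <= col[i]:
            continue
        left = dict(zip(labels, cum[i]))
        right = dict(zip(labels, cum[-1] - cum[i]))
        if cum_w[i] < min_leaf or (cum_w[-1] - cum_w[i]) < min_leaf:
            continue
        gain = parent_h - _weighted_entropy_partition((left, right), total)
        if gain > _EPS and (best_gain is None or gain > best_gain + _EPS):
            best_gain = gain
            best_thr = (col[i] + col[i + 1]) / 2.0
    if best_gain is None:
        return None
    return best_gain, float(best_thr)


def fit_tree(
    X: pd.DataFrame,
    y: Sequence[str],
    attributes: Optional[Sequence[str]] = None,
    min_leaf: float = 2.0,
    max_depth: Optional[int] = None,
    sample_weight: Optional[Sequence[float]] = None,
) -> TreeNode:
    """Recursive partitioning by maximum information gain.

    Deterministic given the dataset and parameters, and invariant to row
    order.  ``min_leaf`` is the minimum (weighted) number of rows every
    child of a split must retain.
    """
    if len(X) == 0:
        raise ValueError("cannot fit a tree on an empty dataset")
    if len(X) != len(y):
        raise ValueError("X and y length mismatch")
    attributes = list(attributes) if attributes is not None else list(X.columns)
    y_arr = np.asarray([str(v) for v in y], dtype=object)
    w = (np.ones(len(y_arr)) if sample_weight is None
         else np.asarray(sample_weight, dtype=float))
    cols = _prepare_columns(X, attributes)

    def build(idx: np.ndarray, depth: int) -> TreeNode:
        ys, ws = y_arr[idx], w[idx]
        counts = _counts(ys, ws, sorted(set(ys)))
        node = TreeNode(kind="LEAF", class_counts=counts)
        if len(counts) < 2 or (max_depth is not None and depth >= max_depth):
            return node
        sub = {a: c[idx] for a, c in cols.items()}
        choice = _best_split_arrays(sub, ys, ws, min_leaf)
        if choice is None:
            return node
        node.kind = choice.kind
        node.attribute = choice.attribute
        col = sub[choice.attribute]
        if choice.kind == "SPLIT_NUMERIC":
            node.threshold = choice.threshold
            node.branches = {"le": build(idx[col <= choice.threshold], depth + 1),
                             "gt": build(idx[col > choice.threshold], depth + 1)}
        else:
            node.branches = {v: build(idx[col == v], depth + 1)
                             for v in sorted(set(col))}
        return node

    return build(np.arange(len(y_arr)), 0)


def predict(tree: TreeNode, row: Mapping[str, object],
            missing: str = "error") -> str:
    """Deterministic descent to a leaf-class prediction.

    ``missing`` controls behavior at a split whose attribute is absent
    (or whose categorical value was never seen in training): ``"error"``
    raises, ``"majority"`` answers with the node's majority class.
    """
    if missing not in ("error", "majority"):
        raise ValueError("missing must be 'error' or 'majority'")
    node = tree
    while node.kind != "LEAF":
        val = row.get(node.attribute) if hasattr(row, "get") else row[node.attribute]
        if node.kind == "SPLIT_NUMERIC":
            if val is None or (isinstance(val, float) and math.isnan(val)):
                branch = None
            else:
                branch = node.branches["le" if float(val) <= node.threshold
                                       else "gt"]
        else:
            branch = node.branches.get(str(val)) if val is not None else None
        if branch is None:
            if missing == "error":
                raise KeyError(
                    f"cannot descend: attribute {node.attribute!r} missing or "
                    f"value {val!r} unseen")
            return node.leaf_class
        node = branch
    return node.leaf_class


def predict_frame(tree: TreeNode, X: pd.DataFrame,
                  missing: str = "error") -> list[str]:
    return [predict(tree, row, missing=missing)
            for row in X.to_dict(orient="records")]


@dataclass
class ConfusionMatrix:
    """Square count matrix oriented (predicted row, actual column)."""

    labels: list[str]
    counts: np.ndarray

    @classmethod
    def from_predictions(cls, predicted: Sequence[str], actual: Sequence[str],
                         labels: Optional[Sequence[str]] = None
                         ) -> "ConfusionMatrix":
        if len(predicted) != len(actual):
            raise ValueError("prediction/label length mismatch")
        labs = (list(labels) if labels is not None
                else sorted({str(v) for v in actual} | {str(v) for v in predicted}))
        idx = {l: i for i, l in enumerate(labs)}
        counts = np.zeros((len(labs), len(labs)), dtype=np.int64)
        for p, a in zip(predicted, actual):
            counts[idx[str(p)], idx[str(a)]] += 1
        return cls(labels=labs, counts=counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def accuracy(self) -> float:
        return float(np.trace(self.counts)) / self.total

    def recall(self, label: str) -> float:
        j = self.labels.index(label)
        col = self.counts[:, j].sum()
        return float(self.counts[j, j]) / col if col else float("nan")

    def balanced_accuracy(self) -> float:
        """Mean per-class recall over classes that occur in the data."""
        recalls = [self.recall(l) for l in self.labels
                   if self.counts[:, self.labels.index(l)].sum() > 0]
        return float(np.mean(recalls))

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.counts, index=self.labels, columns=self.labels)
        frame.index.name = "predicted"
        frame.columns.name = "actual"
        return frame


def confusion(tree: TreeNode, X: pd.DataFrame, y: Sequence[str],
              labels: Optional[Sequence[str]] = None,
              missing: str = "error") -> ConfusionMatrix:
    return ConfusionMatrix.from_predictions(
        predict_frame(tree, X, missing=missing), [str(v) for v in y], labels)


def render(tree: TreeNode, indent: str = "|   ") -> str:
    """Indented-text diagram of a fitted tree."""
    lines: list[str] = []

    def fmt_counts(node: TreeNode) -> str:
        inner = ", ".join(f"{l}={g:g}" for l, g in sorted(node.class_counts.items()))
        return f"({inner})"

    def walk(node: TreeNode, depth: int) -> None:
        pad = indent * depth
        if node.kind == "LEAF":
            lines.append(f"{pad}-> {node.leaf_class} {fmt_counts(node)}")
            return
        if node.kind == "SPLIT_NUMERIC":
            for key, op in (("le", "<="), ("gt", ">")):
                lines.append(f"{pad}{node.attribute} {op} {node.threshold:g}")
                walk(node.branches[key], depth + 1)
        else:
            for val, child in node.branches.items():
                lines.append(f"{pad}{node.attribute} = {val}")
                walk(child, depth + 1)

    walk(tree, 0)
    return "\n".join(lines)
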