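"""Information-gain tree learner: entropy, split search, fitting, metrics."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from draize_miner.simulate import make_rulebook_dataset
from draize_miner.tree import (
    ConfusionMatrix,
    best_split,
    confusion,
    entropy,
    fit_tree,
    predict,
    predict_frame,
    render,
    TreeNode,
)


@pytest.mark.parametrize("counts,expected", [
    ({"A": 2, "B": 2}, 1.0),
    ({"A": 4}, 0.0),
    ({"A": 3, "B": 1}, 0.8113),
])
def test_entropy_values(counts, expected):
    assert entropy(counts) == pytest.approx(expected, abs=1e-4)
    # cross-check against scipy's entropy in bits
    probs = np.array(list(counts.values())) / sum(counts.values())
    assert entropy(counts) == pytest.approx(sps.entropy(probs, base=2))


def test_entropy_empty_errors():
    with pytest.raises(ValueError):
        entropy({"A": 0})


def _brute_force_best(X, y):
    """Independent exhaustive oracle: scan every attribute and midpoint,
    computing gain from first principles."""
    def h(labels):
        n = len(labels)
        return -sum((c / n) * math.log2(c / n)
                    for c in pd.Series(list(labels)).value_counts())

    parent = h(y)
    best = (None, None, -1.0)
    for attr in X.columns:
        vals = sorted(set(X[attr]))
        for lo, hi in zip(vals, vals[1:]):
            thr = (lo + hi) / 2
            left = [lab for v, lab in zip(X[attr], y) if v <= thr]
            right = [lab for v, lab in zip(X[attr], y) if v > thr]
            gain = parent - (len(left) * h(left) + len(right) * h(right)) / len(y)
            if gain > best[2] + 1e-12:
                best = (attr, thr, gain)
    return best


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_best_split_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame({
        "u": rng.integers(0, 8, 60) / 2.0,
        "v": rng.integers(0, 6, 60) / 2.0,
        "w": rng.integers(0, 4, 60) / 2.0,
    })
    y = ["pos" if (u + v > 3) != (rng.random() < 0.2) else "neg"
         for u, v in zip(X.u, X.v)]
    choice = best_split(X, y)
    attr, thr, gain = _brute_force_best(X, y)
    assert choice.attribute == attr
    assert choice.threshold == pytest.approx(thr)
    assert choice.gain == pytest.approx(gain, abs=1e-12)


def test_perfect_split_gain_equals_parent_entropy():
    X = pd.DataFrame({"flag": [0.0, 0.0, 1.0, 1.0, 1.0]})
    y = ["a", "a", "b", "b", "b"]
    choice = best_split(X, y)
    assert choice.attribute == "flag"
    assert choice.gain == pytest.approx(entropy({"a": 2, "b": 3}))


def test_gain_tie_broken_by_declaration_order():
    X = pd.DataFrame({"second": [0.0, 0.0, 1.0, 1.0],
                      "first": [0.0, 0.0, 1.0, 1.0]})
    y = ["a", "a", "b", "b"]
    assert best_split(X, y, attributes=["first", "second"]).attribute == "first"
    assert best_split(X, y, attributes=["second", "first"]).attribute == "second"


def test_pure_dataset_single_leaf():
    X = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
    tree = fit_tree(X, ["same"] * 3)
    assert tree.kind == "LEAF" and tree.leaf_class == "same"


def test_fit_invariant_to_row_shuffle():
    X, y = make_rulebook_dataset(120, seed=5)
    ref = fit_tree(X, y, min_leaf=1).to_dict()
    rng = np.random.default_rng(0)
    for _ in range(3):
        perm = rng.permutation(len(y))
        shuffled = fit_tree(X.iloc[perm].reset_index(drop=True),
                            [y[i] for i in perm], min_leaf=1)
        assert shuffled.to_dict() == ref


def test_training_accuracy_nondecreasing_in_depth():
    X, y = make_rulebook_dataset(150, seed=2)
    prev = 0.0
    for depth in (1, 2, 3, 4, 6, None):
        tree = fit_tree(X, y, min_leaf=1, max_depth=depth)
        acc = float(np.mean(np.array(predict_frame(tree, X)) == np.array(y)))
        assert acc >= prev - 1e-12
        prev = acc
    assert prev == 1.0  # labels are a function of the features


def test_matches_sklearn_reference_on_rulebook_data():
    """Independent cross-check: scikit-learn's entropy tree also reaches
    purity on the deterministic rulebook dataset."""
    from sklearn.tree import DecisionTreeClassifier

    X, y = make_rulebook_dataset(200, seed=3)
    Xn = X.drop(columns=["reversibility"]).assign(
        rev_rank=X.reversibility.map({"REVERSED_7D": 0, "REVERSED_21D": 1,
                                      "IRREVERSIBLE": 2}))
    ours = fit_tree(Xn, y, min_leaf=1)
    ours_acc = np.mean(np.array(predict_frame(ours, Xn)) == np.array(y))
    ref = DecisionTreeClassifier(criterion="entropy", random_state=0).fit(Xn, y)
    assert ours_acc == pytest.approx(ref.score(Xn, y)) == 1.0


def test_predict_missing_attribute_policies():
    X = pd.DataFrame({"x": [0.0, 0.0, 1.0, 1.0, 1.0]})
    tree = fit_tree(X, ["a", "a", "b", "b", "b"], min_leaf=1)
    with pytest.raises(KeyError):
        predict(tree, {}, missing="error")
    assert predict(tree, {}, missing="majority") == "b"


def test_confusion_shapes_and_conservation():
    X, y = make_rulebook_dataset(100, seed=7)
    tree = fit_tree(X, y, min_leaf=1)
    cm = confusion(tree, X, y)
    assert cm.total == len(y)
    assert np.trace(cm.counts) == cm.total  # perfect on training data
    assert cm.accuracy() == 1.0 and cm.balanced_accuracy() == 1.0


def test_confusion_orientation_predicted_rows():
    cm = ConfusionMatrix.from_predictions(
        predicted=["a", "a", "b"], actual=["a", "b", "b"], labels=["a", "b"])
    assert cm.counts[0, 1] == 1  # predicted a, actually b
    assert cm.counts[1, 0] == 0


def test_serialization_and_render_round_trip(tmp_path):
    X, y = make_rulebook_dataset(80, seed=1)
    tree = fit_tree(X, y, min_leaf=1)
    path = tmp_path / "tree.json"
    tree.to_json(path)
    clone = TreeNode.from_json(path)
    assert clone.to_dict() == tree.to_dict()
    text = render(tree)
    assert "->" in text and tree.leaf_class in text or "<=" in text
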