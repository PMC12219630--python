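"""Exact SHAP values for scikit-learn decision-tree ensembles.

Implements the path-dependent polynomial-time TreeSHAP algorithm
(Lundberg et al., 2018, algorithm 2): for one decision tree the Shapley
value of every feature is computed exactly with respect to the tree's
own conditional expectation function, where "missing" features are
marginalized by the training cover (weighted sample counts) stored in
each node.  For ensembles whose probability output is the average of
per-tree leaf class frequencies (DecisionTree, RandomForest,
ExtraTrees, Bagging of trees), averaging per-tree SHAP values yields
attributions that are *exactly* additive in probability space:

    base_value + sum(phi) == predict_proba(x)[positive class]

This additivity is asserted by the test suite at 1e-6 per model/sample
and is the contract the explanation layer relies on.
"""

from __future__ import annotations

from typing import List, Tuple

import numpy as np
from sklearn.ensemble import (
    BaggingClassifier,
    ExtraTreesClassifier,
    RandomForestClassifier,
)
from sklearn.tree import DecisionTreeClassifier

# path element slots
_FEAT, _ZERO, _ONE, _W = 0, 1, 2, 3


def _extend(path: list, pz: float, po: float, pi: int) -> None:
    l = len(path)
    path.append([pi, pz, po, 1.0 if l == 0 else 0.0])
    for i in range(l - 1, -1, -1):
        path[i + 1][_W] += po * path[i][_W] * (i + 1) / (l + 1)
        path[i][_W] = pz * path[i][_W] * (l - i) / (l + 1)


def _unwind(path: list, path_index: int) -> None:
    depth = len(path) - 1
    one = path[path_index][_ONE]
    zero = path[path_index][_ZERO]
    nxt = path[depth][_W]
    for i in range(depth - 1, -1, -1):
        if one != 0:
            tmp = path[i][_W]
            path[i][_W] = nxt * (depth + 1) / ((i + 1) * one)
            nxt = tmp - path[i][_W] * zero * (depth - i) / (depth + 1)
        else:
            path[i][_W] = path[i][_W] * (depth + 1) / (zero * (depth - i))
    for i in range(path_index, depth):
        path[i][_FEAT] = path[i + 1][_FEAT]
        path[i][_ZERO] = path[i + 1][_ZERO]
        path[i][_ONE] = path[i + 1][_ONE]
    path.pop()


def _unwound_sum(path: list, path_index: int) -> float:
    depth = len(path) - 1
    one = path[path_index][_ONE]
    zero = path[path_index][_ZERO]
    nxt = path[depth][_W]
    total = 0.0
    for i in range(depth - 1, -1, -1):
        if one != 0:
            tmp = nxt * (depth + 1) / ((i + 1) * one)
            total += tmp
            nxt = path[i][_W] - tmp * zero * (depth - i) / (depth + 1)
        else:
            total += path[i][_W] * (depth + 1) / (zero * (depth - i))
    return total


def _recurse(
    tree,
    leaf_values: np.ndarray,
    x: np.ndarray,
    phi: np.ndarray,
    node: int,
    path: list,
    pz: float,
    po: float,
    pi: int,
) -> None:
    path = [elem[:] for elem in path]
    _extend(path, pz, po, pi)
    left, right = tree.children_left[node], tree.children_right[node]
    if left < 0:  # leaf
        for i in range(1, len(path)):
            w = _unwound_sum(path, i)
            phi[path[i][_FEAT]] += (
                w * (path[i][_ONE] - path[i][_ZERO]) * leaf_values[node]
            )
        return
    feat = tree.feature[node]
    hot, cold = (
        (left, right) if x[feat] <= tree.threshold[node] else (right, left)
    )
    iz, io = 1.0, 1.0
    for k in range(1, len(path)):
        if path[k][_FEAT] == feat:
            iz, io = path[k][_ZERO], path[k][_ONE]
            _unwind(path, k)
            break
    w_node = tree.weighted_n_node_samples[node]
    _recurse(
        tree, leaf_values, x, phi, hot, path,
        iz * tree.weighted_n_node_samples[hot] / w_node, io, feat,
    )
    _recurse(
        tree, leaf_values, x, phi, cold, path,
        iz * tree.weighted_n_node_samples[cold] / w_node, 0.0, feat,
    )


def _leaf_values(estimator: DecisionTreeClassifier, positive_class) -> np.ndarray:
    """Per-node probability of the positive class."""
    value = estimator.tree_.value  # (n_nodes, 1, n_classes)
    v = value[:, 0, :]
    v = v / v.sum(axis=1, keepdims=True)
    cls = list(estimator.classes_)
    if positive_class not in cls:
        raise ValueError(f"class {positive_class!r} not in estimator classes")
    return v[:, cls.index(positive_class)]


def shap_values_single_tree(
    estimator: DecisionTreeClassifier, X: np.ndarray, positive_class=1
) -> Tuple[np.ndarray, float]:
    """Exact SHAP values (n_samples, n_features) and base value of one tree."""
    tree = estimator.tree_
    lv = _leaf_values(estimator, positive_class)
    leaves = tree.children_left < 0
    base = float(
        np.sum(lv[leaves] * tree.weighted_n_node_samples[leaves])
        / tree.weighted_n_node_samples[0]
    )
    X = np.asarray(X, dtype=float)
    phi = np.zeros((X.shape[0], estimator.n_features_in_))
    for i in range(X.shape[0]):
        _recurse(tree, lv, X[i], phi[i], 0, [], 1.0, 1.0, -1)
    return phi, base


def _component_trees(model) -> List[DecisionTreeClassifier]:
    if isinstance(model, DecisionTreeClassifier):
        return [model]
    if isinstance(
        model, (RandomForestClassifier, ExtraTreesClassifier, BaggingClassifier)
    ):
        trees = list(model.estimators_)
        if not all(isinstance(t, DecisionTreeClassifier) for t in trees):
            raise TypeError("ensemble members must be decision-tree classifiers")
        return trees
    raise TypeError(
        f"{type(model).__name__} is not a supported tree model "
        "(probability output must be an average of leaf class frequencies)"
    )


def is_tree_model(model) -> bool:
    try:
        _component_trees(model)
        return True
    except TypeError:
        return False


def shap_values(model, X, positive_class=1) -> Tuple[np.ndarray, float]:
    """SHAP values and base value of a tree model in probability space.

    For ensembles the per-tree attributions are averaged, matching the
    probability-averaging of ``predict_proba``.
    """
    X = np.asarray(X, dtype=float)
    trees = _component_trees(model)
    phi = np.zeros((X.shape[0], X.shape[1]))
    base = 0.0
    for t in trees:
        p, b = shap_values_single_tree(t, X, positive_class)
        phi += p
        base += b
    return phi / len(trees), base / len(trees)


# ---------------------------------------------------------------------------
# brute-force oracle (exponential; for testing only)


def _expvalue(estimator, x: np.ndarray, subset: frozenset, positive_class=1) -> float:
    """Conditional expectation of the tree for features in ``subset`` known."""
    tree = estimator.tree_
    lv = _leaf_values(estimator, positive_class)

    def rec(node: int) -> float:
        left = tree.children_left[node]
        if left < 0:
            return lv[node]
        right = tree.children_right[node]
        feat = tree.feature[node]
        if feat in subset:
            child = left if x[feat] <= tree.threshold[node] else right
            return rec(child)
        w = tree.weighted_n_node_samples
        return (
            rec(left) * w[left] + rec(right) * w[right]
        ) / w[node]

    return rec(0)


def brute_force_shap(
    estimator, x: np.ndarray, n_features: int, positive_class=1
) -> np.ndarray:
    """Exact Shapley values by subset enumeration (oracle for small trees)."""
    import itertools
    from math import factorial

    x = np.asarray(x, dtype=float)
    phi = np.zeros(n_features)
    feats = list(range(n_features))
    for i in feats:
        rest = [f for f in feats if f != i]
        for r in range(len(rest) + 1):
            for s in itertools.combinations(rest, r):
                weight = (
                    factorial(len(s))
                    * factorial(n_features - len(s) - 1)
                    / factorial(n_features)
                )
                gain = _expvalue(
                    estimator, x, frozenset(s) | {i}, positive_class
                ) - _expvalue(estimator, x, frozenset(s), positive_class)
                phi[i] += weight * gain
    return phi
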