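"""Four small-sample classifiers and their evaluation protocol.

The candidate feature sets are fitted to a linear-kernel SVM, an L2
logistic regression (liblinear solver), a k-nearest-neighbour classifier
(k=5, Euclidean distance) and a depth-limited Gini decision tree.  The
tree depth follows the feature-set size: depth 3 for sets of 4 or 5
features, depth 2 otherwise, so each selected feature can be used once
without giving the tree room to overfit.

Two accuracy estimates are reported per model and feature set: mean
leave-one-out (LOO) accuracy, and the mean over 100 rounds of stratified
80% train / 20% test splits.  The margin- and distance-based models (SVM,
LR, KNN) see features standardized with training-fold statistics only;
trees are scale-invariant and run unscaled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import LeaveOneOut, StratifiedShuffleSplit
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "MODEL_KINDS",
    "tree_max_depth",
    "make_model",
    "fit_models",
    "loo_accuracy",
    "split_accuracy",
    "evaluate_feature_sets",
    "report_coefficients",
    "TreeExport",
    "export_tree",
]

MODEL_KINDS = ("svm_linear", "logreg_l2", "knn", "tree")
#: display order convention for count pairs: (unruptured, ruptured)
CLASS_ORDER = ("unruptured", "ruptured")


def tree_max_depth(n_features: int) -> int:
    """Depth 3 for feature sets of size >= 4, otherwise depth 2."""
    return 3 if n_features >= 4 else 2


def make_model(kind: str, n_features: int, seed: int = 0):
    """A fresh unfitted estimator of the given kind."""
    if kind == "svm_linear":
        return Pipeline([("scale", StandardScaler()), ("clf", SVC(kernel="linear"))])
    if kind == "logreg_l2":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                # L2 penalty is the liblinear default
                ("clf", LogisticRegression(solver="liblinear")),
            ]
        )
    if kind == "knn":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("clf", KNeighborsClassifier(n_neighbors=5, metric="euclidean")),
            ]
        )
    if kind == "tree":
        return DecisionTreeClassifier(
            criterion="gini", max_depth=tree_max_depth(n_features), random_state=seed
        )
    raise ValueError(f"unknown model kind {kind!r}")


def _check_classes(y: np.ndarray, context: str = "training data") -> None:
    values, counts = np.unique(y, return_counts=True)
    if len(values) < 2:
        raise ValueError(f"single-class {context} (only {values[0]!r} present)")
    if counts.min() < 2:
        raise ValueError(f"{context} has fewer than 2 cases of class {values[np.argmin(counts)]!r}")


def fit_models(matrix: pd.DataFrame, labels, seed: int = 0) -> dict:
    """Fit all four models on the full data; returns kind -> fitted estimator."""
    y = np.asarray(labels)
    _check_classes(y)
    X = matrix.to_numpy(dtype=float)
    fitted = {}
    for kind in MODEL_KINDS:
        model = make_model(kind, matrix.shape[1], seed)
        fitted[kind] = model.fit(X, y)
    return fitted


def loo_accuracy(matrix: pd.DataFrame, labels, kind: str, seed: int = 0) -> float:
    """Leave-one-out accuracy in percent (n folds for n cases)."""
    y = np.asarray(labels)
    X = matrix.to_numpy(dtype=float)
    if len(y) < 3:
        raise ValueError("need at least 3 cases for leave-one-out")
    correct = 0
    for fold, (train, test) in enumerate(LeaveOneOut().split(X)):
        ytr = y[train]
        try:
            _check_classes(ytr, context=f"training fold {fold}")
        except ValueError as exc:
            raise ValueError(str(exc)) from None
        model = make_model(kind, X.shape[1], seed)
        model.fit(X[train], ytr)
        correct += int(model.predict(X[test])[0] == y[test][0])
    return 100.0 * correct / len(y)


def split_accuracy(
    matrix: pd.DataFrame,
    labels,
    kind: str,
    rounds: int = 100,
    seed: int = 0,
) -> float:
    """Mean accuracy over stratified 80/20 train/test splits, in percent."""
    y = np.asarray(labels)
    X = matrix.to_numpy(dtype=float)
    if len(y) < 5:
        raise ValueError("need at least 5 cases for repeated splitting")
    splitter = StratifiedShuffleSplit(n_splits=rounds, test_size=0.2, random_state=seed)
    accs = []
    for train, test in splitter.split(X, y):
        model = make_model(kind, X.shape[1], seed)
        model.fit(X[train], y[train])
        accs.append(np.mean(model.predict(X[test]) == y[test]))
    return 100.0 * float(np.mean(accs))


def evaluate_feature_sets(
    matrix: pd.DataFrame,
    labels,
    feature_sets: dict,
    rounds: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """LOO and repeated-split accuracy for every model x feature set.

    ``feature_sets`` maps a set name to a list of feature column names.
    Returns a tidy frame with columns: feature_set, model, n_features,
    loo_accuracy, split_accuracy (percent).
    """
    rows = []
    for set_name, names in feature_sets.items():
        sub = matrix[list(names)]
        for kind in MODEL_KINDS:
            rows.append(
                {
                    "feature_set": set_name,
                    "model": kind,
                    "n_features": len(names),
                    "loo_accuracy": loo_accuracy(sub, labels, kind, seed),
                    "split_accuracy": split_accuracy(sub, labels, kind, rounds, seed),
                }
            )
    return pd.DataFrame(rows)


def report_coefficients(matrix: pd.DataFrame, labels, seed: int = 0) -> pd.DataFrame:
    """Signed coefficients of the linear SVM and logistic regression.

    Both models are fitted on the full standardized data; the sign pattern
    indicates the direction each feature pushes the rupture prediction
    (positive = toward the ruptured class).
    """
    fitted = fit_models(matrix, labels, seed)
    out = {}
    for col, kind in (("SVM", "svm_linear"), ("LR", "logreg_l2")):
        clf = fitted[kind].named_steps["clf"]
        coef = clf.coef_[0]
        # sklearn orients coefficients toward classes_[1]; flip if needed so
        # positive always means "toward ruptured"
        if clf.classes_[1] != "ruptured":
            coef = -coef
        out[col] = coef
    return pd.DataFrame(out, index=list(matrix.columns))


# ---------------------------------------------------------------------------
# decision-tree export


@dataclass
class TreeNode:
    node_id: int
    depth: int
    samples: int
    value: tuple  # (unruptured count, ruptured count)
    klass: str  # majority class
    feature: str | None = None  # split feature (non-leaf only)
    threshold: float | None = None
    left: int | None = None  # child node ids
    right: int | None = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None


@dataclass
class TreeExport:
    """Human-readable structure of a fitted decision tree."""

    nodes: list
    max_depth: int

    def render(self) -> str:
        lines = []

        def walk(node_id: int, indent: int):
            node = self.nodes[node_id]
            pad = "  " * indent
            head = (
                f"{node.feature} <= {node.threshold:.3f}"
                if not node.is_leaf
                else "leaf"
            )
            lines.append(
                f"{pad}{head} | samples={node.samples} "
                f"value={list(node.value)} class={node.klass}"
            )
            if not node.is_leaf:
                walk(node.left, indent + 1)
                walk(node.right, indent + 1)

        walk(0, 0)
        return "\n".join(lines)


def export_tree(tree: DecisionTreeClassifier, feature_names) -> TreeExport:
    """Walk a fitted sklearn tree into :class:`TreeExport`.

    ``value`` pairs are reported as (unruptured count, ruptured count) and
    the node class follows the majority rule, exactly as the rendered tree
    is read clinically.
    """
    t = tree.tree_
    classes = list(tree.classes_)
    order = [classes.index(c) for c in CLASS_ORDER if c in classes]

    depths = np.zeros(t.node_count, dtype=int)
    for i in range(t.node_count):
        left, right = t.children_left[i], t.children_right[i]
        for child in (left, right):
            if child != -1:
                depths[child] = depths[i] + 1

    nodes = []
    for i in range(t.node_count):
        raw = np.asarray(t.value[i][0], dtype=float)
        if raw.sum() <= 1.0 + 1e-9:  # stored as per-node class fractions
            raw = raw * t.weighted_n_node_samples[i]
        counts = np.round(raw).astype(int)
        pair = tuple(int(counts[j]) for j in order)
        majority = (
            CLASS_ORDER[int(np.argmax(pair))]
            if len(pair) == 2
            else classes[int(np.argmax(counts))]
        )
        leaf = t.children_left[i] == -1
        nodes.append(
            TreeNode(
                node_id=i,
                depth=int(depths[i]),
                samples=int(t.n_node_samples[i]),
                value=pair,
                klass=majority,
                feature=None if leaf else feature_names[t.feature[i]],
                threshold=None if leaf else float(t.threshold[i]),
                left=None if leaf else int(t.children_left[i]),
                right=None if leaf else int(t.children_right[i]),
            )
        )
    return TreeExport(nodes=nodes, max_depth=int(depths.max()))
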