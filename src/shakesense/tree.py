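"""Binary CART-style decision tree with Gini impurity, built from scratch.

The split search is exhaustive: every feature, every midpoint between
consecutive distinct sorted values.  Ties in impurity decrease are broken
deterministically (lower feature index, then smaller threshold), so fitting
is a pure function of the data.  The default depth cap is 2, matching the
interpretable two-level trees used for on-device shaking detection; leaf
ties predict the aggressive class, favoring sensitivity in a safety
application.

Also provides the segment-level 70/30 stratified train/test split (with an
optional participant-grouped variant) and impurity-based feature importance.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

__all__ = [
    "Leaf",
    "InternalNode",
    "DecisionTree",
    "SplitSpec",
    "gini",
    "best_split",
    "fit_tree",
    "predict",
    "split_data",
    "feature_importance",
]


def gini(counts: Sequence[int]) -> float:
    """Gini impurity ``1 - sum(p_i^2)`` of a node's class counts.

    Bounded by 0.5 for two classes; 0 for a pure node.
    """
    c = np.asarray(counts, dtype=float)
    if np.any(c < 0):
        raise ValueError("class counts must be nonnegative")
    total = c.sum()
    if total == 0:
        raise ValueError("at least one class count must be positive")
    p = c / total
    return float(1.0 - np.sum(p * p))


@dataclass(frozen=True)
class SplitSpec:
    """A candidate split: rows with ``value <= threshold`` go left."""

    feature_index: int
    threshold: float
    impurity_decrease: float

    def __post_init__(self) -> None:
        if self.impurity_decrease < 0:
            raise ValueError("impurity_decrease must be nonnegative")


@dataclass
class Leaf:
    counts: tuple[int, int]  # (non-aggressive, aggressive)
    prediction: int

    @property
    def n(self) -> int:
        return sum(self.counts)


@dataclass
class InternalNode:
    feature_index: int
    threshold: float
    impurity_decrease: float
    counts: tuple[int, int]
    left: Union["InternalNode", Leaf]
    right: Union["InternalNode", Leaf]

    @property
    def n(self) -> int:
        return sum(self.counts)


Node = Union[InternalNode, Leaf]


@dataclass
class DecisionTree:
    """A fitted depth-capped binary tree over feature vectors."""

    root: Node
    max_depth: int
    n_features: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        return predict(self, X)

    def depth(self) -> int:
        def _d(node: Node) -> int:
            if isinstance(node, Leaf):
                return 0
            return 1 + max(_d(node.left), _d(node.right))

        return _d(self.root)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        def _node(node: Node) -> dict:
            if isinstance(node, Leaf):
                return {"counts": list(node.counts), "class": node.prediction}
            return {
                "feature": node.feature_index,
                "threshold": node.threshold,
                "impurity_decrease": node.impurity_decrease,
                "counts": list(node.counts),
                "left": _node(node.left),
                "right": _node(node.right),
            }

        return {
            "max_depth": self.max_depth,
            "n_features": self.n_features,
            "nodes": _node(self.root),
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "DecisionTree":
        def _node(d: dict) -> Node:
            if "class" in d:
                return Leaf(counts=tuple(d["counts"]), prediction=int(d["class"]))
            return InternalNode(
                feature_index=int(d["feature"]),
                threshold=float(d["threshold"]),
                impurity_decrease=float(d["impurity_decrease"]),
                counts=tuple(d["counts"]),
                left=_node(d["left"]),
                right=_node(d["right"]),
            )

        return cls(
            root=_node(doc["nodes"]),
            max_depth=int(doc["max_depth"]),
            n_features=int(doc["n_features"]),
        )

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        return path

    @classmethod
    def load(cls, path: str | Path) -> "DecisionTree":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def _class_counts(y: np.ndarray) -> tuple[int, int]:
    y = np.asarray(y)
    return (int(np.sum(y == 0)), int(np.sum(y == 1)))


def _exact_decrease(left0: int, left1: int, right0: int, right1: int) -> Fraction:
    """Weighted Gini decrease as an exact rational, from the four cell counts."""
    n = left0 + left1 + right0 + right1
    c0, c1 = left0 + right0, left1 + right1
    parent = Fraction(n * n - c0 * c0 - c1 * c1, n * n)
    nl, nr = left0 + left1, right0 + right1
    wl = Fraction(nl * nl - left0 * left0 - left1 * left1, nl) if nl else Fraction(0)
    wr = Fraction(nr * nr - right0 * right0 - right1 * right1, nr) if nr else Fraction(0)
    return parent - (wl + wr) / n


def best_split(X: np.ndarray, y: np.ndarray) -> Optional[SplitSpec]:
    """Exhaustive best split by weighted Gini decrease.

    Candidates are midpoints between consecutive distinct sorted values of
    each feature.  Ties are broken toward the lower feature index, then the
    smaller threshold; near-ties are resolved in exact rational arithmetic so
    the tie-break never depends on floating-point rounding.  Returns None
    when no split strictly decreases the weighted impurity.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n, n_features = X.shape
    if n < 2:
        return None
    c0, c1 = _class_counts(y)
    parent = gini((c0, c1))
    # float pass: decrease for every (feature, candidate cut)
    per_feature: list[tuple[int, np.ndarray, np.ndarray, np.ndarray]] = []
    best_float = -np.inf
    for j in range(n_features):
        order = np.argsort(X[:, j], kind="stable")
        xs = X[order, j]
        ys = y[order]
        # cumulative class-1 count for left blocks of size k = 1..n-1
        cum1 = np.cumsum(ys)
        ks = np.arange(1, n)
        distinct = xs[1:] > xs[:-1]
        if not np.any(distinct):
            continue
        ks = ks[distinct]
        left1 = cum1[ks - 1]
        left0 = ks - left1
        right1 = c1 - left1
        right0 = (n - ks) - right1
        g_left = 1.0 - ((left0 / ks) ** 2 + (left1 / ks) ** 2)
        nr = n - ks
        g_right = 1.0 - ((right0 / nr) ** 2 + (right1 / nr) ** 2)
        decrease = parent - (ks * g_left + nr * g_right) / n
        per_feature.append((j, xs, ks, decrease, cum1))
        best_float = max(best_float, float(decrease.max()))
    if best_float <= 0:
        return None
    # exact pass over near-ties only (float error is << 1e-12 per value)
    tol = 1e-12
    best_exact: Optional[Fraction] = None
    best_spec: Optional[SplitSpec] = None
    for j, xs, ks, decrease, cum1 in per_feature:
        for i in np.flatnonzero(decrease >= best_float - tol):
            k = int(ks[i])
            left1 = int(cum1[k - 1])
            exact = _exact_decrease(k - left1, left1, (n - k) - (c1 - left1), c1 - left1)
            if best_exact is None or exact > best_exact:
                best_exact = exact
                best_spec = SplitSpec(
                    feature_index=j,
                    threshold=float(0.5 * (xs[k - 1] + xs[k])),
                    impurity_decrease=float(decrease[i]),
                )
    if best_exact is None or best_exact <= 0:
        return None
    return best_spec


def fit_tree(
    X: np.ndarray,
    y: np.ndarray,
    max_depth: int = 2,
    min_samples_split: int = 2,
) -> DecisionTree:
    """Recursively grow a tree until the depth cap, purity or no improving split.

    Deterministic: no randomness is involved in fitting.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or len(X) == 0:
        raise ValueError("X must be a nonempty 2-D matrix")
    if len(X) != len(y):
        raise ValueError("X and y length mismatch")
    if not set(np.unique(y)) <= {0, 1}:
        raise ValueError("y must be binary (0 = non-aggressive, 1 = aggressive)")

    def _leaf(yy: np.ndarray) -> Leaf:
        c = _class_counts(yy)
        # tie predicts aggressive: ambiguous leaves favor sensitivity
        return Leaf(counts=c, prediction=1 if c[1] >= c[0] else 0)

    def _build(XX: np.ndarray, yy: np.ndarray, depth: int) -> Node:
        counts = _class_counts(yy)
        if (
            depth >= max_depth
            or len(yy) < min_samples_split
            or counts[0] == 0
            or counts[1] == 0
        ):
            return _leaf(yy)
        sp = best_split(XX, yy)
        if sp is None:
            return _leaf(yy)
        mask = XX[:, sp.feature_index] <= sp.threshold
        return InternalNode(
            feature_index=sp.feature_index,
            threshold=sp.threshold,
            impurity_decrease=sp.impurity_decrease,
            counts=counts,
            left=_build(XX[mask], yy[mask], depth + 1),
            right=_build(XX[~mask], yy[~mask], depth + 1),
        )

    return DecisionTree(root=_build(X, y, 0), max_depth=max_depth, n_features=X.shape[1])


def predict(tree: DecisionTree, X: np.ndarray) -> np.ndarray:
    """Route each row through the tree (``value <= threshold`` goes left)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != tree.n_features:
        raise ValueError(
            f"expected feature matrix with {tree.n_features} columns, got shape {X.shape}"
        )
    out = np.empty(len(X), dtype=int)
    for i, row in enumerate(X):
        node = tree.root
        while isinstance(node, InternalNode):
            node = node.left if row[node.feature_index] <= node.threshold else node.right
        out[i] = node.prediction
    return out


def split_data(
    y: np.ndarray,
    train_frac: float = 0.7,
    seed=None,
    stratified: bool = True,
    group_ids: Optional[Sequence] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Random train/test partition; returns sorted (train_idx, test_idx).

    Stratified by class by default (segment-level).  When ``group_ids`` are
    given (e.g. participant ids), whole groups are assigned to one side so
    overlapping windows cannot leak across the split; stratification then
    applies at the group level only approximately.
    """
    y = np.asarray(y)
    n = len(y)
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must be in (0, 1)")
    rng = np.random.default_rng(seed)
    if group_ids is not None:
        groups = np.asarray(group_ids)
        if len(groups) != n:
            raise ValueError("group_ids length mismatch")
        uniq = np.unique(groups)
        order = rng.permutation(len(uniq))
        train_groups = []
        n_train = 0
        target = train_frac * n
        for gi in order:
            g = uniq[gi]
            size = int(np.sum(groups == g))
            if n_train + size <= target or n_train == 0:
                train_groups.append(g)
                n_train += size
        train_mask = np.isin(groups, train_groups)
        train_idx = np.flatnonzero(train_mask)
        test_idx = np.flatnonzero(~train_mask)
    elif stratified:
        train_parts = []
        test_parts = []
        for cls in np.unique(y):
            idx = np.flatnonzero(y == cls)
            idx = rng.permutation(idx)
            k = int(round(train_frac * len(idx)))
            train_parts.append(idx[:k])
            test_parts.append(idx[k:])
        train_idx = np.sort(np.concatenate(train_parts))
        test_idx = np.sort(np.concatenate(test_parts))
    else:
        perm = rng.permutation(n)
        k = int(round(train_frac * n))
        train_idx = np.sort(perm[:k])
        test_idx = np.sort(perm[k:])
    for cls in np.unique(y):
        if not np.any(y[train_idx] == cls) or (
            len(test_idx) > 0 and not np.any(y[test_idx] == cls)
        ):
            warnings.warn(
                f"class {cls} is absent from one side of the split", stacklevel=2
            )
    return np.sort(train_idx), np.sort(test_idx)


def feature_importance(tree: DecisionTree) -> tuple[np.ndarray, bool]:
    """Impurity-based importances: sample-weighted Gini decrease per feature.

    Returns ``(weights, normalized)``: weights sum to 1 when the tree has at
    least one internal node; a single-leaf tree yields an all-zero vector
    with ``normalized=False``.
    """
    raw = np.zeros(tree.n_features)
    total_n = tree.root.n

    def _walk(node: Node) -> None:
        if isinstance(node, Leaf):
            return
        raw[node.feature_index] += (node.n / total_n) * node.impurity_decrease
        _walk(node.left)
        _walk(node.right)

    _walk(tree.root)
    s = raw.sum()
    if s == 0:
        return raw, False
    return raw / s, True
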