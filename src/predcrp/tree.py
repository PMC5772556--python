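"""A small C4.5-style decision tree: gain-ratio splits on continuous
features at midpoints between adjacent observed values, minimum-leaf-size
stopping, and pessimistic-error pruning with the classical binomial upper
confidence bound.  Root-to-leaf paths convert into interval rules.

Deterministic: no randomness; ties between candidate splits are broken by
feature order then by smaller threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist

from .rules import Interval, Predicate, Rule


@dataclass
class TreeNode:
    feature: str | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None  # feature <= threshold
    right: "TreeNode | None" = None  # feature > threshold
    prediction: str | None = None
    class_counts: dict = field(default_factory=dict)

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    def n(self) -> int:
        return sum(self.class_counts.values())


def _entropy(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


def _class_counts(y: np.ndarray, classes: list[str]) -> np.ndarray:
    return np.array([(y == c).sum() for c in classes])


def _pessimistic_errors(errors: int, n: int, cf: float = 0.25) -> float:
    """Expected errors under the binomial upper confidence limit used by
    C4.5's error-based pruning."""
    if n == 0:
        return 0.0
    if errors >= n:
        return float(n)
    if errors == 0:
        return n * (1.0 - cf ** (1.0 / n))
    # p_U solves P(X <= errors | n, p_U) = cf
    p_u = float(beta_dist.ppf(1.0 - cf, errors + 1, n - errors))
    return n * p_u


@dataclass
class C45Config:
    min_leaf: int = 2
    min_gain: float = 1e-9
    max_depth: int | None = None
    prune: bool = True
    prune_cf: float = 0.25


class C45Tree:
    """Gain-ratio decision tree over continuous features."""

    def __init__(self, config: C45Config | None = None):
        self.config = config or C45Config()
        self.root: TreeNode | None = None
        self.classes_: list[str] = []
        self.feature_names_: list[str] = []

    # -- fitting -----------------------------------------------------------

    def fit(self, X: pd.DataFrame, y) -> "C45Tree":
        y = np.asarray(list(y), dtype=object)
        if len(X) != len(y):
            raise ValueError("X/y length mismatch")
        self.classes_ = sorted(set(y.tolist()))
        self.feature_names_ = list(X.columns)
        self.root = self._build(X.to_numpy(dtype=float), y, depth=0)
        if self.config.prune:
            self._prune(self.root)
        return self

    def _leaf(self, y: np.ndarray) -> TreeNode:
        counts = {c: int((y == c).sum()) for c in self.classes_}
        # majority; ties broken by class order for determinism
        best = max(counts.values())
        pred = next(c for c in self.classes_ if counts[c] == best)
        return TreeNode(prediction=pred, class_counts=counts)

    def _build(self, X: np.ndarray, y: np.ndarray, depth: int) -> TreeNode:
        cfg = self.config
        counts = _class_counts(y, self.classes_)
        if (
            (counts > 0).sum() <= 1
            or len(y) < 2 * cfg.min_leaf
            or (cfg.max_depth is not None and depth >= cfg.max_depth)
        ):
            return self._leaf(y)

        parent_entropy = _entropy(counts)
        best = None  # (gain_ratio, gain, fi, thr, mask)
        for fi in range(X.shape[1]):
            col = X[:, fi]
            order = np.argsort(col, kind="stable")
            vals = col[order]
            distinct = np.unique(vals)
            if len(distinct) < 2:
                continue
            for a, b in zip(distinct[:-1], distinct[1:]):
                thr = (a + b) / 2.0
                mask = col <= thr
                nl = int(mask.sum())
                nr = len(y) - nl
                if nl < cfg.min_leaf or nr < cfg.min_leaf:
                    continue
                hl = _entropy(_class_counts(y[mask], self.classes_))
                hr = _entropy(_class_counts(y[~mask], self.classes_))
                gain = parent_entropy - (nl * hl + nr * hr) / len(y)
                if gain <= cfg.min_gain:
                    continue
                pl = nl / len(y)
                split_info = -(pl * math.log2(pl) + (1 - pl) * math.log2(1 - pl))
                ratio = gain / split_info if split_info > 0 else 0.0
                key = (ratio, gain, -fi, -thr)
                if best is None or key > best[0]:
                    best = (key, fi, thr, mask)
        if best is None:
            return self._leaf(y)
        _, fi, thr, mask = best
        node = TreeNode(
            feature=self.feature_names_[fi],
            threshold=float(thr),
            class_counts={c: int((y == c).sum()) for c in self.classes_},
        )
        node.left = self._build(X[mask], y[mask], depth + 1)
        node.right = self._build(X[~mask], y[~mask], depth + 1)
        return node

    def _prune(self, node: TreeNode) -> float:
        """Returns pessimistic error estimate of the (possibly collapsed)
        subtree; collapses a split when a leaf would not be worse."""
        n = node.n()
        counts = node.class_counts
        leaf_errors = n - max(counts.values()) if counts else 0
        leaf_est = _pessimistic_errors(leaf_errors, n, self.config.prune_cf)
        if node.is_leaf:
            return leaf_est
        subtree_est = self._prune(node.left) + self._prune(node.right)
        if leaf_est <= subtree_est:
            best = max(counts.values())
            node.prediction = next(c for c in self.classes_ if counts[c] == best)
            node.feature = None
            node.threshold = None
            node.left = node.right = None
            return leaf_est
        return subtree_est

    # -- prediction & rules ------------------------------------------------

    def predict_one(self, values) -> str:
        node = self.root
        if node is None:
            raise ValueError("tree is not fitted")
        while not node.is_leaf:
            node = node.left if float(values[node.feature]) <= node.threshold else node.right
        return node.prediction

    def predict(self, X: pd.DataFrame) -> list[str]:
        return [self.predict_one(row) for _, row in X.iterrows()]

    def depth(self) -> int:
        def d(node):
            return 0 if node.is_leaf else 1 + max(d(node.left), d(node.right))

        return d(self.root)

    def leaves(self) -> list[TreeNode]:
        out: list[TreeNode] = []

        def walk(node):
            if node.is_leaf:
                out.append(node)
            else:
                walk(node.left)
                walk(node.right)

        walk(self.root)
        return out


def extract_rules(tree: C45Tree, X: pd.DataFrame | None = None, y=None) -> list[Rule]:
    """One rule per leaf: the root-to-leaf conjunction with redundant bounds
    on each feature collapsed into a single interval.  When a labeled
    dataset is given, per-rule stats are computed on it."""
    if tree.root is None:
        raise ValueError("tree is not fitted")
    rules: list[Rule] = []

    def walk(node: TreeNode, bounds: dict[str, tuple[float, float]]):
        if node.is_leaf:
            # left branches are <=, right branches are >, so lo is open
            preds = tuple(
                Predicate(f, (Interval(lo=lo, hi=hi, lo_closed=(lo == -math.inf)),))
                for f, (lo, hi) in sorted(bounds.items())
            ) or (Predicate("__any__", (Interval(),)),)
            rules.append(
                Rule(
                    name=f"path{len(rules) + 1}",
                    predicates=preds,
                    consequent=node.prediction,
                    stats=dict(node.class_counts),
                )
            )
            return
        lo, hi = bounds.get(node.feature, (-math.inf, math.inf))
        left_bounds = dict(bounds)
        left_bounds[node.feature] = (lo, min(hi, node.threshold))
        walk(node.left, left_bounds)
        right_bounds = dict(bounds)
        right_bounds[node.feature] = (max(lo, node.threshold), hi)
        walk(node.right, right_bounds)

    walk(tree.root, {})

    if X is not None and y is not None:
        y = list(y)
        for rule in rules:
            mask = [
                all(p.feature == "__any__" or p.holds(row) for p in rule.predicates)
                for _, row in X.iterrows()
            ]
            n_match = sum(mask)
            correct = sum(1 for m, lab in zip(mask, y) if m and lab == rule.consequent)
            rule.stats = {
                "coverage_count": correct,
                "covered_class_total": y.count(rule.consequent),
                "correct": correct,
                "covered_total": n_match,
            }
    return rules
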