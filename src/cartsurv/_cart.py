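"""Classification-tree core for binary features.

All tree features here are 0/1 biomarker indicators, so any tree is a
function of the distinct feature patterns only.  Growth (Gini), weakest-link
cost-complexity pruning and cross-validated subtree selection therefore
operate on pattern count tables, which makes the thousands of tree builds of
the permutation correction cheap.  The implementation follows the classic
CART recipe; agreement with scikit-learn's DecisionTreeClassifier (training
error, pruning behavior, selected partitions) is asserted in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["PatternData", "grow_tree", "collapse_alphas",
           "predict_patterns", "tree_error", "n_leaves_at"]

_EPS = 1e-12


@dataclass
class _Node:
    feature: int = -1            # -1 for leaves
    low: "_Node | None" = None
    high: "_Node | None" = None
    pats: np.ndarray | None = None  # compressed pattern ids in this node
    n: float = 0.0
    pos: float = 0.0
    g: float = math.inf          # alpha at which this split collapses

    @property
    def is_leaf(self) -> bool:
        return self.feature < 0

    def majority(self) -> float:
        # ties predict the negative (survived) class
        return 1.0 if self.pos * 2.0 > self.n else 0.0


@dataclass
class PatternData:
    """Count tables over the distinct binary feature patterns."""

    codes: np.ndarray       # per-row compressed pattern id
    bits: np.ndarray        # (n_patterns, k) 0/1 feature values per pattern
    n_features: int

    @classmethod
    def from_matrix(cls, X: np.ndarray) -> "PatternData":
        X = np.asarray(X, dtype=float)
        n, k = X.shape
        raw = (X.astype(np.int64) @ (1 << np.arange(k, dtype=np.int64)))
        uniq, codes = np.unique(raw, return_inverse=True)
        bits = ((uniq[:, None] >> np.arange(k)) & 1).astype(np.int8)
        return cls(codes=codes, bits=bits, n_features=k)

    def counts(self, y: np.ndarray, mask: np.ndarray | None = None):
        codes = self.codes if mask is None else self.codes[mask]
        yy = y if mask is None else y[mask]
        m = len(self.bits)
        tot = np.bincount(codes, minlength=m).astype(float)
        pos = np.bincount(codes, weights=yy, minlength=m)
        return pos, tot


def _gini_total(pos: float, n: float) -> float:
    if n <= 0:
        return 0.0
    return 2.0 * pos * (n - pos) / n


def grow_tree(data: PatternData, pos: np.ndarray, tot: np.ndarray,
              min_leaf: int) -> _Node:
    """Grow a Gini tree over the pattern counts (deterministic: ties go to
    the lowest feature index)."""

    def build(pats: np.ndarray) -> _Node:
        n = float(tot[pats].sum())
        p = float(pos[pats].sum())
        node = _Node(pats=pats, n=n, pos=p)
        if n < 2 * min_leaf or p <= 0.0 or p >= n:
            return node
        parent_imp = _gini_total(p, n)
        # zero-gain splits are admissible (an XOR-type signal has zero
        # marginal gain); the pruning stage removes unhelpful ones
        best_gain, best_f = -1.0, -1
        for f in range(data.n_features):
            hi = pats[data.bits[pats, f] == 1]
            lo = pats[data.bits[pats, f] == 0]
            n_hi = float(tot[hi].sum())
            n_lo = n - n_hi
            if n_hi < min_leaf or n_lo < min_leaf:
                continue
            p_hi = float(pos[hi].sum())
            gain = parent_imp - _gini_total(p_hi, n_hi) \
                - _gini_total(p - p_hi, n_lo)
            if gain > best_gain:
                best_gain, best_f = gain, f
        if best_f < 0:
            return node
        node.feature = best_f
        node.low = build(pats[data.bits[pats, best_f] == 0])
        node.high = build(pats[data.bits[pats, best_f] == 1])
        return node

    return build(np.arange(len(data.bits)))


def collapse_alphas(root: _Node, n_total: float) -> np.ndarray:
    """Weakest-link pruning: annotate each internal node with the cost-
    complexity alpha at which its split collapses; return the increasing
    sequence of pruning alphas (0 first, root-collapse last)."""
    alphas = [0.0]
    if root.is_leaf:
        return np.asarray(alphas)

    def leaves_risk(node: _Node, cut: float):
        """(subtree risk, leaf count) of node under collapse level ``cut``."""
        if node.is_leaf or node.g <= cut:
            return _gini_total(node.pos, node.n) / n_total, 1
        rl, ll = leaves_risk(node.low, cut)
        rh, lh = leaves_risk(node.high, cut)
        return rl + rh, ll + lh

    level = 0.0
    while not (root.g <= level):
        weakest = math.inf
        nodes = []

        def scan(node: _Node):
            nonlocal weakest, nodes
            if node.is_leaf or node.g <= level:
                return
            r_sub, n_leaves = leaves_risk(node, level)
            r_leaf = _gini_total(node.pos, node.n) / n_total
            g = (r_leaf - r_sub) / (n_leaves - 1)
            nodes.append((node, g))
            scan(node.low)
            scan(node.high)

        scan(root)
        weakest = min(g for _, g in nodes)
        for node, g in nodes:
            if g <= weakest + _EPS:
                node.g = weakest
        level = weakest
        alphas.append(weakest)
    return np.asarray(alphas)


def predict_patterns(root: _Node, n_patterns: int, alpha: float) -> np.ndarray:
    """Per-pattern predicted label of the subtree at pruning level alpha."""
    out = np.zeros(n_patterns)

    def walk(node: _Node):
        if node.is_leaf or node.g <= alpha + _EPS:
            out[node.pats] = node.majority()
            return
        walk(node.low)
        walk(node.high)

    walk(root)
    return out


def tree_error(pred: np.ndarray, pos: np.ndarray, tot: np.ndarray) -> float:
    """Misclassification count of per-pattern predictions against counts."""
    return float(np.where(pred == 1.0, tot - pos, pos).sum())


def n_leaves_at(root: _Node, alpha: float) -> int:
    if root.is_leaf or root.g <= alpha + _EPS:
        return 1
    return n_leaves_at(root.low, alpha) + n_leaves_at(root.high, alpha)
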