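"""Classification-tree construction over dichotomized biomarkers.

The tree predicts the binary three-year survival label from low/high
biomarker indicators.  It is grown by Gini-impurity splitting (scikit-learn),
pruned along the cost-complexity path, and the subtree with the lowest
10-fold cross-validated misclassification rate is selected (ties toward the
smaller tree).  Leaves are labelled A, B, C, ... in depth-first low-side-
first order; classes are then compared by Cox regression against the class
with the highest Kaplan-Meier survival at the horizon and grouped into
prognostic classes I (HRR < threshold) and II (HRR >= threshold).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._cart import (
    PatternData,
    collapse_alphas,
    grow_tree,
    n_leaves_at,
    predict_patterns,
    tree_error,
)
from ._cox import cox_fit, km_survival_at

logger = logging.getLogger(__name__)

__all__ = [
    "TreeNode",
    "CartModel",
    "build_cart",
    "assign_classes",
    "class_hrrs",
    "group_classes",
    "reference_tree",
    "ClassHRRs",
    "ClassGrouping",
]

DEFAULT_MIN_LEAF = 10
DEFAULT_CV_FOLDS = 10
DEFAULT_GROUP_THRESHOLD = 2.0
DEFAULT_HORIZON = 36.0


@dataclass
class TreeNode:
    """Binary tree node; leaves carry a class label, internal nodes a
    feature split (low -> ``low`` child, high -> ``high`` child)."""

    feature: str | None = None
    low: "TreeNode | None" = None
    high: "TreeNode | None" = None
    label: str | None = None
    n: int = 0
    death_frac: float = math.nan

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        return self.low.leaves() + self.high.leaves()

    def depth(self) -> int:
        if self.is_leaf:
            return 0
        return 1 + max(self.low.depth(), self.high.depth())


@dataclass
class CartModel:
    """Fitted classification tree over dichotomized biomarkers."""

    root: TreeNode
    features: tuple[str, ...]
    cv_error: float = math.nan
    cv_folds: int = DEFAULT_CV_FOLDS

    @property
    def leaf_labels(self) -> tuple[str, ...]:
        return tuple(leaf.label for leaf in self.root.leaves())

    @property
    def n_leaves(self) -> int:
        return len(self.root.leaves())

    def used_features(self) -> tuple[str, ...]:
        used: list[str] = []

        def walk(node: TreeNode) -> None:
            if node.is_leaf:
                return
            if node.feature not in used:
                used.append(node.feature)
            walk(node.low)
            walk(node.high)

        walk(self.root)
        return tuple(used)

    def describe(self) -> str:
        lines: list[str] = []

        def walk(node: TreeNode, indent: int, prefix: str) -> None:
            pad = "  " * indent
            if node.is_leaf:
                frac = ("?" if math.isnan(node.death_frac)
                        else f"{node.death_frac:.2f}")
                lines.append(f"{pad}{prefix}class {node.label} "
                             f"(n={node.n}, death_by_36={frac})")
            else:
                lines.append(f"{pad}{prefix}split on {node.feature}")
                walk(node.low, indent + 1, "low : ")
                walk(node.high, indent + 1, "high: ")

        walk(self.root, 0, "")
        return "\n".join(lines)

    # -- plain-text serialization -----------------------------------------
    def to_text(self) -> str:
        lines = [f"cartsurv-tree v1 cv_error={self.cv_error!r} "
                 f"cv_folds={self.cv_folds} features={','.join(self.features)}"]

        def walk(node: TreeNode, depth: int) -> None:
            if node.is_leaf:
                lines.append(f"{'  ' * depth}leaf {node.label} {node.n} "
                             f"{node.death_frac!r}")
            else:
                lines.append(f"{'  ' * depth}split {node.feature}")
                walk(node.low, depth + 1)
                walk(node.high, depth + 1)

        walk(self.root, 0)
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "CartModel":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        header = lines[0].split()
        if header[0] != "cartsurv-tree":
            raise ValueError("not a cartsurv tree file")
        meta = dict(part.split("=", 1) for part in header[2:])
        tokens = [(len(ln) - len(ln.lstrip())) // 2 for ln in lines[1:]]
        items = [ln.split() for ln in lines[1:]]
        pos = 0

        def parse(depth: int) -> TreeNode:
            nonlocal pos
            kind = items[pos][0]
            if tokens[pos] != depth:
                raise ValueError("malformed tree indentation")
            if kind == "leaf":
                node = TreeNode(label=items[pos][1], n=int(items[pos][2]),
                                death_frac=float(items[pos][3]))
                pos += 1
                return node
            feature = items[pos][1]
            pos += 1
            low = parse(depth + 1)
            high = parse(depth + 1)
            return TreeNode(feature=feature, low=low, high=high)

        root = parse(0)
        return cls(root=root,
                   features=tuple(meta["features"].split(",")),
                   cv_error=float(meta["cv_error"]),
                   cv_folds=int(meta["cv_folds"]))


def _relabel(root: TreeNode) -> None:
    """Assign class letters A, B, ... by depth-first low-first traversal."""
    counter = 0

    def walk(node: TreeNode) -> None:
        nonlocal counter
        if node.is_leaf:
            node.label = chr(ord("A") + counter)
            counter += 1
        else:
            walk(node.low)
            walk(node.high)

    walk(root)


def _extract(core_root, alpha: float, feature_names) -> TreeNode:
    """Convert the pruned pattern-tree into a TreeNode structure with
    per-leaf training counts and death fractions."""

    def walk(node) -> TreeNode:
        if node.is_leaf or node.g <= alpha + 1e-12:
            n = int(round(node.n))
            frac = node.pos / node.n if node.n else math.nan
            return TreeNode(label="?", n=n, death_frac=float(frac))
        return TreeNode(feature=feature_names[node.feature],
                        low=walk(node.low), high=walk(node.high))

    root = walk(core_root)
    _relabel(root)
    return root


def _stratified_folds(y: np.ndarray, n_folds: int, rng) -> np.ndarray:
    """Fold assignment stratified on the binary label."""
    fold = np.zeros(y.size, dtype=int)
    for cls in np.unique(y):
        idx = rng.permutation(np.flatnonzero(y == cls))
        fold[idx] = np.arange(idx.size) % n_folds
    return fold


def build_cart(
    features: pd.DataFrame,
    labels,
    cv_folds: int = DEFAULT_CV_FOLDS,
    min_leaf: int = DEFAULT_MIN_LEAF,
    seed: int = 0,
    require_split: bool = False,
) -> CartModel:
    """Grow, prune and select the classification tree.

    ``features`` holds 0/1 biomarker indicators (no missing values);
    ``labels`` the binary three-year outcome (1 = died within 36 months).
    The cost-complexity pruning sequence is evaluated by stratified
    ``cv_folds``-fold cross-validated misclassification and the subtree with
    minimal CV error is returned, ties broken toward the smaller tree.  With
    ``require_split`` the best non-trivial subtree is preferred over the
    root whenever any admissible split exists (used by the permutation
    machinery, which needs a test statistic from every dataset).
    """
    if features.shape[1] == 0:
        raise ValueError("empty feature set")
    X = features.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("features must be complete (apply exclusions first)")
    y = np.asarray(labels)
    if y.dtype == object:
        y = (y == "died_within_36").astype(float)
    y = y.astype(float)
    names = tuple(features.columns)
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0x7ee)))

    if np.unique(y).size < 2:
        root = TreeNode(label="A", n=y.size, death_frac=float(y.mean()))
        return CartModel(root=root, features=names, cv_error=0.0,
                         cv_folds=cv_folds)

    data = PatternData.from_matrix(X)
    pos_all, tot_all = data.counts(y)
    full = grow_tree(data, pos_all, tot_all, min_leaf)
    alphas = collapse_alphas(full, float(y.size))
    # evaluate at midpoints between consecutive pruning alphas (plus ends)
    cand = [0.0]
    for a, b in zip(alphas[:-1], alphas[1:]):
        cand.append((a + b) / 2.0)
    cand.append(alphas[-1] + 1e-6)
    cand = np.unique(np.asarray(cand))

    folds = _stratified_folds(y, min(cv_folds, max(2, int(y.sum()))), rng)
    n_folds = int(folds.max()) + 1
    cv_err = np.zeros(cand.size)
    m_pat = len(data.bits)
    for f in range(n_folds):
        tr = folds != f
        pos_tr, tot_tr = data.counts(y, tr)
        pos_te, tot_te = pos_all - pos_tr, tot_all - tot_tr
        fold_tree = grow_tree(data, pos_tr, tot_tr, min_leaf)
        collapse_alphas(fold_tree, float(tot_tr.sum()))
        for j, alpha in enumerate(cand):
            pred = predict_patterns(fold_tree, m_pat, alpha)
            cv_err[j] += tree_error(pred, pos_te, tot_te)
    cv_err /= y.size

    # minimal CV error; ties toward the larger alpha (smaller tree)
    best = int(np.flatnonzero(cv_err == cv_err.min())[-1])
    if require_split and n_leaves_at(full, cand[best]) < 2:
        nontrivial = [j for j in range(cand.size)
                      if n_leaves_at(full, cand[j]) >= 2]
        if nontrivial:
            best = int(min(nontrivial, key=lambda j: (cv_err[j], -cand[j])))
    root = _extract(full, cand[best], names)
    model = CartModel(root=root, features=names,
                      cv_error=float(cv_err[best]), cv_folds=n_folds)
    logger.debug("CART: %d leaves, cv_error=%.4f, features=%s",
                 model.n_leaves, model.cv_error, model.used_features())
    return model


def assign_classes(model: CartModel, features: pd.DataFrame) -> pd.Series:
    """Route patients down the tree; a missing feature on a patient's path
    leaves the class as NA (patient excluded downstream)."""
    for f in model.used_features():
        if f not in features.columns:
            raise ValueError(f"feature matrix lacks tree feature {f}")
    n = len(features)
    out = np.full(n, None, dtype=object)
    idx = np.arange(n)

    def walk(node: TreeNode, rows: np.ndarray) -> None:
        if rows.size == 0:
            return
        if node.is_leaf:
            out[rows] = node.label
            return
        vals = features[node.feature].to_numpy(dtype=float)[rows]
        missing = np.isnan(vals)
        walk(node.low, rows[(vals == 0.0) & ~missing])
        walk(node.high, rows[(vals == 1.0) & ~missing])
        # rows with missing feature stay None

    walk(model.root, idx)
    n_missing = int(sum(v is None for v in out))
    if n_missing:
        logger.info("assign_classes: %d patients unroutable (missing scores)",
                    n_missing)
    return pd.Series(out, index=features.index, dtype=object)


@dataclass
class ClassHRRs:
    """Per-class Cox hazard rate ratios against the best-surviving class."""

    reference: str
    hrrs: dict = field(default_factory=dict)   # class -> HRR (reference: 1.0)
    cis: dict = field(default_factory=dict)    # class -> (lo, hi)
    non_estimable: tuple[str, ...] = ()
    fit_converged: bool = True


def class_hrrs(classes, times, events,
               horizon: float = DEFAULT_HORIZON,
               log_warnings: bool = True) -> ClassHRRs:
    """Cox HRR of each class versus the class with the highest Kaplan-Meier
    survival at the horizon (ties toward the lexicographically first class).

    Classes without events are reported non-estimable and excluded from
    downstream grouping with a warning.
    """
    cl = pd.Series(classes).astype(object)
    mask = cl.notna().to_numpy()
    cl = cl[mask]
    t = np.asarray(times, dtype=float)[mask]
    e = np.asarray(events, dtype=float)[mask]
    labels = sorted(cl.unique())
    if len(labels) < 2:
        raise ValueError("need at least two classes for HRR estimation")
    surv = {}
    for lab in labels:
        m = (cl == lab).to_numpy()
        surv[lab] = km_survival_at(t[m], e[m], horizon)
    reference = max(labels, key=lambda lab: (surv[lab], [-ord(c) for c in lab]))
    non_est = tuple(lab for lab in labels
                    if lab != reference and e[(cl == lab).to_numpy()].sum() == 0)
    estimable = [lab for lab in labels if lab != reference
                 and lab not in non_est]
    if non_est and log_warnings:
        logger.warning("classes with no events reported non-estimable: %s",
                       non_est)
    keep = cl.isin([reference] + estimable).to_numpy()
    design = np.column_stack([(cl[keep] == lab).to_numpy(dtype=float)
                              for lab in estimable]) \
        if estimable else np.empty((int(keep.sum()), 0))
    fit = cox_fit(t[keep], e[keep], design, names=tuple(estimable))
    hrrs = {reference: 1.0}
    cis = {reference: (1.0, 1.0)}
    ci = fit.ci() if estimable else np.empty((0, 2))
    for j, lab in enumerate(estimable):
        hrrs[lab] = float(np.exp(fit.coef[j]))
        cis[lab] = (float(ci[j, 0]), float(ci[j, 1]))
    return ClassHRRs(reference=reference, hrrs=hrrs, cis=cis,
                     non_estimable=non_est, fit_converged=fit.converged)


@dataclass
class ClassGrouping:
    """Partition of tree classes into prognostic classes I and II."""

    reference_class: str
    class_hrrs: dict
    threshold: float
    group_I: tuple[str, ...]
    group_II: tuple[str, ...]
    discriminative: bool = True

    def membership(self, classes) -> pd.Series:
        cl = pd.Series(classes).astype(object)
        out = pd.Series(np.full(len(cl), None, dtype=object), index=cl.index)
        out[cl.isin(self.group_I)] = "I"
        out[cl.isin(self.group_II)] = "II"
        return out


def group_classes(hrrs: ClassHRRs | dict,
                  threshold: float = DEFAULT_GROUP_THRESHOLD,
                  reference: str | None = None,
                  log_warnings: bool = True) -> ClassGrouping:
    """Group classes by HRR similarity: HRR < threshold joins the reference
    in group I, HRR >= threshold forms group II.  A one-sided partition is
    returned as a single group flagged non-discriminative."""
    if isinstance(hrrs, ClassHRRs):
        mapping = dict(hrrs.hrrs)
        reference = hrrs.reference
    else:
        mapping = dict(hrrs)
        if reference is None:
            reference = min(mapping, key=lambda lab: (mapping[lab], lab))
        mapping.setdefault(reference, 1.0)
    if not mapping:
        raise ValueError("empty class-HRR map")
    group_i = tuple(sorted(lab for lab, h in mapping.items()
                           if lab == reference or h < threshold))
    group_ii = tuple(sorted(lab for lab, h in mapping.items()
                            if lab != reference and h >= threshold))
    discriminative = bool(group_i and group_ii)
    if not discriminative and log_warnings:
        logger.warning("grouping is one-sided; classifier non-discriminative")
    return ClassGrouping(reference_class=reference, class_hrrs=mapping,
                         threshold=threshold, group_I=group_i,
                         group_II=group_ii, discriminative=discriminative)


def reference_tree(cutoff_map: dict | None = None) -> CartModel:
    """The published three-marker tree: AURKA low -> A; AURKA high splits on
    PTGS2 (high -> D), and PTGS2 low splits on MMP9 (low -> B, high -> C)."""
    root = TreeNode(
        feature="AURKA",
        low=TreeNode(label="A"),
        high=TreeNode(
            feature="PTGS2",
            low=TreeNode(feature="MMP9",
                         low=TreeNode(label="B"),
                         high=TreeNode(label="C")),
            high=TreeNode(label="D"),
        ),
    )
    return CartModel(root=root, features=("AURKA", "PTGS2", "MMP9"))
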