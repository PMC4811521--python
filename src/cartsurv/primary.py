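"""Primary-tumor / metastasis concordance and classifier transfer.

Expression of most markers is positively correlated between the primary
colorectal tumor and its liver metastasis, so a classifier fitted on
metastasis scores may be applicable to primary-tumor scores.  Markers whose
matched scores are uncorrelated cannot transfer: their splits are collapsed
out of the tree before application, and the remaining classes are re-grouped
by re-estimated hazard rate ratios on the fitting cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortTable, dichotomize, score_column
from .tree import (
    CartModel,
    ClassGrouping,
    TreeNode,
    assign_classes,
    class_hrrs,
    group_classes,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PairCorrelation",
    "pair_correlations",
    "prune_markers",
    "apply_classifier_primary",
    "PrimaryTransferResult",
]


@dataclass
class PairCorrelation:
    """Pearson correlation between matched primary and metastasis scores."""

    marker: str
    n_pairs: int
    r: float
    p: float | None

    @property
    def defined(self) -> bool:
        return self.p is not None


def pair_correlations(cohort: CohortTable, markers, channel_map=None
                      ) -> list[PairCorrelation]:
    """Pearson r (ordinal scores treated as numeric 0-3) per marker over
    complete primary/metastasis pairs; fewer than 3 pairs leaves the p-value
    undefined."""
    if channel_map is None:
        channel_map = {}
    out = []
    for m in markers:
        ch = channel_map.get(m, "intensity")
        a = cohort.df[score_column(m, "prim", ch)].to_numpy(dtype=float)
        b = cohort.df[score_column(m, "crclm", ch)].to_numpy(dtype=float)
        ok = ~(np.isnan(a) | np.isnan(b))
        n = int(ok.sum())
        if n < 3:
            r = np.nan
            if n == 2:
                with np.errstate(invalid="ignore"):
                    r = float(np.corrcoef(a[ok], b[ok])[0, 1])
            out.append(PairCorrelation(m, n, r, None))
            logger.warning("%s: only %d complete pairs; p undefined", m, n)
            continue
        if np.std(a[ok]) == 0.0 or np.std(b[ok]) == 0.0:
            out.append(PairCorrelation(m, n, np.nan, None))
            continue
        r, p = stats.pearsonr(a[ok], b[ok])
        out.append(PairCorrelation(m, n, float(r), float(p)))
    return out


def _merge(a: TreeNode, b: TreeNode) -> TreeNode:
    """Merge the two children of a collapsed split into one subtree."""
    if a.is_leaf and b.is_leaf:
        label = "".join(sorted(set(a.label) | set(b.label)))
        n = a.n + b.n
        frac = np.nan
        if n and not (np.isnan(a.death_frac) or np.isnan(b.death_frac)):
            frac = (a.n * a.death_frac + b.n * b.death_frac) / n
        return TreeNode(label=label, n=n, death_frac=frac)
    if a.is_leaf:
        return TreeNode(feature=b.feature, low=_merge(a, b.low),
                        high=_merge(a, b.high))
    if b.is_leaf:
        return TreeNode(feature=a.feature, low=_merge(a.low, b),
                        high=_merge(a.high, b))
    if a.feature == b.feature:
        return TreeNode(feature=a.feature, low=_merge(a.low, b.low),
                        high=_merge(a.high, b.high))
    return TreeNode(feature=a.feature,
                    low=_merge(a.low, b), high=_merge(a.high, b))


def prune_markers(model: CartModel, markers) -> CartModel:
    """Collapse every split on the given markers, merging both children.

    Leaf classes separated only by a pruned marker coalesce into a single
    merged class (label = union of letters); the number of distinct classes
    never increases.
    """
    drop = set(markers)

    def walk(node: TreeNode) -> TreeNode:
        if node.is_leaf:
            return TreeNode(label=node.label, n=node.n,
                            death_frac=node.death_frac)
        low, high = walk(node.low), walk(node.high)
        if node.feature in drop:
            return _merge(low, high)
        return TreeNode(feature=node.feature, low=low, high=high)

    root = walk(model.root)
    if root.is_leaf and len(model.root.leaves()) > 1 and not drop:
        raise ValueError("no classifier remains")
    features = tuple(f for f in model.features if f not in drop)
    if root.is_leaf:
        raise ValueError("no classifier remains after pruning all tree markers")
    return CartModel(root=root, features=features,
                     cv_error=model.cv_error, cv_folds=model.cv_folds)


@dataclass
class PrimaryTransferResult:
    """Classifier applied to primary-tumor expression."""

    model: CartModel                 # possibly reduced tree
    pruned_markers: tuple[str, ...]
    grouping: ClassGrouping          # re-estimated on the fitting cohort
    classes_primary: pd.Series
    membership_primary: pd.Series
    rule: str                        # human-readable reduced decision rule

    @property
    def correlations(self):
        return getattr(self, "_correlations", None)


def _describe_rule(model: CartModel, grouping: ClassGrouping) -> str:
    """Simplified description of the group-II region; recognizes the case
    where the grouping boundary coincides with a single marker split."""
    if not grouping.discriminative:
        return "non-discriminative"
    paths: list[tuple[tuple[tuple[str, int], ...], str]] = []

    def walk(node: TreeNode, conds) -> None:
        if node.is_leaf:
            paths.append((tuple(conds), node.label))
            return
        walk(node.low, conds + [(node.feature, 0)])
        walk(node.high, conds + [(node.feature, 1)])

    walk(model.root, [])
    ii_paths = [set(c) for c, lab in paths if lab in grouping.group_II]
    if not ii_paths:
        return "group II empty"
    common = set.intersection(*ii_paths) if ii_paths else set()
    # drop conditions shared by group-I paths too
    i_paths = [set(c) for c, lab in paths if lab in grouping.group_I]
    defining = {c for c in common if not any(c in p for p in i_paths)}
    if defining and all(p >= defining for p in ii_paths) and \
            not any(p >= defining for p in i_paths):
        terms = " and ".join(f"{f} {'high' if v else 'low'}"
                             for f, v in sorted(defining))
        return f"class II iff {terms}"
    return "class II = {" + ", ".join(grouping.group_II) + "}"


def apply_classifier_primary(
    model: CartModel,
    cohort: CohortTable,
    cutoffs: dict,
    omit_uncorrelated: bool = True,
    correlation_p_threshold: float = 0.05,
    group_threshold: float = 2.0,
    horizon: float = 36.0,
    omit: tuple[str, ...] = (),
) -> PrimaryTransferResult:
    """Apply a metastasis-fitted classifier to primary-tumor scores.

    Markers listed in ``omit``, plus (when ``omit_uncorrelated``) markers
    whose primary/metastasis pair correlation is non-positive or
    non-significant (p >= ``correlation_p_threshold``), are collapsed out of
    the tree.  The remaining classes are re-grouped by class HRRs
    re-estimated on the metastasis outcomes, and the reduced classifier is
    then applied to dichotomized primary-tumor scores.

    ``cutoffs`` maps marker -> :class:`~cartsurv.cohort.Cutoff` (the
    screening-selected channel and threshold).
    """
    tree_markers = model.used_features()
    to_drop = set(omit) & set(tree_markers)
    corrs = None
    if omit_uncorrelated:
        corrs = pair_correlations(
            cohort, tree_markers,
            {m: cutoffs[m].channel for m in tree_markers})
        for c in corrs:
            if c.r <= 0 or c.p is None or c.p >= correlation_p_threshold:
                to_drop.add(c.marker)
                logger.info("omitting %s (pair r=%.3f, p=%s)", c.marker, c.r,
                            "NA" if c.p is None else f"{c.p:.3g}")
    if to_drop >= set(tree_markers):
        raise ValueError("no classifier remains: all tree markers omitted")
    reduced = prune_markers(model, to_drop) if to_drop else model

    # re-estimate class HRRs of the reduced tree on the fitting (CRCLM) data
    feats_crclm = pd.DataFrame({
        m: dichotomize(cohort.df[score_column(m, "crclm",
                                              cutoffs[m].channel)],
                       cutoffs[m])
        for m in reduced.used_features()
    }, index=cohort.df.index)
    classes_crclm = assign_classes(reduced, feats_crclm)
    ch = class_hrrs(classes_crclm,
                    cohort.df["os_months"].to_numpy(dtype=float),
                    cohort.df["event"].to_numpy(dtype=float),
                    horizon=horizon)
    grouping = group_classes(ch, threshold=group_threshold)

    feats_prim = pd.DataFrame({
        m: dichotomize(cohort.df[score_column(m, "prim",
                                              cutoffs[m].channel)],
                       cutoffs[m])
        for m in reduced.used_features()
    }, index=cohort.df.index)
    classes_prim = assign_classes(reduced, feats_prim)
    membership = grouping.membership(classes_prim)
    result = PrimaryTransferResult(
        model=reduced,
        pruned_markers=tuple(sorted(to_drop)),
        grouping=grouping,
        classes_primary=classes_prim,
        membership_primary=membership,
        rule=_describe_rule(reduced, grouping),
    )
    result._correlations = corrs
    logger.info("primary-tumor classifier: pruned %s; rule: %s",
                result.pruned_markers or "nothing", result.rule)
    return result
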