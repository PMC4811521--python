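"""Survival inference on the fitted classifier.

Covers Kaplan-Meier curves with logrank testing, the class II vs I hazard
rate ratio (crude and stepwise-adjusted for the clinical risk factors), the
permutation-based p-value correction that re-runs the classifier
construction on outcome-permuted data, analysis-of-deviance comparison
against the clinicopathological model, and subgroup analyses.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._cox import cox_fit, logrank_two_group, stepwise_backward
from .cohort import CLINICAL_FLAGS
from .screening import StepwiseSpec
from .tree import (
    DEFAULT_GROUP_THRESHOLD,
    DEFAULT_HORIZON,
    build_cart,
    class_hrrs,
    group_classes,
)

logger = logging.getLogger(__name__)

__all__ = [
    "KMResult",
    "kaplan_meier",
    "HRREstimate",
    "classifier_hrr",
    "PermutationRun",
    "permutation_corrected_p",
    "ModelComparison",
    "compare_models",
    "SubgroupResult",
    "subgroup_analysis",
    "ClassifierReport",
]


@dataclass
class KMResult:
    curves: dict            # group -> (times, survival) step arrays
    logrank_chi2: float | None
    df: int | None
    p: float | None


def kaplan_meier(times, events, groups) -> KMResult:
    """Kaplan-Meier estimate per group plus the k-sample logrank test
    (no test when a single group is supplied)."""
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import multivariate_logrank_test

    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=float)
    g = pd.Series(groups).astype(object)
    labels = [lab for lab in pd.unique(g) if lab is not None and not pd.isna(lab)]
    if not labels:
        raise ValueError("no non-empty groups")
    curves = {}
    for lab in labels:
        m = (g == lab).to_numpy()
        kmf = KaplanMeierFitter()
        kmf.fit(t[m], e[m])
        curves[lab] = (kmf.survival_function_.index.to_numpy(dtype=float),
                       kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float))
    if len(labels) < 2:
        return KMResult(curves, None, None, None)
    mask = g.isin(labels).to_numpy()
    res = multivariate_logrank_test(t[mask], g[mask].to_numpy(), e[mask])
    return KMResult(curves, float(res.test_statistic), len(labels) - 1,
                    float(res.p_value))


def save_km_plot(km: KMResult, path, title: str = "Overall survival") -> None:
    """Write the Kaplan-Meier curves as an image (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for label, (t, s) in sorted(km.curves.items()):
        ax.step(t, s, where="post", label=f"class {label}")
    if km.p is not None:
        ax.text(0.55, 0.9, f"logrank p = {km.p:.2g}", transform=ax.transAxes)
    ax.set_xlabel("months")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


@dataclass
class HRREstimate:
    hrr: float
    ci: tuple[float, float]
    p: float
    retained_terms: tuple[str, ...] = ()
    converged: bool = True


def classifier_hrr(
    membership,
    cohort_df: pd.DataFrame,
    adjust: bool = False,
    stepwise: StepwiseSpec | None = None,
) -> HRREstimate:
    """Cox hazard rate ratio of prognostic class II versus class I.

    With ``adjust`` the five clinical risk factors enter the model and
    undergo stepwise backward elimination (class indicator forced).
    """
    mem = pd.Series(membership).astype(object)
    keep = mem.isin(["I", "II"]).to_numpy()
    t = cohort_df["os_months"].to_numpy(dtype=float)[keep]
    e = cohort_df["event"].to_numpy(dtype=float)[keep]
    ind = (mem[keep] == "II").to_numpy(dtype=float)
    if ind.sum() == 0 or ind.sum() == ind.size:
        raise ValueError("both classifier groups must be non-empty")
    if e[ind == 1].sum() == 0 or e[ind == 0].sum() == 0:
        raise ValueError("each classifier group needs at least one event")
    if not adjust:
        fit = cox_fit(t, e, ind, names=("class_II",))
        if not fit.converged:
            raise ValueError(f"Cox fit failed: {fit.flag or 'non-convergence'}")
        ci = fit.ci()[0]
        return HRREstimate(float(np.exp(fit.coef[0])),
                           (float(ci[0]), float(ci[1])), float(fit.p[0]),
                           ("class_II",), True)
    spec = stepwise or StepwiseSpec()
    clinical = {f: cohort_df[f].to_numpy(dtype=float)[keep]
                for f in spec.removable_terms}
    complete = np.ones(ind.size, dtype=bool)
    for arr in clinical.values():
        complete &= ~np.isnan(arr)
    design = {"class_II": ind[complete],
              **{f: clinical[f][complete] for f in clinical}}
    res = stepwise_backward(t[complete], e[complete], design,
                            forced=("class_II",),
                            removable=spec.removable_terms,
                            exit_p=spec.exit_p)
    if not res.converged:
        raise ValueError(f"adjusted Cox fit failed: {res.fit.flag}")
    j = res.fit.term("class_II")
    ci = res.fit.ci()[j]
    return HRREstimate(float(np.exp(res.fit.coef[j])),
                       (float(ci[0]), float(ci[1])), float(res.fit.p[j]),
                       res.retained, True)


# ---------------------------------------------------------------------------
# permutation correction


def _route_classes(root, X: np.ndarray, colidx: dict) -> np.ndarray:
    """Vectorized tree routing for complete binary feature matrices."""
    out = np.empty(X.shape[0], dtype=object)

    def walk(node, rows):
        if rows.size == 0:
            return
        if node.is_leaf:
            out[rows] = node.label
            return
        vals = X[rows, colidx[node.feature]]
        walk(node.low, rows[vals == 0.0])
        walk(node.high, rows[vals == 1.0])

    walk(root, np.arange(X.shape[0]))
    return out


def _construction_p(
    X: pd.DataFrame,
    times: np.ndarray,
    events: np.ndarray,
    cv_folds: int,
    min_leaf: int,
    group_threshold: float,
    horizon: float,
    seed: int,
) -> float:
    """Uncorrected logrank p of the classifier built from scratch on the
    given outcomes.

    The full construction is re-run: three-year labelling, CART build with
    CV pruning, per-class HRRs, HRR grouping, logrank of II vs I.  The
    construction always yields a statistic when one exists (best non-trivial
    subtree; the highest-HRR class is split off if the threshold grouping is
    one-sided); datasets with no admissible classifier contribute p = 1.
    """
    defined = (times > horizon) | (events == 1.0)
    y = ((events == 1.0) & (times <= horizon))[defined].astype(float)
    if defined.sum() < 2 * min_leaf or np.unique(y).size < 2:
        return 1.0
    model = build_cart(X.loc[defined], y, cv_folds=cv_folds,
                       min_leaf=min_leaf, seed=seed, require_split=True)
    if model.n_leaves < 2:
        return 1.0
    Xnp = X.to_numpy(dtype=float)
    colidx = {c: j for j, c in enumerate(X.columns)}
    classes = _route_classes(model.root, Xnp, colidx)
    try:
        ch = class_hrrs(classes, times, events, horizon=horizon,
                        log_warnings=False)
    except ValueError:
        return 1.0
    grouping = group_classes(ch, threshold=group_threshold,
                             log_warnings=False)
    if not grouping.discriminative:
        # fall back: split off the worst-prognosis estimable class
        estimable = {lab: h for lab, h in ch.hrrs.items()
                     if lab not in ch.non_estimable}
        if len(estimable) < 2:
            return 1.0
        worst = max(sorted(estimable), key=lambda lab: estimable[lab])
        best = min(sorted(estimable), key=lambda lab: estimable[lab])
        if worst == best:
            return 1.0
        grouping = group_classes(
            {lab: (group_threshold if lab == worst else 0.0)
             for lab in estimable},
            threshold=group_threshold, reference=best,
            log_warnings=False)
    in_ii = np.isin(classes, grouping.group_II)
    in_i = np.isin(classes, grouping.group_I)
    keep = in_i | in_ii
    ind = in_ii[keep].astype(float)
    if ind.sum() == 0 or ind.sum() == ind.size:
        return 1.0
    _, p = logrank_two_group(times[keep], events[keep], ind)
    return float(p)


@dataclass
class PermutationRun:
    """Permutation-corrected significance of the classifier construction."""

    n_perm: int
    original_p: float
    perm_p: np.ndarray
    corrected_p: float       # literal count/n_perm, as printed
    corrected_p_add_one: float  # (count+1)/(n_perm+1)
    seed: int

    def summary(self) -> str:
        if self.corrected_p == 0.0:
            return f"< {1.0 / self.n_perm:g}"
        return f"{self.corrected_p:g}"


def _strict_features(scores: pd.DataFrame, t: np.ndarray, e: np.ndarray,
                     horizon: float) -> pd.DataFrame | None:
    """Re-optimize each marker's cutoff on the (permuted) outcomes and
    dichotomize; markers without an admissible cutoff are dropped."""
    from .screening import survival_roc_cutoff

    cols = {}
    for m in scores.columns:
        s = scores[m].to_numpy(dtype=float)
        try:
            cut = survival_roc_cutoff(t, e, s, horizon)
        except ValueError:
            continue
        cols[m] = np.where(np.isnan(s), np.nan,
                           (s >= cut.threshold).astype(float))
    if not cols:
        return None
    return pd.DataFrame(cols)


def permutation_corrected_p(
    features: pd.DataFrame,
    times,
    events,
    n_perm: int = 10000,
    seed: int = 0,
    cv_folds: int = 10,
    min_leaf: int = 10,
    group_threshold: float = DEFAULT_GROUP_THRESHOLD,
    horizon: float = DEFAULT_HORIZON,
    strict_scores: pd.DataFrame | None = None,
) -> PermutationRun:
    """Selection-aware permutation correction of the classifier p-value.

    The outcome pair (time, event) is permuted jointly across patients while
    the marker columns stay fixed; the full classifier construction is re-run
    on each permuted dataset and the corrected p-value is the fraction of
    permuted uncorrected p-values smaller than the original one.

    By default the dichotomization cutoffs stay fixed at their
    screening-derived values (``features`` already binary).  Passing the raw
    ordinal scores as ``strict_scores`` switches to strict mode: each
    permutation first re-optimizes every marker's cutoff on the permuted
    outcomes before rebuilding the tree (intended for reduced ``n_perm``).
    """
    if n_perm < 100:
        warnings.warn(f"n_perm = {n_perm} gives a corrected-p resolution of "
                      f"only {1.0 / n_perm:g}", stacklevel=2)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=float)
    X = features.reset_index(drop=True)
    scores = None if strict_scores is None \
        else strict_scores.reset_index(drop=True)

    def construct(tt, ee, bseed):
        Xb = X if scores is None else _strict_features(scores, tt, ee,
                                                       horizon)
        if Xb is None:
            return 1.0
        return _construction_p(Xb, tt, ee, cv_folds, min_leaf,
                               group_threshold, horizon, seed=bseed)

    ss = np.random.SeedSequence(seed)
    build_seed = int(ss.generate_state(1)[0] % (2**31))
    p_obs = construct(t, e, build_seed)
    children = ss.spawn(n_perm)
    perm_p = np.empty(n_perm)
    for b in range(n_perm):
        rng = np.random.default_rng(children[b])
        order = rng.permutation(t.size)
        perm_p[b] = construct(t[order], e[order], int(rng.integers(2**31)))
    count = int((perm_p < p_obs).sum())
    run = PermutationRun(
        n_perm=n_perm,
        original_p=p_obs,
        perm_p=perm_p,
        corrected_p=count / n_perm,
        corrected_p_add_one=(count + 1) / (n_perm + 1),
        seed=seed,
    )
    logger.info("permutation correction: original p=%.4g, corrected p=%s "
                "(%d permutations)", p_obs, run.summary(), n_perm)
    return run


# ---------------------------------------------------------------------------
# model comparison


@dataclass
class ModelComparison:
    chi2: float
    df: int
    p: float
    degenerate: bool = False


def compare_models(cohort_df: pd.DataFrame, membership,
                   clinical_terms: tuple[str, ...] = CLINICAL_FLAGS) -> ModelComparison:
    """Analysis of deviance between nested Cox models: clinical factors only
    versus clinical factors plus the classifier indicator.

    The chi-square is the difference in -2 log partial likelihood; degrees
    of freedom are the independent added terms (0 with a flag if the
    classifier column is collinear with the clinical design).
    """
    mem = pd.Series(membership).astype(object)
    keep = mem.isin(["I", "II"]).to_numpy()
    df_ = cohort_df.loc[keep]
    complete = np.ones(len(df_), dtype=bool)
    for f in clinical_terms:
        complete &= df_[f].notna().to_numpy()
    df_ = df_.loc[complete]
    ind = (mem[keep][complete] == "II").to_numpy(dtype=float)
    t = df_["os_months"].to_numpy(dtype=float)
    e = df_["event"].to_numpy(dtype=float)
    X_clin = np.column_stack([df_[f].to_numpy(dtype=float)
                              for f in clinical_terms])
    X_full = np.column_stack([X_clin, ind])
    rank_clin = np.linalg.matrix_rank(X_clin - X_clin.mean(axis=0))
    rank_full = np.linalg.matrix_rank(X_full - X_full.mean(axis=0))
    df_added = int(rank_full - rank_clin)
    if df_added == 0:
        logger.warning("classifier indicator is collinear with the clinical "
                       "model; df collapses to 0")
        return ModelComparison(0.0, 0, 1.0, degenerate=True)
    reduced = cox_fit(t, e, X_clin, names=clinical_terms)
    full = cox_fit(t, e, X_full, names=clinical_terms + ("class_II",))
    if not (reduced.converged and full.converged):
        raise ValueError("nested Cox fits did not converge")
    chi2 = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    return ModelComparison(chi2, df_added,
                           float(stats.chi2.sf(chi2, df_added)))


# ---------------------------------------------------------------------------
# subgroup analyses


@dataclass
class SubgroupResult:
    stratum: str
    n: int
    hrr: float | None
    ci: tuple[float, float] | None
    corrected_p: float | None
    estimable: bool
    reason: str = ""


def subgroup_analysis(
    cohort_df: pd.DataFrame,
    membership,
    stratifier: str,
    features: pd.DataFrame | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    group_threshold: float = DEFAULT_GROUP_THRESHOLD,
    horizon: float = DEFAULT_HORIZON,
) -> dict[str, SubgroupResult]:
    """Per-stratum classifier HRR with within-stratum permutation correction.

    The classifier is applied as fitted on the full cohort (membership is
    not re-derived); patients with unknown stratifier values are excluded.
    When ``features`` are supplied the corrected p re-runs the construction
    on outcome permutations restricted to the stratum; otherwise only the
    HRR is reported.
    """
    if stratifier not in ("systemic_therapy", "primary_site"):
        raise ValueError("stratifier must be systemic_therapy or primary_site")
    mem = pd.Series(membership).astype(object).reset_index(drop=True)
    df_ = cohort_df.reset_index(drop=True)
    strat = df_[stratifier]
    if stratifier == "systemic_therapy":
        level_names = {1.0: "systemic_therapy", 0.0: "no_systemic_therapy"}
        levels = [lv for lv in (1.0, 0.0) if (strat == lv).any()]
    else:
        level_names = {"colon": "colon", "rectum": "rectum"}
        levels = [lv for lv in ("colon", "rectum") if (strat == lv).any()]
    excluded = int(strat.isna().sum())
    if excluded:
        logger.info("subgroup %s: %d patients with unknown stratum excluded",
                    stratifier, excluded)
    out: dict[str, SubgroupResult] = {}
    ss = np.random.SeedSequence((int(seed), 0x5b))
    for child_seed, lv in zip(ss.spawn(len(levels)), levels):
        name = level_names[lv]
        m = (strat == lv).to_numpy()
        mem_s = mem[m]
        in_groups = mem_s.isin(["I", "II"]).to_numpy()
        t = df_["os_months"].to_numpy(dtype=float)[m][in_groups]
        e = df_["event"].to_numpy(dtype=float)[m][in_groups]
        ind = (mem_s[in_groups] == "II").to_numpy(dtype=float)
        n_strat = int(in_groups.sum())
        if n_strat == 0 or ind.sum() == 0 or ind.sum() == ind.size \
                or e[ind == 1].sum() < 2 or e[ind == 0].sum() < 2:
            out[name] = SubgroupResult(name, n_strat, None, None, None, False,
                                       reason="fewer than 2 events per group")
            continue
        fit = cox_fit(t, e, ind, names=("class_II",))
        ci = fit.ci()[0]
        corrected = None
        if features is not None and fit.converged:
            feats = features.reset_index(drop=True).loc[m].loc[in_groups]
            _, p_obs = logrank_two_group(t, e, ind)
            rng_children = child_seed.spawn(n_perm)
            perm_p = np.empty(n_perm)
            for b in range(n_perm):
                rng = np.random.default_rng(rng_children[b])
                order = rng.permutation(t.size)
                perm_p[b] = _construction_p(
                    feats, t[order], e[order], 10, 10, group_threshold,
                    horizon, seed=int(rng.integers(2**31)))
            corrected = float((perm_p < p_obs).mean())
        out[name] = SubgroupResult(
            name, n_strat, float(np.exp(fit.coef[0])),
            (float(ci[0]), float(ci[1])), corrected, True)
    return out


@dataclass
class ClassifierReport:
    """End-to-end summary of the fitted classifier on a cohort."""

    class_per_patient: pd.Series
    membership: pd.Series
    km: KMResult
    logrank_p_uncorrected: float | None
    hrr_uni: HRREstimate | None   # None when grouping is non-discriminative
    hrr_multi: HRREstimate | None
    permutation: PermutationRun | None
    comparison: ModelComparison | None
    subgroup_results: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "n_classified": int(self.membership.isin(["I", "II"]).sum()),
            "logrank_p_uncorrected": self.logrank_p_uncorrected,
            "discriminative": self.hrr_uni is not None,
        }
        if self.hrr_uni is not None:
            d["hrr_univariate"] = self.hrr_uni.hrr
            d["hrr_univariate_ci"] = list(self.hrr_uni.ci)
        if self.hrr_multi is not None:
            d["hrr_multivariate"] = self.hrr_multi.hrr
            d["hrr_multivariate_ci"] = list(self.hrr_multi.ci)
            d["retained_clinical_terms"] = [
                x for x in self.hrr_multi.retained_terms if x != "class_II"]
        if self.permutation is not None:
            d["corrected_p"] = self.permutation.corrected_p
            d["corrected_p_add_one"] = self.permutation.corrected_p_add_one
            d["n_permutations"] = self.permutation.n_perm
        if self.comparison is not None:
            d["model_comparison"] = {
                "chi2": self.comparison.chi2,
                "df": self.comparison.df,
                "p": self.comparison.p,
            }
        d["subgroups"] = {
            name: {"n": r.n, "hrr": r.hrr, "corrected_p": r.corrected_p,
                   "estimable": r.estimable}
            for name, r in self.subgroup_results.items()
        }
        return d
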