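"""Per-biomarker prognostic screening.

For each biomarker and IHC score channel, a Monte-Carlo cross-validation
(default 500 random 2/3-1/3 train/validation partitions, stratified on event
status) repeatedly (i) optimizes the low/high cutoff on the training set with
a time-dependent (cumulative-case / dynamic-control) ROC analysis at the
36-month horizon, and (ii) estimates the validation-set hazard rate ratio of
high vs low expression, both crude and adjusted for the five clinical risk
factors via stepwise backward Cox regression (exit p > .1, marker forced).

The screening statistics are HRR_av — the arithmetic mean of the valid
validation-set HRRs — and the opposite-direction proportion P(HRR < 1) (when
HRR_av > 1) or P(HRR > 1) (when HRR_av < 1), a cross-validation stability
measure used for candidate selection.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from ._cox import cox_fit, km_survival_at, stepwise_backward
from .cohort import CLINICAL_FLAGS, CohortTable, Cutoff, apply_exclusions, score_column

logger = logging.getLogger(__name__)

__all__ = [
    "StepwiseSpec",
    "SplitRecord",
    "CVScreenResult",
    "survival_roc_cutoff",
    "mccv_screen",
    "opposite_proportion",
    "select_channel",
    "select_candidates",
]

DEFAULT_HORIZON = 36.0
DEFAULT_N_SPLITS = 500
DEFAULT_TRAIN_FRACTION = 2.0 / 3.0


@dataclass
class StepwiseSpec:
    """Stepwise backward elimination settings for the multivariate fits."""

    forced_terms: tuple[str, ...] = ()
    removable_terms: tuple[str, ...] = CLINICAL_FLAGS
    exit_p: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 < self.exit_p < 1.0:
            raise ValueError("exit_p must be in (0, 1)")


@dataclass
class SplitRecord:
    threshold: int | None
    hrr_uni: float = math.nan
    hrr_multi: float = math.nan
    valid: bool = False
    reason: str = ""


@dataclass
class CVScreenResult:
    """Aggregated Monte-Carlo cross-validation output for one marker/channel."""

    marker: str
    channel: str
    per_split: list[SplitRecord] = field(default_factory=list)
    hrr_av_uni: float = math.nan
    hrr_av_multi: float = math.nan
    p_lt1: float = math.nan
    p_gt1: float = math.nan
    p_lt1_uni: float = math.nan
    p_gt1_uni: float = math.nan
    n_valid_splits: int = 0

    @property
    def opposite_p(self) -> float:
        """The reported statistic: the proportion opposite to HRR_av."""
        return self.p_lt1 if self.hrr_av_multi > 1.0 else self.p_gt1

    @property
    def opposite_direction(self) -> str:
        return "P(HRR<1)" if self.hrr_av_multi > 1.0 else "P(HRR>1)"

    @property
    def modal_threshold(self) -> int:
        thr = [r.threshold for r in self.per_split if r.valid]
        values, counts = np.unique(thr, return_counts=True)
        return int(values[np.argmax(counts)])


def survival_roc_cutoff(times, events, marker_scores, horizon: float = DEFAULT_HORIZON,
                        marker: str = "", channel: str = "intensity") -> Cutoff:
    """Optimal ordinal cutoff by time-dependent ROC analysis at ``horizon``.

    Cumulative-case / dynamic-control sensitivity and specificity are
    estimated with Kaplan-Meier survival within the high/low groups (the
    mixture form, which reduces to empirical fractions without censoring):

        Sens(c) = (1 - S_hi(t)) p_hi / (1 - S(t))
        Spec(c) = S_lo(t) (1 - p_hi) / S(t)

    and the threshold in {1, 2, 3} maximizing |Youden's J| is returned (ties
    toward the lowest threshold).  The absolute value makes the criterion
    direction-agnostic: protective markers (high expression anticipating
    longer survival) yield a negative J on the case-oriented ROC, and their
    best-discriminating threshold is the one with the largest |J|.
    """
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=float)
    s = np.asarray(marker_scores, dtype=float)
    ok = ~np.isnan(s)
    t, d, s = t[ok], d[ok], s[ok]
    if np.unique(s).size < 2:
        raise ValueError("no admissible cutoff: marker scores are constant")
    if not np.any((d == 1.0) & (t <= horizon)):
        raise ValueError("no events before the horizon")
    best: tuple[float, int] | None = None
    for c in (1, 2, 3):
        hi = s >= c
        p_hi = float(hi.mean())
        if p_hi in (0.0, 1.0):
            continue
        s_hi = km_survival_at(t[hi], d[hi], horizon)
        s_lo = km_survival_at(t[~hi], d[~hi], horizon)
        s_all = p_hi * s_hi + (1.0 - p_hi) * s_lo
        if s_all >= 1.0 or s_all <= 0.0:
            continue
        sens = (1.0 - s_hi) * p_hi / (1.0 - s_all)
        spec = s_lo * (1.0 - p_hi) / s_all
        j = abs(min(max(sens, 0.0), 1.0) + min(max(spec, 0.0), 1.0) - 1.0)
        if best is None or j > best[0] + 1e-12:
            best = (j, c)
    if best is None:
        raise ValueError("no admissible cutoff")
    return Cutoff(marker=marker, channel=channel, threshold=best[1])


def opposite_proportion(hrrs, hrr_av: float) -> float:
    """Fraction of per-split HRRs pointing opposite to the average HRR;
    values exactly 1 count in neither direction."""
    h = np.asarray(hrrs, dtype=float)
    if h.size == 0:
        raise ValueError("empty HRR vector")
    if hrr_av > 1.0:
        return float((h < 1.0).mean())
    if hrr_av < 1.0:
        return float((h > 1.0).mean())
    raise ValueError("hrr_av is exactly 1; opposite direction undefined")


def _stratified_split(rng, events: np.ndarray, train_fraction: float):
    idx_event = np.flatnonzero(events == 1.0)
    idx_cens = np.flatnonzero(events != 1.0)
    train = []
    for idx in (idx_event, idx_cens):
        perm = rng.permutation(idx)
        k = int(round(train_fraction * idx.size))
        train.append(perm[:k])
    train_idx = np.concatenate(train)
    mask = np.zeros(events.size, dtype=bool)
    mask[train_idx] = True
    return mask


def mccv_screen(
    cohort: CohortTable,
    marker: str,
    channel: str = "intensity",
    n_splits: int = DEFAULT_N_SPLITS,
    horizon: float = DEFAULT_HORIZON,
    stepwise: StepwiseSpec | None = None,
    seed: int = 0,
    train_fraction: float = DEFAULT_TRAIN_FRACTION,
    min_valid_fraction: float = 0.5,
    pre_excluded: bool = False,
) -> CVScreenResult:
    """Monte-Carlo cross-validated cutoff/HRR screening of one marker channel.

    Each split optimizes the cutoff on its training set and computes the
    univariate and stepwise-multivariate validation-set HRRs; splits with
    degenerate groups or non-convergent fits are dropped from the averages
    (their reasons are recorded).  Seeds are spawned per split index so split
    k is reproducible in isolation.
    """
    if stepwise is None:
        stepwise = StepwiseSpec(forced_terms=("marker",))
    sub = cohort if pre_excluded else apply_exclusions(cohort, "survival")[0]
    df = sub.df
    col = score_column(marker, "crclm", channel)
    if col not in df.columns:
        raise ValueError(f"marker column {col} absent from cohort")
    usable = df[col].notna()
    for f in stepwise.removable_terms:
        usable &= df[f].notna()
    df = df.loc[usable]
    if len(df) < 30:
        raise ValueError(
            f"only {len(df)} patients with {marker} {channel} scores; need >= 30")
    times = df["os_months"].to_numpy(dtype=float)
    events = df["event"].to_numpy(dtype=float)
    scores = df[col].to_numpy(dtype=float)
    clinical = {f: df[f].to_numpy(dtype=float) for f in stepwise.removable_terms}

    children = np.random.SeedSequence(seed).spawn(n_splits)
    records: list[SplitRecord] = []
    for k in range(n_splits):
        rng = np.random.default_rng(children[k])
        train_mask = _stratified_split(rng, events, train_fraction)
        val = ~train_mask
        try:
            cut = survival_roc_cutoff(times[train_mask], events[train_mask],
                                      scores[train_mask], horizon,
                                      marker=marker, channel=channel)
        except ValueError as exc:
            records.append(SplitRecord(None, reason=f"cutoff: {exc}"))
            continue
        hi = (scores[val] >= cut.threshold).astype(float)
        t_val, e_val = times[val], events[val]
        if hi.sum() == 0 or hi.sum() == hi.size:
            records.append(SplitRecord(cut.threshold,
                                       reason="degenerate validation groups"))
            continue
        if e_val.sum() == 0:
            records.append(SplitRecord(cut.threshold, reason="no events"))
            continue
        uni = cox_fit(t_val, e_val, hi, names=("marker",))
        design = {"marker": hi, **{f: clinical[f][val]
                                   for f in stepwise.removable_terms}}
        multi = stepwise_backward(t_val, e_val, design,
                                  forced=("marker",),
                                  removable=stepwise.removable_terms,
                                  exit_p=stepwise.exit_p)
        if not (uni.converged and multi.converged):
            records.append(SplitRecord(cut.threshold,
                                       reason="non-convergent Cox fit"))
            continue
        records.append(SplitRecord(
            cut.threshold,
            hrr_uni=float(np.exp(uni.coef[0])),
            hrr_multi=multi.hrr_of("marker"),
            valid=True,
        ))

    valid = [r for r in records if r.valid]
    if len(valid) < min_valid_fraction * n_splits:
        reasons = {}
        for r in records:
            if not r.valid:
                reasons[r.reason] = reasons.get(r.reason, 0) + 1
        raise ValueError(
            f"only {len(valid)}/{n_splits} valid splits for {marker} "
            f"({channel}); failures: {reasons}")
    h_uni = np.array([r.hrr_uni for r in valid])
    h_multi = np.array([r.hrr_multi for r in valid])
    result = CVScreenResult(
        marker=marker,
        channel=channel,
        per_split=records,
        hrr_av_uni=float(h_uni.mean()),
        hrr_av_multi=float(h_multi.mean()),
        p_lt1=float((h_multi < 1.0).mean()),
        p_gt1=float((h_multi > 1.0).mean()),
        p_lt1_uni=float((h_uni < 1.0).mean()),
        p_gt1_uni=float((h_uni > 1.0).mean()),
        n_valid_splits=len(valid),
    )
    logger.info("screen %s/%s: HRR_av multi %.3f, %s = %.3f (%d valid splits)",
                marker, channel, result.hrr_av_multi,
                result.opposite_direction, result.opposite_p,
                result.n_valid_splits)
    return result


def select_channel(result_int: CVScreenResult,
                   result_freq: CVScreenResult) -> CVScreenResult:
    """Pick the score channel with maximum deviation of HRR_av from 1
    (|log HRR_av|, symmetric on the log scale); exact ties prefer intensity."""
    if result_int.marker != result_freq.marker:
        raise ValueError("channel results belong to different markers")
    dev_int = abs(math.log(result_int.hrr_av_multi))
    dev_freq = abs(math.log(result_freq.hrr_av_multi))
    if dev_freq > dev_int:
        return result_freq
    if dev_freq == dev_int:
        logger.info("channel tie for %s; preferring intensity", result_int.marker)
    return result_int


def select_candidates(results, p_threshold: float = 0.10) -> list[str]:
    """Markers whose opposite-direction proportion is at most ``p_threshold``,
    ordered by that proportion then by deviation of HRR_av from 1."""
    chosen = [r for r in results if r.opposite_p <= p_threshold]
    if not chosen:
        raise ValueError(
            f"no markers pass the opposite-direction threshold {p_threshold}; "
            "consider raising it")
    chosen.sort(key=lambda r: (r.opposite_p, -abs(math.log(r.hrr_av_multi))))
    return [r.marker for r in chosen]
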