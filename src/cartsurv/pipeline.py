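"""End-to-end pipeline orchestration.

screen -> candidate selection -> dichotomize -> CART -> HRR grouping ->
inference (KM/logrank, crude and adjusted classifier HRR, permutation
correction, model comparison, subgroups) -> optional primary-tumor transfer.
Every stage writes plain-text artifacts into the output directory together
with a manifest carrying the configuration hash and seeds, so any stage can
be re-run and re-checked in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (
    CohortTable,
    Cutoff,
    apply_exclusions,
    dichotomize,
    label_three_year,
    read_cohort,
    write_cohort,
)
from .inference import (
    ClassifierReport,
    classifier_hrr,
    compare_models,
    kaplan_meier,
    permutation_corrected_p,
    subgroup_analysis,
)
from .screening import StepwiseSpec, mccv_screen, select_candidates, select_channel
from .synthetic import (
    SyntheticConfig,
    fig1_profile,
    generate_cohort,
    generate_matched_pairs,
    paper2015_profile,
)
from .tree import assign_classes, build_cart, class_hrrs, group_classes
from .primary import apply_classifier_primary

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "make_profile"]


def make_profile(name: str, n_patients: int, seed: int, **kwargs) -> SyntheticConfig:
    """Named generator profiles exposed to the CLI and config files."""
    if name == "paper2015":
        return paper2015_profile(n_patients=n_patients, seed=seed, **kwargs)
    if name == "fig1":
        return fig1_profile(n_patients=n_patients, seed=seed, **kwargs)
    raise ValueError(f"unknown profile {name!r} (expected paper2015 or fig1)")


@dataclass
class PipelineConfig:
    """Settings of the full construction; see the CLI for file format."""

    cohort_path: str | None = None
    profile: str | None = None            # synthetic profile name
    profile_options: dict = field(default_factory=dict)
    n_patients: int = 500
    markers: tuple[str, ...] | None = None  # None -> all cohort markers
    n_splits: int = 500
    horizon: float = 36.0
    train_fraction: float = 2.0 / 3.0
    p_threshold: float = 0.10
    cv_folds: int = 10
    min_leaf: int = 10
    group_threshold: float = 2.0
    n_perm: int = 1000
    run_permutation: bool = True
    subgroups: tuple[str, ...] = ("systemic_therapy", "primary_site")
    run_subgroups: bool = False
    primary_transfer: bool = False
    out_dir: str = "cartsurv_out"
    seed: int = 0

    def validate(self) -> None:
        if self.cohort_path is None and self.profile is None:
            raise ValueError("config needs either cohort_path or profile")
        if self.markers is not None and len(self.markers) == 0:
            raise ValueError("config lists no markers")
        if self.n_splits < 2:
            raise ValueError("n_splits must be >= 2")

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("out_dir", None)  # where results land is not a setting
        return hashlib.sha256(json.dumps(payload, sort_keys=True,
                                         default=str).encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    cohort: CohortTable
    screening: list
    candidates: list[str]
    cutoffs: dict
    model: object
    grouping: object
    report: ClassifierReport
    primary: object | None = None
    manifest: dict = field(default_factory=dict)


def _screen_all(cohort, markers, cfg: PipelineConfig, seed_seq):
    results = []
    spec = StepwiseSpec(forced_terms=("marker",))
    survival_cohort, _ = apply_exclusions(cohort, "survival")
    children = seed_seq.spawn(len(markers) * 2)
    i = 0
    for m in markers:
        per_channel = []
        for ch in ("intensity", "frequency"):
            child = children[i]
            i += 1
            try:
                res = mccv_screen(
                    survival_cohort, m, ch, n_splits=cfg.n_splits,
                    horizon=cfg.horizon, stepwise=spec,
                    seed=int(child.generate_state(1)[0] % (2**31)),
                    train_fraction=cfg.train_fraction, pre_excluded=True)
                per_channel.append(res)
            except ValueError as exc:
                logger.warning("screening failed for %s/%s: %s", m, ch, exc)
        if len(per_channel) == 2:
            results.append(select_channel(per_channel[0], per_channel[1]))
        elif per_channel:
            results.append(per_channel[0])
    return results


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full classifier construction; artifacts land in
    ``config.out_dir``.  Reproducible given the config (incl. seed)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    ss = np.random.SeedSequence(config.seed)
    ss_screen, ss_cart, ss_perm, ss_synth = ss.spawn(4)

    # ---- stage: cohort ---------------------------------------------------
    if config.cohort_path is not None:
        cohort = read_cohort(config.cohort_path)
    else:
        prof = make_profile(config.profile, config.n_patients, config.seed,
                            **config.profile_options)
        gen = generate_matched_pairs if config.primary_transfer else generate_cohort
        if config.primary_transfer and not prof.pair_correlation:
            prof = make_profile(config.profile, config.n_patients, config.seed,
                                matched=True, **config.profile_options)
        cohort = gen(prof)
        write_cohort(cohort, out / "cohort.csv")
    markers = tuple(config.markers or cohort.markers)
    if not markers:
        raise ValueError("config lists no markers")

    # ---- stage: screening ------------------------------------------------
    screening = _screen_all(cohort, markers, config, ss_screen)
    if not screening:
        raise RuntimeError("stage screening produced no results")
    rows = [{
        "marker": r.marker, "channel": r.channel,
        "hrr_av_uni": r.hrr_av_uni, "hrr_av_multi": r.hrr_av_multi,
        "opposite_direction": r.opposite_direction,
        "opposite_p": r.opposite_p, "n_valid_splits": r.n_valid_splits,
        "modal_cutoff": r.modal_threshold, "config": chash,
    } for r in screening]
    pd.DataFrame(rows).to_csv(out / "screening.csv", index=False)

    candidates = select_candidates(screening, p_threshold=config.p_threshold)
    by_marker = {r.marker: r for r in screening}
    cutoffs = {m: Cutoff(m, by_marker[m].channel, by_marker[m].modal_threshold)
               for m in candidates}
    (out / "candidates.json").write_text(json.dumps({
        "config": chash, "candidates": candidates,
        "cutoffs": {m: {"channel": c.channel, "threshold": c.threshold}
                    for m, c in cutoffs.items()},
    }, indent=2))

    # ---- stage: CART -----------------------------------------------------
    surv_cohort, _ = apply_exclusions(cohort, "survival",
                                      required=tuple(cutoffs.values()))
    feats = pd.DataFrame({
        m: dichotomize(surv_cohort.df[cutoffs[m].column], cutoffs[m])
        for m in candidates}, index=surv_cohort.df.index)
    times = surv_cohort.df["os_months"].to_numpy(dtype=float)
    events = surv_cohort.df["event"].to_numpy(dtype=float)
    labels = label_three_year(times, events)
    defined = labels != "undefined"
    model = build_cart(feats.loc[defined],
                       (labels[defined] == "died_within_36").astype(float),
                       cv_folds=config.cv_folds, min_leaf=config.min_leaf,
                       seed=int(ss_cart.generate_state(1)[0] % (2**31)))
    (out / "model.txt").write_text(model.to_text())

    classes = assign_classes(model, feats)
    ch = class_hrrs(classes, times, events, horizon=config.horizon)
    grouping = group_classes(ch, threshold=config.group_threshold)

    # ---- stage: inference ------------------------------------------------
    membership = grouping.membership(classes)
    km = kaplan_meier(times, events, membership)
    hrr_uni = None
    hrr_multi = None
    if grouping.discriminative:
        hrr_uni = classifier_hrr(membership, surv_cohort.df, adjust=False)
        try:
            hrr_multi = classifier_hrr(membership, surv_cohort.df,
                                       adjust=True)
        except ValueError as exc:
            logger.warning("adjusted classifier HRR unavailable: %s", exc)
    else:
        logger.warning("classifier is non-discriminative (single prognostic "
                       "group); no HRR estimable")
    permutation = None
    if config.run_permutation:
        permutation = permutation_corrected_p(
            feats, times, events, n_perm=config.n_perm,
            seed=int(ss_perm.generate_state(1)[0] % (2**31)),
            cv_folds=config.cv_folds, min_leaf=config.min_leaf,
            group_threshold=config.group_threshold, horizon=config.horizon)
    comparison = None
    if grouping.discriminative:
        try:
            comparison = compare_models(surv_cohort.df, membership)
        except ValueError as exc:
            logger.warning("model comparison unavailable: %s", exc)
    subgroups = {}
    if config.run_subgroups and grouping.discriminative:
        for strat in config.subgroups:
            subgroups.update(subgroup_analysis(
                surv_cohort.df, membership, strat, features=feats,
                n_perm=min(config.n_perm, 500),
                seed=int(ss_perm.generate_state(2)[1] % (2**31)),
                group_threshold=config.group_threshold,
                horizon=config.horizon))

    report = ClassifierReport(
        class_per_patient=classes, membership=membership, km=km,
        logrank_p_uncorrected=km.p, hrr_uni=hrr_uni, hrr_multi=hrr_multi,
        permutation=permutation, comparison=comparison,
        subgroup_results=subgroups)

    primary = None
    if config.primary_transfer:
        primary = apply_classifier_primary(model, surv_cohort, cutoffs,
                                           group_threshold=config.group_threshold,
                                           horizon=config.horizon)

    manifest = {
        "cartsurv_version": __version__,
        "config": dataclasses.asdict(config),
        "config_hash": chash,
        "seed": config.seed,
        "n_input": cohort.n,
        "n_analysis": surv_cohort.n,
        "tree_features": list(model.used_features()),
        "grouping": {"I": list(grouping.group_I), "II": list(grouping.group_II)},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=str))
    payload = report.to_dict()
    payload["config"] = chash
    if primary is not None:
        payload["primary_transfer"] = {
            "pruned_markers": list(primary.pruned_markers),
            "rule": primary.rule,
        }
    (out / "report.json").write_text(json.dumps(payload, indent=2,
                                                default=float))
    return PipelineResult(cohort=cohort, screening=screening,
                          candidates=candidates, cutoffs=cutoffs, model=model,
                          grouping=grouping, report=report, primary=primary,
                          manifest=manifest)
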