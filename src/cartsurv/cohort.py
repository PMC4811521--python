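"""Cohort data model, delimited-file IO, dichotomization and exclusion rules.

A cohort is one row per patient with overall survival (months from liver-
metastasis resection to death or censoring), an event indicator, five binary
clinicopathological risk factors, two subgroup labels, and per-biomarker
ordinal immunohistochemistry (IHC) scores: intensity (0 negative .. 3 strong)
and frequency (0 = 0-25% .. 3 = 76-100% positive cells), for the metastasis
("crclm") lesion and optionally the matched primary tumor ("prim").

File dialect: UTF-8 CSV, one header row, missing values as empty fields.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: the five established clinicopathological risk factors
CLINICAL_FLAGS = (
    "interval_lt_12mo",
    "node_positive",
    "diameter_gt_5cm",
    "multiple_crclm",
    "cea_gt_200",
)

SUBGROUP_COLUMNS = ("systemic_therapy", "primary_site")

BASE_COLUMNS = ("patient_id", "os_months", "event") + CLINICAL_FLAGS + SUBGROUP_COLUMNS

CHANNELS = ("intensity", "frequency")
_CHANNEL_SUFFIX = {"intensity": "int", "frequency": "freq"}
LESIONS = ("crclm", "prim")

#: minimum survival (months) required for any survival analysis
MIN_SURVIVAL_MONTHS = 2.0
#: horizon (months) of the three-year survival label
THREE_YEAR_MONTHS = 36.0

SCHEMA_VERSION = "cohort-v1"


class CohortValidationError(ValueError):
    """Raised when a cohort table violates the schema invariants."""


def score_column(marker: str, lesion: str = "crclm", channel: str = "intensity") -> str:
    if lesion not in LESIONS:
        raise ValueError(f"unknown lesion {lesion!r}")
    if channel not in CHANNELS:
        raise ValueError(f"unknown channel {channel!r}")
    return f"{marker}_{lesion}_{_CHANNEL_SUFFIX[channel]}"


def cohort_columns(markers: list[str] | tuple[str, ...]) -> list[str]:
    cols = list(BASE_COLUMNS)
    for m in markers:
        for lesion in LESIONS:
            for ch in CHANNELS:
                cols.append(score_column(m, lesion, ch))
    return cols


def column_dictionary(markers) -> pd.DataFrame:
    """Machine-readable description of the cohort file columns."""
    rows = [
        ("patient_id", "id", "opaque unique patient identifier"),
        ("os_months", "positive real", "overall survival, months from CRCLM resection"),
        ("event", "binary", "1 = died, 0 = censored"),
    ]
    descs = {
        "interval_lt_12mo": "primary tumor-to-CRCLM interval < 12 months",
        "node_positive": "lymph node positivity at primary diagnosis",
        "diameter_gt_5cm": "maximal CRCLM diameter > 5.0 cm",
        "multiple_crclm": "number of CRCLM > 1",
        "cea_gt_200": "serum CEA > 200 ng/ml",
    }
    for f in CLINICAL_FLAGS:
        rows.append((f, "binary (may be missing)", descs[f]))
    rows.append(("systemic_therapy", "binary (may be missing)", "systemic therapy given"))
    rows.append(("primary_site", "colon|rectum (may be missing)", "primary tumor site"))
    for m in markers:
        for lesion in LESIONS:
            where = "CRCLM lesion" if lesion == "crclm" else "matched primary tumor"
            rows.append((score_column(m, lesion, "intensity"), "ordinal 0-3",
                         f"{m} IHC staining intensity, {where}"))
            rows.append((score_column(m, lesion, "frequency"), "ordinal 0-3",
                         f"{m} IHC staining frequency, {where}"))
    return pd.DataFrame(rows, columns=["column", "type", "description"])


@dataclass
class Cutoff:
    """Dichotomization rule: 'high' iff ordinal score >= threshold."""

    marker: str
    channel: str
    threshold: int

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}, got {self.channel!r}")
        if self.threshold not in (1, 2, 3):
            raise ValueError(f"threshold must be in {{1,2,3}}, got {self.threshold!r}")

    @property
    def column(self) -> str:
        return score_column(self.marker, "crclm", self.channel)


@dataclass
class CohortTable:
    """Patient-level cohort table (one row per patient).

    ``df`` carries the columns of :func:`cohort_columns`.  ``markers`` lists
    the biomarkers whose score columns are present.
    """

    df: pd.DataFrame
    markers: tuple[str, ...]
    provenance: str = "file"
    seed: int | None = None

    def __post_init__(self) -> None:
        self.markers = tuple(self.markers)
        validate_cohort(self.df, self.markers)

    @property
    def n(self) -> int:
        return len(self.df)

    def copy(self) -> "CohortTable":
        return CohortTable(self.df.copy(), self.markers, self.provenance, self.seed)


def validate_cohort(df: pd.DataFrame, markers) -> None:
    missing = [c for c in ("patient_id", "os_months", "event") if c not in df.columns]
    if missing:
        raise CohortValidationError(f"missing required columns: {missing}")
    ids = df["patient_id"]
    dup = ids[ids.duplicated()].unique()
    if len(dup):
        raise CohortValidationError(f"duplicated patient_id values: {list(dup)[:10]}")
    os_known = df["os_months"].notna()
    if (df.loc[os_known, "os_months"] <= 0).any():
        bad = df.index[os_known & (df["os_months"] <= 0)].tolist()
        raise CohortValidationError(f"os_months must be > 0 (rows {bad[:10]})")
    ev = df["event"].dropna()
    if not ev.isin([0, 1]).all():
        raise CohortValidationError("event must be binary (0/1)")
    for m in markers:
        for lesion in LESIONS:
            for ch in CHANNELS:
                col = score_column(m, lesion, ch)
                if col in df.columns:
                    vals = df[col].dropna()
                    if not vals.isin([0, 1, 2, 3]).all():
                        raise CohortValidationError(
                            f"{col}: ordinal scores must lie in 0..3")


def infer_markers(columns) -> tuple[str, ...]:
    markers = []
    for c in columns:
        if c.endswith("_crclm_int"):
            markers.append(c[: -len("_crclm_int")])
    return tuple(markers)


def write_cohort(cohort: CohortTable, path) -> None:
    cohort.df.to_csv(path, index=False)


def read_cohort(path, schema_version: str = SCHEMA_VERSION) -> CohortTable:
    """Read a cohort CSV, type the columns and validate the schema.

    Unknown categories and empty fields are preserved as missing.  Malformed
    rows raise with their row numbers; a duplicated patient_id raises naming
    the id.
    """
    if schema_version != SCHEMA_VERSION:
        raise CohortValidationError(f"unsupported schema version {schema_version!r}")
    df = pd.read_csv(path, dtype={"patient_id": str, "primary_site": str})
    if "patient_id" not in df.columns:
        raise CohortValidationError("header lacks patient_id column")
    markers = infer_markers(df.columns)
    bad_rows = []
    for col in df.columns:
        if col in ("patient_id", "primary_site"):
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        newly_bad = df.index[coerced.isna() & df[col].notna()]
        bad_rows.extend(int(i) for i in newly_bad)
        df[col] = coerced
    if bad_rows:
        raise CohortValidationError(
            f"malformed numeric fields in rows {sorted(set(bad_rows))[:20]}")
    if "primary_site" in df.columns:
        site = df["primary_site"].str.strip().str.lower()
        site = site.where(site.isin(["colon", "rectum"]))
        df["primary_site"] = site
    cohort = CohortTable(df, markers, provenance="file")
    if cohort.n == 0:
        logger.warning("read empty cohort from %s", path)
    logger.info("read %d patients (%d markers) from %s", cohort.n, len(markers), path)
    return cohort


def dichotomize(scores, cutoff: Cutoff) -> np.ndarray:
    """Map ordinal scores to 1.0 (high, score >= threshold) / 0.0 (low);
    missing scores propagate as NaN."""
    s = np.asarray(pd.to_numeric(pd.Series(scores), errors="coerce"), dtype=float)
    out = np.where(np.isnan(s), np.nan, (s >= cutoff.threshold).astype(float))
    return out


def label_three_year(os_months, event):
    """Three-year survival label.

    died_within_36 iff event and os_months <= 36; survived_36 iff
    os_months > 36 (any event status); undefined iff censored at <= 36.
    Accepts scalars or arrays; returns str or object array.
    """
    os_arr = np.atleast_1d(np.asarray(os_months, dtype=float))
    ev_arr = np.atleast_1d(np.asarray(event, dtype=float))
    out = np.where(
        os_arr > THREE_YEAR_MONTHS,
        "survived_36",
        np.where(ev_arr == 1, "died_within_36", "undefined"),
    ).astype(object)
    out[np.isnan(os_arr) | np.isnan(ev_arr)] = "undefined"
    if np.isscalar(os_months) or np.ndim(os_months) == 0:
        return out[0]
    return out


@dataclass
class ExclusionLog:
    """Per-reason exclusion counts; counts sum to rows dropped."""

    counts: dict = field(default_factory=dict)

    def add(self, reason: str, n: int) -> None:
        if n:
            self.counts[reason] = self.counts.get(reason, 0) + int(n)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


_ANALYSES = ("survival", "three_year", "classifier")


def apply_exclusions(
    cohort: CohortTable,
    analysis: str = "survival",
    required: tuple[Cutoff, ...] | tuple = (),
) -> tuple[CohortTable, ExclusionLog]:
    """Apply the study exclusion rules and report per-reason counts.

    All survival analyses drop patients with unknown survival (time or event)
    or survival under two months.  ``three_year`` analyses additionally drop
    patients censored before the 36-month horizon (label undefined).
    ``required`` lists marker/channel cutoffs whose scores must be present
    (classifier analyses).  Idempotent by construction.
    """
    if analysis not in _ANALYSES:
        raise ValueError(f"analysis must be one of {_ANALYSES}")
    df = cohort.df
    log = ExclusionLog()
    keep = pd.Series(True, index=df.index)

    unknown = df["os_months"].isna() | df["event"].isna()
    log.add("unknown survival", int((keep & unknown).sum()))
    keep &= ~unknown

    short = df["os_months"] < MIN_SURVIVAL_MONTHS
    log.add("survival < 2 months", int((keep & short.fillna(False)).sum()))
    keep &= ~short.fillna(False)

    if analysis == "three_year":
        labels = label_three_year(df["os_months"].to_numpy(), df["event"].to_numpy())
        undefined = pd.Series(labels, index=df.index) == "undefined"
        log.add("three-year label undefined", int((keep & undefined).sum()))
        keep &= ~undefined

    for cut in required:
        col = cut.column
        if col not in df.columns:
            raise CohortValidationError(f"required score column {col} absent")
        miss = df[col].isna()
        log.add(f"missing {cut.marker} ({cut.channel})", int((keep & miss).sum()))
        keep &= ~miss

    out = df.loc[keep].reset_index(drop=True)
    if len(out) == 0:
        raise CohortValidationError("no evaluable patients after exclusions")
    result = CohortTable(out, cohort.markers, cohort.provenance, cohort.seed)
    logger.info("exclusions (%s): kept %d of %d (%s)", analysis, len(out),
                len(df), log.counts or "none")
    return result, log
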