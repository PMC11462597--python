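"""Patient-level survival data: reading, validation, derived variables and
design-matrix encoding.

The cohort is one row per patient: survival time in months since diagnosis,
an event indicator (1 = died, 0 = censored/alive at last follow-up), the
region the patient lives in, and categorical covariates (sex, age group,
histology, clinical stage, ECOG performance, smoking, MDT presentation,
diagnosing hospital, delay flags, comorbidities, remoteness, socioeconomic
quintile).  Derived-variable rules implemented here:

* diagnostic delay — referral-to-diagnosis interval strictly greater than
  28 days; treatment delay — diagnosis-to-treatment interval strictly
  greater than 42 days; a missing interval is "not_stated";
* ECOG performance dichotomised: score < 2 "good", >= 2 "poor";
* area socioeconomic score (IRSAD) quintiled over the supplied regions,
  quintile 1 = least advantaged fifth.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DAYS_PER_MONTH = 30.4375  # mean Gregorian month, for day->month conversion

TIMELY, DELAYED, NOT_STATED = "timely", "delayed", "not_stated"
GOOD, POOR = "good", "poor"

__all__ = [
    "SurvivalRecord",
    "CohortTable",
    "FactorSpec",
    "read_cohort",
    "write_cohort",
    "derive_delay_flags",
    "dichotomize_ecog",
    "assign_irsad_quantile",
    "encode_design",
]


@dataclass(frozen=True)
class SurvivalRecord:
    """One patient: follow-up time (months, > 0), event indicator and
    covariate values."""

    time: float
    event: int
    region_id: str
    covariates: dict

    def __post_init__(self) -> None:
        if not (self.time > 0) or not math.isfinite(self.time):
            raise ValueError(f"time must be a positive finite number, got {self.time}")
        if self.event not in (0, 1):
            raise ValueError(f"event must be 0 or 1, got {self.event}")
        if not self.region_id:
            raise ValueError("region_id must be non-empty")


@dataclass(frozen=True)
class FactorSpec:
    """A categorical covariate: ordered levels and the reference level
    (which contributes no indicator column under treatment contrasts)."""

    name: str
    levels: tuple[str, ...]
    reference: str

    def __post_init__(self) -> None:
        if self.reference not in self.levels:
            raise ValueError(
                f"reference {self.reference!r} not among levels of factor {self.name!r}"
            )


@dataclass(frozen=True)
class CohortTable:
    """Validated cohort with optional expanded design matrix.

    ``design`` (n x p) holds treatment-contrast indicator columns named in
    ``design_columns`` ("factor=level"); the reference level of each factor
    contributes no column, so p = sum(levels - 1) over encoded factors.
    """

    records: tuple[SurvivalRecord, ...]
    factor_metadata: tuple[FactorSpec, ...] = ()
    design_columns: tuple[str, ...] = ()
    design: np.ndarray | None = field(default=None, compare=False)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def times(self) -> np.ndarray:
        return np.array([r.time for r in self.records])

    @property
    def events(self) -> np.ndarray:
        return np.array([r.event for r in self.records], dtype=np.int64)

    @property
    def region_ids(self) -> list[str]:
        return [r.region_id for r in self.records]

    @property
    def n_events(self) -> int:
        return int(self.events.sum())

    def covariate(self, name: str) -> list:
        return [r.covariates.get(name) for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        base = pd.DataFrame(
            {
                "time_months": self.times,
                "event": self.events,
                "region_id": self.region_ids,
            }
        )
        cov = pd.DataFrame([r.covariates for r in self.records])
        return pd.concat([base, cov.set_index(base.index)], axis=1)


def read_cohort(
    path,
    schema: dict | None = None,
    *,
    strict: bool = True,
    factors: list[FactorSpec] | None = None,
    time_unit: str = "months",
) -> CohortTable:
    """Read and validate a cohort CSV.

    Parameters
    ----------
    path
        CSV with header; missing values empty or "NA".
    schema
        Optional mapping from the canonical names ``time``, ``event``,
        ``region_id`` to the file's column names.  Unmapped remaining
        columns are taken as covariates.
    strict
        If True, rows failing validation raise; otherwise they are dropped
        with a logged count (rows missing time or event are always dropped,
        with the count logged).
    factors
        If given, categorical values are checked against the declared
        levels (strict mode errors on unknown categories).
    time_unit
        "months" (default) stores times as-is; "days" divides by 30.4375.
    """
    schema = schema or {}
    col = {k: schema.get(k, k) for k in ("time", "event", "region_id")}
    if "time" not in schema and "time" not in pd.read_csv(path, nrows=0).columns:
        col["time"] = "time_months"
    df = pd.read_csv(path, dtype={col["region_id"]: str}, na_values=["", "NA"])
    for key, c in col.items():
        if c not in df.columns:
            raise KeyError(f"schema error: required column {c!r} (for {key!r}) missing")
    if time_unit not in ("months", "days"):
        raise ValueError(f"unknown time_unit {time_unit!r}")

    n_missing = int(df[col["time"]].isna().sum() + df[col["event"]].isna().sum())
    if n_missing:
        keep = df[col["time"]].notna() & df[col["event"]].notna()
        logger.info("dropped %d row(s) missing time or event", int((~keep).sum()))
        df = df[keep]

    times = pd.to_numeric(df[col["time"]], errors="coerce")
    bad_time = df.index[~(times > 0) | ~np.isfinite(times)].tolist()
    events = pd.to_numeric(df[col["event"]], errors="coerce")
    bad_event = df.index[~events.isin([0, 1])].tolist()
    bad = sorted(set(bad_time) | set(bad_event))
    if bad:
        rows = [i + 2 for i in bad]  # 1-based file rows incl. header
        msg = f"validation error in {len(bad)} row(s) (file rows {rows[:20]}): " \
              "time must be positive and event in {0,1}"
        if strict:
            raise ValueError(msg)
        logger.warning("%s -- dropped", msg)
        df = df.drop(index=bad)
        times = times.drop(index=bad)
        events = events.drop(index=bad)

    level_map = {f.name: set(f.levels) for f in (factors or [])}
    cov_cols = [c for c in df.columns if c not in col.values()]
    scale = 1.0 / DAYS_PER_MONTH if time_unit == "days" else 1.0

    records = []
    for idx, row in df.iterrows():
        covs = {}
        for c in cov_cols:
            v = row[c]
            covs[c] = None if pd.isna(v) else (str(v) if not isinstance(v, str) else v)
            if c in level_map and covs[c] is not None and covs[c] not in level_map[c]:
                msg = f"row {idx + 2}: unknown category {covs[c]!r} for factor {c!r}"
                if strict:
                    raise ValueError(msg)
                logger.warning(msg)
        records.append(
            SurvivalRecord(
                time=float(times.loc[idx]) * scale,
                event=int(events.loc[idx]),
                region_id=str(row[col["region_id"]]),
                covariates=covs,
            )
        )
    table = CohortTable(records=tuple(records), factor_metadata=tuple(factors or ()))
    if factors:
        table = encode_design(table, factors)
    return table


def write_cohort(cohort: CohortTable, path) -> None:
    """Write the cohort back to CSV (columns time_months, event, region_id,
    then covariates); round-trips bit-identically through read_cohort."""
    cohort.to_frame().to_csv(path, index=False, na_rep="NA")


def derive_delay_flags(
    referral_to_diagnosis_days: float | None,
    diagnosis_to_treatment_days: float | None,
) -> tuple[str, str]:
    """Classify the two care intervals.

    An interval that *exceeds* the threshold is delayed — strictly greater
    than 28 days for diagnosis, 42 days for treatment — so day 28/42 itself
    is timely.  A missing interval maps to "not_stated".
    """
    out = []
    for days, threshold in (
        (referral_to_diagnosis_days, 28),
        (diagnosis_to_treatment_days, 42),
    ):
        if days is None or (isinstance(days, float) and math.isnan(days)):
            out.append(NOT_STATED)
            continue
        if days < 0:
            raise ValueError(f"interval must be nonnegative, got {days}")
        out.append(DELAYED if days > threshold else TIMELY)
    return out[0], out[1]


def dichotomize_ecog(score: int | None) -> str:
    """ECOG performance 0-5 -> "good" (< 2) / "poor" (>= 2) / "not_stated"."""
    if score is None or (isinstance(score, float) and math.isnan(score)):
        return NOT_STATED
    if score != int(score) or not (0 <= score <= 5):
        raise ValueError(f"ECOG score must be an integer in 0..5, got {score}")
    return GOOD if score < 2 else POOR


def assign_irsad_quantile(region_scores: dict[str, float]) -> dict[str, int]:
    """Quintile regions by socioeconomic score; 1 = least advantaged fifth.

    Boundaries are the 20/40/60/80th percentiles of the supplied scores;
    ties broken by stable rank order so output is deterministic.
    """
    if len(region_scores) < 5:
        raise ValueError("need at least 5 regions to form quintiles")
    if len(set(region_scores.values())) == 1:
        warnings.warn("all scores equal; every region assigned quintile 1", stacklevel=2)
        return {r: 1 for r in region_scores}
    regions = list(region_scores)
    scores = np.array([region_scores[r] for r in regions], dtype=float)
    order = np.argsort(scores, kind="stable")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(len(regions))
    n = len(regions)
    # stable-rank quintiles: region with rank k falls in fifth floor(5k/n)+1
    quintile = (5 * ranks) // n + 1
    return {r: int(q) for r, q in zip(regions, quintile)}


def encode_design(cohort: CohortTable, factors: list[FactorSpec]) -> CohortTable:
    """Expand factors into treatment-contrast indicator columns.

    Each non-reference level of each factor yields one 0/1 column named
    "factor=level"; "not_stated" is an ordinary modelled level wherever it
    is declared, never dropped.
    """
    n = len(cohort)
    columns: list[str] = []
    data: list[np.ndarray] = []
    for spec in factors:
        observed = set()
        values = []
        for r in cohort.records:
            v = r.covariates.get(spec.name)
            if v is None:
                raise ValueError(f"record missing factor {spec.name!r}")
            if v not in spec.levels:
                raise ValueError(f"value {v!r} not a declared level of {spec.name!r}")
            observed.add(v)
            values.append(v)
        if spec.reference not in observed:
            raise ValueError(
                f"reference level {spec.reference!r} of factor {spec.name!r} never observed"
            )
        arr = np.asarray(values, dtype=object)
        for level in spec.levels:
            if level == spec.reference:
                continue
            columns.append(f"{spec.name}={level}")
            data.append((arr == level).astype(float))
    design = np.column_stack(data) if data else np.empty((n, 0))
    return replace(
        cohort,
        factor_metadata=tuple(factors),
        design_columns=tuple(columns),
        design=design,
    )
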