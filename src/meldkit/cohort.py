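"""Waiting-list cohort data model: file I/O, eligibility, outcome semantics.

A cohort lives in a pandas DataFrame with one row per transplant candidate.
Canonical columns (the column dictionary of the delimiter-separated cohort
file):

    id, age, sex, race, dx, weight_kg, blood_group, region,
    bili_mgdl, creat_mgdl, inr, na_mmoll, alb_gdl, dialysis,
    followup_days, outcome

``outcome`` is one of ``death``, ``transplant``, ``removal_too_sick``,
``withdrawal``, ``administrative_censor``.  Missing numeric values (notably
sodium) are empty fields on disk and NaN in memory.  Optional boolean
eligibility-flag columns (``multi_organ``, ``living_donor``, ``status_1``,
``inactive``, ``exception_case``, ``prior_transplant``) default to false when
absent.

Outcome semantics follow waiting-list mortality convention: death within the
horizon is the event; transplantation, withdrawal, and end of follow-up censor;
removal because the candidate became too sick to transplant is counted as a
death by default (toggleable, since it is a judgement call with a documented
sensitivity in the literature).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields as dc_fields

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "OUTCOMES",
    "REQUIRED_COLUMNS",
    "Candidate",
    "EligibilityCriteria",
    "OutcomeAtHorizon",
    "read_cohort",
    "write_cohort",
    "apply_eligibility",
    "outcome_at_horizon",
    "outcomes_at_horizon",
]

OUTCOMES = (
    "death",
    "transplant",
    "removal_too_sick",
    "withdrawal",
    "administrative_censor",
)

REQUIRED_COLUMNS = (
    "id",
    "age",
    "bili_mgdl",
    "creat_mgdl",
    "inr",
    "alb_gdl",
    "followup_days",
    "outcome",
)

OPTIONAL_NUMERIC = ("na_mmoll", "weight_kg")
FLAG_COLUMNS = (
    "multi_organ",
    "living_donor",
    "status_1",
    "inactive",
    "exception_case",
    "prior_transplant",
)


@dataclass(frozen=True)
class Candidate:
    """One waiting-list registrant (a typed view of a cohort row)."""

    id: str
    age: float
    followup_days: float
    outcome: str
    bili_mgdl: float
    creat_mgdl: float
    inr: float
    alb_gdl: float
    na_mmoll: float | None = None
    sex: str = ""
    race: str = ""
    dx: str = ""
    weight_kg: float | None = None
    blood_group: str = ""
    region: str = ""
    dialysis: bool = False

    def __post_init__(self) -> None:
        if self.followup_days < 0:
            raise ValueError(f"followup_days must be >= 0, got {self.followup_days}")
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")

    @classmethod
    def from_row(cls, row: pd.Series) -> "Candidate":
        kwargs = {}
        for f in dc_fields(cls):
            if f.name in row.index:
                v = row[f.name]
                kwargs[f.name] = None if pd.isna(v) else v
        kwargs["id"] = str(kwargs["id"])
        kwargs["dialysis"] = bool(kwargs.get("dialysis") or False)
        return cls(**kwargs)


@dataclass(frozen=True)
class EligibilityCriteria:
    """Listing eligibility filter; each exclusion independently toggleable.

    Order of fields is the order of precedence when a candidate matches
    several rules (first matching rule is the recorded reason).
    """

    min_age: float = 18.0
    exclude_multi_organ: bool = True
    exclude_living_donor: bool = True
    exclude_status_1: bool = True
    exclude_inactive: bool = True
    exclude_exception_case: bool = True
    exclude_prior_transplant: bool = True
    exclude_missing_labs: bool = True
    required_labs: tuple[str, ...] = ("bili_mgdl", "creat_mgdl", "inr", "alb_gdl")


@dataclass(frozen=True)
class OutcomeAtHorizon:
    """Event indicator and analysis time after applying the horizon."""

    event: bool
    time: float
    horizon_days: float = 90.0

    def __post_init__(self) -> None:
        if self.time > self.horizon_days:
            raise ValueError("analysis time cannot exceed the horizon")


def read_cohort(path, column_map: dict[str, str] | None = None, sep: str = ",") -> pd.DataFrame:
    """Read a delimiter-separated cohort file into the canonical frame.

    ``column_map`` maps source column names to canonical ones.  Rows whose
    numeric fields fail to parse are dropped and reported (with 1-based data
    line numbers) via the logger.  A missing mandatory column raises a schema
    error listing every absentee.
    """
    df = pd.read_csv(path, sep=sep, dtype={"id": str})
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory columns: {', '.join(missing)}")

    numeric = ["age", "bili_mgdl", "creat_mgdl", "inr", "alb_gdl", "followup_days"]
    numeric += [c for c in OPTIONAL_NUMERIC if c in df.columns]
    bad = pd.Series(False, index=df.index)
    for c in numeric:
        coerced = pd.to_numeric(df[c], errors="coerce")
        # labs may be legitimately empty (missingness is an eligibility
        # question, not a parse error); text in a numeric field is a bad row
        newly_bad = coerced.isna() & df[c].notna()
        if c in ("age", "followup_days"):
            newly_bad |= df[c].isna()
        bad |= newly_bad
        df[c] = coerced
    bad |= ~df["outcome"].isin(OUTCOMES)
    bad |= df["followup_days"] < 0
    if bad.any():
        for i in df.index[bad]:
            logger.warning("read_cohort: rejected line %d (unparseable or invalid)", i + 2)
        df = df[~bad]
    if "dialysis" in df.columns:
        df["dialysis"] = df["dialysis"].fillna(0).astype(bool)
    else:
        df["dialysis"] = False
    return df.reset_index(drop=True)


def write_cohort(df: pd.DataFrame, path, sep: str = ",") -> None:
    """Write a cohort frame; inverse of :func:`read_cohort`."""
    df.to_csv(path, sep=sep, index=False)


def apply_eligibility(
    cohort: pd.DataFrame, criteria: EligibilityCriteria | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Filter a cohort; returns (retained, exclusion ledger).

    The ledger records exactly one reason per excluded candidate, using the
    first matching rule in precedence order.  Retained + excluded counts equal
    the input count.
    """
    criteria = criteria or EligibilityCriteria()
    n = len(cohort)
    reason = pd.Series([""] * n, index=cohort.index, dtype=object)

    def flag(col: str) -> pd.Series:
        if col in cohort.columns:
            return cohort[col].fillna(False).astype(bool)
        return pd.Series(False, index=cohort.index)

    rules: list[tuple[str, pd.Series]] = [("age", cohort["age"] < criteria.min_age)]
    for crit, col in (
        (criteria.exclude_multi_organ, "multi_organ"),
        (criteria.exclude_living_donor, "living_donor"),
        (criteria.exclude_status_1, "status_1"),
        (criteria.exclude_inactive, "inactive"),
        (criteria.exclude_exception_case, "exception_case"),
        (criteria.exclude_prior_transplant, "prior_transplant"),
    ):
        if crit:
            rules.append((col, flag(col)))
    if criteria.exclude_missing_labs:
        miss = pd.Series(False, index=cohort.index)
        for lab in criteria.required_labs:
            if lab in cohort.columns:
                miss |= cohort[lab].isna()
            else:
                miss |= True
        rules.append(("missing labs", miss))

    for name, mask in rules:  # first matching rule wins
        hit = mask & (reason == "")
        reason[hit] = name

    excluded = reason != ""
    ledger = pd.DataFrame(
        {"id": cohort.loc[excluded, "id"].values, "reason": reason[excluded].values}
    )
    return cohort[~excluded].reset_index(drop=True), ledger


def outcome_at_horizon(
    candidate: Candidate, horizon_days: float = 90.0, too_sick_as_death: bool = True
) -> OutcomeAtHorizon:
    """Resolve one candidate's event status at the horizon.

    Death (and, when ``too_sick_as_death``, removal for being too sick) within
    the horizon is the event; the event-at-exactly-horizon case counts as
    within ("within 90 days" read as <= 90).  Everything else censors at
    ``min(followup, horizon)``; transplantation censors at transplant time.
    """
    if candidate.followup_days < 0:
        raise ValueError("negative follow-up")
    death_like = candidate.outcome == "death" or (
        too_sick_as_death and candidate.outcome == "removal_too_sick"
    )
    event = bool(death_like and candidate.followup_days <= horizon_days)
    return OutcomeAtHorizon(
        event=event,
        time=min(candidate.followup_days, horizon_days),
        horizon_days=horizon_days,
    )


def outcomes_at_horizon(
    cohort: pd.DataFrame, horizon_days: float = 90.0, too_sick_as_death: bool = True
) -> pd.DataFrame:
    """Vectorized :func:`outcome_at_horizon`; returns columns ``time``, ``event``."""
    if (cohort["followup_days"] < 0).any():
        raise ValueError("negative follow-up in cohort")
    death_like = cohort["outcome"].eq("death")
    if too_sick_as_death:
        death_like |= cohort["outcome"].eq("removal_too_sick")
    event = death_like & (cohort["followup_days"] <= horizon_days)
    time = np.minimum(cohort["followup_days"].to_numpy(float), horizon_days)
    return pd.DataFrame({"time": time, "event": event.to_numpy(bool)}, index=cohort.index)
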