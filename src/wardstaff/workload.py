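"""Deterministic workload arithmetic for one ward-day.

From a day's patient classification census to: required establishment (WTE),
implied daily care hours, the registered-nurse / nursing-assistant split,
staffing shortfalls in hours per patient day (HPPD), and patient turnover per
staff hour.

Sign convention: shortfall = required - deployed, so positive values mean the
ward was understaffed relative to the tool's estimate.

The reporting day runs 07:00-07:00; patient_hours are occupied-bed hours over
that window, and patient-days are patient_hours / 24.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import MultiplierSet

logger = logging.getLogger(__name__)


class EmptyCensusError(ValueError):
    """Raised when a shift-leader census contains no patients."""


class UndefinedDayError(ValueError):
    """Raised when a quantity is undefined for the day (e.g. zero patient-hours)."""


@dataclass(frozen=True)
class CensusDay:
    """One unit-day's patient classification and flows.

    ``admin_patient_count`` comes from the patient administration system at
    07:00 and may legitimately differ from the sum of the shift leader's
    per-level counts: the establishment calculation deliberately multiplies
    the census-weighted multiplier by the administrative count in case
    patients were omitted from shift-leader reports.
    """

    unit_id: str
    date: object
    counts_per_level: Mapping[str, float]
    admin_patient_count: float
    patient_hours: float
    admissions: float = 0.0
    discharges: float = 0.0
    specialing_count: float = 0.0
    assessment_time: object = None

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.counts_per_level.values()):
            raise ValueError("level counts must be >= 0")
        if self.admin_patient_count < 0:
            raise ValueError("admin_patient_count must be >= 0")
        if self.patient_hours < 0:
            raise ValueError("patient_hours must be >= 0")
        if min(self.admissions, self.discharges, self.specialing_count) < 0:
            raise ValueError("flows and specialing counts must be >= 0")


@dataclass(frozen=True)
class StaffingDay:
    """Deployed care hours for one unit-day, 07:00-07:00."""

    unit_id: str
    date: object
    rn_hours: float
    na_hours: float
    planned_skill_mix: float = 0.5

    def __post_init__(self) -> None:
        if self.rn_hours < 0 or self.na_hours < 0:
            raise ValueError("deployed hours must be >= 0")
        if not 0.0 <= self.planned_skill_mix <= 1.0:
            raise ValueError("planned_skill_mix must lie in [0, 1]")


@dataclass(frozen=True)
class WorkloadResult:
    """Derived staffing quantities for one unit-day."""

    establishment_wte: float
    required_daily_hours: float
    required_rn_hours: float
    required_na_hours: float
    rn_shortfall_hppd: float
    na_shortfall_hppd: float
    total_hppd: float
    requirement_hppd: float
    turnover_per_staff_hour: float


def weighted_multiplier(
    counts_per_level: Mapping[str, float], multipliers: MultiplierSet
) -> float:
    """Census-weighted mean of the level multipliers.

    Returns sum(n_l * m_l) / sum(n_l) over the levels present in the
    multiplier set; raises :class:`EmptyCensusError` on an all-zero census so
    the caller can decide whether to skip the day.
    """
    total = 0.0
    weighted = 0.0
    for level, mult in zip(multipliers.levels, multipliers.multipliers):
        n = float(counts_per_level.get(level, 0.0))
        if n < 0:
            raise ValueError(f"negative count for level {level!r}")
        total += n
        weighted += n * mult
    if total == 0:
        raise EmptyCensusError("census has no patients in any level")
    return weighted / total


def establishment_wte(census: CensusDay, multipliers: MultiplierSet) -> float:
    """Required unit establishment (staff to employ, WTE) for one day.

    Weighted multiplier x administrative patient count.  Zero when the
    administrative count is zero; an empty shift-leader census with a nonzero
    administrative count is an error because no multiplier is defined.
    """
    if census.admin_patient_count == 0:
        return 0.0
    return weighted_multiplier(census.counts_per_level, multipliers) * float(
        census.admin_patient_count
    )


def establishment_to_daily_hours(
    establishment: float, multipliers: MultiplierSet
) -> float:
    """Convert an establishment (WTE) into implied daily care hours.

    Removes the uplift (which funds leave and sickness, not bedside hours)
    and converts contracted weekly hours to a daily figure:
    ``establishment / (1 + uplift) * weekly_hours / 7``.
    """
    if establishment < 0:
        raise ValueError("establishment must be >= 0")
    return (
        establishment
        / (1.0 + multipliers.uplift_fraction)
        * multipliers.wte_weekly_hours
        / 7.0
    )


def daily_hours_to_establishment(hours: float, multipliers: MultiplierSet) -> float:
    """Inverse of :func:`establishment_to_daily_hours`."""
    if hours < 0:
        raise ValueError("hours must be >= 0")
    return hours * (1.0 + multipliers.uplift_fraction) * 7.0 / multipliers.wte_weekly_hours


def required_hours(
    census: CensusDay,
    multipliers: MultiplierSet,
    include_specialing: bool = False,
) -> float:
    """Required daily care hours for one unit-day.

    Specialing (one-to-one supervision) hours are added only when
    ``include_specialing`` is set: ON for daily shortfall calculations, OFF
    when estimating establishments, because the enhanced care that drives
    specialing is already averaged into the tool's multipliers.
    """
    base = establishment_to_daily_hours(establishment_wte(census, multipliers), multipliers)
    if include_specialing:
        base += census.specialing_count * multipliers.specialing_hours_per_patient_day
    return base


def split_by_skill_mix(hours: float, planned_skill_mix: float) -> tuple[float, float]:
    """Split care hours into (registered-nurse, assistant) by the planned mix."""
    if not 0.0 <= planned_skill_mix <= 1.0:
        raise ValueError("planned_skill_mix must lie in [0, 1]")
    rn = hours * planned_skill_mix
    return rn, hours - rn


def hppd(staff_hours: float, patient_hours: float) -> float:
    """Hours per patient day: staff hours / (patient hours / 24)."""
    if patient_hours <= 0:
        raise UndefinedDayError("patient_hours must be > 0 for an HPPD")
    return staff_hours / (patient_hours / 24.0)


def shortfall_hppd(
    required: float, deployed: float, patient_hours: float
) -> float:
    """Signed staffing shortfall in HPPD: positive means understaffed."""
    return hppd(required - deployed, patient_hours)


def turnover_per_staff_hour(
    admissions: float, discharges: float, total_staff_hours: float
) -> float:
    """Patients entering plus leaving, per deployed staff hour."""
    if total_staff_hours <= 0:
        raise ValueError("total_staff_hours must be > 0")
    return (admissions + discharges) / total_staff_hours


def compute_workload(
    census: CensusDay, staffing: StaffingDay, multipliers: MultiplierSet
) -> WorkloadResult:
    """All derived staffing quantities for one linked unit-day."""
    est = establishment_wte(census, multipliers)
    req = required_hours(census, multipliers, include_specialing=True)
    req_rn, req_na = split_by_skill_mix(req, staffing.planned_skill_mix)
    deployed = staffing.rn_hours + staffing.na_hours
    return WorkloadResult(
        establishment_wte=est,
        required_daily_hours=req,
        required_rn_hours=req_rn,
        required_na_hours=req_na,
        rn_shortfall_hppd=shortfall_hppd(req_rn, staffing.rn_hours, census.patient_hours),
        na_shortfall_hppd=shortfall_hppd(req_na, staffing.na_hours, census.patient_hours),
        total_hppd=hppd(deployed, census.patient_hours),
        requirement_hppd=hppd(req, census.patient_hours),
        turnover_per_staff_hour=turnover_per_staff_hour(
            census.admissions, census.discharges, deployed
        ),
    )


# ---------------------------------------------------------------------------
# Vectorised table interface

LEVEL_COLUMNS = {
    "0": "n_level0",
    "1a": "n_level1a",
    "1b": "n_level1b",
    "2": "n_level2",
    "3": "n_level3",
}


def level_column(level: str) -> str:
    return LEVEL_COLUMNS.get(level, f"n_level{level}")


def workload_table(
    census: pd.DataFrame,
    staffing: pd.DataFrame,
    multipliers: MultiplierSet,
    skill_mix: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Compute per-day workload quantities for whole census/staffing tables.

    ``census`` follows the census.csv layout (one row per unit-day with
    ``n_level*`` columns, ``admin_count_0700``, ``patient_hours``, flows and
    ``specialing_count``); ``staffing`` carries ``rn_hours``/``na_hours``.
    ``skill_mix`` maps unit_id -> planned RN proportion; when omitted it is
    estimated as each unit's average observed RN share of deployed hours (the
    study's proxy for the planned skill mix).

    Days with zero patient-hours or an empty census are excluded with a
    logged warning rather than imputed.
    """
    df = census.merge(staffing, on=["unit_id", "date"], how="inner", validate="1:1")

    cols = [level_column(lv) for lv in multipliers.levels]
    counts = df[cols].to_numpy(dtype=float)
    mults = np.asarray(multipliers.multipliers, dtype=float)
    census_total = counts.sum(axis=1)

    bad = (census_total == 0) | (df["patient_hours"].to_numpy(dtype=float) <= 0)
    if bad.any():
        logger.warning(
            "excluding %d unit-days with empty census or zero patient-hours", bad.sum()
        )
        df = df.loc[~bad].reset_index(drop=True)
        counts = counts[~bad]
        census_total = census_total[~bad]

    if skill_mix is None:
        deployed = df["rn_hours"] + df["na_hours"]
        obs = df["rn_hours"] / deployed.where(deployed > 0)
        skill_mix = obs.groupby(df["unit_id"]).mean().to_dict()
    mix = df["unit_id"].map(skill_mix).to_numpy(dtype=float)

    wmult = counts @ mults / census_total
    est = wmult * df["admin_count_0700"].to_numpy(dtype=float)
    base_hours = est / (1.0 + multipliers.uplift_fraction) * multipliers.wte_weekly_hours / 7.0
    req = base_hours + (
        df["specialing_count"].to_numpy(dtype=float)
        * multipliers.specialing_hours_per_patient_day
    )
    req_rn = req * mix
    req_na = req - req_rn
    pdays = df["patient_hours"].to_numpy(dtype=float) / 24.0
    rn_dep = df["rn_hours"].to_numpy(dtype=float)
    na_dep = df["na_hours"].to_numpy(dtype=float)
    deployed_total = rn_dep + na_dep

    out = df[["unit_id", "date"]].copy()
    out["weighted_multiplier"] = wmult
    out["establishment_wte"] = est
    out["required_daily_hours"] = req
    out["required_rn_hours"] = req_rn
    out["required_na_hours"] = req_na
    out["rn_shortfall_hppd"] = (req_rn - rn_dep) / pdays
    out["na_shortfall_hppd"] = (req_na - na_dep) / pdays
    out["total_shortfall_hppd"] = (req - deployed_total) / pdays
    out["total_hppd"] = deployed_total / pdays
    out["requirement_hppd"] = req / pdays
    out["skill_mix"] = mix
    with np.errstate(divide="ignore", invalid="ignore"):
        out["turnover_per_staff_hour"] = np.where(
            deployed_total > 0,
            (
                df["admissions"].to_numpy(dtype=float)
                + df["discharges"].to_numpy(dtype=float)
            )
            / deployed_total,
            np.nan,
        )
    return out


def establishment_series(
    census: pd.DataFrame, multipliers: MultiplierSet
) -> dict[str, np.ndarray]:
    """Time-ordered daily establishment estimates (WTE) per unit.

    Days with an empty shift-leader census are skipped.
    """
    cols = [level_column(lv) for lv in multipliers.levels]
    counts = census[cols].to_numpy(dtype=float)
    total = counts.sum(axis=1)
    keep = total > 0
    mults = np.asarray(multipliers.multipliers, dtype=float)
    est = np.full(len(census), np.nan)
    est[keep] = (
        counts[keep] @ mults / total[keep]
        * census["admin_count_0700"].to_numpy(dtype=float)[keep]
    )
    frame = census[["unit_id", "date"]].copy()
    frame["establishment"] = est
    frame = frame.dropna(subset=["establishment"]).sort_values(["unit_id", "date"])
    return {
        unit: grp["establishment"].to_numpy()
        for unit, grp in frame.groupby("unit_id", sort=True)
    }
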