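"""Cleaning and linkage rules applied before modelling.

The modelling stage sees one record per unit-day: the 07:00-07:00 staffing
and census window of day d, joined to the staffing-adequacy microsurvey
answered the following morning (which reports on the preceding 24 h).
Cleaning covers: choosing one acuity assessment per day, removing extreme
shortfall days (mean ± 3 SD within unit), splitting units at major
configuration changes, and detecting units whose yes/no responses were
consistently reverse-coded by mistrained staff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RESPONSE_COLUMNS = ("enough_staff", "care_left_undone", "breaks_missed")


def select_daily_assessment(assessments: pd.DataFrame) -> pd.DataFrame:
    """Keep the first available acuity rating per unit-day.

    Morning ratings are preferred simply because they come first; when the
    morning rating is missing, a later assessment from the same day
    substitutes.  Returns one row per (unit_id, date) present in the input;
    unit-days with no assessment at all are simply absent.
    """
    if assessments.empty:
        return assessments.copy()
    ordered = assessments.sort_values(["unit_id", "date", "assessment_time"])
    return ordered.groupby(["unit_id", "date"], as_index=False).first()


def remove_shortfall_outliers(
    linked: pd.DataFrame,
    k_sd: float = 3.0,
    column: str = "total_shortfall_hppd",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop unit-days whose shortfall lies outside mean ± k_sd·SD.

    The rule is applied within unit, targeting atypical periods for that ward
    (e.g. holiday closures) and gross recording errors.  Returns the
    ``(kept, removed)`` partition so the removal is auditable; with SD zero
    (identical values) nothing is removed.
    """
    vals = linked[column]
    grp = vals.groupby(linked["unit_id"])
    mean = grp.transform("mean")
    sd = grp.transform("std").fillna(0.0)
    outlier = (vals - mean).abs() > k_sd * sd
    outlier &= sd > 0
    kept = linked.loc[~outlier]
    removed = linked.loc[outlier]
    if len(removed):
        logger.info(
            "outlier rule removed %d of %d unit-days (%.2f%%)",
            len(removed),
            len(linked),
            100.0 * len(removed) / len(linked),
        )
    return kept, removed


def split_units_on_change(
    timeline: pd.DataFrame,
    change_events: pd.DataFrame,
    min_segment_days: int = 28,
) -> pd.DataFrame:
    """Treat a unit as separate units before/after major configuration changes.

    ``change_events`` has columns ``unit_id, date``; each dated event starts a
    new segment, and each segment gets a derived id ``<unit>/a``, ``<unit>/b``
    ...  Segments shorter than ``min_segment_days`` are dropped with a log
    entry (too short to support any audit-length analysis).  Units without
    events keep their original id.
    """
    if change_events.empty:
        return timeline.copy()
    events = {
        unit: np.sort(pd.to_datetime(grp["date"]).to_numpy())
        for unit, grp in change_events.groupby("unit_id")
    }
    out = timeline.copy()
    dates = pd.to_datetime(out["date"])
    new_ids = out["unit_id"].astype(str).copy()
    for unit, cuts in events.items():
        mask = out["unit_id"] == unit
        if not mask.any():
            raise ValueError(f"change event for unknown unit {unit!r}")
        seg = np.searchsorted(cuts, dates[mask].to_numpy(), side="right")
        suffix = np.array([chr(ord("a") + s) for s in seg])
        new_ids.loc[mask] = unit + "/" + suffix
    out["unit_id"] = new_ids
    sizes = out.groupby("unit_id")["date"].count()
    too_short = sizes[sizes < min_segment_days].index
    if len(too_short):
        logger.info(
            "dropping %d segments shorter than %d days: %s",
            len(too_short),
            min_segment_days,
            ", ".join(too_short),
        )
        out = out[~out["unit_id"].isin(too_short)]
    return out.reset_index(drop=True)


@dataclass
class ReverseCodingReport:
    flagged_units: list[str] = field(default_factory=list)
    fleet_medians: dict[str, float] = field(default_factory=dict)
    unit_rates: pd.DataFrame | None = None
    skipped_units: list[str] = field(default_factory=list)


def detect_and_recode_reverse_coding(
    responses: pd.DataFrame,
    min_days: int = 30,
    enabled: bool = True,
) -> tuple[pd.DataFrame, ReverseCodingReport]:
    """Detect units whose yes/no answers were entered with inverted coding.

    Mistrained staff on some units recorded 0 for yes and 1 for no,
    consistently across the three adequacy questions.  Such a unit's response
    *rates* sit on the wrong side of 0.5: "enough staff" (fleet-typical rate
    ~0.78) drops below 0.5 while "care left undone" and "breaks missed"
    (fleet-typical ~0.05) rise above it.  Pairwise associations between the
    responses are useless here — inverting every answer preserves them — so
    the rule votes on rate direction: a unit is flagged when at least two of
    its three rates fall on the opposite side of 0.5 from the fleet median.
    An honestly struggling ward (low "enough staff" but also low "care left
    undone") casts at most one discordant vote and is never flagged.

    Flagged units have all three binaries inverted in the returned copy.
    Units with fewer than ``min_days`` responded days are left untouched with
    a warning.  The recode is an involution at unit level: re-running
    detection on the output does not re-flag a recoded unit.
    """
    report = ReverseCodingReport()
    out = responses.copy()
    if not enabled or out.empty:
        return out, report

    rates = out.groupby("unit_id")[list(RESPONSE_COLUMNS)].mean()
    counts = out.groupby("unit_id")["enough_staff"].count()
    medians = rates.median()
    report.fleet_medians = medians.to_dict()
    report.unit_rates = rates

    for unit in rates.index:
        if counts[unit] < min_days:
            report.skipped_units.append(unit)
            logger.warning(
                "unit %s has only %d responded days (<%d); reverse-coding "
                "check skipped",
                unit,
                counts[unit],
                min_days,
            )
            continue
        votes = sum(
            1
            for col in RESPONSE_COLUMNS
            # discordant: the unit's rate and the fleet median lie on
            # opposite sides of 0.5
            if (rates.loc[unit, col] - 0.5) * (medians[col] - 0.5) < 0
        )
        if votes >= 2:
            report.flagged_units.append(unit)
            logger.info(
                "unit %s flagged as reverse-coded (rates %s vs fleet medians %s)",
                unit,
                rates.loc[unit].round(3).to_dict(),
                medians.round(3).to_dict(),
            )
    if report.flagged_units:
        mask = out["unit_id"].isin(report.flagged_units)
        for col in RESPONSE_COLUMNS:
            out.loc[mask, col] = 1 - out.loc[mask, col]
    return out, report


def link_day(
    workload: pd.DataFrame,
    responses: pd.DataFrame,
    profiles: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Join each staffing day to the next morning's adequacy responses.

    The microsurvey answered on the morning of day d+1 reports on the
    07:00-07:00 window that started on day d, so responses are joined at
    ``response date - 1 day``.  Duplicate unit-day keys raise; unmatched
    responses (orphans) and staffing days without a response are counted in
    the frame's ``attrs['linkage']``.  Unit profile attributes (hospital,
    specialty, single rooms) are merged on when given.
    """
    for name, frame in ("workload", workload), ("responses", responses):
        dup = frame.duplicated(["unit_id", "date"])
        if dup.any():
            offenders = frame.loc[dup, ["unit_id", "date"]].head(5)
            raise ValueError(f"duplicate unit-days in {name}: {offenders.to_dict('records')}")
    resp = responses.copy()
    resp["date"] = pd.to_datetime(resp["date"]) - pd.Timedelta(days=1)
    left = workload.copy()
    left["date"] = pd.to_datetime(left["date"])
    linked = left.merge(
        resp.drop(columns=["response_time"], errors="ignore"),
        on=["unit_id", "date"],
        how="left",
        indicator=True,
    )
    n_without_outcome = int((linked["_merge"] == "left_only").sum())
    orphan_keys = set(zip(resp["unit_id"], resp["date"])) - set(
        zip(left["unit_id"], left["date"])
    )
    linked = linked.drop(columns="_merge")
    if profiles is not None:
        clash = [c for c in profiles.columns if c != "unit_id" and c in linked.columns]
        linked = linked.drop(columns=clash).merge(
            profiles, on="unit_id", how="left", validate="m:1"
        )
    linked["day_of_week"] = pd.to_datetime(linked["date"]).dt.day_name()
    linked.attrs["linkage"] = {
        "n_linked": len(linked),
        "n_without_outcome": n_without_outcome,
        "n_orphan_responses": len(orphan_keys),
    }
    if orphan_keys:
        logger.info("%d responses had no matching staffing day", len(orphan_keys))
    return linked
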