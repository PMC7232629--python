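"""Configuration objects for the SNCT staffing calculations.

The Safer Nursing Care Tool (SNCT) classifies ward patients into acuity/
dependency levels; each level carries a multiplier giving the whole-time-
equivalent (WTE) staff required per patient.  The establishment produced by
the tool already contains an "uplift" covering annual leave, study time and
sickness, which must be removed when converting an establishment into daily
care hours actually available at the bedside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

#: Default multipliers for the five general adult inpatient levels.  These are
#: the published tool constants, shipped here as editable configuration.
DEFAULT_LEVELS = ("0", "1a", "1b", "2", "3")
DEFAULT_MULTIPLIERS = (0.99, 1.39, 1.72, 1.97, 5.96)


@dataclass(frozen=True)
class MultiplierSet:
    """The level->WTE weights plus uplift and working-week constants.

    Parameters
    ----------
    levels
        Ordered level labels.
    multipliers
        WTE required per patient at each level, aligned with ``levels``.
    uplift_fraction
        Fraction added on top of the base requirement to cover leave and
        sickness (0.22 means the establishment is 1.22x the base need).
    wte_weekly_hours
        Contracted hours per week for one whole-time-equivalent member of
        staff.
    specialing_hours_per_patient_day
        Care hours added per patient requiring continuous one-to-one
        supervision ("specialing").
    """

    levels: tuple[str, ...] = DEFAULT_LEVELS
    multipliers: tuple[float, ...] = DEFAULT_MULTIPLIERS
    uplift_fraction: float = 0.22
    wte_weekly_hours: float = 37.5
    specialing_hours_per_patient_day: float = 24.0

    def __post_init__(self) -> None:
        if len(self.levels) < 1:
            raise ValueError("at least one acuity level is required")
        if len(self.levels) != len(self.multipliers):
            raise ValueError(
                f"{len(self.levels)} levels but {len(self.multipliers)} multipliers"
            )
        if any(m <= 0 for m in self.multipliers):
            raise ValueError("all multipliers must be > 0")
        if self.uplift_fraction < 0:
            raise ValueError("uplift_fraction must be >= 0")
        if self.wte_weekly_hours <= 0:
            raise ValueError("wte_weekly_hours must be > 0")
        if self.specialing_hours_per_patient_day < 0:
            raise ValueError("specialing hours must be >= 0")

    @property
    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.levels, self.multipliers))

    @classmethod
    def from_yaml(cls, path) -> "MultiplierSet":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            levels=tuple(str(x) for x in raw["levels"]),
            multipliers=tuple(float(x) for x in raw["multipliers"]),
            uplift_fraction=float(raw.get("uplift_fraction", 0.22)),
            wte_weekly_hours=float(raw.get("wte_weekly_hours", 37.5)),
            specialing_hours_per_patient_day=float(
                raw.get("specialing_hours_per_patient_day", 24.0)
            ),
        )

    def to_yaml(self, path) -> None:
        payload = {
            "levels": list(self.levels),
            "multipliers": [float(m) for m in self.multipliers],
            "uplift_fraction": self.uplift_fraction,
            "wte_weekly_hours": self.wte_weekly_hours,
            "specialing_hours_per_patient_day": self.specialing_hours_per_patient_day,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)
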