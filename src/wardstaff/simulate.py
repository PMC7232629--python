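"""Synthetic hospital-fleet generator.

Builds fleets of hospitals x units x days with the statistical structure the
analysis assumes: per-unit acuity census tables whose daily establishment
series has a planted coefficient of variation, deployed staffing as the
requirement minus a Normal shortfall draw, and three binary adequacy
outcomes sampled from the three-level logistic model with planted
coefficients and random-intercept variances.  The defaults reproduce the
study conditions: 4 hospitals x 20 units x 365 days, mean census ~21.3
patients, mean weighted multiplier 1.64 (hence mean establishment ~35 WTE
and requirement ~7.2 HPPD), per-unit establishment CV averaging 9.4%,
shortfalls ~ N(0.1, 0.9) HPPD, and marginal outcome rates 0.78 / 0.05 /
0.05.

Contamination injectors (reverse-coded units, missing morning assessments
and responses) write their ground truth to a sidecar dict so the cleaning
rules can be tested round-trip.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import optimize, special

from .config import MultiplierSet
from .workload import workload_table
from .cleaning import RESPONSE_COLUMNS, link_day, select_daily_assessment

WEEKDAY_ORDER = ("Tuesday", "Wednesday", "Thursday", "Friday", "Saturday", "Sunday")


@dataclass(frozen=True)
class FleetConfig:
    """Shape and unit-attribute distributions of the synthetic fleet."""

    n_hospitals: int = 4
    units_per_hospital: int = 20
    days: int = 365
    start_date: str = "2017-01-01"
    beds_low: int = 20
    beds_high: int = 35  # inclusive; mean ~27.5 beds, fleet total ~2200
    occupancy_mean: float = 0.79
    occupancy_sd: float = 0.05
    frac_surgical: float = 0.35
    single_room_alpha: float = 2.0
    single_room_beta: float = 4.0
    skill_mix_mean: float = 0.56
    skill_mix_sd: float = 0.08

    def __post_init__(self) -> None:
        if self.n_hospitals < 1 or self.units_per_hospital < 1 or self.days < 1:
            raise ValueError("fleet must have at least one hospital, unit and day")
        for frac in (self.occupancy_mean, self.frac_surgical, self.skill_mix_mean):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")


@dataclass(frozen=True)
class CalibrationProfile:
    """Day-level calibration of workload and staffing draws.

    ``mean_weighted_multiplier`` 1.64 makes the implied requirement ~7.2
    HPPD; ``cv_mean`` 0.094 makes a 20-day audit's precision average ~4.1%
    (closed form 1.96 x CV / sqrt(20)).  Shortfalls are drawn in HPPD on the
    total-hours scale and split between staff groups by the unit's planned
    skill mix.
    """

    mean_weighted_multiplier: float = 1.64
    multiplier_between_unit_sd: float = 0.12
    cv_mean: float = 0.094
    cv_shape: float = 4.0  # gamma shape of the per-unit CV distribution
    shortfall_mean_hppd: float = 0.1
    shortfall_sd_hppd: float = 0.9
    specialing_rate: float = 0.15
    turnover_per_staff_hour: float = 0.042
    afternoon_assessment_prob: float = 0.0


@dataclass(frozen=True)
class AdequacyTruth:
    """Planted coefficients (log odds) of one outcome's generating model."""

    outcome: str
    marginal_rate: float
    beta_rn: float
    beta_na: float
    beta_turnover: float
    beta_surgical: float
    beta_single_rooms: float
    beta_day_of_week: tuple[float, ...]  # Tuesday..Sunday, Monday = 0
    var_unit: float = 1.097
    var_hosp: float = 0.598
    threshold_at: float | None = None
    threshold_slope: float = 0.0
    interaction_rn_na: float = 0.0

    def coefficient(self, term: str) -> float:
        return {
            "rn_shortfall_hppd": self.beta_rn,
            "na_shortfall_hppd": self.beta_na,
            "turnover": self.beta_turnover,
            "surgical": self.beta_surgical,
            "single_room_prop": self.beta_single_rooms,
        }[term]


def _ln(x: float) -> float:
    return math.log(x)


#: Default truths: the adjusted odds ratios of the study's three outcome
#: models, on the log scale, with the latent random-intercept variances that
#: reproduce unit/hospital variance partition coefficients of 0.22 / 0.12.
DEFAULT_TRUTHS: dict[str, AdequacyTruth] = {
    "enough_staff": AdequacyTruth(
        outcome="enough_staff",
        marginal_rate=0.78,
        beta_rn=_ln(0.89),
        beta_na=_ln(0.86),
        beta_turnover=_ln(0.91),
        beta_surgical=_ln(0.54),
        beta_single_rooms=_ln(0.54),
        beta_day_of_week=tuple(
            _ln(x) for x in (1.12, 1.28, 1.08, 1.03, 1.29, 1.02)
        ),
    ),
    "care_left_undone": AdequacyTruth(
        outcome="care_left_undone",
        marginal_rate=0.05,
        beta_rn=_ln(1.14),
        beta_na=_ln(1.14),
        beta_turnover=_ln(3.36),
        beta_surgical=_ln(2.13),
        beta_single_rooms=_ln(3.01),
        beta_day_of_week=tuple(
            _ln(x) for x in (0.86, 0.96, 0.91, 0.93, 0.75, 1.11)
        ),
    ),
    "breaks_missed": AdequacyTruth(
        outcome="breaks_missed",
        marginal_rate=0.05,
        beta_rn=_ln(1.12),
        beta_na=_ln(1.11),
        beta_turnover=_ln(4.94),
        beta_surgical=_ln(2.15),
        beta_single_rooms=_ln(2.06),
        beta_day_of_week=tuple(
            _ln(x) for x in (0.71, 0.61, 0.81, 0.79, 0.50, 0.82)
        ),
    ),
}


def generate_fleet(
    config: FleetConfig, seed: int | np.random.Generator | None = None
) -> pd.DataFrame:
    """Draw the fleet's unit profile table; attributes are fixed for the year.

    Columns: unit_id, hospital, beds, occupancy, specialty, surgical,
    single_room_prop, planned_skill_mix.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for h in range(config.n_hospitals):
        hosp = chr(ord("A") + h) if h < 26 else f"H{h}"
        for u in range(config.units_per_hospital):
            beds = int(rng.integers(config.beds_low, config.beds_high + 1))
            occ = float(
                np.clip(
                    rng.normal(config.occupancy_mean, config.occupancy_sd), 0.55, 0.95
                )
            )
            surgical = bool(rng.random() < config.frac_surgical)
            rows.append(
                {
                    "unit_id": f"{hosp}{u + 1:02d}",
                    "hospital": hosp,
                    "beds": beds,
                    "occupancy": occ,
                    "specialty": "surgical" if surgical else "medical",
                    "surgical": int(surgical),
                    "single_room_prop": float(
                        rng.beta(config.single_room_alpha, config.single_room_beta)
                    ),
                    "planned_skill_mix": float(
                        np.clip(
                            rng.normal(config.skill_mix_mean, config.skill_mix_sd),
                            0.35,
                            0.85,
                        )
                    ),
                }
            )
    return pd.DataFrame(rows)


def _compose_counts(
    totals: np.ndarray,
    target_mults: np.ndarray,
    mults: np.ndarray,
    base_comp: np.ndarray,
) -> np.ndarray:
    """Integer per-level counts matching a target weighted multiplier.

    Starts from a largest-remainder rounding of the base composition and
    greedily moves single patients between levels (vectorised across days)
    until no move brings the weighted sum closer to ``totals * target``.
    The residual error on the weighted mean is far below the day-to-day
    variation being planted.
    """
    n_days, n_levels = len(totals), len(mults)
    raw = base_comp[None, :] * totals[:, None]
    counts = np.floor(raw).astype(np.int64)
    shortfall = (totals - counts.sum(axis=1)).astype(np.int64)
    remainders = raw - np.floor(raw)
    order = np.argsort(-remainders, axis=1)
    for j in range(n_levels):
        bump = shortfall > j
        counts[np.arange(n_days)[bump], order[bump, j]] += 1

    target_sum = target_mults * totals
    # all ordered level pairs and the change in weighted sum each move causes
    pairs = [(a, b) for a in range(n_levels) for b in range(n_levels) if a != b]
    deltas = np.array([mults[b] - mults[a] for a, b in pairs])
    for _ in range(60):
        err = target_sum - counts @ mults
        cand = np.abs(err[:, None] - deltas[None, :])
        feasible = np.stack([counts[:, a] > 0 for a, _ in pairs], axis=1)
        cand = np.where(feasible, cand, np.inf)
        best = np.argmin(cand, axis=1)
        improves = cand[np.arange(n_days), best] < np.abs(err) - 1e-12
        if not improves.any():
            break
        idx = np.flatnonzero(improves)
        for i in idx:
            a, b = pairs[best[i]]
            counts[i, a] -= 1
            counts[i, b] += 1
    return counts


def generate_unit_days(
    profiles: pd.DataFrame,
    calibration: CalibrationProfile,
    multipliers: MultiplierSet,
    days: int = 365,
    start_date: str = "2017-01-01",
    seed: int | np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate census.csv and staffing.csv content for every unit-day.

    Per unit: a mean weighted multiplier and an establishment CV are drawn
    once; per day, the patient count and the weighted multiplier fluctuate
    log-normally (splitting the CV between them), integer level counts are
    composed to match the day's multiplier, and deployed hours equal the
    requirement minus a Normal shortfall draw (floored at zero).
    """
    rng = np.random.default_rng(seed)
    mults = np.asarray(multipliers.multipliers)
    m_lo, m_hi = mults.min() + 0.02, mults.max() - 0.02
    dates = pd.date_range(start_date, periods=days, freq="D")
    # fleet-typical acuity mix used as the composition search's starting point
    base_comp = np.array([0.45, 0.25, 0.15, 0.10, 0.05])
    if len(mults) != len(base_comp):
        base_comp = np.full(len(mults), 1.0 / len(mults))

    census_rows, staffing_rows = [], []
    for _, unit in profiles.iterrows():
        mu_m = float(
            np.clip(
                rng.normal(
                    calibration.mean_weighted_multiplier,
                    calibration.multiplier_between_unit_sd,
                ),
                1.30,
                2.40,
            )
        )
        cv = float(
            rng.gamma(calibration.cv_shape, calibration.cv_mean / calibration.cv_shape)
        )
        cv = min(max(cv, 0.005), 0.35)
        cv_n = cv * 0.6  # census share of the day-to-day variation
        cv_m = cv * 0.8  # acuity share; 0.6^2 + 0.8^2 = 1
        mean_census = unit["beds"] * unit["occupancy"]

        z1, z2 = rng.standard_normal((2, days))
        n_admin = np.clip(
            np.round(mean_census * np.exp(cv_n * z1 - cv_n**2 / 2.0)),
            1,
            unit["beds"],
        ).astype(int)
        m_t = np.clip(mu_m * np.exp(cv_m * z2 - cv_m**2 / 2.0), m_lo, m_hi)
        counts = _compose_counts(n_admin.astype(np.int64), m_t, mults, base_comp)
        wmult = counts @ mults / counts.sum(axis=1)

        est = wmult * n_admin
        base_hours = (
            est / (1.0 + multipliers.uplift_fraction) * multipliers.wte_weekly_hours / 7.0
        )
        specialing = rng.poisson(calibration.specialing_rate, size=days)
        req = base_hours + specialing * multipliers.specialing_hours_per_patient_day
        mix = float(unit["planned_skill_mix"])
        patient_hours = n_admin * 24.0
        pdays = patient_hours / 24.0
        # independent RN and NA shortfall components whose sum is
        # N(shortfall_mean, shortfall_sd): means split by the skill mix,
        # variances apportioned by it
        rn_short = rng.normal(
            calibration.shortfall_mean_hppd * mix,
            calibration.shortfall_sd_hppd * math.sqrt(mix),
            size=days,
        )
        na_short = rng.normal(
            calibration.shortfall_mean_hppd * (1 - mix),
            calibration.shortfall_sd_hppd * math.sqrt(1 - mix),
            size=days,
        )
        rn_hours = np.maximum(req * mix - rn_short * pdays, 0.0)
        na_hours = np.maximum(req * (1 - mix) - na_short * pdays, 0.0)
        lam_flow = calibration.turnover_per_staff_hour * req / 2.0
        admissions = rng.poisson(lam_flow)
        discharges = rng.poisson(lam_flow)

        afternoon = rng.random(days) < calibration.afternoon_assessment_prob
        for i, date in enumerate(dates):
            row = {
                "unit_id": unit["unit_id"],
                "date": date,
                "assessment_time": pd.Timestamp(date) + pd.Timedelta(hours=7, minutes=30),
                **{
                    f"n_level{lv}": int(counts[i, j])
                    for j, lv in enumerate(multipliers.levels)
                },
                "admin_count_0700": int(n_admin[i]),
                "patient_hours": float(patient_hours[i]),
                "admissions": int(admissions[i]),
                "discharges": int(discharges[i]),
                "specialing_count": int(specialing[i]),
            }
            census_rows.append(row)
            if afternoon[i]:
                late = dict(row)
                late["assessment_time"] = pd.Timestamp(date) + pd.Timedelta(hours=15)
                census_rows.append(late)
            staffing_rows.append(
                {
                    "unit_id": unit["unit_id"],
                    "date": date,
                    "rn_hours": float(rn_hours[i]),
                    "na_hours": float(na_hours[i]),
                }
            )
    return pd.DataFrame(census_rows), pd.DataFrame(staffing_rows)


def generate_calibration_series(
    n_units: int = 86,
    days: int = 365,
    calibration: CalibrationProfile | None = None,
    multipliers: MultiplierSet | None = None,
    seed: int | np.random.Generator | None = None,
) -> dict[str, np.ndarray]:
    """Daily establishment series for a fleet of audit units.

    The precision analysis counts split unit segments as separate units
    (hence the default 86 rather than the 80 modelling units); hospitals are
    irrelevant to it, so units are spread over hospitals only for id
    purposes.  Series are produced end-to-end: census tables are generated
    and the establishment recomputed from them through the workload
    arithmetic.
    """
    calibration = calibration or CalibrationProfile()
    multipliers = multipliers or MultiplierSet()
    rng = np.random.default_rng(seed)
    per_hosp = -(-n_units // 4)
    profiles = generate_fleet(
        FleetConfig(n_hospitals=4, units_per_hospital=per_hosp), seed=rng
    ).iloc[:n_units]
    census, _ = generate_unit_days(
        profiles, calibration, multipliers, days=days, seed=rng
    )
    from .workload import establishment_series

    return establishment_series(census, multipliers)


def simulate_adequacy(
    linked: pd.DataFrame,
    truths: dict[str, AdequacyTruth] | None = None,
    seed: int | np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Sample the three adequacy binaries for each linked unit-day.

    Unit and hospital intercepts are drawn from their planted Normal
    variances; each outcome's fixed intercept is solved numerically so the
    fleet's marginal rate matches the truth's target.  Outcomes are sampled
    independently given the linear predictor (the study models them
    separately).  Responses are stamped the following morning, which is the
    day they report on plus one.
    """
    if truths is None:
        truths = DEFAULT_TRUTHS
    rng = np.random.default_rng(seed)
    units = np.sort(linked["unit_id"].unique())
    hospitals = np.sort(linked["hospital"].astype(str).unique())
    unit_pos = linked["unit_id"].map({u: i for i, u in enumerate(units)}).to_numpy()
    hosp_pos = (
        linked["hospital"].astype(str).map({h: i for i, h in enumerate(hospitals)}).to_numpy()
    )

    x = {
        "rn_shortfall_hppd": linked["rn_shortfall_hppd"].to_numpy(float),
        "na_shortfall_hppd": linked["na_shortfall_hppd"].to_numpy(float),
        "turnover": linked["turnover_per_staff_hour"].to_numpy(float),
        "surgical": linked["surgical"].to_numpy(float),
        "single_room_prop": linked["single_room_prop"].to_numpy(float),
    }
    dow = linked["day_of_week"].astype(str).to_numpy()

    out = linked[["unit_id", "date"]].copy()
    sidecar: dict = {"intercepts": {}, "random_effects": {}}
    for outcome, truth in truths.items():
        b_u = rng.normal(0.0, math.sqrt(truth.var_unit), size=len(units))
        b_h = rng.normal(0.0, math.sqrt(truth.var_hosp), size=len(hospitals))
        eta = b_u[unit_pos] + b_h[hosp_pos]
        for term in x:
            eta = eta + truth.coefficient(term) * x[term]
        for day, beta in zip(WEEKDAY_ORDER, truth.beta_day_of_week):
            eta = eta + beta * (dow == day)
        if truth.threshold_at is not None:
            eta = eta + truth.threshold_slope * np.maximum(
                x["rn_shortfall_hppd"] - truth.threshold_at, 0.0
            )
        if truth.interaction_rn_na:
            eta = eta + truth.interaction_rn_na * (
                x["rn_shortfall_hppd"] * x["na_shortfall_hppd"]
            )

        def marginal(c: float) -> float:
            return float(special.expit(c + eta).mean()) - truth.marginal_rate

        intercept = optimize.brentq(marginal, -25.0, 25.0)
        p = special.expit(intercept + eta)
        out[outcome] = (rng.random(len(p)) < p).astype(int)
        sidecar["intercepts"][outcome] = float(intercept)
        sidecar["random_effects"][outcome] = {
            "unit": dict(zip(units.tolist(), b_u.round(6).tolist())),
            "hospital": dict(zip(hospitals.tolist(), b_h.round(6).tolist())),
        }

    out["date"] = pd.to_datetime(out["date"]) + pd.Timedelta(days=1)
    out["response_time"] = out["date"] + pd.Timedelta(hours=8)
    cols = ["unit_id", "date", "response_time", *truths.keys()]
    return out[cols], sidecar


def inject_reverse_coding(
    responses: pd.DataFrame, unit_ids: list[str]
) -> tuple[pd.DataFrame, dict]:
    """Invert all three yes/no binaries for the listed units.

    Emulates consistently mistrained data entry.  Applying it twice restores
    the original (involution).  Returns the contaminated table and a
    ground-truth record of the flipped units.
    """
    known = set(responses["unit_id"])
    unknown = [u for u in unit_ids if u not in known]
    if unknown:
        raise ValueError(f"unknown unit(s): {unknown}")
    out = responses.copy()
    mask = out["unit_id"].isin(unit_ids)
    for col in RESPONSE_COLUMNS:
        out.loc[mask, col] = 1 - out.loc[mask, col]
    return out, {"reverse_coded_units": sorted(unit_ids)}


def inject_missingness(
    table: pd.DataFrame,
    rate: float,
    seed: int | np.random.Generator | None = None,
    morning_only: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Remove a random fraction of rows (seeded).

    With ``morning_only`` set, only rows whose ``assessment_time`` falls
    before noon are candidates for removal, so a later assessment from the
    same day — when one exists — survives for the fallback path.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    if morning_only and "assessment_time" in table.columns:
        candidate = pd.to_datetime(table["assessment_time"]).dt.hour < 12
    else:
        candidate = pd.Series(True, index=table.index)
    drop = candidate & (rng.random(len(table)) < rate)
    kept = table.loc[~drop].reset_index(drop=True)
    return kept, {"n_removed": int(drop.sum()), "rate": rate}


def generate_dataset(
    config: FleetConfig | None = None,
    calibration: CalibrationProfile | None = None,
    multipliers: MultiplierSet | None = None,
    truths: dict[str, AdequacyTruth] | None = None,
    seed: int | None = None,
    assessment_missing_rate: float = 0.04,
    response_missing_rate: float = 0.15,
    reverse_coded_units: list[str] | None = None,
) -> dict:
    """End-to-end synthetic dataset: profiles, census, staffing, responses.

    Returns a dict with the four tables, the linked covariate table the
    outcomes were simulated from, and a ``truth`` sidecar holding every
    planted parameter and contamination ground truth.
    """
    config = config or FleetConfig()
    calibration = calibration or CalibrationProfile()
    multipliers = multipliers or MultiplierSet()
    truths = truths or DEFAULT_TRUTHS
    ss = np.random.SeedSequence(seed)
    r_fleet, r_days, r_outcome, r_miss_a, r_miss_r = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    profiles = generate_fleet(config, seed=r_fleet)
    census, staffing = generate_unit_days(
        profiles,
        calibration,
        multipliers,
        days=config.days,
        start_date=config.start_date,
        seed=r_days,
    )
    chosen = select_daily_assessment(census)
    skill = dict(zip(profiles["unit_id"], profiles["planned_skill_mix"]))
    workload = workload_table(chosen, staffing, multipliers, skill_mix=skill)
    covariates = workload.merge(
        profiles[["unit_id", "hospital", "surgical", "specialty", "single_room_prop"]],
        on="unit_id",
    )
    covariates["day_of_week"] = pd.to_datetime(covariates["date"]).dt.day_name()
    covariates = covariates.rename(columns={})
    responses, sidecar = simulate_adequacy(covariates, truths, seed=r_outcome)

    truth = {
        "config": asdict(config),
        "calibration": asdict(calibration),
        "truths": {k: asdict(v) for k, v in truths.items()},
        "adequacy": sidecar,
        "contamination": {},
    }
    if reverse_coded_units:
        responses, rc = inject_reverse_coding(responses, reverse_coded_units)
        truth["contamination"].update(rc)
    if assessment_missing_rate:
        census, ma = inject_missingness(
            census, assessment_missing_rate, seed=r_miss_a, morning_only=True
        )
        truth["contamination"]["assessments_removed"] = ma["n_removed"]
    if response_missing_rate:
        responses, mr = inject_missingness(responses, response_missing_rate, seed=r_miss_r)
        truth["contamination"]["responses_removed"] = mr["n_removed"]

    return {
        "profiles": profiles,
        "census": census,
        "staffing": staffing,
        "responses": responses,
        "covariates": covariates,
        "truth": truth,
    }


def write_dataset(dataset: dict, outdir) -> None:
    """Write the generator tables in their CSV/JSON interchange forms."""
    import pathlib

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name in ("profiles", "census", "staffing", "responses"):
        dataset[name].to_csv(outdir / f"{name}.csv", index=False)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(dataset["truth"], fh, indent=1, default=str)
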