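"""Do staffing shortfalls predict nurses' judgements of inadequate staffing?

Links each simulated unit-day's workload to the next morning's microsurvey,
applies the cleaning rules (reverse-coding detection, +-3 SD shortfall
outliers), and fits the three-level logistic models (day in unit in
hospital) for the three outcomes, plus the quadratic-term comparison and the
RN x NA interaction scan.  Writes fit tables, the effect-curve figure and
model metadata under results/adequacy/.

Run:  python analysis/03_adequacy.py   (after 01_simulate.py)
"""

import json
import pathlib
import sys

import numpy as np
import pandas as pd

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from wardstaff.cleaning import (
    detect_and_recode_reverse_coding,
    link_day,
    remove_shortfall_outliers,
    select_daily_assessment,
)
from wardstaff.config import MultiplierSet
from wardstaff.glmm import (
    ModelSpec,
    add_quadratic_and_compare,
    fit_glmm,
    interaction_scan,
    or_to_percent_change,
    shortfall_effect_curve,
)
from wardstaff.pipeline import plot_effect_curve
from wardstaff.workload import workload_table

ROOT = pathlib.Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    sim = ROOT / "synthetic"
    census = pd.read_csv(sim / "census.csv", parse_dates=["date"])
    staffing = pd.read_csv(sim / "staffing.csv", parse_dates=["date"])
    responses = pd.read_csv(sim / "responses.csv", parse_dates=["date"])
    profiles = pd.read_csv(sim / "profiles.csv")

    multipliers = MultiplierSet()
    work = workload_table(select_daily_assessment(census), staffing, multipliers)
    responses, rc = detect_and_recode_reverse_coding(responses)
    if rc.flagged_units:
        print("reverse-coded units recoded:", rc.flagged_units)
    linked = link_day(
        work,
        responses,
        profiles[["unit_id", "hospital", "surgical", "specialty", "single_room_prop"]],
    )
    kept, removed = remove_shortfall_outliers(linked)
    print(f"linked {len(linked)} unit-days; outlier rule removed {len(removed)} "
          f"({100 * len(removed) / len(linked):.2f}%)")

    out = ROOT / "adequacy"
    out.mkdir(parents=True, exist_ok=True)
    fits = {}
    for outcome in ("enough_staff", "care_left_undone", "breaks_missed"):
        fit = fit_glmm(ModelSpec(outcome=outcome), kept)
        fits[outcome] = fit
        fit.terms.to_csv(out / f"fit_{outcome}.csv")
        meta = {
            "var_unit": fit.var_unit, "var_hosp": fit.var_hosp,
            "vpc_unit": fit.vpc_unit, "vpc_hosp": fit.vpc_hosp,
            "aic": fit.aic, "bic": fit.bic, "n_obs": fit.n_obs,
            "converged": fit.converged,
        }
        (out / f"fit_{outcome}.json").write_text(json.dumps(meta, indent=1))
        rn = fit.terms.loc["rn_shortfall_hppd"]
        print(
            f"{outcome}: RN shortfall OR {rn['or_']:.2f} "
            f"({or_to_percent_change(rn['or_']):+.0f}% odds per HPPD), "
            f"VPC unit {fit.vpc_unit:.2f} / hospital {fit.vpc_hosp:.2f}, "
            f"AIC {fit.aic:.0f}"
        )

    # is the shortfall-adequacy relationship linear, or is there a threshold?
    comp = add_quadratic_and_compare(ModelSpec(outcome="care_left_undone"), kept)
    print(
        f"quadratic comparison (care left undone): dAIC {comp.delta_aic:+.1f}, "
        f"dBIC {comp.delta_bic:+.1f}, preferred: {comp.preferred}"
    )
    curve = shortfall_effect_curve(
        comp.fit_quadratic, np.linspace(-3, 3, 61), "rn_shortfall_hppd"
    )
    curve.to_csv(out / "effect_curve.csv", index=False)
    plot_effect_curve(curve, out / "figure2_effect_curve.png")

    scan = interaction_scan(
        ModelSpec(outcome="enough_staff"),
        kept,
        (("rn_shortfall_hppd", "na_shortfall_hppd"),),
    )
    scan.to_csv(out / "interaction_scan.csv", index=False)
    print("RN x NA interaction significant:", bool(scan["significant"].iloc[0]))


if __name__ == "__main__":
    main()
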