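"""Reproducible runs tying the stages together.

A run executes simulate -> clean -> workload -> precision -> adequacy ->
report, writing each stage's table under an output directory together with a
manifest (seed, row counts at each stage) so the numbers in the report are
traceable to stage outputs.  A single master seed is expanded into per-stage
seeds with ``numpy.random.SeedSequence(master).spawn()`` in a fixed order
(simulate, precision), so stages can be rerun in isolation reproducibly.
"""

from __future__ import annotations

import json
import logging
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .bootstrap import DEFAULT_SAMPLE_SIZES, precision_sweep
from .cleaning import (
    detect_and_recode_reverse_coding,
    link_day,
    remove_shortfall_outliers,
    select_daily_assessment,
)
from .config import MultiplierSet
from .glmm import ModelSpec, fit_glmm, or_to_percent_change
from .simulate import generate_dataset
from .workload import establishment_series, workload_table

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Inputs and knobs for one pipeline run."""

    outdir: str = "results/run"
    seed: int = 0
    input_dir: str | None = None  # read census/staffing/responses CSVs here
    generator_kwargs: dict = field(default_factory=dict)  # else simulate
    multipliers: MultiplierSet = field(default_factory=MultiplierSet)
    sample_sizes: tuple[int, ...] = DEFAULT_SAMPLE_SIZES
    n_boot: int = 1000
    outlier_k_sd: float = 3.0
    reverse_coding_detection: bool = True
    outcomes: tuple[str, ...] = ("enough_staff", "care_left_undone", "breaks_missed")
    exclude_hospital: str | None = None
    make_figures: bool = True


def _load_inputs(config: RunConfig, seed_children) -> dict:
    if config.input_dir is not None:
        d = pathlib.Path(config.input_dir)
        tables = {
            name: pd.read_csv(d / f"{name}.csv", parse_dates=["date"])
            for name in ("profiles", "census", "staffing", "responses")
        }
        tables["truth"] = None
        return tables
    if config.generator_kwargs is None:
        raise ValueError("config must name an input directory or generator settings")
    sim_seed = int(seed_children[0].generate_state(1)[0] % (2**31))
    return generate_dataset(
        seed=sim_seed, multipliers=config.multipliers, **config.generator_kwargs
    )


def prepare_model_table(dataset: dict, k_sd: float = 3.0) -> pd.DataFrame:
    """Generator output -> outlier-cleaned linked table ready for modelling.

    Joins the simulated covariate table to the next-morning responses and
    applies the within-unit mean ± 3 SD shortfall rule.
    """
    profile_cols = ["unit_id", "hospital", "surgical", "specialty", "single_room_prop"]
    linked = link_day(
        dataset["covariates"], dataset["responses"], dataset["profiles"][profile_cols]
    )
    kept, _ = remove_shortfall_outliers(linked, k_sd=k_sd)
    return kept


def run_pipeline(config: RunConfig) -> pathlib.Path:
    """Execute the full pipeline; returns the run directory."""
    outdir = pathlib.Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(2)  # 0: simulate, 1: precision bootstrap
    manifest: dict = {"seed": config.seed, "wardstaff_version": __version__, "stages": {}}

    def fail(stage: str, err: Exception):
        record = {"stage": stage, "error": type(err).__name__, "message": str(err)}
        (outdir / "error.json").write_text(json.dumps(record, indent=1))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    try:
        data = _load_inputs(config, children)
    except Exception as err:  # noqa: BLE001 - converted to stage record
        fail("simulate", err)
    census, staffing, responses, profiles = (
        data["census"],
        data["staffing"],
        data["responses"],
        data["profiles"],
    )
    manifest["stages"]["inputs"] = {
        "census_rows": len(census),
        "staffing_rows": len(staffing),
        "response_rows": len(responses),
        "units": int(profiles["unit_id"].nunique()),
        "hospitals": int(profiles["hospital"].nunique()),
    }

    try:
        chosen = select_daily_assessment(census)
        responses_clean, rc_report = detect_and_recode_reverse_coding(
            responses, enabled=config.reverse_coding_detection
        )
    except Exception as err:  # noqa: BLE001
        fail("clean", err)
    manifest["stages"]["clean"] = {
        "assessment_days": len(chosen),
        "reverse_coded_units_flagged": rc_report.flagged_units,
    }

    try:
        work = workload_table(chosen, staffing, config.multipliers)
        series = establishment_series(chosen, config.multipliers)
    except Exception as err:  # noqa: BLE001
        fail("workload", err)
    work.to_csv(outdir / "workload.csv", index=False)

    try:
        boot_seed = int(children[1].generate_state(1)[0] % (2**31))
        sweep = precision_sweep(
            series, config.sample_sizes, n_boot=config.n_boot, seed=boot_seed
        )
    except Exception as err:  # noqa: BLE001
        fail("precision", err)
    sweep.to_csv(outdir / "precision_sweep.csv", index=False)
    manifest["stages"]["precision"] = {"rows": len(sweep), "n_boot": config.n_boot}

    try:
        linked = link_day(
            work,
            responses_clean,
            profiles[["unit_id", "hospital", "surgical", "specialty", "single_room_prop"]],
        )
        kept, removed = remove_shortfall_outliers(linked, k_sd=config.outlier_k_sd)
    except Exception as err:  # noqa: BLE001
        fail("link", err)
    manifest["stages"]["link"] = {
        **linked.attrs.get("linkage", {}),
        "rows_in": len(linked),
        "rows_kept": len(kept),
        "rows_removed": len(removed),
        "pct_removed": round(100.0 * len(removed) / max(len(linked), 1), 3),
    }
    cleaning_report = {
        "outlier_rule": manifest["stages"]["link"],
        "reverse_coded_units": rc_report.flagged_units,
    }
    (outdir / "cleaning_report.json").write_text(json.dumps(cleaning_report, indent=1))

    fits = {}
    for outcome in config.outcomes:
        try:
            fit = fit_glmm(
                ModelSpec(outcome=outcome, exclude_hospital=config.exclude_hospital),
                kept,
            )
        except Exception as err:  # noqa: BLE001
            fail(f"adequacy:{outcome}", err)
        fits[outcome] = fit
        fit.terms.to_csv(outdir / f"fit_{outcome}.csv")
        (outdir / f"fit_{outcome}.json").write_text(
            json.dumps(
                {
                    "var_unit": fit.var_unit,
                    "var_hosp": fit.var_hosp,
                    "vpc_unit": fit.vpc_unit,
                    "vpc_hosp": fit.vpc_hosp,
                    "aic": fit.aic,
                    "bic": fit.bic,
                    "loglik": fit.loglik,
                    "n_obs": fit.n_obs,
                    "n_units": fit.n_units,
                    "n_hospitals": fit.n_hospitals,
                    "converged": fit.converged,
                },
                indent=1,
            )
        )
        manifest["stages"][f"adequacy:{outcome}"] = {
            "n_obs": fit.n_obs,
            "converged": fit.converged,
        }

    table1 = make_table1(kept, profiles)
    table1.to_csv(outdir / "table1.csv", index=False)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    make_report(outdir, figures=config.make_figures)
    return outdir


def make_table1(linked: pd.DataFrame, profiles: pd.DataFrame) -> pd.DataFrame:
    """Per-hospital mean/min/max of unit-average HPPD, skill mix, requirement."""
    per_unit = (
        linked.groupby("unit_id")
        .agg(
            total_hppd=("total_hppd", "mean"),
            skill_mix_pct=("skill_mix", lambda s: 100.0 * s.mean()),
            requirement_hppd=("requirement_hppd", "mean"),
        )
        .reset_index()
        .merge(profiles[["unit_id", "hospital"]], on="unit_id")
    )
    rows = []
    groups = [(h, g) for h, g in per_unit.groupby("hospital")] + [("All", per_unit)]
    for name, grp in groups:
        row = {"hospital": name, "n_units": len(grp)}
        for col in ("total_hppd", "skill_mix_pct", "requirement_hppd"):
            row[f"{col}_mean"] = grp[col].mean()
            row[f"{col}_min"] = grp[col].min()
            row[f"{col}_max"] = grp[col].max()
        rows.append(row)
    return pd.DataFrame(rows)


def make_report(run_dir, figures: bool = True) -> pathlib.Path:
    """Assemble a markdown report from whatever stage outputs exist.

    Missing stages are marked absent rather than failing the run; an empty
    run directory is an error.
    """
    run_dir = pathlib.Path(run_dir)
    if not run_dir.exists() or not any(run_dir.iterdir()):
        raise FileNotFoundError(f"no stage outputs under {run_dir}")
    lines = ["# Ward staffing analysis report", ""]
    manifest_path = run_dir / "manifest.json"
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        lines += [f"Seed {manifest['seed']}, wardstaff {manifest['wardstaff_version']}", ""]

    t1 = run_dir / "table1.csv"
    lines.append("## Unit staffing levels and estimated requirements")
    if t1.exists():
        df = pd.read_csv(t1)
        lines += ["", df.round(2).to_markdown(index=False), ""]
    else:
        lines += ["", "_absent_", ""]

    sweep_path = run_dir / "precision_sweep.csv"
    lines.append("## Precision of establishment estimates by audit length")
    if sweep_path.exists():
        sweep = pd.read_csv(sweep_path)
        lines += ["", sweep.round(2).to_markdown(index=False), ""]
        if figures:
            _plot_precision(sweep, run_dir / "figure1_precision.png")
            lines += ["![precision](figure1_precision.png)", ""]
    else:
        lines += ["", "_absent_", ""]

    lines.append("## Staffing shortfalls and reported adequacy")
    any_fit = False
    for outcome in ("enough_staff", "care_left_undone", "breaks_missed"):
        path = run_dir / f"fit_{outcome}.csv"
        if not path.exists():
            continue
        any_fit = True
        fit = pd.read_csv(path)
        meta = json.loads((run_dir / f"fit_{outcome}.json").read_text())
        lines += [
            "",
            f"### {outcome}",
            "",
            fit.round({"coef": 3, "se": 3, "or_": 2, "ci_low": 2, "ci_high": 2, "p": 3})
            .to_markdown(index=False),
            "",
            f"VPC unit {meta['vpc_unit']:.2f}, hospital {meta['vpc_hosp']:.2f}; "
            f"AIC {meta['aic']:.0f}, BIC {meta['bic']:.0f}; n={meta['n_obs']}",
        ]
    if not any_fit:
        lines += ["", "_absent_", ""]
    report = run_dir / "report.md"
    report.write_text("\n".join(lines) + "\n")
    return report


def _plot_precision(sweep: pd.DataFrame, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax1 = plt.subplots(figsize=(6, 4))
    ax1.plot(sweep["n_days"], sweep["avg_precision_pct"], "o-", color="tab:blue")
    ax1.set_xlabel("days sampled")
    ax1.set_ylabel("mean precision (%)", color="tab:blue")
    ax2 = ax1.twinx()
    ax2.plot(sweep["n_days"], sweep["avg_ci_width_wte"], "s--", color="tab:red")
    ax2.set_ylabel("mean 95% CI width (WTE)", color="tab:red")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_effect_curve(curve: pd.DataFrame, path) -> None:
    """Odds of reporting the outcome vs staffing shortfall (relative to zero)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve["shortfall_hppd"], curve["odds_ratio"], color="tab:blue")
    ax.fill_between(
        curve["shortfall_hppd"], curve["ci_low"], curve["ci_high"], alpha=0.2
    )
    ax.axhline(1.0, color="grey", lw=0.8)
    ax.set_xlabel("staffing shortfall (HPPD)")
    ax.set_ylabel("odds ratio vs no shortfall")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
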