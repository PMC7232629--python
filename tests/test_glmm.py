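"""Multilevel logistic fitter: collapses, oracles, comparisons, curves."""

import json
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from wardstaff.glmm import (
    DegenerateOutcomeError,
    ModelSpec,
    add_quadratic_and_compare,
    fit_glmm,
    interaction_scan,
    or_to_percent_change,
    shortfall_effect_curve,
    univariable_or,
    vpc,
)
from wardstaff.simulate import (
    DEFAULT_TRUTHS,
    AdequacyTruth,
    FleetConfig,
    generate_dataset,
)
from wardstaff.pipeline import prepare_model_table


def _flat_dataset(seed=5, n_units=30, days=80, beta_rn=-0.5, **truth_kw):
    """Small fleet with zero random-effect variances and one planted slope."""
    truths = {
        "enough_staff": AdequacyTruth(
            outcome="enough_staff",
            marginal_rate=0.6,
            beta_rn=beta_rn,
            beta_na=0.0,
            beta_turnover=0.0,
            beta_surgical=0.0,
            beta_single_rooms=0.0,
            beta_day_of_week=(0.0,) * 6,
            var_unit=0.0,
            var_hosp=0.0,
            **truth_kw,
        )
    }
    d = generate_dataset(
        config=FleetConfig(n_hospitals=3, units_per_hospital=n_units // 3, days=days),
        truths=truths,
        seed=seed,
        assessment_missing_rate=0.0,
        response_missing_rate=0.0,
    )
    d["linked"] = prepare_model_table(d)
    return d


class TestVpc:
    def test_planted_pair(self):
        # the variance pair that yields unit/hospital shares of 22% and 12%
        u, h = vpc(1.097, 0.598)
        assert round(u, 3) == 0.220
        assert round(h, 3) == 0.120

    def test_zero_variances(self):
        assert vpc(0.0, 0.0) == (0.0, 0.0)

    def test_unit_variance_equal_to_residual(self):
        u, h = vpc(np.pi**2 / 3, 0.0)
        assert u == pytest.approx(0.5)
        assert h == 0.0

    def test_shares_below_one(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            u, h = vpc(*rng.exponential(2.0, 2))
            assert 0 <= u < 1 and 0 <= h < 1 and u + h < 1


class TestOrTransform:
    @pytest.mark.parametrize(
        "or_value, pct", [(0.89, -11.0), (1.14, 14.0), (1.0, 0.0)]
    )
    def test_examples(self, or_value, pct):
        assert or_to_percent_change(or_value) == pytest.approx(pct, abs=1e-9)

    def test_reciprocal_identity(self):
        # 100*(1/x - 1) == -100*(x - 1)/x; at x=0.89 both give +12.36%
        x = 0.89
        assert or_to_percent_change(1 / x) == pytest.approx(
            -or_to_percent_change(x) / x
        )
        assert or_to_percent_change(1 / x) == pytest.approx(12.36, abs=0.005)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            or_to_percent_change(0.0)


class TestFitCollapsesAndErrors:
    def test_zero_variance_matches_plain_logistic(self):
        import statsmodels.api as sm

        d = _flat_dataset()
        spec = ModelSpec(outcome="enough_staff", fixed_terms=("rn_shortfall_hppd",))
        fit = fit_glmm(spec, d["linked"])
        df = d["linked"].dropna(subset=["enough_staff"])
        X = sm.add_constant(df["rn_shortfall_hppd"].to_numpy())
        ref = sm.Logit(df["enough_staff"].to_numpy(), X).fit(disp=0)
        assert fit.var_unit < 0.02 and fit.var_hosp < 0.02
        assert fit.terms["coef"].to_numpy() == pytest.approx(ref.params, abs=1e-3)
        # information criteria: verified against the hand formula with k
        # counting the fixed effects plus the two variance parameters
        k = len(fit.terms) + 2
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * k, abs=1e-8)
        assert fit.bic == pytest.approx(
            -2 * fit.loglik + k * np.log(fit.n_obs), abs=1e-8
        )
        # and the likelihood itself collapses to the plain logistic one
        assert fit.loglik == pytest.approx(ref.llf, abs=2.0)

    def test_slope_recovered_near_truth(self):
        d = _flat_dataset(beta_rn=-0.5)
        fit = fit_glmm(
            ModelSpec(outcome="enough_staff", fixed_terms=("rn_shortfall_hppd",)),
            d["linked"],
        )
        row = fit.terms.loc["rn_shortfall_hppd"]
        assert row["coef"] == pytest.approx(-0.5, abs=2.5 * row["se"])

    def test_degenerate_outcome_rejected(self):
        d = _flat_dataset()
        df = d["linked"].copy()
        df["enough_staff"] = 1.0
        with pytest.raises(DegenerateOutcomeError):
            fit_glmm(ModelSpec(outcome="enough_staff"), df)

    def test_mutually_exclusive_shortfall_terms(self):
        with pytest.raises(ValueError):
            ModelSpec(
                outcome="enough_staff",
                fixed_terms=("total_shortfall_hppd", "rn_shortfall_hppd"),
            )

    def test_fit_deterministic(self):
        d = _flat_dataset()
        spec = ModelSpec(outcome="enough_staff", fixed_terms=("rn_shortfall_hppd",))
        a = fit_glmm(spec, d["linked"])
        b = fit_glmm(spec, d["linked"])
        assert (a.terms["coef"] == b.terms["coef"]).all()
        assert a.loglik == b.loglik


def test_against_lme4_oracle(tmp_path):
    """Independent cross-check: lme4::glmer on a small nested-intercept fit."""
    rng = np.random.default_rng(7)
    rows = []
    for h in range(3):
        bh = rng.normal(0, 0.6)
        for u in range(10):
            bu = rng.normal(0, 0.9)
            x1 = rng.normal(0, 1, 60)
            x2 = float(rng.random() < 0.4)
            eta = 0.8 - 0.4 * x1 - 0.7 * x2 + bu + bh
            y = (rng.random(60) < expit(eta)).astype(int)
            for i in range(60):
                rows.append(
                    {
                        "hospital": f"H{h}",
                        "unit_id": f"H{h}U{u}",
                        "rn_shortfall_hppd": x1[i],
                        "surgical": x2,
                        "enough_staff": y[i],
                    }
                )
    df = pd.DataFrame(rows)
    csv = tmp_path / "fixture.csv"
    df.to_csv(csv, index=False)
    rscript = tmp_path / "oracle.R"
    rscript.write_text(
        textwrap.dedent(
            f"""
            library(lme4); library(jsonlite)
            d <- read.csv("{csv}")
            m <- glmer(enough_staff ~ rn_shortfall_hppd + surgical +
                       (1|hospital/unit_id), data=d, family=binomial)
            vc <- as.data.frame(VarCorr(m))
            writeLines(toJSON(list(
              beta=fixef(m), se=sqrt(diag(vcov(m))),
              var_unit=vc$vcov[vc$grp=="unit_id:hospital"],
              var_hosp=vc$vcov[vc$grp=="hospital"],
              loglik=as.numeric(logLik(m))), digits=10))
            """
        )
    )
    proc = subprocess.run(
        ["Rscript", str(rscript)], capture_output=True, text=True, timeout=300
    )
    assert proc.returncode == 0, proc.stderr
    oracle = json.loads(proc.stdout.strip().splitlines()[-1])

    fit = fit_glmm(
        ModelSpec(
            outcome="enough_staff", fixed_terms=("rn_shortfall_hppd", "surgical")
        ),
        df,
    )
    assert fit.terms["coef"].to_numpy() == pytest.approx(
        np.array(oracle["beta"]), abs=0.03
    )
    assert fit.terms["se"].to_numpy() == pytest.approx(
        np.array(oracle["se"]), rel=0.02
    )
    assert fit.var_unit == pytest.approx(oracle["var_unit"][0], abs=0.05)
    assert fit.var_hosp == pytest.approx(oracle["var_hosp"][0], abs=0.05)
    assert fit.loglik == pytest.approx(oracle["loglik"][0], abs=0.1)


class TestUnivariable:
    def test_confounded_covariates_shift_univariable_or(self):
        # correlated RN/NA shortfalls: the univariable RN estimate absorbs
        # part of the (same-signed) NA effect, so it is farther from 1 than
        # the adjusted estimate
        rng = np.random.default_rng(17)
        n = 8000
        common = rng.normal(0, 1, n)
        rn = common + rng.normal(0, 0.6, n)
        na = common + rng.normal(0, 0.6, n)
        eta = 0.5 - 0.3 * rn - 0.3 * na
        df = pd.DataFrame(
            {
                "unit_id": np.repeat([f"U{i}" for i in range(20)], n // 20),
                "hospital": np.repeat(["A", "B"], n // 2),
                "rn_shortfall_hppd": rn,
                "na_shortfall_hppd": na,
                "enough_staff": (rng.random(n) < expit(eta)).astype(int),
            }
        )
        uni = univariable_or("rn_shortfall_hppd", df, "enough_staff")
        multi = fit_glmm(
            ModelSpec(
                outcome="enough_staff",
                fixed_terms=("rn_shortfall_hppd", "na_shortfall_hppd"),
            ),
            df,
        )
        b_uni = uni.terms.loc["rn_shortfall_hppd", "coef"]
        b_adj = multi.terms.loc["rn_shortfall_hppd", "coef"]
        assert b_uni < b_adj < 0  # confounding pushes the crude estimate down
        assert b_adj == pytest.approx(-0.3, abs=3 * multi.terms.loc["rn_shortfall_hppd", "se"])

    def test_single_term_fit_shape(self):
        d = _flat_dataset()
        fit = univariable_or("rn_shortfall_hppd", d["linked"], "enough_staff")
        assert list(fit.terms.index) == ["intercept", "rn_shortfall_hppd"]


class TestQuadraticAndInteractions:
    def test_linear_truth_prefers_linear_by_bic(self):
        d = _flat_dataset(seed=23, days=150, beta_rn=-0.4)
        comp = add_quadratic_and_compare(
            ModelSpec(outcome="enough_staff", fixed_terms=("rn_shortfall_hppd",)),
            d["linked"],
        )
        assert comp.delta_bic > 0
        assert comp.fit_quadratic.terms.loc["rn_shortfall_hppd^2", "p"] > 0.01
        assert comp.preferred in ("linear", "ambiguous")

    def test_threshold_truth_flags_curvature(self):
        # logit bends at zero shortfall: the quadratic term must pick it up
        d = _flat_dataset(
            seed=29, days=250, beta_rn=0.0, threshold_at=0.0, threshold_slope=-1.2
        )
        comp = add_quadratic_and_compare(
            ModelSpec(outcome="enough_staff", fixed_terms=("rn_shortfall_hppd",)),
            d["linked"],
        )
        assert comp.fit_quadratic.terms.loc["rn_shortfall_hppd^2", "p"] < 0.05

    def test_identical_fits_zero_delta(self):
        d = _flat_dataset()
        spec = ModelSpec(outcome="enough_staff", fixed_terms=("rn_shortfall_hppd",))
        a = fit_glmm(spec, d["linked"])
        b = fit_glmm(spec, d["linked"])
        assert a.aic - b.aic == 0.0

    def test_interaction_scan_null_and_planted(self):
        pair = (("rn_shortfall_hppd", "na_shortfall_hppd"),)
        null = _flat_dataset(seed=41, days=200, beta_rn=-0.3)
        scan0 = interaction_scan(
            ModelSpec(
                outcome="enough_staff",
                fixed_terms=("rn_shortfall_hppd", "na_shortfall_hppd"),
            ),
            null["linked"],
            pair,
        )
        assert not scan0["significant"].iloc[0]

        planted = _flat_dataset(
            seed=43, days=200, beta_rn=-0.3, interaction_rn_na=0.5
        )
        scan1 = interaction_scan(
            ModelSpec(
                outcome="enough_staff",
                fixed_terms=("rn_shortfall_hppd", "na_shortfall_hppd"),
            ),
            planted["linked"],
            pair,
        )
        assert scan1["significant"].iloc[0]
        assert scan1["delta_aic"].iloc[0] < 0

    def test_empty_candidate_list(self):
        d = _flat_dataset()
        scan = interaction_scan(
            ModelSpec(outcome="enough_staff", fixed_terms=("rn_shortfall_hppd",)),
            d["linked"],
            (),
        )
        assert scan.empty


class TestEffectCurve:
    def _fit(self, **kw):
        d = _flat_dataset(**kw)
        return fit_glmm(
            ModelSpec(
                outcome="enough_staff",
                fixed_terms=("rn_shortfall_hppd",),
                quadratic_terms=("rn_shortfall_hppd",),
            ),
            d["linked"],
        )

    def test_linear_only_closed_form(self):
        d = _flat_dataset(beta_rn=-0.4)
        fit = fit_glmm(
            ModelSpec(outcome="enough_staff", fixed_terms=("rn_shortfall_hppd",)),
            d["linked"],
        )
        grid = np.linspace(-2, 2, 9)
        curve = shortfall_effect_curve(fit, grid)
        b = fit.terms.loc["rn_shortfall_hppd", "coef"]
        assert curve["odds_ratio"].to_numpy() == pytest.approx(np.exp(b * grid))
        assert curve.loc[curve["shortfall_hppd"] == 0, "odds_ratio"].iloc[0] == 1.0

    def test_quadratic_curve_matches_coefficients(self):
        fit = self._fit(seed=47, days=150, beta_rn=-0.3)
        grid = np.linspace(-1.5, 1.5, 7)
        curve = shortfall_effect_curve(fit, grid)
        b1 = fit.terms.loc["rn_shortfall_hppd", "coef"]
        b2 = fit.terms.loc["rn_shortfall_hppd^2", "coef"]
        assert curve["odds_ratio"].to_numpy() == pytest.approx(
            np.exp(b1 * grid + b2 * grid**2)
        )
        assert (curve["ci_low"] <= curve["odds_ratio"]).all()
        assert (curve["odds_ratio"] <= curve["ci_high"]).all()

    def test_zero_coefficients_flat_line(self):
        fit = self._fit(seed=47, days=150, beta_rn=-0.3)
        flat = fit.terms.copy()
        flat.loc[:, "coef"] = 0.0
        fit.terms = flat
        curve = shortfall_effect_curve(fit, np.linspace(-2, 2, 5))
        assert (curve["odds_ratio"] == 1.0).all()


def test_exclude_hospital_sensitivity(small_dataset):
    full = fit_glmm(ModelSpec(outcome="enough_staff"), small_dataset["linked"])
    hosp = small_dataset["linked"]["hospital"].iloc[0]
    with pytest.warns(UserWarning, match="hospital"):
        reduced = fit_glmm(
            ModelSpec(outcome="enough_staff", exclude_hospital=hosp),
            small_dataset["linked"],
        )
    assert reduced.n_hospitals == full.n_hospitals - 1
    assert reduced.var_hosp == 0.0
    assert reduced.n_obs < full.n_obs
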