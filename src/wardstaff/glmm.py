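"""Three-level logistic models of nurse-reported staffing adequacy.

Day-level binary outcomes (enough staff for quality / care left undone /
breaks missed) are modelled with logistic regression carrying random
intercepts for unit nested in hospital:

    logit P(y_ij = 1) = x_ij' beta + b_unit(i) + b_hosp(j)
    b_unit ~ N(0, var_unit),  b_hosp ~ N(0, var_hosp)

Estimation is maximum likelihood under the Laplace approximation.  The
random effects are expressed spherically (b = sigma * u, u ~ N(0, I)); an
inner penalised iteratively reweighted least squares (PIRLS) loop maximises
the joint penalised log-likelihood over (beta, u), and an outer Nelder-Mead
search over the two standard deviations minimises the Laplace deviance

    dev(theta) = -2 * sum_i [y_i eta_i - log(1 + e^{eta_i})] + ||u||^2
                 + log det(I + S Z' W Z S)

with S the diagonal of per-column standard deviations.  This is the scheme
used by mainstream mixed-model software; with the large clusters seen here
(hundreds of days per unit) the Laplace approximation is essentially exact,
and with both variances at zero the fit collapses to ordinary logistic
regression.

Variance partition coefficients use the latent-variable formulation: the
day-level residual variance of a logistic model is pi^2/3, and each level's
VPC is its variance over the common total var_unit + var_hosp + pi^2/3.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

logger = logging.getLogger(__name__)

OUTCOMES = ("enough_staff", "care_left_undone", "breaks_missed")

#: Fixed-effect terms of the fully adjusted model.
DEFAULT_TERMS = (
    "rn_shortfall_hppd",
    "na_shortfall_hppd",
    "turnover",
    "surgical",
    "single_room_prop",
    "day_of_week",
)

#: Monday is the reference category for day of week.
WEEKDAYS = ("Tuesday", "Wednesday", "Thursday", "Friday", "Saturday", "Sunday")

_TERM_COLUMNS = {
    "turnover": "turnover_per_staff_hour",
}


class DegenerateOutcomeError(ValueError):
    """Outcome has a single observed class; the model is unidentifiable."""


class SeparationError(RuntimeError):
    """A covariate perfectly separates the outcome."""


@dataclass(frozen=True)
class ModelSpec:
    """Specification of one adequacy model."""

    outcome: str
    fixed_terms: tuple[str, ...] = DEFAULT_TERMS
    quadratic_terms: tuple[str, ...] = ()
    interaction_pairs: tuple[tuple[str, str], ...] = ()
    exclude_hospital: str | None = None

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if "total_shortfall_hppd" in self.fixed_terms and (
            "rn_shortfall_hppd" in self.fixed_terms
            or "na_shortfall_hppd" in self.fixed_terms
        ):
            raise ValueError(
                "total_shortfall_hppd and the RN/NA shortfall pair are mutually exclusive"
            )


@dataclass
class AdequacyFit:
    """Result of one multilevel logistic fit."""

    spec: ModelSpec
    terms: pd.DataFrame  # coef, se, or_, ci_low, ci_high, p per coded column
    cov_beta: pd.DataFrame
    var_unit: float
    var_hosp: float
    loglik: float
    aic: float
    bic: float
    n_obs: int
    n_units: int
    n_hospitals: int
    converged: bool
    n_dropped: int = 0

    @property
    def vpc_unit(self) -> float:
        return vpc(self.var_unit, self.var_hosp)[0]

    @property
    def vpc_hosp(self) -> float:
        return vpc(self.var_unit, self.var_hosp)[1]

    def odds_ratio(self, term: str) -> float:
        return float(self.terms.loc[term, "or_"])


def vpc(var_unit: float, var_hosp: float) -> tuple[float, float]:
    """Variance partition coefficients under the latent-variable approach.

    Each level's share of total latent variance, with the day-level logistic
    residual fixed at pi^2/3; both shares use the same denominator.
    """
    if var_unit < 0 or var_hosp < 0:
        raise ValueError("variances must be >= 0")
    total = var_unit + var_hosp + np.pi**2 / 3.0
    return var_unit / total, var_hosp / total


def or_to_percent_change(or_value: float) -> float:
    """Signed percent change in odds for an odds ratio (0.89 -> -11%)."""
    if or_value <= 0:
        raise ValueError("odds ratio must be > 0")
    return 100.0 * (or_value - 1.0)


# ---------------------------------------------------------------------------
# Design matrix


def _base_column(term: str, data: pd.DataFrame) -> np.ndarray:
    if term == "surgical":
        if "surgical" in data.columns:
            return data["surgical"].to_numpy(dtype=float)
        return (data["specialty"].astype(str) == "surgical").to_numpy(dtype=float)
    col = _TERM_COLUMNS.get(term, term)
    return data[col].to_numpy(dtype=float)


def build_design(
    data: pd.DataFrame, spec: ModelSpec
) -> tuple[np.ndarray, list[str]]:
    """Expand the spec's terms into a design matrix (without intercept).

    Day of week becomes six indicators with Monday as reference; quadratic
    terms append squared columns; interaction pairs append products.
    Covariates enter in natural units (per HPPD, per proportion), never
    standardised, so odds ratios are per natural unit.
    """
    cols: list[np.ndarray] = []
    names: list[str] = []
    for term in spec.fixed_terms:
        if term == "day_of_week":
            dow = data["day_of_week"].astype(str)
            for day in WEEKDAYS:
                cols.append((dow == day).to_numpy(dtype=float))
                names.append(f"day_of_week[{day}]")
        else:
            cols.append(_base_column(term, data))
            names.append(term)
    for term in spec.quadratic_terms:
        cols.append(_base_column(term, data) ** 2)
        names.append(f"{term}^2")
    for a, b in spec.interaction_pairs:
        cols.append(_base_column(a, data) * _base_column(b, data))
        names.append(f"{a}:{b}")
    return np.column_stack(cols) if cols else np.empty((len(data), 0)), names


# ---------------------------------------------------------------------------
# Laplace-ML fitter


def _expit(eta: np.ndarray) -> np.ndarray:
    return special.expit(np.clip(eta, -30.0, 30.0))


class _Design:
    """[X | Z_unit | Z_hosp] with the indicator blocks kept implicit.

    The random-effect columns are group indicators, so every cross-product
    the Newton step needs reduces to per-group sums: Z'WZ blocks are
    diagonal (unit-in-hospital nesting makes the unit-hospital block a
    one-entry-per-unit scatter), and Z'WX is a group-sum of the weighted
    fixed-effect rows.  This keeps each PIRLS iteration O(n k^2) in the
    number of fixed effects k rather than O(n p^2) in the full dimension.
    """

    def __init__(self, X: np.ndarray, unit_idx: np.ndarray, hosp_idx: np.ndarray | None):
        self.X = X
        self.unit_idx = unit_idx
        self.hosp_idx = hosp_idx
        self.k = X.shape[1]
        self.q_u = int(unit_idx.max()) + 1
        self.q_h = int(hosp_idx.max()) + 1 if hosp_idx is not None else 0
        self.p = self.k + self.q_u + self.q_h
        if hosp_idx is not None:
            # nested: each unit sits inside exactly one hospital
            self.unit_to_hosp = np.zeros(self.q_u, dtype=int)
            self.unit_to_hosp[unit_idx] = hosp_idx

    def eta(self, gamma: np.ndarray, scale: np.ndarray) -> np.ndarray:
        k, q_u = self.k, self.q_u
        out = self.X @ gamma[:k]
        out += (scale[k] * gamma[k : k + q_u])[self.unit_idx]
        if self.q_h:
            out += (scale[k + q_u] * gamma[k + q_u :])[self.hosp_idx]
        return out

    def hessian_and_grad(
        self, w: np.ndarray, resid: np.ndarray, gamma: np.ndarray, scale: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        k, q_u, q_h, p = self.k, self.q_u, self.q_h, self.p
        s_u = scale[k]
        s_h = scale[k + q_u] if q_h else 0.0
        Xw = self.X * w[:, None]
        H = np.zeros((p, p))
        H[:k, :k] = self.X.T @ Xw
        w_u = np.bincount(self.unit_idx, weights=w, minlength=q_u)
        Hxu = np.column_stack(
            [
                np.bincount(self.unit_idx, weights=Xw[:, j], minlength=q_u)
                for j in range(k)
            ]
        )
        H[:k, k : k + q_u] = s_u * Hxu.T
        H[k : k + q_u, :k] = s_u * Hxu
        iu = np.arange(k + 0, k + q_u)
        H[iu, iu] += s_u**2 * w_u
        grad = np.empty(p)
        grad[:k] = self.X.T @ resid
        grad[k : k + q_u] = s_u * np.bincount(
            self.unit_idx, weights=resid, minlength=q_u
        )
        if q_h:
            w_h = np.bincount(self.hosp_idx, weights=w, minlength=q_h)
            Hxv = np.column_stack(
                [
                    np.bincount(self.hosp_idx, weights=Xw[:, j], minlength=q_h)
                    for j in range(k)
                ]
            )
            H[:k, k + q_u :] = s_h * Hxv.T
            H[k + q_u :, :k] = s_h * Hxv
            iv = np.arange(k + q_u, p)
            H[iv, iv] += s_h**2 * w_h
            cross = s_u * s_h * w_u  # one entry per unit, at its hospital
            H[iu, k + q_u + self.unit_to_hosp] += cross
            H[k + q_u + self.unit_to_hosp, iu] += cross
            grad[k + q_u :] = s_h * np.bincount(
                self.hosp_idx, weights=resid, minlength=q_h
            )
        # identity penalty on the spherical random effects
        ir = np.arange(k, p)
        H[ir, ir] += 1.0
        grad[k:] -= gamma[k:]
        return H, grad


def _pirls(
    y: np.ndarray,
    design: _Design,
    scale: np.ndarray,
    gamma: np.ndarray,
    max_iter: int = 60,
    tol: float = 1e-10,
) -> tuple[np.ndarray, float, np.ndarray, bool]:
    """Penalised Newton over joint (beta, u) with step-halving.

    ``scale`` carries [1]*k followed by sigma_unit (and sigma_hosp) for the
    spherical random-effect blocks.  Returns the maximiser, the penalised
    deviance, the penalised Hessian S A'WA S + P at it, and a flag.
    """
    k = design.k

    def pdev(g: np.ndarray) -> float:
        eta = design.eta(g, scale)
        ll = y * eta - np.logaddexp(0.0, eta)
        return -2.0 * ll.sum() + float(g[k:] @ g[k:])

    current = pdev(gamma)
    converged = False
    for _ in range(max_iter):
        eta = design.eta(gamma, scale)
        mu = _expit(eta)
        w = mu * (1.0 - mu)
        H, grad = design.hessian_and_grad(w, y - mu, gamma, scale)
        # grad here is of the penalised loglik; Newton ascent step
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        lam = 1.0
        for _ in range(30):
            cand = gamma + lam * step
            new = pdev(cand)
            if new <= current + 1e-12:
                break
            lam *= 0.5
        else:  # no improving step: already at the optimum
            converged = True
            break
        if current - new < tol * (abs(current) + 1.0):
            gamma, current = cand, new
            converged = True
            break
        gamma, current = cand, new
    eta = design.eta(gamma, scale)
    mu = _expit(eta)
    H, _ = design.hessian_and_grad(mu * (1.0 - mu), y - mu, gamma, scale)
    return gamma, current, H, converged


@dataclass
class _LaplaceResult:
    beta: np.ndarray
    u: np.ndarray
    sigmas: np.ndarray
    loglik: float
    cov_beta: np.ndarray
    converged: bool


def _fit_laplace(
    y: np.ndarray,
    X: np.ndarray,
    unit_idx: np.ndarray,
    hosp_idx: np.ndarray | None,
    start_sigmas: tuple[float, float] = (1.0, 0.7),
) -> _LaplaceResult:
    design = _Design(X, unit_idx, hosp_idx)
    k, q_u, q_h, p = design.k, design.q_u, design.q_h, design.p

    state = {"gamma": np.zeros(p)}

    def make_scale(sig: np.ndarray) -> np.ndarray:
        scale = np.ones(p)
        scale[k : k + q_u] = abs(sig[0])
        if q_h:
            scale[k + q_u :] = abs(sig[1])
        return scale

    def laplace_deviance(sig: np.ndarray) -> float:
        gamma, dev, H, _ = _pirls(y, design, make_scale(sig), state["gamma"].copy())
        state["gamma"] = gamma
        sign, logdet = np.linalg.slogdet(H[k:, k:])
        if sign <= 0:
            return np.inf
        return dev + logdet

    n_var = 2 if q_h else 1
    x0 = np.array(start_sigmas[:n_var])
    res = optimize.minimize(
        lambda s: laplace_deviance(np.concatenate([s, [0.0]])[:2]),
        x0,
        method="Nelder-Mead",
        options={"xatol": 1e-3, "fatol": 1e-4, "maxiter": 400},
    )
    sig_opt = np.abs(np.concatenate([res.x, [0.0]])[:2])
    # final solve at the optimum, from a cold start for reproducibility
    scale = make_scale(sig_opt)
    gamma, dev, H, inner_ok = _pirls(y, design, scale, np.zeros(p))
    _, logdet = np.linalg.slogdet(H[k:, k:])
    loglik = -0.5 * (dev + logdet)
    cov = np.linalg.inv(H)[:k, :k]
    return _LaplaceResult(
        beta=gamma[:k],
        u=gamma[k:],
        sigmas=sig_opt,
        loglik=float(loglik),
        cov_beta=cov,
        converged=bool(res.success and inner_ok),
    )


def fit_glmm(
    spec: ModelSpec,
    data: pd.DataFrame,
    ci_level: float = 0.95,
) -> AdequacyFit:
    """Fit a three-level logistic model of one adequacy outcome.

    Rows with a missing outcome or covariate are dropped listwise (counts
    recorded on the fit).  With fewer than two hospitals after any exclusion
    the hospital level is dropped with a warning and its variance reported as
    zero.  Non-convergence is flagged on the result, never silent; complete
    separation raises :class:`SeparationError` naming the covariate.
    """
    df = data.copy()
    if spec.exclude_hospital is not None:
        df = df[df["hospital"].astype(str) != str(spec.exclude_hospital)]
    X_raw, names = build_design(df, spec)
    y_raw = df[spec.outcome].to_numpy(dtype=float)
    ok = np.isfinite(y_raw) & np.isfinite(X_raw).all(axis=1)
    n_dropped = int((~ok).sum())
    df, X_raw, y = df.loc[ok], X_raw[ok], y_raw[ok]
    if len(np.unique(y)) < 2:
        raise DegenerateOutcomeError(
            f"outcome {spec.outcome!r} has a single observed class"
        )
    X = np.column_stack([np.ones(len(y)), X_raw])
    names = ["intercept"] + names

    unit_idx, units = pd.factorize(df["unit_id"], sort=True)
    hosp_codes, hospitals = pd.factorize(df["hospital"].astype(str), sort=True)
    if len(hospitals) < 2:
        warnings.warn(
            "fewer than two hospitals; dropping the hospital random level",
            stacklevel=2,
        )
        hosp_idx = None
    else:
        hosp_idx = hosp_codes

    res = _fit_laplace(y, X, unit_idx, hosp_idx)
    if not res.converged:
        logger.warning("GLMM for %s did not fully converge", spec.outcome)
    # complete separation: an absurd effect per SD of the covariate
    sds = X.std(axis=0)
    sds[0] = 0.0  # intercept exempt
    scaled = np.abs(res.beta) * sds
    if scaled.max() > 10.0:
        worst = names[int(scaled.argmax())]
        raise SeparationError(f"covariate {worst!r} appears to separate the outcome")

    se = np.sqrt(np.diag(res.cov_beta))
    z = stats.norm.ppf(1 - (1 - ci_level) / 2)
    table = pd.DataFrame(
        {
            "coef": res.beta,
            "se": se,
            "or_": np.exp(res.beta),
            "ci_low": np.exp(res.beta - z * se),
            "ci_high": np.exp(res.beta + z * se),
            "p": 2 * stats.norm.sf(np.abs(res.beta) / se),
        },
        index=pd.Index(names, name="term"),
    )
    n_obs = len(y)
    # k counts fixed effects plus the two variance parameters
    k = len(names) + (2 if hosp_idx is not None else 1)
    aic = -2.0 * res.loglik + 2.0 * k
    bic = -2.0 * res.loglik + k * np.log(n_obs)
    return AdequacyFit(
        spec=spec,
        terms=table,
        cov_beta=pd.DataFrame(res.cov_beta, index=table.index, columns=table.index),
        var_unit=float(res.sigmas[0] ** 2),
        var_hosp=float(res.sigmas[1] ** 2),
        loglik=res.loglik,
        aic=float(aic),
        bic=float(bic),
        n_obs=n_obs,
        n_units=len(units),
        n_hospitals=len(hospitals),
        converged=res.converged,
        n_dropped=n_dropped,
    )


def univariable_or(term: str, data: pd.DataFrame, outcome: str) -> AdequacyFit:
    """Fit one covariate plus the nested random intercepts only."""
    return fit_glmm(ModelSpec(outcome=outcome, fixed_terms=(term,)), data)


@dataclass
class QuadraticComparison:
    fit_linear: AdequacyFit
    fit_quadratic: AdequacyFit
    delta_aic: float
    delta_bic: float
    preferred: str  # "linear", "quadratic" or "ambiguous"


def add_quadratic_and_compare(
    spec: ModelSpec, data: pd.DataFrame, terms: tuple[str, ...] | None = None
) -> QuadraticComparison:
    """Refit with squared staffing terms and compare AIC/BIC.

    ``preferred`` is the model favoured by both criteria; when AIC and BIC
    disagree the comparison is reported as ambiguous.
    """
    if terms is None:
        terms = tuple(
            t for t in spec.fixed_terms if t.endswith("shortfall_hppd")
        )
    if not terms:
        raise ValueError("base spec contains no staffing shortfall term")
    fit_lin = fit_glmm(spec, data)
    fit_quad = fit_glmm(replace(spec, quadratic_terms=terms), data)
    d_aic = fit_quad.aic - fit_lin.aic
    d_bic = fit_quad.bic - fit_lin.bic
    if d_aic < 0 and d_bic < 0:
        preferred = "quadratic"
    elif d_aic >= 0 and d_bic >= 0:
        preferred = "linear"
    else:
        preferred = "ambiguous"
    return QuadraticComparison(fit_lin, fit_quad, float(d_aic), float(d_bic), preferred)


def interaction_scan(
    spec: ModelSpec,
    data: pd.DataFrame,
    candidate_pairs: tuple[tuple[str, str], ...],
) -> pd.DataFrame:
    """Fit base + each candidate interaction; report significance and ΔAIC/ΔBIC."""
    rows = []
    if not candidate_pairs:
        return pd.DataFrame(
            columns=["pair", "coef", "p", "delta_aic", "delta_bic", "significant"]
        )
    base = fit_glmm(spec, data)
    for pair in candidate_pairs:
        fit = fit_glmm(replace(spec, interaction_pairs=(pair,)), data)
        name = f"{pair[0]}:{pair[1]}"
        rows.append(
            {
                "pair": name,
                "coef": float(fit.terms.loc[name, "coef"]),
                "p": float(fit.terms.loc[name, "p"]),
                "delta_aic": fit.aic - base.aic,
                "delta_bic": fit.bic - base.bic,
                "significant": bool(fit.terms.loc[name, "p"] < 0.05),
            }
        )
    return pd.DataFrame(rows)


def shortfall_effect_curve(
    fit: AdequacyFit,
    grid: np.ndarray,
    term: str = "rn_shortfall_hppd",
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Odds ratio relative to zero shortfall across a grid, with CI band.

    Uses the linear and (when present) quadratic coefficients for ``term``:
    OR(x) = exp(b1*x + b2*x^2), with a delta-method CI from the coefficient
    covariance.
    """
    grid = np.asarray(grid, dtype=float)
    b1 = float(fit.terms.loc[term, "coef"])
    quad = f"{term}^2"
    has_quad = quad in fit.terms.index
    b2 = float(fit.terms.loc[quad, "coef"]) if has_quad else 0.0
    eta = b1 * grid + b2 * grid**2
    v11 = float(fit.cov_beta.loc[term, term])
    if has_quad:
        v22 = float(fit.cov_beta.loc[quad, quad])
        v12 = float(fit.cov_beta.loc[term, quad])
    else:
        v22 = v12 = 0.0
    var_eta = grid**2 * v11 + grid**4 * v22 + 2 * grid**3 * v12
    z = stats.norm.ppf(1 - (1 - ci_level) / 2)
    half = z * np.sqrt(np.maximum(var_eta, 0.0))
    return pd.DataFrame(
        {
            "shortfall_hppd": grid,
            "odds_ratio": np.exp(eta),
            "ci_low": np.exp(eta - half),
            "ci_high": np.exp(eta + half),
        }
    )
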