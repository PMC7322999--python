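"""Valuation regressions: composite SWB on capability levels and SES controls.

The estimating equation regresses each respondent's composite SWB on dummy
variables for levels 2–4 of the five capability dimensions (level 1, full
capability, is the reference) plus socio-economic controls:

    SWB_i = b0 + sum_d sum_{l=2..4} D_{i,d,l} * beta_{d,l} + SES_i' gamma + e_i

Four estimators are provided: OLS (reduced and full models), restricted
least squares with fixed-value equality constraints (used to repair illogical
level orderings, e.g. fixing one offending coefficient to zero), and a
two-sided Tobit for the censoring of the SWB index at 0 and 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.base.model import GenericLikelihoodModel

from .instruments import FINANCE_CATEGORIES, FINANCE_DUMMIES, InstrumentSpec
from .swb import swb_response

logger = logging.getLogger("icetariff")

LevelKey = tuple[str, int]
Constraint = tuple[str, int, float]


class EstimationError(RuntimeError):
    """Raised when a model cannot be estimated (rank deficiency, divergence)."""


def level_column(dimension: str, level: int) -> str:
    return f"{dimension}_{level}"


@dataclass
class ModelConfig:
    """Choice of model and estimator for one regression run.

    model: "reduced" (capability dummies only) or "full" (+ SES controls).
    estimator: "ols", "constrained" (restricted least squares) or "tobit".
    constraints: fixed-value constraints (dimension, level, value) imposed
        when estimator == "constrained"; if empty, violations detected on the
        OLS fit are converted to zero constraints automatically.
    swb_source: response variable ("composite", "cantril_only", "swls_only").
    """

    model: str = "full"
    estimator: str = "ols"
    constraints: list[Constraint] = field(default_factory=list)
    swb_source: str = "composite"
    include_worst_dummy: bool = False

    def __post_init__(self) -> None:
        if self.model not in ("reduced", "full"):
            raise ValueError(f"model must be 'reduced' or 'full', got {self.model!r}")
        if self.estimator not in ("ols", "constrained", "tobit"):
            raise ValueError(f"unknown estimator {self.estimator!r}")


@dataclass
class DesignMatrix:
    """Dummy-coded design and response for one instrument sample."""

    X: pd.DataFrame
    y: pd.Series
    spec: InstrumentSpec
    include_ses: bool
    include_worst_dummy: bool
    n_dropped: int = 0

    @property
    def n(self) -> int:
        return len(self.X)

    def level_keys(self) -> list[LevelKey]:
        return self.spec.level_columns()


@dataclass
class CoefficientSet:
    """Estimated coefficients of one valuation regression.

    ``level_disutilities`` maps (dimension, level in {2,3,4}) to the level's
    coefficient in SWB units (expected <= 0 under the disutility convention);
    level 1 is the reference and implicitly carries 0.
    """

    instrument: str
    intercept: float
    level_disutilities: dict[LevelKey, float]
    ses_effects: dict[str, float]
    standard_errors: dict[object, float]
    r_squared: float | None
    n: int
    model_tag: str
    constraints: list[Constraint] = field(default_factory=list)
    sigma: float | None = None
    n_censored: int | None = None

    def level_coef(self, dimension: str, level: int) -> float:
        if level == 1:
            return 0.0
        return self.level_disutilities[(dimension, level)]

    def predict_profile(self, profile, ses: dict[str, float] | None = None) -> float:
        """Model-implied SWB of a capability profile.

        ``profile`` is a 5-character string like "44444" or a sequence of
        five levels, ordered as the instrument's dimensions.  SES covariates
        default to zero (their reference values).
        """
        levels = _parse_profile(profile)
        dims = _dimension_order(self.level_disutilities)
        value = self.intercept
        for dim, lev in zip(dims, levels):
            value += self.level_coef(dim, lev)
        if ses:
            for name, x in ses.items():
                value += self.ses_effects[name] * x
        return value


def _parse_profile(profile) -> list[int]:
    if isinstance(profile, str):
        levels = [int(c) for c in profile.strip()]
    else:
        levels = [int(v) for v in profile]
    if len(levels) != 5 or any(l < 1 or l > 4 for l in levels):
        raise ValueError(f"profile must be five levels in 1..4, got {profile!r}")
    return levels


def _dimension_order(level_disutilities: dict[LevelKey, float]) -> list[str]:
    seen: list[str] = []
    for dim, _ in level_disutilities:
        if dim not in seen:
            seen.append(dim)
    return seen


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------

def build_design(
    df: pd.DataFrame,
    spec: InstrumentSpec,
    include_ses: bool = True,
    include_worst_dummy: bool = False,
    swb_source: str = "composite",
) -> DesignMatrix:
    """Dummy-code a respondent table into a regression design.

    Levels 2–4 of every dimension become indicator columns (level 1 is the
    reference).  With ``include_ses``, age enters as age and age², the
    financial-difficulty item as three dummies against the reference
    "with great difficulty", and the monetary covariate on the instrument's
    scale (wealth in £ millions, income in £/month).  Rows with any missing
    field are dropped (complete-case analysis) with a logged count.
    """
    df = df.reset_index(drop=True)
    level_cols = [f"dim{i + 1}" for i in range(5)]
    for col in level_cols:
        vals = df[col]
        bad = ~vals.isin([1, 2, 3, 4]) & vals.notna()
        if bad.any():
            i = int(bad.idxmax())
            raise ValueError(
                f"invalid capability level {vals[i]!r} in column {col} (row {i})"
            )

    used = ["cantril", "swls"] + level_cols
    if include_ses:
        used += ["sex", "age", "tertiary", "married", "finance_cat", "wealth_or_income"]
    complete = df[used].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("dropped %d incomplete rows (complete-case analysis)", n_dropped)
    df = df.loc[complete].reset_index(drop=True)
    if df.empty:
        raise ValueError("no complete rows left after dropping missing data")

    X = pd.DataFrame(index=df.index)
    X["const"] = 1.0
    for i, dim in enumerate(spec.dimensions):
        lev = df[f"dim{i + 1}"].astype(int)
        for l in range(2, spec.n_levels + 1):
            X[level_column(dim, l)] = (lev == l).astype(float)
    if include_worst_dummy:
        worst = np.zeros(len(df), dtype=bool)
        for i in range(5):
            worst |= df[f"dim{i + 1}"].astype(int).to_numpy() == spec.n_levels
        X["worst_level_any"] = worst.astype(float)
    if include_ses:
        fin = df["finance_cat"].astype(str)
        unknown = ~fin.isin(FINANCE_CATEGORIES)
        if unknown.any():
            i = int(unknown.idxmax())
            raise ValueError(
                f"unknown finance_cat {fin[i]!r} (row {i}); "
                f"expected one of {FINANCE_CATEGORIES}"
            )
        X["male"] = df["sex"].astype(float)
        age = df["age"].astype(float)
        X["age"] = age
        X["age_sq"] = age**2
        X["tertiary"] = df["tertiary"].astype(float)
        X["married"] = df["married"].astype(float)
        for cat, colname in zip(FINANCE_CATEGORIES[1:], FINANCE_DUMMIES):
            X[colname] = (fin == cat).astype(float)
        X[spec.money_covariate] = df["wealth_or_income"].astype(float) / spec.money_scale

    y = swb_response(df, swb_source)
    return DesignMatrix(
        X=X,
        y=y,
        spec=spec,
        include_ses=include_ses,
        include_worst_dummy=include_worst_dummy,
        n_dropped=n_dropped,
    )


def _check_rank(X: pd.DataFrame) -> None:
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify columns whose removal restores full rank
        culprits = []
        arr = X.to_numpy()
        for j, name in enumerate(X.columns):
            rest = np.delete(arr, j, axis=1)
            if np.linalg.matrix_rank(rest) == rank:
                culprits.append(name)
        raise EstimationError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            f"collinear columns: {culprits}"
        )


def _to_coefficient_set(
    params: pd.Series,
    bse: pd.Series,
    design: DesignMatrix,
    r_squared: float | None,
    model_tag: str,
    constraints: list[Constraint] | None = None,
    sigma: float | None = None,
    n_censored: int | None = None,
) -> CoefficientSet:
    level_dis: dict[LevelKey, float] = {}
    ses: dict[str, float] = {}
    errs: dict[object, float] = {"const": float(bse["const"])}
    for dim, l in design.level_keys():
        col = level_column(dim, l)
        level_dis[(dim, l)] = float(params[col])
        errs[(dim, l)] = float(bse[col])
    for col in design.X.columns:
        if col == "const" or "_" in col and any(
            col == level_column(d, l) for d, l in design.level_keys()
        ):
            continue
        ses[col] = float(params[col])
        errs[col] = float(bse[col])
    return CoefficientSet(
        instrument=design.spec.name,
        intercept=float(params["const"]),
        level_disutilities=level_dis,
        ses_effects=ses,
        standard_errors=errs,
        r_squared=r_squared,
        n=design.n,
        model_tag=model_tag,
        constraints=list(constraints or []),
        sigma=sigma,
        n_censored=n_censored,
    )


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------

def fit_ols(design: DesignMatrix, model_tag: str = "full") -> CoefficientSet:
    """Ordinary least squares with classical (homoskedastic) standard errors."""
    _check_rank(design.X)
    res = sm.OLS(design.y.to_numpy(), design.X).fit()
    return _to_coefficient_set(
        res.params, res.bse, design, float(res.rsquared), model_tag
    )


def _validate_constraints(design: DesignMatrix, constraints: list[Constraint]) -> None:
    seen: dict[str, float] = {}
    for dim, level, value in constraints:
        col = level_column(dim, level)
        if col not in design.X.columns:
            raise ValueError(f"constraint references unknown column {col!r}")
        if col in seen:
            if seen[col] != value:
                raise ValueError(
                    f"inconsistent duplicate constraints on {col}: "
                    f"{seen[col]} vs {value}"
                )
            raise ValueError(f"duplicate constraint on {col}")
        seen[col] = value


def fit_constrained_ols(
    design: DesignMatrix,
    constraints: list[Constraint],
    model_tag: str = "constrained",
) -> CoefficientSet:
    """Restricted least squares imposing fixed-value equality constraints.

    Each constraint fixes one level coefficient to a value (typically zero,
    to repair an illogical ordering).  Free coefficients and their standard
    errors come from the restricted fit; constrained coefficients are exact
    with zero standard error.  With no constraints this reduces to OLS.
    """
    _validate_constraints(design, constraints)
    if not constraints:
        out = fit_ols(design, model_tag=model_tag)
        out.constraints = []
        return out
    _check_rank(design.X)
    y = design.y.to_numpy()
    glm = sm.GLM(y, design.X, family=sm.families.Gaussian())
    spec_strs = [
        f"{level_column(dim, level)} = {value!r}" for dim, level, value in constraints
    ]
    res = glm.fit_constrained(", ".join(spec_strs))
    params = pd.Series(np.asarray(res.params), index=design.X.columns)
    bse = pd.Series(np.asarray(res.bse), index=design.X.columns)
    # exact imposition (fit_constrained is exact up to float roundoff)
    for dim, level, value in constraints:
        col = level_column(dim, level)
        params[col] = value
        bse[col] = 0.0
    fitted = design.X.to_numpy() @ params.to_numpy()
    ssr = float(np.sum((y - fitted) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ssr / sst if sst > 0 else np.nan
    return _to_coefficient_set(params, bse, design, r2, model_tag, constraints)


class _TwoSidedTobit(GenericLikelihoodModel):
    """Censored-normal regression with known lower and upper bounds.

    The latent variable y* = X beta + e, e ~ N(0, sigma²), is observed as
    y = min(max(y*, lower), upper).  Uncensored rows contribute the normal
    density of the residual; censored rows the tail probability of the
    latent variable beyond the bound.  Parameterised with log(sigma) for an
    unconstrained optimisation.
    """

    def __init__(self, endog, exog, lower=0.0, upper=1.0, **kw):
        self.lower = lower
        self.upper = upper
        super().__init__(endog, exog, **kw)

    def loglikeobs(self, params):
        from scipy import stats

        beta, log_sigma = params[:-1], params[-1]
        sigma = np.exp(log_sigma)
        xb = self.exog @ beta
        y = self.endog
        z = (y - xb) / sigma
        at_lower = y <= self.lower
        at_upper = y >= self.upper
        mid = ~(at_lower | at_upper)
        ll = np.empty_like(y)
        ll[mid] = stats.norm.logpdf(z[mid]) - log_sigma
        ll[at_lower] = stats.norm.logcdf((self.lower - xb[at_lower]) / sigma)
        ll[at_upper] = stats.norm.logsf((self.upper - xb[at_upper]) / sigma)
        return ll

    def score_obs(self, params, **kwds):
        from scipy import stats

        beta, log_sigma = params[:-1], params[-1]
        sigma = np.exp(log_sigma)
        xb = self.exog @ beta
        y = self.endog
        at_lower = y <= self.lower
        at_upper = y >= self.upper
        mid = ~(at_lower | at_upper)
        # d ll / d xb (per obs, scaled by 1/sigma) and d ll / d log_sigma
        dxb = np.empty_like(y)
        dls = np.empty_like(y)
        z = (y[mid] - xb[mid]) / sigma
        dxb[mid] = z / sigma
        dls[mid] = z**2 - 1.0
        a = (self.lower - xb[at_lower]) / sigma
        mills_a = np.exp(stats.norm.logpdf(a) - stats.norm.logcdf(a))
        dxb[at_lower] = -mills_a / sigma
        dls[at_lower] = -mills_a * a
        b = (self.upper - xb[at_upper]) / sigma
        mills_b = np.exp(stats.norm.logpdf(b) - stats.norm.logsf(b))
        dxb[at_upper] = mills_b / sigma
        dls[at_upper] = mills_b * b
        return np.column_stack([dxb[:, None] * self.exog, dls])

    def score(self, params, **kwds):
        return self.score_obs(params).sum(axis=0)


def fit_tobit(
    design: DesignMatrix,
    lower: float = 0.0,
    upper: float = 1.0,
    model_tag: str = "tobit",
) -> CoefficientSet:
    """Two-sided Tobit MLE for the SWB index censored at the scale bounds.

    Standard errors come from the observed information at the optimum.  The
    returned set records sigma and the count of censored rows; no R² is
    reported for this estimator.
    """
    _check_rank(design.X)
    y = design.y.to_numpy()
    if np.any((y < lower) | (y > upper)):
        raise ValueError(f"response outside the censoring bounds [{lower}, {upper}]")
    n_cens = int(np.sum((y <= lower) | (y >= upper)))
    if np.all(y <= lower) or np.all(y >= upper):
        raise EstimationError("all observations censored at one bound; mean not identifiable")

    ols = sm.OLS(y, design.X).fit()
    sigma0 = max(float(np.sqrt(ols.mse_resid)), 1e-6)
    start = np.append(np.asarray(ols.params), np.log(sigma0))
    mod = _TwoSidedTobit(
        y, design.X, lower=lower, upper=upper,
        extra_params_names=["log_sigma"],
    )
    res = mod.fit(start_params=start, method="bfgs", maxiter=500, disp=0)
    if not res.mle_retvals.get("converged", False):
        res = mod.fit(start_params=res.params, method="nm",
                      maxiter=5000, maxfun=10000, disp=0)
        if not res.mle_retvals.get("converged", False):
            raise EstimationError(
                f"Tobit did not converge: {res.mle_retvals}"
            )
    par_all = np.asarray(res.params)
    params = pd.Series(par_all[:-1], index=design.X.columns)
    with np.errstate(invalid="ignore"):
        bse_all = np.asarray(res.bse)
    bse = pd.Series(bse_all[:-1], index=design.X.columns)
    sigma = float(np.exp(par_all[-1]))
    return _to_coefficient_set(
        params, bse, design, None, model_tag, sigma=sigma, n_censored=n_cens
    )


# ---------------------------------------------------------------------------
# Monotonicity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Violation:
    """One illogical level ordering in a fitted coefficient set."""

    dimension: str
    level: int
    kind: str  # "positive" | "nonmonotone"
    message: str


def check_monotonicity(coefs: CoefficientSet) -> list[Violation]:
    """Flag illogical orderings of the level coefficients.

    Within a dimension the disutility should grow in magnitude with worse
    levels; a positive level coefficient (a *gain* relative to full
    capability) or a worse level with strictly smaller magnitude than a
    better one is flagged.
    """
    out: list[Violation] = []
    dims = _dimension_order(coefs.level_disutilities)
    for dim in dims:
        for l in range(2, 5):
            c = coefs.level_disutilities[(dim, l)]
            if c > 0:
                out.append(
                    Violation(dim, l, "positive",
                              f"{dim} level {l} coefficient is positive ({c:+.3f})")
                )
        for l in range(3, 5):
            hi = abs(coefs.level_disutilities[(dim, l)])
            lo = abs(coefs.level_disutilities[(dim, l - 1)])
            if hi < lo:
                out.append(
                    Violation(dim, l, "nonmonotone",
                              f"{dim} level {l} disutility magnitude {hi:.3f} "
                              f"smaller than level {l - 1} ({lo:.3f})")
                )
    return out


def constraints_for_violations(
    coefs: CoefficientSet, violations: list[Violation], policy: str = "zero"
) -> list[Constraint]:
    """Translate detected violations into fixed-value constraints.

    policy "zero": positive coefficients are fixed to zero (the single
    repair applied in practice); non-monotone levels are left free.
    policy "tie": additionally fixes a non-monotone level to the better
    adjacent level's estimate.
    """
    if policy not in ("zero", "tie"):
        raise ValueError(f"unknown policy {policy!r}")
    out: list[Constraint] = []
    for v in violations:
        if v.kind == "positive":
            out.append((v.dimension, v.level, 0.0))
        elif policy == "tie":
            out.append(
                (v.dimension, v.level,
                 coefs.level_disutilities[(v.dimension, v.level - 1)])
            )
    return out
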