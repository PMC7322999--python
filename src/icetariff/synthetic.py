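"""Synthetic respondent generator.

No survey microdata are distributed with the instruments' valuation
studies, so the package generates respondent tables with the statistical
structure the valuation model assumes:

* Capability levels come from a single-factor Gaussian latent-threshold
  model: one common factor induces the same latent correlation
  (``dependence``) between every pair of dimensions, and per-dimension
  cut-points reproduce the requested level marginals exactly in expectation.
* Latent SWB is the linear valuation model evaluated at the drawn levels and
  SES covariates plus Normal(0, noise_sd) noise, optionally clamped to
  [0, 1].
* Cantril's ladder and SWLS are generated from that one latent SWB by adding
  independent instrument-specific measurement noise, mapping to the native
  integer scales (0–10 and 5–35), rounding, and clipping — so the composite
  index is a noise-reduced proxy of latent SWB.

SES covariates are drawn independently of capability levels (they enter the
valuation model only as additive controls); marginal distributions default
to the published sample summaries of the two UK surveys.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .instruments import FINANCE_CATEGORIES, InstrumentSpec, get_instrument
from .regression import CoefficientSet

RESPONDENT_COLUMNS = [
    "id", "dim1", "dim2", "dim3", "dim4", "dim5",
    "cantril", "swls",
    "sex", "age", "tertiary", "married", "finance_cat", "wealth_or_income",
]


class ConfigurationError(ValueError):
    """Invalid synthetic-generator configuration."""


@dataclass(frozen=True)
class SesParams:
    """Marginal SES distributions (defaults follow the published samples)."""

    p_male: float
    age_mean: float
    age_sd: float
    p_tertiary: float
    p_married: float
    finance_probs: tuple[float, float, float, float]
    money_log_median: float  # median of the log-normal wealth/income draw
    money_log_sd: float


#: Sample summaries of the two UK surveys (shares, means, medians).
DEFAULT_SES = {
    "ICECAP-O": SesParams(
        p_male=0.537, age_mean=75.1, age_sd=4.97,
        p_tertiary=0.452, p_married=0.601,
        finance_probs=(0.043, 0.262, 0.423, 0.272),
        money_log_median=77_500.0, money_log_sd=0.9,
    ),
    "ICECAP-A": SesParams(
        p_male=0.482, age_mean=42.9, age_sd=13.7,
        p_tertiary=0.454, p_married=0.595,
        finance_probs=(0.080, 0.378, 0.400, 0.142),
        money_log_median=2_250.0, money_log_sd=0.6,
    ),
}

#: Per-dimension level marginals (levels 1..4, level 1 = full capability).
#: The worst level is chosen by 1.6–8.0% of respondents, the range observed
#: across dimensions in the two surveys.
DEFAULT_MARGINALS = {
    "ICECAP-O": {
        "attachment": (0.50, 0.31, 0.15, 0.04),
        "security":   (0.33, 0.37, 0.22, 0.08),
        "role":       (0.40, 0.35, 0.20, 0.05),
        "enjoyment":  (0.33, 0.42, 0.19, 0.06),
        "control":    (0.40, 0.36, 0.20, 0.04),
    },
    "ICECAP-A": {
        "stability":   (0.30, 0.38, 0.24, 0.08),
        "attachment":  (0.46, 0.30, 0.18, 0.06),
        "autonomy":    (0.48, 0.30, 0.18, 0.04),
        "achievement": (0.32, 0.38, 0.23, 0.07),
        "enjoyment":   (0.38, 0.35, 0.21, 0.06),
    },
}


@dataclass
class SyntheticConfig:
    """Generating model for one synthetic respondent sample.

    ``dependence`` is the latent correlation between every pair of
    dimensions (single-factor construction), ``noise_sd`` the SD of the
    structural SWB error, and ``measurement_sd`` the SD of the independent
    noise added to latent SWB before mapping onto each instrument's integer
    scale.  ``censor`` clamps latent SWB to [0, 1] before measurement.
    """

    instrument: str
    n: int
    true_coefficients: CoefficientSet
    level_marginals: dict[str, tuple[float, float, float, float]]
    dependence: float = 0.3
    noise_sd: float = 0.07
    censor: bool = True
    measurement_sd: float = 0.10
    seed: int | None = None
    ses_params: SesParams | None = None
    require_monotone: bool = False

    def validate(self) -> None:
        spec = get_instrument(self.instrument)
        if self.n < 1:
            raise ConfigurationError(f"n must be >= 1, got {self.n}")
        if self.noise_sd < 0 or self.measurement_sd < 0:
            raise ConfigurationError("noise_sd and measurement_sd must be >= 0")
        if not (0.0 <= self.dependence < 1.0):
            raise ConfigurationError(
                f"dependence must lie in [0, 1), got {self.dependence}"
            )
        for dim in spec.dimensions:
            p = np.asarray(self.level_marginals[dim], dtype=float)
            if p.shape != (4,) or np.any(p < 0):
                raise ConfigurationError(
                    f"marginals for {dim!r} must be 4 non-negative probabilities"
                )
            if abs(p.sum() - 1.0) > 1e-12:
                raise ConfigurationError(
                    f"marginals for {dim!r} sum to {p.sum()!r}, not 1"
                )
        if self.require_monotone:
            for (dim, l), c in self.true_coefficients.level_disutilities.items():
                if c > 0:
                    raise ConfigurationError(
                        f"monotone generation requires non-positive level "
                        f"disutilities; ({dim}, {l}) = {c:+.3f}"
                    )


def _expected_ses_contribution(
    spec: InstrumentSpec, ses: SesParams, effects: dict[str, float]
) -> float:
    """Expected SES contribution to SWB under the SES marginals (age terms
    are evaluated like the generator draws them)."""
    money_mean = ses.money_log_median * float(np.exp(ses.money_log_sd**2 / 2.0))
    contrib = (
        effects.get("male", 0.0) * ses.p_male
        + effects.get("age", 0.0) * ses.age_mean
        + effects.get("age_sq", 0.0) * (ses.age_mean**2 + ses.age_sd**2)
        + effects.get("tertiary", 0.0) * ses.p_tertiary
        + effects.get("married", 0.0) * ses.p_married
        + effects.get(spec.money_covariate, 0.0) * money_mean / spec.money_scale
    )
    for p, col in zip(
        ses.finance_probs[1:],
        ("fin_some_difficulty", "fin_fairly_easy", "fin_easy"),
    ):
        contrib += effects.get(col, 0.0) * p
    return contrib


def calibrated_truth(instrument, ses_params: SesParams | None = None) -> CoefficientSet:
    """Generating coefficients on the observable SWB scale.

    Starts from the published full-model column but repairs two artifacts of
    table rounding that would push latent SWB off the unit scale: the age
    and age² coefficients (printed as 0.010 and −0.000, whose face values
    add ~0.75 at the sample mean age) are zeroed, and the intercept is set
    so that expected SWB at full capability with average SES equals the
    published reduced-model intercept.
    """
    from dataclasses import replace as _dc_replace

    from .published import published_coefficients

    spec = get_instrument(instrument)
    ses = ses_params or DEFAULT_SES[spec.name]
    full = published_coefficients(spec, "full")
    reduced = published_coefficients(spec, "reduced")
    effects = dict(full.ses_effects)
    effects["age"] = 0.0
    effects["age_sq"] = 0.0
    intercept = reduced.intercept - _expected_ses_contribution(spec, ses, effects)
    return _dc_replace(
        full, intercept=intercept, ses_effects=effects, model_tag="synthetic-truth"
    )


def default_config(
    instrument, n: int | None = None, seed: int | None = None, **overrides
) -> SyntheticConfig:
    """Study-condition defaults for an instrument.

    Sample size, SES marginals and level marginals follow the published
    survey summaries; the generating coefficients are the published
    full-model levels with the intercept calibrated to the observable scale
    (see ``calibrated_truth``).  Keyword overrides replace any config field.
    """
    spec = get_instrument(instrument)
    ses = DEFAULT_SES[spec.name]
    cfg = SyntheticConfig(
        instrument=spec.name,
        n=n if n is not None else (516 if spec.name == "ICECAP-O" else 1373),
        true_coefficients=calibrated_truth(spec, ses),
        level_marginals=dict(DEFAULT_MARGINALS[spec.name]),
        seed=seed,
        ses_params=ses,
    )
    if overrides:
        cfg = replace(cfg, **overrides)
    return cfg


@dataclass(frozen=True)
class RespondentRecord:
    """One validated respondent row (levels ordered as the instrument)."""

    id: int
    levels: tuple[int, int, int, int, int]
    cantril: int
    swls: int
    sex: int
    age: float
    tertiary: int
    married: int
    finance_cat: str
    wealth_or_income: float

    def validate(self, spec: InstrumentSpec) -> None:
        if any(l not in (1, 2, 3, 4) for l in self.levels):
            raise ValueError(f"levels must lie in 1..4, got {self.levels}")
        if not 0 <= self.cantril <= 10:
            raise ValueError(f"cantril outside [0, 10]: {self.cantril}")
        if not 5 <= self.swls <= 35:
            raise ValueError(f"swls outside [5, 35]: {self.swls}")
        lo, hi = spec.age_range
        if not lo <= self.age <= hi:
            raise ValueError(f"age {self.age} outside {spec.name} range [{lo}, {hi}]")
        if self.finance_cat not in FINANCE_CATEGORIES:
            raise ValueError(f"unknown finance_cat {self.finance_cat!r}")


def records_from_frame(df: pd.DataFrame, spec=None) -> list[RespondentRecord]:
    """View a respondent table as validated record objects."""
    spec = get_instrument(spec) if spec is not None else None
    out = []
    for row in df.itertuples(index=False):
        rec = RespondentRecord(
            id=int(row.id),
            levels=tuple(int(getattr(row, f"dim{i + 1}")) for i in range(5)),
            cantril=int(row.cantril),
            swls=int(row.swls),
            sex=int(row.sex),
            age=float(row.age),
            tertiary=int(row.tertiary),
            married=int(row.married),
            finance_cat=str(row.finance_cat),
            wealth_or_income=float(row.wealth_or_income),
        )
        if spec is not None:
            rec.validate(spec)
        out.append(rec)
    return out


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _draw_levels(
    rng: np.random.Generator,
    n: int,
    marginals: np.ndarray,  # (5, 4)
    dependence: float,
) -> np.ndarray:
    """Threshold correlated latent Gaussians at the marginal cut-points."""
    common = rng.standard_normal(n)
    idio = rng.standard_normal((n, 5))
    z = np.sqrt(dependence) * common[:, None] + np.sqrt(1.0 - dependence) * idio
    levels = np.empty((n, 5), dtype=int)
    for j in range(5):
        cum = np.cumsum(marginals[j])[:3]
        cuts = stats.norm.ppf(np.clip(cum, 0.0, 1.0))
        levels[:, j] = 1 + np.searchsorted(cuts, z[:, j], side="left")
    return levels


def _draw_ses(
    rng: np.random.Generator, n: int, spec: InstrumentSpec, ses: SesParams
) -> pd.DataFrame:
    lo, hi = spec.age_range
    age = np.clip(
        np.round(rng.normal(ses.age_mean, ses.age_sd, size=n)), lo, hi
    ).astype(int)
    finance = rng.choice(
        FINANCE_CATEGORIES, size=n, p=np.asarray(ses.finance_probs) / sum(ses.finance_probs)
    )
    money = np.round(
        np.exp(np.log(ses.money_log_median) + ses.money_log_sd * rng.standard_normal(n)),
        2,
    )
    return pd.DataFrame(
        {
            "sex": (rng.random(n) < ses.p_male).astype(int),
            "age": age,
            "tertiary": (rng.random(n) < ses.p_tertiary).astype(int),
            "married": (rng.random(n) < ses.p_married).astype(int),
            "finance_cat": finance,
            "wealth_or_income": money,
        }
    )


def _ses_contribution(
    ses_df: pd.DataFrame, spec: InstrumentSpec, coefs: CoefficientSet
) -> np.ndarray:
    if not coefs.ses_effects:
        return np.zeros(len(ses_df))
    g = coefs.ses_effects
    age = ses_df["age"].to_numpy(float)
    contrib = (
        g.get("male", 0.0) * ses_df["sex"].to_numpy(float)
        + g.get("age", 0.0) * age
        + g.get("age_sq", 0.0) * age**2
        + g.get("tertiary", 0.0) * ses_df["tertiary"].to_numpy(float)
        + g.get("married", 0.0) * ses_df["married"].to_numpy(float)
        + g.get(spec.money_covariate, 0.0)
        * ses_df["wealth_or_income"].to_numpy(float) / spec.money_scale
    )
    fin = ses_df["finance_cat"].to_numpy()
    for cat, col in zip(
        FINANCE_CATEGORIES[1:],
        ("fin_some_difficulty", "fin_fairly_easy", "fin_easy"),
    ):
        contrib = contrib + g.get(col, 0.0) * (fin == cat)
    return np.asarray(contrib, dtype=float)


def generate_dataset(config: SyntheticConfig) -> pd.DataFrame:
    """Draw a synthetic respondent table (one row per respondent).

    Deterministic for a fixed config including seed.  Columns follow the
    respondent-table schema (``RESPONDENT_COLUMNS``).
    """
    config.validate()
    spec = get_instrument(config.instrument)
    rng = np.random.default_rng(config.seed)
    marg = np.array([config.level_marginals[d] for d in spec.dimensions], dtype=float)

    levels = _draw_levels(rng, config.n, marg, config.dependence)
    ses_df = _draw_ses(rng, config.n, spec, config.ses_params or DEFAULT_SES[spec.name])

    coefs = config.true_coefficients
    mu = np.full(config.n, coefs.intercept)
    for j, dim in enumerate(spec.dimensions):
        for l in (2, 3, 4):
            mu += coefs.level_disutilities[(dim, l)] * (levels[:, j] == l)
    mu += _ses_contribution(ses_df, spec, coefs)
    latent = mu + rng.normal(0.0, config.noise_sd, size=config.n)
    if config.censor:
        latent = np.clip(latent, 0.0, 1.0)

    cl_noise = rng.normal(0.0, config.measurement_sd, size=config.n)
    sw_noise = rng.normal(0.0, config.measurement_sd, size=config.n)
    cantril = np.clip(np.round((latent + cl_noise) * 10.0), 0, 10).astype(int)
    swls = np.clip(np.round((latent + sw_noise) * 30.0 + 5.0), 5, 35).astype(int)

    out = pd.DataFrame({"id": np.arange(1, config.n + 1)})
    for j in range(5):
        out[f"dim{j + 1}"] = levels[:, j]
    out["cantril"] = cantril
    out["swls"] = swls
    out = pd.concat([out, ses_df], axis=1)
    return out[RESPONDENT_COLUMNS]


def write_fixture(records: pd.DataFrame, path) -> None:
    """Write a respondent table as comma-separated text with a header row."""
    if len(records) == 0:
        raise ValueError("refusing to write an empty respondent table")
    records.to_csv(path, index=False)
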