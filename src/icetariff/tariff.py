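"""Value-set (tariff) construction from fitted level coefficients.

The level coefficients of the valuation regression are disutilities relative
to full capability.  They become a 0–1 value set in three steps:

1. *Rescaling*: the five level-4 coefficients are summed and all level
   coefficients are multiplied by the factor that makes that sum −1, so the
   worst describable state (44444) sits a full unit below the best (11111).
2. *Reverse coding*: the reference is switched from the best level to the
   worst, turning disutilities into non-negative utility increments with
   state 44444 at 0 and 11111 at 1.
3. *Uncertainty*: standard errors of the rescaled disutilities come from a
   nonparametric bootstrap that redraws respondents with replacement and
   repeats the regression and rescaling steps.

The resulting experienced-utility tariff is compared entry-by-entry with the
published decision-utility weights, which are treated as fixed constants
(their sampling uncertainty is not published).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .instruments import InstrumentSpec, get_instrument
from .regression import (
    CoefficientSet,
    Constraint,
    DesignMatrix,
    EstimationError,
    LevelKey,
    ModelConfig,
    _parse_profile,
    build_design,
    fit_tobit,
    level_column,
)

logger = logging.getLogger("icetariff")


@dataclass
class DisutilityTable:
    """Rescaled per-level disutilities on the 0–1 scale (level 1 ↦ 0)."""

    instrument: str
    dimensions: tuple[str, ...]
    values: dict[LevelKey, float]
    scale_factor: float
    source_model: str
    se: dict[LevelKey, float] | None = None

    def value(self, dimension: str, level: int) -> float:
        return self.values[(dimension, level)]

    def level4_sum(self) -> float:
        return sum(self.values[(d, 4)] for d in self.dimensions)


@dataclass
class Tariff:
    """A value set: per (dimension, level) utility increments.

    For experienced-utility tariffs derived here, level 4 carries 0 in every
    dimension and the level-1 increments sum to 1.  Published decision-utility
    tariffs keep their printed (occasionally negative) level-4 values.
    """

    instrument: str
    dimensions: tuple[str, ...]
    utilities: dict[LevelKey, float]
    provenance: str  # "experienced" | "decision"
    se: dict[LevelKey, float] | None = None

    def utility(self, dimension: str, level: int) -> float:
        return self.utilities[(dimension, level)]

    def score(self, profile) -> float:
        return score_profile(self, profile)

    def to_dict(self) -> dict:
        d = {
            "instrument": self.instrument,
            "provenance": self.provenance,
            "utilities": {
                dim: [self.utilities[(dim, l)] for l in range(1, 5)]
                for dim in self.dimensions
            },
        }
        if self.se is not None:
            d["se"] = {
                dim: [self.se.get((dim, l), 0.0) for l in range(1, 5)]
                for dim in self.dimensions
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Tariff":
        dims = tuple(d["utilities"].keys())
        utilities = {
            (dim, l): float(v)
            for dim, vals in d["utilities"].items()
            for l, v in zip(range(1, 5), vals)
        }
        se = None
        if d.get("se"):
            se = {
                (dim, l): float(v)
                for dim, vals in d["se"].items()
                for l, v in zip(range(1, 5), vals)
            }
        return cls(
            instrument=d["instrument"],
            dimensions=dims,
            utilities=utilities,
            provenance=d.get("provenance", "experienced"),
            se=se,
        )


@dataclass
class ComparisonRow:
    """Experienced vs. decision disutility for one (dimension, level)."""

    dimension: str
    level: int
    eu_value: float
    du_value: float
    difference: float
    t_stat: float
    p_value: float


@dataclass
class BootstrapResult:
    """Replicate draws and SD-based standard errors from the bootstrap."""

    replications: int
    seed: int | None
    draws: dict[LevelKey, np.ndarray]       # rescaled disutilities per replicate
    ses: dict[LevelKey, float]              # SD of the rescaled draws
    coef_draws: dict[LevelKey, np.ndarray]  # raw (unrescaled) coefficients
    coef_ses: dict[LevelKey, float]
    n_redrawn: int = 0


# ---------------------------------------------------------------------------
# Rescaling and reverse coding
# ---------------------------------------------------------------------------

def rescale_disutilities(coefs: CoefficientSet) -> DisutilityTable:
    """Linearly extend the level coefficients so the level-4 sum is −1.

    The multiplier 1 / |Σ_d β_{d,4}| anchors the worst describable state a
    full unit below the best; level-1 entries are 0 by reference coding.
    """
    dims = tuple(dict.fromkeys(d for d, _ in coefs.level_disutilities))
    if len(dims) != 5 or len(coefs.level_disutilities) != 15:
        raise ValueError("coefficient set must contain all 15 level coefficients")
    total4 = sum(coefs.level_disutilities[(d, 4)] for d in dims)
    if total4 == 0:
        raise ValueError("level-4 coefficients sum to zero; scale undefined")
    factor = 1.0 / abs(total4)
    values: dict[LevelKey, float] = {}
    for d in dims:
        values[(d, 1)] = 0.0
        for l in (2, 3, 4):
            values[(d, l)] = coefs.level_disutilities[(d, l)] * factor
    return DisutilityTable(
        instrument=coefs.instrument,
        dimensions=dims,
        values=values,
        scale_factor=factor,
        source_model=coefs.model_tag,
    )


def reverse_code(dis: DisutilityTable, provenance: str = "experienced") -> Tariff:
    """Switch the reference from the best to the worst level.

    utilities(d, l) = |dis(d, 4)| − |dis(d, l)|, so each dimension's level 4
    carries 0 and level 1 carries the dimension's full weight.
    """
    utilities: dict[LevelKey, float] = {}
    for d in dis.dimensions:
        worst = abs(dis.values[(d, 4)])
        for l in range(1, 5):
            utilities[(d, l)] = worst - abs(dis.values[(d, l)])
    se = None
    if dis.se is not None:
        se = {k: dis.se.get(k, 0.0) for k in utilities}
    return Tariff(
        instrument=dis.instrument,
        dimensions=dis.dimensions,
        utilities=utilities,
        provenance=provenance,
        se=se,
    )


def score_profile(tariff: Tariff, profile) -> float:
    """Index value of a capability profile: sum of its level utilities.

    ``profile`` may be a 5-character string ("33333") or five integers,
    ordered as the tariff's dimensions.
    """
    levels = _parse_profile(profile)
    return sum(
        tariff.utilities[(dim, lev)] for dim, lev in zip(tariff.dimensions, levels)
    )


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def _fast_refit(
    X: np.ndarray,
    y: np.ndarray,
    columns: list[str],
    constraints: list[Constraint],
) -> np.ndarray:
    """Point estimates only: OLS, or restricted LS via substitution."""
    if not constraints:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return beta
    idx = {c: j for j, c in enumerate(columns)}
    fixed = {idx[level_column(d, l)]: v for d, l, v in constraints}
    free = [j for j in range(X.shape[1]) if j not in fixed]
    y_adj = y - sum(v * X[:, j] for j, v in fixed.items())
    beta_free, *_ = np.linalg.lstsq(X[:, free], y_adj, rcond=None)
    beta = np.empty(X.shape[1])
    beta[free] = beta_free
    for j, v in fixed.items():
        beta[j] = v
    return beta


def bootstrap_tariff(
    records,
    spec: InstrumentSpec | str,
    model_config: ModelConfig | None = None,
    B: int = 500,
    seed: int | None = None,
    design: DesignMatrix | None = None,
) -> BootstrapResult:
    """Bootstrap SEs for the rescaled disutilities.

    Respondent rows are redrawn with replacement B times; each replicate
    repeats the regression (re-imposing any constraints) and the rescaling
    step.  The SE of each (dimension, level) entry is the standard deviation
    of its replicate values.  Rank-deficient replicates are redrawn (an
    error is raised if more than 10% of draws must be discarded).
    """
    if B < 2:
        raise ValueError("bootstrap needs B >= 2 replications")
    spec = get_instrument(spec)
    model_config = model_config or ModelConfig()
    if design is None:
        design = build_design(
            records,
            spec,
            include_ses=(model_config.model == "full"),
            include_worst_dummy=model_config.include_worst_dummy,
            swb_source=model_config.swb_source,
        )
    X = design.X.to_numpy()
    y = design.y.to_numpy()
    columns = list(design.X.columns)
    n, p = X.shape
    level_keys = design.level_keys()
    col_idx = {k: columns.index(level_column(*k)) for k in level_keys}
    idx4 = [col_idx[(d, 4)] for d in spec.dimensions]
    constraints = list(model_config.constraints)

    rng = np.random.default_rng(seed)
    draws = {k: np.empty(B) for k in level_keys}
    coef_draws = {k: np.empty(B) for k in level_keys}
    n_redrawn = 0
    b = 0
    max_redraws = max(1, int(0.1 * B))
    use_tobit = model_config.estimator == "tobit"
    while b < B:
        rows = rng.integers(0, n, size=n)
        Xb, yb = X[rows], y[rows]
        if np.linalg.matrix_rank(Xb) < p:
            n_redrawn += 1
            if n_redrawn > max_redraws:
                raise EstimationError(
                    f"more than 10% of bootstrap replicates rank deficient "
                    f"({n_redrawn} redraws at replicate {b})"
                )
            continue
        if use_tobit:
            import pandas as pd

            dm = DesignMatrix(
                X=pd.DataFrame(Xb, columns=columns),
                y=pd.Series(yb, name="swb"),
                spec=spec,
                include_ses=design.include_ses,
                include_worst_dummy=design.include_worst_dummy,
            )
            beta_set = fit_tobit(dm)
            beta = np.empty(p)
            for j, c in enumerate(columns):
                if c == "const":
                    beta[j] = beta_set.intercept
                else:
                    key = next((k for k in level_keys if level_column(*k) == c), None)
                    beta[j] = (
                        beta_set.level_disutilities[key]
                        if key is not None
                        else beta_set.ses_effects[c]
                    )
        else:
            beta = _fast_refit(Xb, yb, columns, constraints)
        total4 = beta[idx4].sum()
        if total4 == 0:
            n_redrawn += 1
            if n_redrawn > max_redraws:
                raise EstimationError("degenerate replicates: zero level-4 sum")
            continue
        factor = 1.0 / abs(total4)
        for k in level_keys:
            coef_draws[k][b] = beta[col_idx[k]]
            draws[k][b] = beta[col_idx[k]] * factor
        b += 1
    if n_redrawn:
        logger.info("redrew %d rank-deficient bootstrap replicates", n_redrawn)

    ses = {k: float(np.std(v, ddof=1)) for k, v in draws.items()}
    coef_ses = {k: float(np.std(v, ddof=1)) for k, v in coef_draws.items()}
    return BootstrapResult(
        replications=B,
        seed=seed,
        draws=draws,
        ses=ses,
        coef_draws=coef_draws,
        coef_ses=coef_ses,
        n_redrawn=n_redrawn,
    )


def percentile_interval(
    boot: BootstrapResult, key: LevelKey, level: float = 0.95
) -> tuple[float, float]:
    """Percentile bootstrap interval for one rescaled disutility entry."""
    a = (1.0 - level) / 2.0
    lo, hi = np.quantile(boot.draws[key], [a, 1.0 - a])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# Comparison with decision-utility weights
# ---------------------------------------------------------------------------

def compare_tariffs(
    eu: DisutilityTable,
    du_reference: DisutilityTable,
    boot: BootstrapResult,
) -> list[ComparisonRow]:
    """Entry-wise t-tests of experienced vs. decision disutilities.

    The decision-utility values are treated as fixed constants; the test
    statistic is (eu − du) / bootstrap SE against a standard normal.
    """
    if eu.instrument != du_reference.instrument:
        raise ValueError(
            f"instrument mismatch: {eu.instrument} vs {du_reference.instrument}"
        )
    rows: list[ComparisonRow] = []
    for d in eu.dimensions:
        for l in (2, 3, 4):
            e = eu.values[(d, l)]
            u = du_reference.values[(d, l)]
            diff = e - u
            se = boot.ses[(d, l)]
            if se == 0.0:
                if diff != 0.0:
                    warnings.warn(
                        f"zero bootstrap SE with nonzero difference at "
                        f"({d}, {l}); p reported as 0",
                        stacklevel=2,
                    )
                    t, pval = np.inf * np.sign(diff), 0.0
                else:
                    t, pval = 0.0, 1.0
            else:
                t = diff / se
                pval = 2.0 * stats.norm.sf(abs(t))
            rows.append(ComparisonRow(d, l, e, u, diff, float(t), float(pval)))
    return rows
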