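"""Readers/writers, run configuration and the end-to-end pipeline.

The analysis of both instruments follows one protocol: compute the composite
SWB index, fit the reduced and full regressions, check the level coefficients
for illogical orderings (applying a fixed-value constraint when configured),
rescale and reverse-code into an experienced-utility tariff, bootstrap its
standard errors, and compare the rescaled disutilities against the published
decision-utility weights.  Every run writes a machine-readable manifest
(config, seed, software versions) sufficient to reproduce it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import swb
from .instruments import FINANCE_CATEGORIES, InstrumentSpec, get_instrument
from .regression import (
    CoefficientSet,
    Constraint,
    ModelConfig,
    Violation,
    build_design,
    check_monotonicity,
    constraints_for_violations,
    fit_constrained_ols,
    fit_ols,
    fit_tobit,
)
from .synthetic import RESPONDENT_COLUMNS
from .tariff import (
    BootstrapResult,
    ComparisonRow,
    DisutilityTable,
    Tariff,
    bootstrap_tariff,
    compare_tariffs,
    rescale_disutilities,
    reverse_code,
    score_profile,
)

logger = logging.getLogger("icetariff")


class SchemaError(ValueError):
    """Respondent table does not match the expected schema."""


def read_respondents(path, spec: InstrumentSpec | str | None = None) -> pd.DataFrame:
    """Read and validate a respondent table (CSV with header).

    Malformed rows (capability level outside 1–4, Cantril outside 0–10,
    SWLS outside 5–35, unknown finance category) are rejected with a message
    naming the file line and field.  Rows with missing fields are kept and
    counted; the regression stage drops them (complete-case analysis).
    """
    df = pd.read_csv(path)
    missing = [c for c in RESPONDENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    problems: list[str] = []

    def _flag(mask: pd.Series, fieldname: str, why: str) -> None:
        for i in df.index[mask]:
            problems.append(f"line {i + 2}: {fieldname} {why} (value {df.at[i, fieldname]!r})")

    for col in ("dim1", "dim2", "dim3", "dim4", "dim5"):
        _flag(df[col].notna() & ~df[col].isin([1, 2, 3, 4]), col, "not a level in 1..4")
    _flag(df["cantril"].notna() & ~df["cantril"].between(0, 10), "cantril", "outside [0, 10]")
    _flag(df["swls"].notna() & ~df["swls"].between(5, 35), "swls", "outside [5, 35]")
    _flag(
        df["finance_cat"].notna() & ~df["finance_cat"].astype(str).isin(FINANCE_CATEGORIES),
        "finance_cat",
        f"not one of {FINANCE_CATEGORIES}",
    )
    if problems:
        raise SchemaError(f"{path}: {len(problems)} malformed row(s):\n" + "\n".join(problems))
    n_incomplete = int(df[RESPONDENT_COLUMNS].isna().any(axis=1).sum())
    if n_incomplete:
        logger.info("%s: %d incomplete rows (dropped at the regression stage)", path, n_incomplete)
    return df


# ---------------------------------------------------------------------------
# Run configuration and pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Configuration of one end-to-end valuation run."""

    instrument: str = "ICECAP-O"
    swb_source: str = "composite"
    model: str = "full"
    estimator: str = "constrained"
    constraints: list[Constraint] = field(default_factory=list)
    include_worst_dummy: bool = False
    bootstrap_b: int = 500
    seed: int | None = None
    input_path: str | None = None
    output_dir: str | None = None
    du_tariff: str = "packaged"

    def __post_init__(self) -> None:
        get_instrument(self.instrument)
        if self.bootstrap_b is not None and self.bootstrap_b < 2:
            raise ValueError("bootstrap_b must be >= 2 (or None to skip)")

    def model_config(self) -> ModelConfig:
        return ModelConfig(
            model=self.model,
            estimator=self.estimator,
            constraints=list(self.constraints),
            swb_source=self.swb_source,
            include_worst_dummy=self.include_worst_dummy,
        )

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        doc = json.loads(Path(path).read_text())
        doc["constraints"] = [tuple(c) for c in doc.get("constraints", [])]
        return cls(**doc)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["constraints"] = [list(c) for c in self.constraints]
        return d


@dataclass
class RunResult:
    """Bundle of everything one pipeline run produces."""

    config: RunConfig
    descriptives: dict
    reduced: CoefficientSet
    full: CoefficientSet
    chosen: CoefficientSet
    violations: list[Violation]
    disutilities: DisutilityTable
    tariff: Tariff
    bootstrap: BootstrapResult | None
    comparison: list[ComparisonRow] | None


def _descriptives(df: pd.DataFrame, spec: InstrumentSpec) -> dict:
    df = swb.add_swb_columns(df)
    freqs = {}
    for i, dim in enumerate(spec.dimensions):
        counts = df[f"dim{i + 1}"].value_counts(normalize=True)
        freqs[dim] = [round(float(counts.get(l, 0.0)), 4) for l in range(1, 5)]
    return {
        "n": int(len(df)),
        "level_frequencies": freqs,
        "mean_cantril_01": round(float(df["cantril_01"].mean()), 4),
        "mean_swls_01": round(float(df["swls_01"].mean()), 4),
        "mean_composite_swb": round(float(df["swb_composite"].mean()), 4),
        "sd_composite_swb": round(float(df["swb_composite"].std(ddof=1)), 4),
    }


def coefficients_to_dict(c: CoefficientSet) -> dict:
    def key(k):
        return f"{k[0]}:{k[1]}" if isinstance(k, tuple) else k

    return {
        "instrument": c.instrument,
        "model_tag": c.model_tag,
        "n": c.n,
        "intercept": c.intercept,
        "level_disutilities": {key(k): v for k, v in c.level_disutilities.items()},
        "ses_effects": dict(c.ses_effects),
        "standard_errors": {key(k): v for k, v in c.standard_errors.items()},
        "r_squared": c.r_squared,
        "constraints": [list(x) for x in c.constraints],
        "sigma": c.sigma,
        "n_censored": c.n_censored,
    }


def coefficients_from_dict(d: dict) -> CoefficientSet:
    def key(k):
        if ":" in k:
            dim, l = k.split(":")
            return (dim, int(l))
        return k

    return CoefficientSet(
        instrument=d["instrument"],
        intercept=d["intercept"],
        level_disutilities={key(k): v for k, v in d["level_disutilities"].items()},
        ses_effects=dict(d["ses_effects"]),
        standard_errors={key(k): v for k, v in d["standard_errors"].items()},
        r_squared=d.get("r_squared"),
        n=d["n"],
        model_tag=d["model_tag"],
        constraints=[tuple(x) for x in d.get("constraints", [])],
        sigma=d.get("sigma"),
        n_censored=d.get("n_censored"),
    )


def run_pipeline(config: RunConfig, records: pd.DataFrame | None = None) -> RunResult:
    """Execute the full valuation protocol for one instrument sample."""
    spec = get_instrument(config.instrument)
    if records is None:
        if config.input_path is None:
            raise ValueError("config.input_path is required when no records are passed")
        records = read_respondents(config.input_path, spec)

    descriptives = _descriptives(records, spec)

    reduced_design = build_design(
        records, spec, include_ses=False,
        include_worst_dummy=config.include_worst_dummy, swb_source=config.swb_source,
    )
    full_design = build_design(
        records, spec, include_ses=True,
        include_worst_dummy=config.include_worst_dummy, swb_source=config.swb_source,
    )
    reduced = fit_ols(reduced_design, model_tag="reduced")
    full = fit_ols(full_design, model_tag="full")

    chosen_design = full_design if config.model == "full" else reduced_design
    base = full if config.model == "full" else reduced
    violations = check_monotonicity(base)

    mc = config.model_config()
    if config.estimator == "ols":
        chosen = base
    elif config.estimator == "tobit":
        chosen = fit_tobit(chosen_design)
    else:  # constrained
        constraints = list(config.constraints)
        if not constraints and violations:
            constraints = constraints_for_violations(base, violations, policy="zero")
            logger.info("auto-derived constraints from violations: %s", constraints)
        mc = ModelConfig(
            model=config.model, estimator="constrained", constraints=constraints,
            swb_source=config.swb_source, include_worst_dummy=config.include_worst_dummy,
        )
        chosen = fit_constrained_ols(chosen_design, constraints)

    dis = rescale_disutilities(chosen)
    boot = None
    comparison = None
    if config.bootstrap_b:
        boot = bootstrap_tariff(
            records, spec, mc, B=config.bootstrap_b, seed=config.seed,
            design=chosen_design,
        )
        dis.se = dict(boot.ses)
        du = _load_du_disutilities(config, spec)
        comparison = compare_tariffs(dis, du, boot)
    eu_tariff = reverse_code(dis)

    result = RunResult(
        config=config,
        descriptives=descriptives,
        reduced=reduced,
        full=full,
        chosen=chosen,
        violations=violations,
        disutilities=dis,
        tariff=eu_tariff,
        bootstrap=boot,
        comparison=comparison,
    )
    if config.output_dir:
        _write_outputs(result, Path(config.output_dir))
    return result


def _load_du_disutilities(config: RunConfig, spec: InstrumentSpec) -> DisutilityTable:
    from .published import published_disutilities

    if config.du_tariff == "packaged":
        return published_disutilities(spec, "du")
    doc = json.loads(Path(config.du_tariff).read_text())
    values = {}
    for dim, vals in doc["values"].items():
        values[(dim, 1)] = 0.0
        for l, v in zip((2, 3, 4), vals):
            values[(dim, l)] = float(v)
    return DisutilityTable(
        instrument=doc.get("instrument", spec.name),
        dimensions=spec.dimensions,
        values=values,
        scale_factor=float("nan"),
        source_model="file-du",
    )


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _write_outputs(result: RunResult, outdir: Path) -> None:
    import scipy
    import statsmodels

    outdir.mkdir(parents=True, exist_ok=True)
    _json_dump(result.descriptives, outdir / "descriptives.json")
    _json_dump(
        {
            "reduced": coefficients_to_dict(result.reduced),
            "full": coefficients_to_dict(result.full),
            "chosen": coefficients_to_dict(result.chosen),
            "violations": [dataclasses.asdict(v) for v in result.violations],
        },
        outdir / "coefficients.json",
    )
    _json_dump(result.tariff.to_dict(), outdir / "tariff.json")
    tariff_table(result.tariff).to_csv(outdir / "tariff_display.csv", index=False)
    if result.comparison is not None:
        pd.DataFrame([dataclasses.asdict(r) for r in result.comparison]).to_csv(
            outdir / "comparison.csv", index=False
        )
    manifest = {
        "config": result.config.to_dict(),
        "seed": result.config.seed,
        "versions": {
            "icetariff": _package_version(),
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "statsmodels": statsmodels.__version__,
        },
    }
    _json_dump(manifest, outdir / "manifest.json")


def _package_version() -> str:
    from importlib.metadata import PackageNotFoundError, version

    try:
        return version("icetariff")
    except PackageNotFoundError:
        return "unknown"


def tariff_table(tariff: Tariff, decimals: int = 3) -> pd.DataFrame:
    """Tariff as a two-column display table (entry label, rounded utility)."""
    rows = [
        {
            "state": f"{dim.capitalize()} {l}",
            "utility": round(tariff.utilities[(dim, l)], decimals),
        }
        for dim in tariff.dimensions
        for l in range(1, 5)
    ]
    return pd.DataFrame(rows)


def score_command(
    tariff: Tariff | str,
    profiles: list[str],
    pairwise: bool = False,
) -> pd.DataFrame:
    """Score capability profiles with a tariff.

    With ``pairwise`` and exactly two profiles, the gain (second minus
    first score) is appended as an extra row.
    """
    if not isinstance(tariff, Tariff):
        tariff = Tariff.from_dict(json.loads(Path(tariff).read_text()))
    rows = [
        {"profile": p, "utility": score_profile(tariff, p)} for p in profiles
    ]
    if pairwise:
        if len(profiles) != 2:
            raise ValueError("pairwise gain needs exactly two profiles")
        rows.append(
            {
                "profile": f"{profiles[0]}->{profiles[1]}",
                "utility": rows[1]["utility"] - rows[0]["utility"],
            }
        )
    return pd.DataFrame(rows)
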