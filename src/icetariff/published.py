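"""Loaders for the packaged published value sets and regression tables.

The package ships, as plain JSON data, the published regression coefficient
columns for both instruments (reduced, full and — for ICECAP-O — the
constrained model), the published experienced- and decision-utility tariffs,
and the rescaled disutility columns used for the tariff comparison.  These
constants allow scoring and comparison without refitting anything, and give
the tests regression-free reference values.
"""

from __future__ import annotations

import json
from importlib import resources

from .instruments import get_instrument
from .regression import CoefficientSet, LevelKey
from .tariff import DisutilityTable, Tariff

_FILES = {
    "ICECAP-O": "icecap_o_coefficients.json",
    "ICECAP-A": "icecap_a_coefficients.json",
}


def _load_json(name: str) -> dict:
    with resources.files("icetariff.data").joinpath(name).open() as fh:
        return json.load(fh)


def published_coefficients(instrument, model: str = "full") -> CoefficientSet:
    """Published coefficient column for an instrument and model.

    ``model`` is "reduced", "full" or (ICECAP-O only) "constrained".
    Standard errors are the printed ones; R² is absent for the constrained
    column as published.
    """
    spec = get_instrument(instrument)
    doc = _load_json(_FILES[spec.name])
    try:
        m = doc["models"][model]
    except KeyError:
        raise ValueError(
            f"no published {model!r} model for {spec.name}; "
            f"available: {sorted(doc['models'])}"
        ) from None
    levels: dict[LevelKey, float] = {}
    errs: dict[object, float] = {"const": m["intercept"][1]}
    for dim, entries in m["levels"].items():
        for l_str, (coef, se) in entries.items():
            levels[(dim, int(l_str))] = coef
            errs[(dim, int(l_str))] = se
    ses = {}
    for name, (coef, se) in m["ses"].items():
        ses[name] = coef
        errs[name] = se
    return CoefficientSet(
        instrument=spec.name,
        intercept=m["intercept"][0],
        level_disutilities=levels,
        ses_effects=ses,
        standard_errors=errs,
        r_squared=m["r_squared"],
        n=doc["n"],
        model_tag=model,
        constraints=[tuple(c) for c in m["constraints"]],
    )


def published_tariff(instrument, provenance: str = "experienced") -> Tariff:
    """Published value set ("experienced" or "decision") for an instrument."""
    spec = get_instrument(instrument)
    key = {"experienced": "eu", "decision": "du"}.get(provenance, provenance)
    if key not in ("eu", "du"):
        raise ValueError(f"provenance must be 'experienced' or 'decision', got {provenance!r}")
    doc = _load_json("published_tariffs.json")[spec.name][key]
    utilities = {
        (dim, l): float(v)
        for dim, vals in doc.items()
        for l, v in zip(range(1, 5), vals)
    }
    return Tariff(
        instrument=spec.name,
        dimensions=spec.dimensions,
        utilities=utilities,
        provenance="experienced" if key == "eu" else "decision",
    )


def published_disutilities(instrument, source: str = "du") -> DisutilityTable:
    """Published rescaled disutility column (levels 2–4; level 1 carries 0).

    ``source`` "eu" gives the experienced-utility column, "du" the
    decision-utility weights with the reference category reversed to level 1
    — the fixed constants against which the derived values are tested.
    """
    spec = get_instrument(instrument)
    if source not in ("eu", "du"):
        raise ValueError(f"source must be 'eu' or 'du', got {source!r}")
    doc = _load_json("published_disutilities.json")[spec.name][source]
    values: dict[LevelKey, float] = {}
    for dim, vals in doc.items():
        values[(dim, 1)] = 0.0
        for l, v in zip((2, 3, 4), vals):
            values[(dim, l)] = float(v)
    return DisutilityTable(
        instrument=spec.name,
        dimensions=spec.dimensions,
        values=values,
        scale_factor=float("nan"),
        source_model=f"published-{source}",
    )
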