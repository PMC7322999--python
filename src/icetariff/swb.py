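"""Composite subjective well-being (SWB) index.

Cantril's ladder (CL, integer 0–10) and the Satisfaction with Life Scale
total (SWLS, integer 5–35) are each min–max rescaled over their theoretical
ranges to the unit interval, and the composite SWB index is their unweighted
average:

    SWB_i = (SWLS01_i + CL01_i) / 2

The composite serves as the response variable of the valuation regressions;
single-measure responses (CL only, SWLS only) are supported for sensitivity
analyses.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

CANTRIL_MIN, CANTRIL_MAX = 0, 10
SWLS_MIN, SWLS_MAX = 5, 35

#: Valid response-variable choices for the regression stage.
SWB_SOURCES = ("composite", "cantril_only", "swls_only")


def rescale_cantril(raw):
    """Map a Cantril's ladder score (0–10) onto [0, 1].

    Accepts a scalar or array-like; raises ``ValueError`` outside the scale.
    """
    arr = np.asarray(raw, dtype=float)
    if np.any((arr < CANTRIL_MIN) | (arr > CANTRIL_MAX)) or np.any(np.isnan(arr)):
        raise ValueError(f"Cantril's ladder score outside [{CANTRIL_MIN}, {CANTRIL_MAX}]")
    out = arr / CANTRIL_MAX
    return out.item() if np.isscalar(raw) or arr.ndim == 0 else out


def rescale_swls(raw):
    """Map an SWLS total (5–35) onto [0, 1] via (raw − 5) / 30."""
    arr = np.asarray(raw, dtype=float)
    if np.any((arr < SWLS_MIN) | (arr > SWLS_MAX)) or np.any(np.isnan(arr)):
        raise ValueError(f"SWLS total outside [{SWLS_MIN}, {SWLS_MAX}]")
    out = (arr - SWLS_MIN) / (SWLS_MAX - SWLS_MIN)
    return out.item() if np.isscalar(raw) or arr.ndim == 0 else out


def composite_swb(cantril_01, swls_01):
    """Unweighted average of the two unit-rescaled well-being measures."""
    c = np.asarray(cantril_01, dtype=float)
    s = np.asarray(swls_01, dtype=float)
    for name, a in (("cantril_01", c), ("swls_01", s)):
        if np.any((a < 0) | (a > 1)) or np.any(np.isnan(a)):
            raise ValueError(f"{name} outside [0, 1]")
    out = (c + s) / 2.0
    scalar = (np.isscalar(cantril_01) or c.ndim == 0) and (
        np.isscalar(swls_01) or s.ndim == 0
    )
    return out.item() if scalar else out


def add_swb_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of a respondent table with cantril_01 / swls_01 /
    swb_composite columns derived from the raw ``cantril`` and ``swls``
    columns."""
    out = df.copy()
    out["cantril_01"] = rescale_cantril(df["cantril"].to_numpy())
    out["swls_01"] = rescale_swls(df["swls"].to_numpy())
    out["swb_composite"] = composite_swb(
        out["cantril_01"].to_numpy(), out["swls_01"].to_numpy()
    )
    return out


def swb_response(df: pd.DataFrame, source: str = "composite") -> pd.Series:
    """Response vector for the valuation regression.

    ``source`` selects the composite index (default) or one of the single
    measures for sensitivity runs.
    """
    if source not in SWB_SOURCES:
        raise ValueError(f"swb_source must be one of {SWB_SOURCES}, got {source!r}")
    if not {"cantril_01", "swls_01", "swb_composite"} <= set(df.columns):
        df = add_swb_columns(df)
    col = {
        "composite": "swb_composite",
        "cantril_only": "cantril_01",
        "swls_only": "swls_01",
    }[source]
    return df[col].rename("swb")
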