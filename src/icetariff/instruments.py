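"""Descriptive systems of the ICECAP-O and ICECAP-A capability instruments.

Both instruments describe well-being with five dimensions, each measured on
four levels where level 1 is full capability and level 4 is no capability.
The regression models use level 1 as the reference category, so every other
level carries a (negative) disutility coefficient relative to it.

The socio-economic (SES) control set is shared between the two instruments
except for the monetary covariate: household wealth (entered in millions of
pounds) for the older-people instrument, monthly household income (pounds)
for the adult instrument.
"""

from __future__ import annotations

from dataclasses import dataclass, field


#: Categories of the "making ends meet" financial-difficulty item, ordered
#: from worst to best.  The first category is the regression reference.
FINANCE_CATEGORIES = (
    "great_difficulty",
    "some_difficulty",
    "fairly_easy",
    "easy",
)

#: SES design-column names derived from the finance categories (reference
#: category "great_difficulty" omitted).
FINANCE_DUMMIES = ("fin_some_difficulty", "fin_fairly_easy", "fin_easy")

N_LEVELS = 4
REFERENCE_LEVEL = 1


@dataclass(frozen=True)
class InstrumentSpec:
    """Static description of one ICECAP instrument variant.

    Attributes
    ----------
    name:
        "ICECAP-O" or "ICECAP-A".
    dimensions:
        The five capability dimensions, in tariff-table order.
    money_covariate:
        Design-column name of the monetary SES covariate.
    money_scale:
        Divisor applied to the raw monetary value before it enters the
        design matrix (1e6 for wealth in pounds -> millions; 1 for monthly
        income in pounds).
    age_range:
        Inclusive (min, max) respondent age targeted by the instrument.
    """

    name: str
    dimensions: tuple[str, ...]
    money_covariate: str
    money_scale: float
    age_range: tuple[int, int]
    n_levels: int = N_LEVELS
    reference_level: int = REFERENCE_LEVEL

    def __post_init__(self) -> None:
        if len(self.dimensions) != 5:
            raise ValueError("an ICECAP instrument has exactly 5 dimensions")
        if self.n_levels != 4 or self.reference_level != 1:
            raise ValueError("ICECAP instruments use 4 levels with level 1 as reference")

    @property
    def ses_covariates(self) -> tuple[str, ...]:
        """Ordered SES design-column names (age entered as age and age²)."""
        return (
            "male",
            "age",
            "age_sq",
            "tertiary",
            "married",
            *FINANCE_DUMMIES,
            self.money_covariate,
        )

    def level_columns(self) -> list[tuple[str, int]]:
        """All 15 (dimension, level) dummy keys, levels 2..4 per dimension."""
        return [(d, l) for d in self.dimensions for l in range(2, self.n_levels + 1)]


ICECAP_O = InstrumentSpec(
    name="ICECAP-O",
    dimensions=("attachment", "security", "role", "enjoyment", "control"),
    money_covariate="wealth_millions",
    money_scale=1e6,
    age_range=(70, 100),
)

ICECAP_A = InstrumentSpec(
    name="ICECAP-A",
    dimensions=("stability", "attachment", "autonomy", "achievement", "enjoyment"),
    money_covariate="income_month",
    money_scale=1.0,
    age_range=(18, 65),
)

_BY_NAME = {
    "ICECAP-O": ICECAP_O,
    "ICECAP-A": ICECAP_A,
    "icecap-o": ICECAP_O,
    "icecap-a": ICECAP_A,
    "O": ICECAP_O,
    "A": ICECAP_A,
}


def get_instrument(name: str | InstrumentSpec) -> InstrumentSpec:
    """Resolve an instrument spec from its name (case-insensitive)."""
    if isinstance(name, InstrumentSpec):
        return name
    try:
        return _BY_NAME[name] if name in _BY_NAME else _BY_NAME[name.upper()]
    except (KeyError, AttributeError):
        raise ValueError(
            f"unknown instrument {name!r}; expected 'ICECAP-O' or 'ICECAP-A'"
        ) from None
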