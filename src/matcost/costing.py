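"""Transfer pricing and the annual cost equation (Steps 4-6).

The annual program cost is

    ML_y = CT * IC_y * (alpha * Pop_y) + AdmCost_y

where ``CT`` is the weekly cash-transfer unit cost derived from a welfare
measure (statutory minimum wage, or the World Bank income poverty line,
optionally doubled), ``IC_y`` the number of weeks covered, ``alpha * Pop_y``
the eligible population, and ``AdmCost_y`` the administrative cost of
operating the program, modelled as a fixed fraction of the transfer outlay
(5.6% Brazil, 5.8% Ghana). The fixed-fraction reading is the only one
consistent with the published per-woman figures (58.3 x 12 x 1.056 -> 739);
a lump-sum administrative cost is also accepted for future configurations.

Money is carried as :class:`decimal.Decimal` throughout; display rounding
is half-up to whole units for totals and per-woman values, one decimal for
weekly amounts. USD and PPP$ are parallel labelled columns — no currency
conversion is ever computed, both weekly amounts are inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from numbers import Real
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .schema import ConfigurationError, CountrySchema, load_reference_config

__all__ = [
    "WelfareMeasure",
    "WeeklyTransfer",
    "Scenario",
    "CostResult",
    "weekly_ct",
    "cost_scenario",
    "scenario_grid",
    "gdp_share",
    "reference_measures",
    "reference_eligible",
    "reference_gdp",
    "MEASURE_ORDER",
    "round_money",
]

MoneyLike = Union[Decimal, int, float, str]

#: Canonical row order of the published cost grid.
MEASURE_ORDER = ("minimum_wage", "poverty_line", "twice_poverty_line")

_MEASURE_TITLES = {
    "minimum_wage": "Minimum wage",
    "poverty_line": "Poverty line",
    "twice_poverty_line": "Twice the poverty line",
}


def _dec(x: MoneyLike, what: str = "value") -> Decimal:
    if isinstance(x, Decimal):
        return x
    if isinstance(x, (int, str)):
        return Decimal(x)
    if isinstance(x, float):
        # via repr: 0.056 -> Decimal("0.056"), not the binary expansion
        return Decimal(repr(x))
    raise TypeError(f"cannot interpret {what} {x!r} as money")


def round_money(x: Decimal, places: int = 0) -> Decimal:
    """Half-up display rounding."""
    q = Decimal(1).scaleb(-places)
    return x.quantize(q, rounding=ROUND_HALF_UP)


@dataclass(frozen=True)
class WelfareMeasure:
    """A welfare benchmark pricing the weekly transfer.

    Either ``override_weekly`` is given (the final weekly amount for this
    measure's multiplier — the multiplier is *not* re-applied), or the
    weekly amount is derived from ``base_value`` per ``base_period`` and
    multiplied by ``multiplier``.
    """

    kind: str  # minimum_wage | poverty_line
    currency_base: str  # USD | PPP
    multiplier: Decimal = Decimal(1)
    base_value: Optional[Decimal] = None
    base_period: str = "per_week"  # per_day | per_week | per_month
    override_weekly: Optional[Decimal] = None
    label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "multiplier", _dec(self.multiplier, "multiplier"))
        if self.base_value is not None:
            object.__setattr__(self, "base_value", _dec(self.base_value, "base_value"))
        if self.override_weekly is not None:
            object.__setattr__(
                self, "override_weekly", _dec(self.override_weekly, "override_weekly")
            )
        if self.multiplier <= 0:
            raise ConfigurationError("multiplier must be positive")
        if not self.label:
            object.__setattr__(self, "label", self.kind)


@dataclass(frozen=True)
class WeeklyTransfer:
    """The weekly cash-transfer unit cost CT."""

    amount: Decimal
    provenance: str  # derived | override
    currency_base: str


@dataclass(frozen=True)
class Scenario:
    """One costing scenario: weeks covered, coverage and eligible count."""

    weeks: int
    eligible: Decimal
    admin_rate: Decimal
    coverage: Decimal = Decimal(1)
    admin_lump_sum: Optional[Decimal] = None  # replaces the fractional loading if set
    currency_base: Optional[str] = None  # if set, must match the transfer's

    def __post_init__(self):
        object.__setattr__(self, "eligible", _dec(self.eligible, "eligible"))
        object.__setattr__(self, "admin_rate", _dec(self.admin_rate, "admin_rate"))
        object.__setattr__(self, "coverage", _dec(self.coverage, "coverage"))
        if self.weeks <= 0:
            raise ConfigurationError(f"weeks must be positive, got {self.weeks}")
        if not (0 < self.coverage <= 1):
            raise ConfigurationError(f"coverage must be in (0, 1], got {self.coverage}")
        if not (0 <= self.admin_rate < 1):
            raise ConfigurationError(f"admin_rate must be in [0, 1), got {self.admin_rate}")


@dataclass(frozen=True)
class CostResult:
    """Annual cost of one scenario, all in one currency base."""

    transfer_cost: Decimal  # money/year
    admin_cost: Decimal  # money/year
    total: Decimal  # money/year, = transfer_cost + admin_cost
    per_woman: Decimal  # money/woman/year
    eligible_used: Decimal  # persons (fractional)
    currency_base: str


def weekly_ct(measure: WelfareMeasure) -> WeeklyTransfer:
    """Step 4: weekly transfer amount from a welfare measure.

    Derivation: per-day bases x 7, per-month bases x 12/52, per-week bases
    as-is, then x multiplier. A configured override is the final weekly
    amount and takes precedence.
    """
    if measure.override_weekly is not None:
        if measure.override_weekly <= 0:
            raise ConfigurationError("weekly transfer override must be positive")
        return WeeklyTransfer(
            amount=measure.override_weekly,
            provenance="override",
            currency_base=measure.currency_base,
        )
    if measure.base_value is None or measure.base_value <= 0:
        raise ConfigurationError("welfare measure needs a positive base value or an override")
    if measure.base_period == "per_day":
        weekly = measure.base_value * 7
    elif measure.base_period == "per_week":
        weekly = measure.base_value
    elif measure.base_period == "per_month":
        weekly = measure.base_value * 12 / 52
    else:
        raise ConfigurationError(f"unknown base period {measure.base_period!r}")
    return WeeklyTransfer(
        amount=weekly * measure.multiplier,
        provenance="derived",
        currency_base=measure.currency_base,
    )


def cost_scenario(scenario: Scenario, ct: WeeklyTransfer) -> CostResult:
    """Steps 5-6: annual cost of one scenario.

    transfer_cost = CT x weeks x coverage x eligible;
    admin_cost = admin_rate x transfer_cost (or the configured lump sum);
    per-woman cost is independent of the eligible count:
    CT x weeks x coverage x (1 + admin_rate).
    """
    if not isinstance(ct, WeeklyTransfer):
        raise TypeError("ct must be a WeeklyTransfer")
    if scenario.currency_base is not None and scenario.currency_base != ct.currency_base:
        raise ConfigurationError(
            f"currency-base mismatch: scenario {scenario.currency_base}, "
            f"transfer {ct.currency_base}"
        )
    if scenario.admin_lump_sum is not None and scenario.eligible == 0:
        raise ConfigurationError("lump-sum administrative cost needs a non-zero population")
    transfer = ct.amount * scenario.weeks * scenario.coverage * scenario.eligible
    if scenario.admin_lump_sum is not None:
        admin = _dec(scenario.admin_lump_sum, "admin_lump_sum")
    else:
        admin = scenario.admin_rate * transfer
    total = transfer + admin
    if scenario.eligible > 0:
        per_woman = total / scenario.eligible
    else:
        per_woman = Decimal(0)
    return CostResult(
        transfer_cost=transfer,
        admin_cost=admin,
        total=total,
        per_woman=per_woman,
        eligible_used=scenario.eligible,
        currency_base=ct.currency_base,
    )


def scenario_grid(
    schemas: Mapping[str, CountrySchema],
    measures: Mapping[str, Sequence[WelfareMeasure]],
    weeks_list: Sequence[int],
    eligibles: Mapping[str, MoneyLike],
    coverage: MoneyLike = 1,
) -> pd.DataFrame:
    """Full cost grid: one row per (weeks x measure x currency x country).

    Rows are ordered with weeks outermost, then measure (minimum wage,
    poverty line, twice the poverty line), then currency base, then
    country — the layout of the published grid. The ``total`` and
    ``per_woman`` columns keep full Decimal precision; ``total_rounded``
    and ``per_woman_rounded`` carry the half-up display values.
    """
    currencies: list[str] = []
    for ms in measures.values():
        for m in ms:
            if m.currency_base not in currencies:
                currencies.append(m.currency_base)
    rows = []
    for weeks in weeks_list:
        for m_label in MEASURE_ORDER:
            for currency in currencies:
                for country, schema in schemas.items():
                    hit = [
                        m
                        for m in measures[country]
                        if m.label == m_label and m.currency_base == currency
                    ]
                    if not hit:
                        continue
                    (m,) = hit
                    ct = weekly_ct(m)
                    scen = Scenario(
                        weeks=weeks,
                        eligible=_dec(eligibles[country], "eligible"),
                        admin_rate=_dec(schema.admin_rate, "admin_rate"),
                        coverage=_dec(coverage, "coverage"),
                    )
                    res = cost_scenario(scen, ct)
                    rows.append(
                        {
                            "country": country,
                            "weeks": weeks,
                            "measure": m_label,
                            "measure_title": _MEASURE_TITLES.get(m_label, m_label),
                            "currency": m.currency_base,
                            "weekly_ct": ct.amount,
                            "transfer_cost": res.transfer_cost,
                            "admin_cost": res.admin_cost,
                            "total": res.total,
                            "per_woman": res.per_woman,
                            "total_rounded": int(round_money(res.total)),
                            "per_woman_rounded": int(round_money(res.per_woman)),
                            "eligible": res.eligible_used,
                        }
                    )
    return pd.DataFrame(rows)


def gdp_share(result: CostResult, gdp: MoneyLike) -> Decimal:
    """Annual program cost as a percentage of GDP (same currency base)."""
    g = _dec(gdp, "gdp")
    if g <= 0:
        raise ConfigurationError(f"gdp must be positive, got {g}")
    return result.total / g * 100


# ---------------------------------------------------------------------------
# Reference constants (shipped configs)


def reference_measures(country: str) -> list[WelfareMeasure]:
    """The six shipped welfare measures (3 benchmarks x 2 currency bases)."""
    cfg = load_reference_config(country)
    out: list[WelfareMeasure] = []
    for label, m in cfg["welfare_measures"].items():
        base = m.get("base_value_per_day_ppp")
        for currency, weekly in m["override_weekly"].items():
            out.append(
                WelfareMeasure(
                    kind=m["kind"],
                    currency_base=currency,
                    multiplier=Decimal(str(m.get("multiplier", 1))),
                    base_value=Decimal(str(base)) if base is not None and currency == "PPP" else None,
                    base_period="per_day" if base is not None else "per_week",
                    override_weekly=Decimal(str(weekly)),
                    label=label,
                )
            )
    return out


def reference_eligible(country: str) -> Decimal:
    """Published count of eligible women for reference-constant runs."""
    return Decimal(load_reference_config(country)["eligible_women"])


def reference_gdp(country: str) -> Decimal:
    """GDP in PPP$ reconstructed as per-capita PPP x total population."""
    macro = load_reference_config(country)["macro"]
    return Decimal(macro["gdp_per_capita_ppp"]) * Decimal(macro["total_population"])
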