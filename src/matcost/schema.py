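"""Country-specific demographic stratification and informal-employment rules.

A costing run stratifies women of reproductive age (16-49 years) by age
group, marital status, educational level and locality, and classifies
employed women as formally or informally employed under a country-specific
rule. This module defines the schema describing those categories, the
enumeration of strata (the Cartesian product of the four category lists),
the mapping from an individual survey record to its stratum, and a small
registry of informal-employment rules so new countries can be added without
touching core code.

Two reference schemas ship with the package: ``brazil`` (180 strata, six
education levels, 5.6% administrative rate) and ``ghana`` (150 strata, five
education levels, 5.8% administrative rate).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, fields as dc_fields
from importlib import resources
from typing import Callable, Iterator, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ConfigurationError",
    "RecordRejected",
    "ClassificationError",
    "CountrySchema",
    "StratumKey",
    "WomanRecord",
    "available_countries",
    "load_reference_config",
    "build_reference_schema",
    "enumerate_strata",
    "stratum_of",
    "stratum_index",
    "assign_strata",
    "classify_informal",
    "classify_informal_frame",
    "register_informal_rule",
    "informal_rules",
]


class ConfigurationError(ValueError):
    """Raised for invalid schema or run configuration."""


class RecordRejected(ValueError):
    """A survey record cannot be mapped to a stratum.

    Carries a machine-readable ``reason`` code (``age_out_of_range``,
    ``unknown_category`` or ``missing_field``) for rejection reports.
    """

    def __init__(self, reason: str, message: str):
        self.reason = reason
        super().__init__(message)


class ClassificationError(ValueError):
    """An employment attribute required by the informal rule is missing."""

    def __init__(self, field_name: str, message: str | None = None):
        self.field_name = field_name
        super().__init__(message or f"missing employment attribute: {field_name!r}")


class StratumKey(NamedTuple):
    """Index of one demographic stratum within a :class:`CountrySchema`."""

    age_group: int
    marital_status: int
    education_level: int
    locality: int


@dataclass
class WomanRecord:
    """One woman-level survey row.

    Employment attribute fields (``formal_contract`` onwards) are only
    meaningful when ``employed`` is True; ``None`` marks a missing value.
    """

    age: int
    marital_status: str
    education_level: str
    locality: str
    employed: bool = False
    formal_contract: Optional[bool] = None
    ss_contribution: Optional[bool] = None
    occupation_class: Optional[str] = None
    benefit_maternity: Optional[bool] = None
    benefit_sick: Optional[bool] = None
    benefit_holiday: Optional[bool] = None
    contract_any: Optional[bool] = None
    gave_birth_12m: bool = False


#: Column order of the canonical microdata DataFrame.
RECORD_COLUMNS = tuple(f.name for f in dc_fields(WomanRecord))


@dataclass(frozen=True)
class CountrySchema:
    """Demographic stratification plus country constants.

    ``age_groups`` are closed integer intervals in completed years; they
    must be disjoint, ordered and jointly cover ``reproductive_age_range``
    exactly. ``admin_rate`` is the administrative loading applied to the
    annual transfer cost (a dimensionless fraction in [0, 1)).
    """

    name: str
    age_groups: tuple[tuple[int, int], ...]
    marital_statuses: tuple[str, ...]
    education_levels: tuple[str, ...]
    localities: tuple[str, ...]
    reproductive_age_range: tuple[int, int]
    informal_rule: str
    admin_rate: float
    currency_bases: tuple[str, ...] = ("USD", "PPP")

    def __post_init__(self):
        object.__setattr__(
            self, "age_groups", tuple((int(lo), int(hi)) for lo, hi in self.age_groups)
        )
        for attr in ("marital_statuses", "education_levels", "localities", "currency_bases"):
            object.__setattr__(self, attr, tuple(getattr(self, attr)))
        object.__setattr__(
            self, "reproductive_age_range", tuple(int(v) for v in self.reproductive_age_range)
        )
        self._validate()

    def _validate(self) -> None:
        lo, hi = self.reproductive_age_range
        if lo > hi:
            raise ConfigurationError(f"empty reproductive age range {lo}-{hi}")
        if not self.age_groups:
            raise ConfigurationError("age_groups must be non-empty")
        cursor = lo
        for a, b in self.age_groups:
            if a > b:
                raise ConfigurationError(f"age group {a}-{b} is empty")
            if a != cursor:
                raise ConfigurationError(
                    f"age groups must tile {lo}-{hi} without gaps or overlaps; "
                    f"expected group starting at {cursor}, got {a}"
                )
            cursor = b + 1
        if cursor != hi + 1:
            raise ConfigurationError(f"age groups stop at {cursor - 1}, range ends at {hi}")
        for attr in ("marital_statuses", "education_levels", "localities"):
            cats = getattr(self, attr)
            if not cats:
                raise ConfigurationError(f"{attr} must be non-empty")
            if len(set(cats)) != len(cats):
                raise ConfigurationError(f"{attr} has duplicate labels")
        if not (0.0 <= self.admin_rate < 1.0):
            raise ConfigurationError(f"admin_rate must be in [0, 1), got {self.admin_rate}")
        if self.informal_rule not in _INFORMAL_RULES:
            raise ConfigurationError(
                f"unknown informal rule {self.informal_rule!r}; "
                f"registered: {sorted(_INFORMAL_RULES)}"
            )

    # -- derived geometry ------------------------------------------------

    @property
    def dim_sizes(self) -> tuple[int, int, int, int]:
        return (
            len(self.age_groups),
            len(self.marital_statuses),
            len(self.education_levels),
            len(self.localities),
        )

    @property
    def n_strata(self) -> int:
        return math.prod(self.dim_sizes)

    @property
    def age_group_labels(self) -> tuple[str, ...]:
        return tuple(f"{lo}-{hi}" for lo, hi in self.age_groups)

    def age_group_index(self, age: int) -> int:
        lo, hi = self.reproductive_age_range
        if not (lo <= age <= hi):
            raise RecordRejected(
                "age_out_of_range", f"age {age} outside reproductive range {lo}-{hi}"
            )
        for i, (a, b) in enumerate(self.age_groups):
            if a <= age <= b:
                return i
        raise RecordRejected("age_out_of_range", f"age {age} not covered by any age group")

    def key_labels(self, key: StratumKey) -> tuple[str, str, str, str]:
        return (
            self.age_group_labels[key.age_group],
            self.marital_statuses[key.marital_status],
            self.education_levels[key.education_level],
            self.localities[key.locality],
        )

    # -- serialisation ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "age_groups": [list(g) for g in self.age_groups],
            "marital_statuses": list(self.marital_statuses),
            "education_levels": list(self.education_levels),
            "localities": list(self.localities),
            "reproductive_age_range": list(self.reproductive_age_range),
            "informal_rule": self.informal_rule,
            "admin_rate": self.admin_rate,
            "currency_bases": list(self.currency_bases),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CountrySchema":
        return cls(
            name=d["name"],
            age_groups=tuple(tuple(g) for g in d["age_groups"]),
            marital_statuses=tuple(d["marital_statuses"]),
            education_levels=tuple(d["education_levels"]),
            localities=tuple(d["localities"]),
            reproductive_age_range=tuple(d["reproductive_age_range"]),
            informal_rule=d["informal_rule"],
            admin_rate=float(d["admin_rate"]),
            currency_bases=tuple(d.get("currency_bases", ("USD", "PPP"))),
        )


# ---------------------------------------------------------------------------
# Reference configurations


def available_countries() -> tuple[str, ...]:
    return ("brazil", "ghana")


def load_reference_config(country: str) -> dict:
    """Load the shipped reference configuration (raw dict) for a country."""
    country = country.lower()
    if country not in available_countries():
        raise ConfigurationError(
            f"unknown country {country!r}; shipped references: {available_countries()}"
        )
    text = resources.files("matcost.data").joinpath(f"{country}.yaml").read_text()
    return yaml.safe_load(text)


def build_reference_schema(country: str) -> CountrySchema:
    """Return the shipped stratification schema for ``brazil`` or ``ghana``."""
    return CountrySchema.from_dict(load_reference_config(country))


# ---------------------------------------------------------------------------
# Strata


def enumerate_strata(schema: CountrySchema) -> list[StratumKey]:
    """All strata in deterministic nested order (age outermost, locality innermost)."""
    na, nm, ne, nl = schema.dim_sizes
    return [
        StratumKey(a, m, e, l)
        for a, m, e, l in itertools.product(range(na), range(nm), range(ne), range(nl))
    ]


def stratum_index(schema: CountrySchema, key: StratumKey) -> int:
    """Position of ``key`` in :func:`enumerate_strata` order."""
    na, nm, ne, nl = schema.dim_sizes
    a, m, e, l = key
    if not (0 <= a < na and 0 <= m < nm and 0 <= e < ne and 0 <= l < nl):
        raise ConfigurationError(f"stratum key {key} out of range for schema {schema.name!r}")
    return ((a * nm + m) * ne + e) * nl + l


def stratum_of(record: WomanRecord, schema: CountrySchema) -> StratumKey:
    """Map one record to its stratum; raises :class:`RecordRejected` otherwise."""
    for f in ("age", "marital_status", "education_level", "locality"):
        if getattr(record, f, None) is None:
            raise RecordRejected("missing_field", f"record missing {f!r}")
    a = schema.age_group_index(int(record.age))
    try:
        m = schema.marital_statuses.index(record.marital_status)
        e = schema.education_levels.index(record.education_level)
        l = schema.localities.index(record.locality)
    except ValueError as exc:
        raise RecordRejected("unknown_category", str(exc)) from None
    return StratumKey(a, m, e, l)


def assign_strata(df: pd.DataFrame, schema: CountrySchema) -> tuple[pd.Series, pd.DataFrame]:
    """Vectorised :func:`stratum_of` over a microdata frame.

    Returns ``(stratum_id, rejections)`` where ``stratum_id`` is an int64
    Series aligned with ``df`` holding the :func:`enumerate_strata` index of
    each accepted record and ``-1`` for rejected ones, and ``rejections``
    counts rejected records by reason code.
    """
    n = len(df)
    lo, hi = schema.reproductive_age_range
    age = pd.to_numeric(df["age"], errors="coerce")

    reasons = np.full(n, "", dtype=object)
    missing = age.isna().to_numpy()
    for col in ("marital_status", "education_level", "locality"):
        missing |= df[col].isna().to_numpy()
    reasons[missing] = "missing_field"

    out_of_range = (~missing) & ((age < lo) | (age > hi)).to_numpy()
    reasons[out_of_range] = "age_out_of_range"

    # age -> group index via interval edges (groups tile the range)
    edges = np.array([g[0] for g in schema.age_groups] + [schema.age_groups[-1][1] + 1])
    a_idx = np.searchsorted(edges, age.fillna(lo).to_numpy(), side="right") - 1

    def _codes(col: str, cats: Sequence[str]) -> np.ndarray:
        c = pd.Categorical(df[col], categories=list(cats)).codes.astype(np.int64)
        return c

    m_idx = _codes("marital_status", schema.marital_statuses)
    e_idx = _codes("education_level", schema.education_levels)
    l_idx = _codes("locality", schema.localities)

    unknown = (~missing) & (~out_of_range) & ((m_idx < 0) | (e_idx < 0) | (l_idx < 0))
    reasons[unknown] = "unknown_category"

    ok = reasons == ""
    na, nm, ne, nl = schema.dim_sizes
    sid = ((a_idx * nm + m_idx) * ne + e_idx) * nl + l_idx
    sid = np.where(ok, sid, -1).astype(np.int64)

    rej = (
        pd.Series(reasons[~ok], dtype=object).value_counts().rename_axis("reason")
        .rename("count").reset_index()
    )
    return pd.Series(sid, index=df.index, name="stratum"), rej


# ---------------------------------------------------------------------------
# Informal-employment rules

#: Occupation classes that the Brazilian rule treats as informal when no
#: formal contract is held (domestic workers, employers and self-employed
#: workers outside social security; unpaid and own-consumption/own-use
#: workers are informal by definition).
BRAZIL_INFORMAL_OCCUPATIONS = frozenset(
    {
        "domestic_worker",
        "employer",
        "self_employed",
        "unpaid_worker",
        "own_consumption_production",
        "own_use_construction",
    }
)


@dataclass(frozen=True)
class InformalRule:
    name: str
    required_fields: tuple[str, ...]
    record_fn: Callable[[WomanRecord], bool]
    frame_fn: Callable[[pd.DataFrame], pd.Series]
    doc: str = ""


_INFORMAL_RULES: dict[str, InformalRule] = {}


def register_informal_rule(rule: InformalRule) -> None:
    _INFORMAL_RULES[rule.name] = rule


def informal_rules() -> tuple[str, ...]:
    return tuple(sorted(_INFORMAL_RULES))


def _require(record: WomanRecord, fields: Sequence[str]) -> None:
    for f in fields:
        v = getattr(record, f, None)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            raise ClassificationError(f)


def _brazil_record(r: WomanRecord) -> bool:
    # No formal contract is necessary; within that, informality holds for the
    # listed occupation classes or for workers outside social security.
    if r.formal_contract:
        return False
    return (r.occupation_class in BRAZIL_INFORMAL_OCCUPATIONS) or (not r.ss_contribution)


def _brazil_frame(df: pd.DataFrame) -> pd.Series:
    no_contract = ~df["formal_contract"].astype(bool)
    occ = df["occupation_class"].isin(BRAZIL_INFORMAL_OCCUPATIONS)
    no_ss = ~df["ss_contribution"].astype(bool)
    return no_contract & (occ | no_ss)


def _ghana_record(r: WomanRecord) -> bool:
    has_benefit = bool(r.benefit_maternity) or bool(r.benefit_sick) or bool(r.benefit_holiday)
    return (not has_benefit) and (not r.contract_any)


def _ghana_frame(df: pd.DataFrame) -> pd.Series:
    has_benefit = (
        df["benefit_maternity"].astype(bool)
        | df["benefit_sick"].astype(bool)
        | df["benefit_holiday"].astype(bool)
    )
    return (~has_benefit) & (~df["contract_any"].astype(bool))


register_informal_rule(
    InformalRule(
        name="brazil_contract_and_social_security",
        required_fields=("formal_contract", "occupation_class", "ss_contribution"),
        record_fn=_brazil_record,
        frame_fn=_brazil_frame,
        doc="No formal contract, and in an informal occupation class or not "
        "contributing to social security.",
    )
)
register_informal_rule(
    InformalRule(
        name="ghana_benefits_and_contract",
        required_fields=("benefit_maternity", "benefit_sick", "benefit_holiday", "contract_any"),
        record_fn=_ghana_record,
        frame_fn=_ghana_frame,
        doc="Lacks maternity-leave, sick-leave and holiday benefits, and has "
        "neither a written nor a verbal contract.",
    )
)


def classify_informal(record: WomanRecord, rule: str) -> bool:
    """True iff an employed record is informally employed under ``rule``.

    Raises :class:`ClassificationError` naming the first missing required
    attribute, and :class:`ValueError` for records that are not employed
    (informality is defined only for the employed).
    """
    try:
        r = _INFORMAL_RULES[rule]
    except KeyError:
        raise ConfigurationError(f"unknown informal rule {rule!r}") from None
    if not record.employed:
        raise ValueError("classify_informal is defined only for employed records")
    _require(record, r.required_fields)
    return bool(r.record_fn(record))


def classify_informal_frame(df: pd.DataFrame, rule: str) -> pd.Series:
    """Vectorised informality flag: True only for employed, informal rows."""
    try:
        r = _INFORMAL_RULES[rule]
    except KeyError:
        raise ConfigurationError(f"unknown informal rule {rule!r}") from None
    for f in r.required_fields:
        if f not in df.columns:
            raise ClassificationError(f)
        if df.loc[df["employed"].astype(bool), f].isna().any():
            raise ClassificationError(f)
    employed = df["employed"].astype(bool)
    flag = pd.Series(False, index=df.index)
    if employed.any():
        flag.loc[employed] = r.frame_fn(df.loc[employed]).astype(bool)
    return flag


def records_from_frame(df: pd.DataFrame) -> Iterator[WomanRecord]:
    """Yield :class:`WomanRecord` objects from a microdata frame."""
    for row in df[list(RECORD_COLUMNS)].itertuples(index=False):
        yield WomanRecord(*row)
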