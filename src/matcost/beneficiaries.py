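"""Eligible beneficiary population (Step 3).

The population projection gives counts of women by age group only, while
``alpha`` varies over the full four-way stratification. The projection is
therefore distributed within each age group across that group's strata in
proportion to the survey's unweighted informal-woman composition, scaled by
the survey's informal share within the age group; the stratum-level
informal populations are then weighted by ``alpha`` and summed.

Totals are kept fractional internally (expected annual claims); rounding
half-up to whole persons happens only at display time, so cost aggregation
never compounds rounding error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .schema import ConfigurationError, CountrySchema, assign_strata, classify_informal_frame

__all__ = [
    "PopulationProjection",
    "EligibleEstimate",
    "allocate_population",
    "eligible_population",
    "projection_from_config",
]

logger = logging.getLogger(__name__)


@dataclass
class PopulationProjection:
    """Projected counts of women per schema age group for one year."""

    year: int
    counts: pd.Series  # index: age-group labels ("16-24", ...), values: persons

    def __post_init__(self):
        self.counts = pd.Series(self.counts, dtype=float)
        if (self.counts < 0).any():
            raise ConfigurationError("projection counts must be non-negative")

    def aligned(self, schema: CountrySchema) -> np.ndarray:
        labels = list(schema.age_group_labels)
        if set(self.counts.index) != set(labels):
            raise ConfigurationError(
                f"projection age groups {sorted(self.counts.index)} do not match "
                f"schema age groups {labels}"
            )
        return self.counts.reindex(labels).to_numpy()

    def to_csv(self, path: Union[str, Path]) -> None:
        out = self.counts.rename_axis("age_group").rename("count").reset_index()
        out["year"] = self.year
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "PopulationProjection":
        df = pd.read_csv(path)
        year = int(df["year"].iloc[0]) if "year" in df.columns and len(df) else 0
        return cls(year=year, counts=pd.Series(df["count"].to_numpy(), index=df["age_group"]))


@dataclass
class EligibleEstimate:
    """Alpha-weighted informal population: expected annual claims."""

    contributions: pd.Series  # per stratum index, persons/year
    informal_pop: pd.Series  # per stratum index, persons

    @property
    def total_eligible(self) -> float:
        return float(self.contributions.sum())

    @property
    def total_rounded(self) -> int:
        """Half-up rounding for display."""
        return int(np.floor(self.total_eligible + 0.5))

    def to_frame(self, schema: CountrySchema) -> pd.DataFrame:
        from .alpha import _stratum_frame

        out = _stratum_frame(schema)
        out["informal_pop"] = self.informal_pop.to_numpy()
        out["eligible"] = self.contributions.to_numpy()
        return out


def allocate_population(
    projection: PopulationProjection,
    df: pd.DataFrame,
    schema: CountrySchema,
    method: str = "survey_composition",
) -> pd.Series:
    """Split age-group projections into per-stratum informal populations.

    Within each age group the projected count is multiplied by the survey's
    informal share for that group and distributed across the group's strata
    in proportion to its informal-woman composition. Age groups absent from
    the survey contribute zero (with a warning).
    """
    if method != "survey_composition":
        raise ConfigurationError(f"unknown allocation method {method!r}")
    proj = projection.aligned(schema)

    sid, _ = assign_strata(df, schema)
    ok = sid.to_numpy() >= 0
    accepted = df.loc[ok]
    sid_ok = sid.to_numpy()[ok]
    informal = classify_informal_frame(accepted, schema.informal_rule).to_numpy()

    na, nm, ne, nl = schema.dim_sizes
    per_group = nm * ne * nl
    a_of_record = sid_ok // per_group

    n_group = np.bincount(a_of_record, minlength=na).astype(float)
    n_informal_stratum = np.bincount(
        sid_ok[informal], minlength=schema.n_strata
    ).astype(float)

    empty = n_group == 0
    if empty.any():
        labels = [schema.age_group_labels[i] for i in np.flatnonzero(empty)]
        logger.warning("no survey records in age group(s) %s; allocating zero", labels)

    a_of_stratum = np.arange(schema.n_strata) // per_group
    denom = np.where(n_group[a_of_stratum] > 0, n_group[a_of_stratum], 1.0)
    alloc = proj[a_of_stratum] * n_informal_stratum / denom
    alloc[n_group[a_of_stratum] == 0] = 0.0
    return pd.Series(alloc, name="informal_pop")


def eligible_population(alpha_table: pd.DataFrame, informal_pop: pd.Series) -> EligibleEstimate:
    """Weight per-stratum informal populations by alpha and sum.

    ``alpha_table`` is the output of :func:`matcost.alpha.compute_alpha`;
    ``informal_pop`` the output of :func:`allocate_population`, indexed by
    the same strata in the same order.
    """
    if len(alpha_table) != len(informal_pop):
        raise ConfigurationError(
            f"alpha table has {len(alpha_table)} strata, informal population "
            f"has {len(informal_pop)}"
        )
    a = alpha_table["alpha"].to_numpy()
    pop = informal_pop.to_numpy(dtype=float)
    contrib = a * pop
    return EligibleEstimate(
        contributions=pd.Series(contrib, index=informal_pop.index, name="eligible"),
        informal_pop=pd.Series(pop, index=informal_pop.index, name="informal_pop"),
    )


def projection_from_config(config: dict) -> PopulationProjection:
    """Synthetic age-group projection built from a reference config.

    The published analyses use World Bank projections that are not shipped
    here; this stand-in scales the country's female population by its
    working-age share and splits it across age groups by the published
    age margin of informal women. It exists so the synthetic pipeline can
    run end to end; reference-constant runs bypass it entirely.
    """
    macro = config["macro"]
    total = float(macro["women_population"]) * float(macro["working_age_share"])
    shares = np.asarray(config["informal_margins"]["age"]["share_pct"], dtype=float)
    shares = shares / shares.sum()
    labels = [f"{lo}-{hi}" for lo, hi in config["age_groups"]]
    return PopulationProjection(
        year=int(config.get("survey_year", 0)),
        counts=pd.Series(total * shares, index=labels),
    )
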