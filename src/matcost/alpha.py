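"""Stratified birth proportions and the informal-worker probability alpha.

Step 1 of the costing method estimates, for every demographic stratum, the
proportion of women of reproductive age who reported a live birth in the
previous 12 months. Step 2 repeats the estimation restricted to informally
employed women, yielding the per-stratum probability ``alpha`` that weights
the population projection in Step 3.

Counts are unweighted throughout: survey expansion factors are built for
other population subgroups and inflate the error of these parameters, so
they are deliberately not used. Proportions are carried at full precision;
one-decimal rounding happens only in reports.

Tables are plain DataFrames, one row per stratum in ``enumerate_strata``
order, keyed by the four category labels for CSV export.
"""

from __future__ import annotations

from typing import Literal

import numpy as np
import pandas as pd

from .schema import CountrySchema, assign_strata, classify_informal_frame, enumerate_strata

__all__ = [
    "compute_fertility_table",
    "compute_alpha",
    "summarize_margins",
    "FLAG_OK",
    "FLAG_EMPTY",
]

FLAG_OK = "ok"
FLAG_EMPTY = "empty_stratum"

Denominator = Literal["within_stratum", "overall"]

_DIMENSIONS = ("age_group", "marital_status", "education_level", "locality")


def _stratum_frame(schema: CountrySchema) -> pd.DataFrame:
    keys = enumerate_strata(schema)
    return pd.DataFrame(
        [schema.key_labels(k) for k in keys],
        columns=list(_DIMENSIONS),
    )


def _count_by_stratum(
    df: pd.DataFrame, schema: CountrySchema
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Women and birth counts per stratum over the accepted records."""
    if len(df) == 0:
        z = np.zeros(schema.n_strata, dtype=np.int64)
        return z, z.copy(), pd.DataFrame(columns=["reason", "count"])
    sid, rejections = assign_strata(df, schema)
    ok = sid.to_numpy() >= 0
    sid_ok = sid.to_numpy()[ok]
    births = df["gave_birth_12m"].astype(bool).to_numpy()[ok]
    n_women = np.bincount(sid_ok, minlength=schema.n_strata).astype(np.int64)
    n_births = np.bincount(sid_ok, weights=births, minlength=schema.n_strata).astype(np.int64)
    return n_women, n_births, rejections


def compute_fertility_table(
    df: pd.DataFrame,
    schema: CountrySchema,
    denominator: Denominator = "within_stratum",
) -> pd.DataFrame:
    """Step 1: per-stratum birth proportions among all accepted women.

    ``denominator="within_stratum"`` (the default used by the cost
    pipeline) divides each stratum's births by the women in that stratum;
    ``"overall"`` divides by all accepted women of reproductive age.
    Strata with no women get proportion 0 and flag ``empty_stratum``.
    """
    n_women, n_births, _ = _count_by_stratum(df, schema)
    out = _stratum_frame(schema)
    out["n_women"] = n_women
    out["n_births"] = n_births
    if denominator == "within_stratum":
        denom = n_women.astype(float)
    elif denominator == "overall":
        denom = np.full(schema.n_strata, float(n_women.sum()))
    else:
        raise ValueError(f"unknown denominator convention {denominator!r}")
    with np.errstate(invalid="ignore", divide="ignore"):
        prop = np.where(denom > 0, n_births / np.where(denom > 0, denom, 1.0), 0.0)
    out["proportion"] = prop
    out["flag"] = np.where(n_women > 0, FLAG_OK, FLAG_EMPTY)
    return out


def compute_alpha(
    df: pd.DataFrame,
    schema: CountrySchema,
    denominator: Denominator = "within_stratum",
) -> pd.DataFrame:
    """Step 2: birth probability ``alpha`` among informally employed women.

    Identical to :func:`compute_fertility_table` restricted to records with
    ``employed`` true that the schema's rule classifies as informal. Strata
    with no informal women contribute alpha = 0 and are flagged: no eligible
    women are claimed there, and no pooling or smoothing is applied.
    """
    informal = classify_informal_frame(df, schema.informal_rule) if len(df) else None
    sub = df.loc[informal] if informal is not None else df
    tab = compute_fertility_table(sub, schema, denominator=denominator)
    tab = tab.rename(
        columns={
            "n_women": "n_informal",
            "n_births": "n_informal_births",
            "proportion": "alpha",
        }
    )
    return tab


def summarize_margins(df: pd.DataFrame, schema: CountrySchema) -> pd.DataFrame:
    """One-way margins of the informal-worker subsample.

    For each stratification dimension: the share of informally employed
    women in each category and the birth proportion within the category,
    mirroring the layout of the published characteristics table. Shares and
    proportions are fractions at full precision.
    """
    informal = classify_informal_frame(df, schema.informal_rule)
    sub = df.loc[informal].copy()
    sid, _ = assign_strata(sub, schema)
    sub = sub.loc[sid.to_numpy() >= 0]
    total = len(sub)

    if total:
        lows = [g[0] for g in schema.age_groups]
        edges = lows + [schema.age_groups[-1][1] + 1]
        sub = sub.assign(
            age_group=pd.cut(
                sub["age"], bins=edges, right=False, labels=list(schema.age_group_labels)
            )
        )

    dim_categories = {
        "age_group": list(schema.age_group_labels),
        "marital_status": list(schema.marital_statuses),
        "education_level": list(schema.education_levels),
        "locality": list(schema.localities),
    }
    rows = []
    for dim, cats in dim_categories.items():
        for cat in cats:
            if total:
                mask = sub[dim].astype(object) == cat
                n = int(mask.sum())
                births = int(sub.loc[mask, "gave_birth_12m"].astype(bool).sum())
            else:
                n = births = 0
            rows.append(
                {
                    "dimension": dim,
                    "category": cat,
                    "n_informal": n,
                    "share": n / total if total else 0.0,
                    "n_births": births,
                    "birth_proportion": births / n if n else 0.0,
                }
            )
    return pd.DataFrame(rows)
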