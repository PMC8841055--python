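"""Synthetic woman-level survey microdata.

Real applications of the costing method rest on national household surveys
(PNAD 2015 for Brazil, GLSS7 2017 for Ghana) that are not redistributable
here. This module generates woman-level microdata with the same structure:
each woman of reproductive age carries the four stratification variables,
an employment flag, employment attributes consistent with the country's
informal-employment rule, and a birth-in-the-last-12-months flag.

The default fixtures (:func:`calibrate_to_published_margins`) reproduce the published
one-way marginal composition of informally employed women in each country
(age group, marital status, education, locality) and the per-margin birth
proportions. Only one-way margins are published, so dimensions are drawn
independently; joint-dependent statistics are deliberately not calibrated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .schema import (
    RECORD_COLUMNS,
    CountrySchema,
    build_reference_schema,
    load_reference_config,
)

__all__ = [
    "SynthSpec",
    "generate_survey",
    "calibrate_to_published_margins",
    "write_survey_csv",
    "read_survey_csv",
]

_BOOL_COLUMNS = (
    "employed",
    "formal_contract",
    "ss_contribution",
    "benefit_maternity",
    "benefit_sick",
    "benefit_holiday",
    "contract_any",
    "gave_birth_12m",
)

#: Occupation classes sampled for informal workers (all classify informal
#: under the Brazilian rule when held without a formal contract).
_INFORMAL_OCC_CHOICES = ("self_employed", "domestic_worker", "unpaid_worker", "employer")
_INFORMAL_OCC_PROBS = (0.55, 0.2, 0.15, 0.1)


def _per_stratum(x, n_strata: int, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 0:
        arr = np.full(n_strata, float(arr))
    if arr.shape != (n_strata,):
        raise ValueError(f"{name} must be scalar or length {n_strata}, got shape {arr.shape}")
    if ((arr < 0) | (arr > 1)).any():
        raise ValueError(f"{name} values must lie in [0, 1]")
    return arr


@dataclass
class SynthSpec:
    """Parameters of one synthetic survey draw.

    All per-stratum arrays are indexed in ``enumerate_strata`` order;
    scalars broadcast. ``birth_prob`` applies to women who are not
    informally employed; ``birth_prob_informal`` (default: same values)
    applies to informal workers, mirroring that the published birth
    proportions are conditional on informal employment.
    """

    schema: CountrySchema
    n_women: int
    stratum_weights: np.ndarray
    employment_rate: Union[float, np.ndarray]
    informal_share: Union[float, np.ndarray]
    birth_prob: Union[float, np.ndarray]
    birth_prob_informal: Optional[Union[float, np.ndarray]] = None
    seed: int = 0

    def __post_init__(self):
        n = self.schema.n_strata
        if self.n_women < 0:
            raise ValueError(f"n_women must be non-negative, got {self.n_women}")
        w = np.asarray(self.stratum_weights, dtype=float)
        if w.shape != (n,):
            raise ValueError(f"stratum_weights must have length {n}, got {w.shape}")
        if (w < 0).any() or not np.isfinite(w).all():
            raise ValueError("stratum_weights must be finite and non-negative")
        total = w.sum()
        if total <= 0:
            raise ValueError("stratum_weights are not normalizable (sum <= 0)")
        if abs(total - 1.0) > 1e-9:
            w = w / total
        self.stratum_weights = w
        self.employment_rate = _per_stratum(self.employment_rate, n, "employment_rate")
        self.informal_share = _per_stratum(self.informal_share, n, "informal_share")
        self.birth_prob = _per_stratum(self.birth_prob, n, "birth_prob")
        if self.birth_prob_informal is None:
            self.birth_prob_informal = self.birth_prob.copy()
        else:
            self.birth_prob_informal = _per_stratum(
                self.birth_prob_informal, n, "birth_prob_informal"
            )
        self.seed = int(self.seed)

    # -- serialisation (same YAML dialect as the schema configs) ---------

    def to_dict(self) -> dict:
        return {
            "schema": self.schema.to_dict(),
            "n_women": int(self.n_women),
            "stratum_weights": [float(v) for v in self.stratum_weights],
            "employment_rate": [float(v) for v in self.employment_rate],
            "informal_share": [float(v) for v in self.informal_share],
            "birth_prob": [float(v) for v in self.birth_prob],
            "birth_prob_informal": [float(v) for v in self.birth_prob_informal],
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SynthSpec":
        return cls(
            schema=CountrySchema.from_dict(d["schema"]),
            n_women=d["n_women"],
            stratum_weights=np.asarray(d["stratum_weights"], dtype=float),
            employment_rate=np.asarray(d["employment_rate"], dtype=float),
            informal_share=np.asarray(d["informal_share"], dtype=float),
            birth_prob=np.asarray(d["birth_prob"], dtype=float),
            birth_prob_informal=np.asarray(d["birth_prob_informal"], dtype=float),
            seed=d.get("seed", 0),
        )

    def save(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: Union[str, Path]) -> "SynthSpec":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def generate_survey(spec: SynthSpec) -> pd.DataFrame:
    """Draw one synthetic survey as a microdata DataFrame.

    Stratum membership is multinomial in ``stratum_weights``; age is uniform
    within the assigned age interval; employment, informality and birth
    flags are Bernoulli with the stratum's probabilities. Employment
    attributes are set so that the schema's informal rule classifies each
    employed record exactly as drawn (and the other shipped rule agrees).
    Identical ``(spec, seed)`` pairs give identical frames.
    """
    schema = spec.schema
    n = int(spec.n_women)
    rng = np.random.default_rng(spec.seed)

    na, nm, ne, nl = schema.dim_sizes
    sid = rng.choice(schema.n_strata, size=n, p=spec.stratum_weights)
    l_idx = sid % nl
    e_idx = (sid // nl) % ne
    m_idx = (sid // (nl * ne)) % nm
    a_idx = sid // (nl * ne * nm)

    lows = np.array([g[0] for g in schema.age_groups])
    highs = np.array([g[1] for g in schema.age_groups])
    age = lows[a_idx] + rng.integers(0, highs[a_idx] - lows[a_idx] + 1, size=n)

    employed = rng.random(n) < spec.employment_rate[sid]
    informal = employed & (rng.random(n) < spec.informal_share[sid])
    p_birth = np.where(informal, spec.birth_prob_informal[sid], spec.birth_prob[sid])
    birth = rng.random(n) < p_birth

    occ = np.full(n, "none", dtype=object)
    formal = employed & ~informal
    occ[formal] = "employee"
    n_inf = int(informal.sum())
    occ[informal] = rng.choice(_INFORMAL_OCC_CHOICES, size=n_inf, p=_INFORMAL_OCC_PROBS)

    # benefit texture for formal workers; maternity benefit always present so
    # the Ghanaian rule agrees with the draw
    ben_sick = formal & (rng.random(n) < 0.7)
    ben_holiday = formal & (rng.random(n) < 0.7)

    df = pd.DataFrame(
        {
            "age": age.astype(np.int64),
            "marital_status": pd.Categorical.from_codes(
                m_idx, categories=list(schema.marital_statuses)
            ).astype(object),
            "education_level": pd.Categorical.from_codes(
                e_idx, categories=list(schema.education_levels)
            ).astype(object),
            "locality": pd.Categorical.from_codes(
                l_idx, categories=list(schema.localities)
            ).astype(object),
            "employed": employed,
            "formal_contract": formal,
            "ss_contribution": formal,
            "occupation_class": occ,
            "benefit_maternity": formal,
            "benefit_sick": ben_sick,
            "benefit_holiday": ben_holiday,
            "contract_any": formal,
            "gave_birth_12m": birth,
        },
        columns=list(RECORD_COLUMNS),
    )
    return df


def calibrate_to_published_margins(
    country: str, n_women: int = 100_000, seed: Optional[int] = None
) -> SynthSpec:
    """Default fixture: a spec matching the published informal-women margins.

    The four dimensions are drawn independently with the published one-way
    marginal shares (normalised per dimension); the per-stratum birth
    probability is taken from the age margin of the published table, both
    for informal workers and (lacking a published all-women table) for
    everyone else. Employment rate and the informal share among the
    employed are country-level constants from the reference config.
    """
    cfg = load_reference_config(country)
    schema = build_reference_schema(country)
    margins = cfg["informal_margins"]

    def _norm(dim: str) -> np.ndarray:
        s = np.asarray(margins[dim]["share_pct"], dtype=float)
        return s / s.sum()

    pa = _norm("age")
    pm = _norm("marital_status")
    pe = _norm("education_level")
    pl = _norm("locality")
    weights = (
        pa[:, None, None, None]
        * pm[None, :, None, None]
        * pe[None, None, :, None]
        * pl[None, None, None, :]
    ).reshape(-1)

    birth_age = np.asarray(margins["age"]["birth_pct"], dtype=float) / 100.0
    na, nm, ne, nl = schema.dim_sizes
    a_of_s = np.arange(schema.n_strata) // (nl * ne * nm)
    birth = birth_age[a_of_s]

    if seed is None:
        seed = int(cfg.get("survey_year", 0))
    return SynthSpec(
        schema=schema,
        n_women=n_women,
        stratum_weights=weights,
        employment_rate=float(cfg["employment_rate"]),
        informal_share=float(cfg["informal_share_employed"]),
        birth_prob=birth,
        birth_prob_informal=birth,
        seed=seed,
    )


def write_survey_csv(df: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write microdata with the documented header (booleans as 0/1)."""
    out = df.copy()
    for c in _BOOL_COLUMNS:
        out[c] = out[c].astype(int)
    out.to_csv(path, index=False)


def read_survey_csv(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"survey CSV missing columns: {sorted(missing)}")
    for c in _BOOL_COLUMNS:
        df[c] = df[c].astype(bool)
    return df[list(RECORD_COLUMNS)]
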