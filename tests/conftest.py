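import numpy as np
import pandas as pd
import pytest

from matcost import build_reference_schema, calibrate_to_published_margins, generate_survey
from matcost.schema import RECORD_COLUMNS, CountrySchema


@pytest.fixture(scope="session")
def brazil_schema():
    return build_reference_schema("brazil")


@pytest.fixture(scope="session")
def ghana_schema():
    return build_reference_schema("ghana")


@pytest.fixture(scope="session")
def toy_schema():
    """Tiny 2x2x2x2 schema used for hand-computable cases."""
    return CountrySchema(
        name="toyland",
        age_groups=((16, 29), (30, 49)),
        marital_statuses=("single", "married"),
        education_levels=("low", "high"),
        localities=("urban", "rural"),
        reproductive_age_range=(16, 49),
        informal_rule="brazil_contract_and_social_security",
        admin_rate=0.05,
    )


@pytest.fixture(scope="session")
def brazil_survey_small():
    """Calibrated synthetic Brazilian survey, 20k women (fixed seed)."""
    return generate_survey(calibrate_to_published_margins("brazil", n_women=20_000, seed=11))


@pytest.fixture(scope="session")
def ghana_survey_small():
    return generate_survey(calibrate_to_published_margins("ghana", n_women=20_000, seed=12))


def make_survey_frame(rows: list[dict]) -> pd.DataFrame:
    """Build a microdata frame from sparse row dicts (defaults filled in)."""
    defaults = {
        "age": 25,
        "marital_status": "single",
        "education_level": "no_education",
        "locality": "urban",
        "employed": False,
        "formal_contract": False,
        "ss_contribution": False,
        "occupation_class": "none",
        "benefit_maternity": False,
        "benefit_sick": False,
        "benefit_holiday": False,
        "contract_any": False,
        "gave_birth_12m": False,
    }
    full = [{**defaults, **r} for r in rows]
    return pd.DataFrame(full, columns=list(RECORD_COLUMNS))


def repeated_rows(row: dict, n: int, n_births: int = 0) -> list[dict]:
    """n copies of a row, the first n_births of them with a birth flag."""
    return [{**row, "gave_birth_12m": i < n_births} for i in range(n)]
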