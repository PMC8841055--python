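"""Steps 1-2: stratified birth proportions and alpha on the synthetic surveys.

Reads the microdata written by 01_simulate_surveys.py (regenerating it if
absent), computes the per-stratum fertility table among all women and the
alpha table among informally employed women, and writes both to results/.

Run from the repository root:  python analysis/02_estimate_alpha.py
"""

from pathlib import Path

from matcost import build_reference_schema, compute_alpha, compute_fertility_table
from matcost.alpha import FLAG_EMPTY
from matcost.synth import calibrate_to_published_margins, generate_survey, read_survey_csv, write_survey_csv

SCRATCH = Path("scratch")
RESULTS = Path("results")


def load_survey(country: str):
    path = SCRATCH / f"survey_{country}.csv"
    if path.exists():
        return read_survey_csv(path)
    SCRATCH.mkdir(exist_ok=True)
    df = generate_survey(calibrate_to_published_margins(country, n_women=100_000))
    write_survey_csv(df, path)
    return df


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    for country in ("brazil", "ghana"):
        schema = build_reference_schema(country)
        df = load_survey(country)

        fert = compute_fertility_table(df, schema)
        alpha = compute_alpha(df, schema)
        fert.to_csv(RESULTS / f"fertility_table_{country}.csv", index=False)
        alpha.to_csv(RESULTS / f"alpha_table_{country}.csv", index=False)

        pooled = alpha["n_informal_births"].sum() / alpha["n_informal"].sum()
        empty = int((alpha["flag"] == FLAG_EMPTY).sum())
        print(f"{country}: {schema.n_strata} strata, "
              f"{alpha['n_informal'].sum():,} informal women, "
              f"pooled birth rate {100 * pooled:.1f}%, "
              f"{empty} strata without informal women (alpha = 0 there)")


if __name__ == "__main__":
    main()
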