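"""Generate calibrated synthetic survey microdata for both countries.

Draws woman-level microdata whose informal-worker margins match the
published characteristics tables (Brazil 2015, Ghana 2017), writes the
microdata to scratch/ (large, regenerable) and a small margin-check table
to results/.

Run from the repository root:  python analysis/01_simulate_surveys.py
"""

from pathlib import Path

import pandas as pd

from matcost import calibrate_to_published_margins, generate_survey, summarize_margins
from matcost.synth import write_survey_csv

N_WOMEN = 100_000
SCRATCH = Path("scratch")
RESULTS = Path("results")


def main() -> None:
    SCRATCH.mkdir(exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    checks = []
    for country in ("brazil", "ghana"):
        spec = calibrate_to_published_margins(country, n_women=N_WOMEN)  # seed = survey year
        df = generate_survey(spec)
        path = SCRATCH / f"survey_{country}.csv"
        write_survey_csv(df, path)

        margins = summarize_margins(df, spec.schema)
        margins.insert(0, "country", country)
        checks.append(margins)
        n_informal = margins[margins["dimension"] == "locality"]["n_informal"].sum()
        print(f"{country}: {len(df):,} women -> {path} "
              f"({n_informal:,} informally employed, "
              f"{100 * n_informal / len(df):.1f}%)")
        for dim, cat in (("locality", "rural"), ("marital_status", "married_or_cohabiting")):
            row = margins[(margins["dimension"] == dim) & (margins["category"] == cat)]
            print(f"  informal {cat}: share {100 * row['share'].iloc[0]:.1f}%, "
                  f"birth rate {100 * row['birth_proportion'].iloc[0]:.1f}%")

    out = RESULTS / "synthetic_margins.csv"
    pd.concat(checks, ignore_index=True).to_csv(out, index=False)
    print(f"\nmargin tables -> {out}")


if __name__ == "__main__":
    main()
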