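"""Step 3: alpha-weighted eligible population from the synthetic pipeline.

Allocates a synthetic age-group population projection (female population x
working-age share, split by the published age margin) across strata using
the survey's informal composition, weights by alpha, and compares the
resulting expected annual claims with the published eligible counts
(291,699 Brazil; 434,410 Ghana) that reference-constant costing runs use.

Run from the repository root:  python analysis/03_eligible_population.py
"""

import importlib.util
from pathlib import Path

import pandas as pd

from matcost import allocate_population, build_reference_schema, compute_alpha, eligible_population
from matcost.beneficiaries import projection_from_config
from matcost.costing import reference_eligible
from matcost.schema import load_reference_config

_loader = importlib.util.spec_from_file_location(
    "simulate", Path(__file__).parent / "02_estimate_alpha.py"
)
_mod = importlib.util.module_from_spec(_loader)
_loader.loader.exec_module(_mod)
load_survey = _mod.load_survey

RESULTS = Path("results")


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    rows = []
    for country in ("brazil", "ghana"):
        schema = build_reference_schema(country)
        cfg = load_reference_config(country)
        df = load_survey(country)

        projection = projection_from_config(cfg)
        informal_pop = allocate_population(projection, df, schema)
        alpha = compute_alpha(df, schema)
        est = eligible_population(alpha, informal_pop)
        est.to_frame(schema).to_csv(RESULTS / f"eligible_by_stratum_{country}.csv", index=False)

        published = int(reference_eligible(country))
        rows.append(
            {
                "country": country,
                "projected_women_16_49": round(projection.counts.sum()),
                "informal_women": round(informal_pop.sum()),
                "eligible_synthetic": est.total_rounded,
                "eligible_published": published,
            }
        )
        print(f"{country}: projected women 16-49 {projection.counts.sum():,.0f}, "
              f"informal {informal_pop.sum():,.0f}, "
              f"synthetic eligible {est.total_rounded:,} "
              f"(published constant: {published:,})")

    pd.DataFrame(rows).to_csv(RESULTS / "eligible_summary.csv", index=False)
    print(f"\nsummary -> {RESULTS / 'eligible_summary.csv'}")
    print("Synthetic estimates depend on the synthetic employment and projection "
          "assumptions; cost reproduction uses the published constants.")


if __name__ == "__main__":
    main()
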