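"""Steps 4-6: the annual cost grid and GDP shares from published constants.

Prices the weekly transfer with the three welfare measures (minimum wage,
poverty line, twice the poverty line) in US$ and PPP$, costs the 12/14/18/26
week scenarios for both countries with the published eligible counts, and
reports each PPP$ total as a share of GDP (per-capita PPP x population).

Run from the repository root:  python analysis/04_cost_scenarios.py
"""

from pathlib import Path

import pandas as pd

from matcost import build_reference_schema
from matcost.costing import (
    reference_eligible,
    reference_gdp,
    reference_measures,
    scenario_grid,
)
from matcost.pipeline import format_cost_table

RESULTS = Path("results")
WEEKS = [12, 14, 18, 26]


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    schemas = {c: build_reference_schema(c) for c in ("brazil", "ghana")}
    grid = scenario_grid(
        schemas=schemas,
        measures={c: reference_measures(c) for c in schemas},
        weeks_list=WEEKS,
        eligibles={c: reference_eligible(c) for c in schemas},
    )
    out = grid.copy()
    for col in ("weekly_ct", "transfer_cost", "admin_cost", "total", "per_woman", "eligible"):
        out[col] = out[col].map(str)
    out.to_csv(RESULTS / "cost_grid.csv", index=False)

    shares = []
    for country in schemas:
        print(format_cost_table(grid, country))
        gdp = reference_gdp(country)
        ppp = grid[(grid["country"] == country) & (grid["currency"] == "PPP")]
        vals = [float(t / gdp * 100) for t in ppp["total"]]
        shares.append({"country": country,
                       "gdp_share_min_pct": min(vals), "gdp_share_max_pct": max(vals)})
        print(f"{country}: annual cost between {min(vals):.4f}% and {max(vals):.4f}% of GDP\n")
        (RESULTS / f"cost_table_{country}.txt").write_text(format_cost_table(grid, country))

    pd.DataFrame(shares).to_csv(RESULTS / "gdp_shares.csv", index=False)
    print(f"grid -> {RESULTS / 'cost_grid.csv'}; GDP shares -> {RESULTS / 'gdp_shares.csv'}")


if __name__ == "__main__":
    main()
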