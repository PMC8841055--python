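"""End-to-end run configuration, validation and report generation.

`run_pipeline` executes the six costing steps in order on one of three data
sources — a survey CSV, the synthetic generator, or the published
reference constants — and writes every intermediate table plus a run log
(seed, config hash, rejection and empty-stratum warnings) into the
configured output directory. Outputs carry no timestamps, so two runs with
the same configuration and seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from decimal import Decimal
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from . import alpha as alpha_mod
from . import beneficiaries as ben_mod
from . import costing, synth
from .schema import (
    ConfigurationError,
    CountrySchema,
    available_countries,
    build_reference_schema,
    load_reference_config,
)

__all__ = ["RunConfig", "Finding", "validate_config", "run_pipeline", "format_cost_table"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Finding:
    level: str  # error | warning
    code: str
    message: str


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one data source applies: ``use_printed_constants`` (published
    eligible counts, skipping Steps 1-3), ``survey_csv``, or the synthetic
    generator (the default, calibrated to the published margins).
    """

    country: str = "brazil"
    survey_csv: Optional[Path] = None
    use_printed_constants: bool = False
    n_women: int = 100_000
    weeks: Sequence[int] = (12, 14, 18, 26)
    coverage: float = 1.0
    seed: int = 0
    out_dir: Path = Path("matcost_out")
    measures: Optional[Sequence[str]] = None  # None = all configured
    gdp: Optional[float] = None  # PPP; None = per-capita PPP x population
    projection_csv: Optional[Path] = None

    def canonical(self) -> dict:
        return {
            "country": self.country,
            "survey_csv": str(self.survey_csv) if self.survey_csv else None,
            "use_printed_constants": self.use_printed_constants,
            "n_women": int(self.n_women),
            "weeks": [int(w) for w in self.weeks],
            "coverage": float(self.coverage),
            "seed": int(self.seed),
            "measures": list(self.measures) if self.measures else None,
            "gdp": float(self.gdp) if self.gdp is not None else None,
            "projection_csv": str(self.projection_csv) if self.projection_csv else None,
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.canonical(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def validate_config(config: RunConfig) -> list[Finding]:
    """Machine-readable findings; never raises, never runs the pipeline."""
    findings: list[Finding] = []
    if config.country not in available_countries():
        findings.append(
            Finding("error", "unknown_country", f"unknown country {config.country!r}")
        )
    if not list(config.weeks):
        findings.append(Finding("error", "weeks_empty", "weeks list must be non-empty"))
    elif any(int(w) <= 0 for w in config.weeks):
        findings.append(Finding("error", "weeks_nonpositive", "weeks must all be positive"))
    if not (0 < config.coverage <= 1):
        findings.append(
            Finding("error", "coverage_range", f"coverage must be in (0, 1], got {config.coverage}")
        )
    if config.survey_csv is not None and config.use_printed_constants:
        findings.append(
            Finding("error", "ambiguous_source", "choose exactly one data source")
        )
    if config.n_women < 0:
        findings.append(Finding("error", "n_women_negative", "n_women must be non-negative"))
    if config.survey_csv is not None and not Path(config.survey_csv).exists():
        findings.append(
            Finding("error", "survey_missing", f"survey CSV not found: {config.survey_csv}")
        )
    if config.gdp is not None and config.gdp <= 0:
        findings.append(Finding("error", "gdp_nonpositive", "gdp must be positive"))
    if config.measures:
        known = set(costing.MEASURE_ORDER)
        for m in config.measures:
            if m not in known:
                findings.append(Finding("error", "unknown_measure", f"unknown measure {m!r}"))
    return findings


@dataclass
class RunReport:
    """Paths and in-memory tables produced by one run."""

    out_dir: Path
    grid: pd.DataFrame
    eligible: Decimal
    warnings: list[str] = field(default_factory=list)
    fertility: Optional[pd.DataFrame] = None
    alpha: Optional[pd.DataFrame] = None
    margins: Optional[pd.DataFrame] = None
    gdp_shares: Optional[pd.DataFrame] = None


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute Steps 1-6 and write the report bundle.

    Raises :class:`ConfigurationError` naming the stage on invalid input.
    """
    errors = [f for f in validate_config(config) if f.level == "error"]
    if errors:
        raise ConfigurationError(
            "invalid configuration: " + "; ".join(f"{f.code}: {f.message}" for f in errors)
        )

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    warnings: list[str] = []

    schema = build_reference_schema(config.country)
    cfg = load_reference_config(config.country)

    fertility = alpha_tab = margins = None
    if config.use_printed_constants:
        eligible = costing.reference_eligible(config.country)
    else:
        # Steps 1-2: microdata -> stratified proportions and alpha
        if config.survey_csv is not None:
            df = synth.read_survey_csv(config.survey_csv)
        else:
            spec = synth.calibrate_to_published_margins(
                config.country, n_women=config.n_women, seed=config.seed
            )
            df = synth.generate_survey(spec)
        fertility = alpha_mod.compute_fertility_table(df, schema)
        alpha_tab = alpha_mod.compute_alpha(df, schema)
        margins = alpha_mod.summarize_margins(df, schema)
        n_empty = int((alpha_tab["flag"] == alpha_mod.FLAG_EMPTY).sum())
        if n_empty:
            msg = f"{n_empty} strata have no informal women (alpha = 0 there)"
            warnings.append(msg)
            logger.warning(msg)

        # Step 3: projection -> eligible population
        if config.projection_csv is not None:
            projection = ben_mod.PopulationProjection.from_csv(config.projection_csv)
        else:
            projection = ben_mod.projection_from_config(cfg)
        informal_pop = ben_mod.allocate_population(projection, df, schema)
        estimate = ben_mod.eligible_population(alpha_tab, informal_pop)
        eligible = Decimal(repr(estimate.total_eligible))

        fertility.to_csv(out / "fertility_table.csv", index=False)
        alpha_tab.to_csv(out / "alpha_table.csv", index=False)
        margins.to_csv(out / "informal_margins.csv", index=False)
        estimate.to_frame(schema).to_csv(out / "eligible_by_stratum.csv", index=False)

    # Steps 4-6: cost grid
    measures = costing.reference_measures(config.country)
    if config.measures:
        measures = [m for m in measures if m.label in set(config.measures)]
    grid = costing.scenario_grid(
        schemas={config.country: schema},
        measures={config.country: measures},
        weeks_list=[int(w) for w in config.weeks],
        eligibles={config.country: eligible},
        coverage=Decimal(repr(float(config.coverage))),
    )
    grid_out = grid.copy()
    for col in ("weekly_ct", "transfer_cost", "admin_cost", "total", "per_woman", "eligible"):
        grid_out[col] = grid_out[col].map(str)
    grid_out.to_csv(out / "cost_grid.csv", index=False)
    (out / "cost_table.txt").write_text(format_cost_table(grid, config.country))

    gdp = Decimal(repr(config.gdp)) if config.gdp is not None else costing.reference_gdp(config.country)
    ppp = grid[grid["currency"] == "PPP"]
    shares = pd.DataFrame(
        {
            "weeks": ppp["weeks"],
            "measure": ppp["measure"],
            "gdp_share_pct": [
                float(t / gdp * 100) for t in ppp["total"]
            ],
        }
    )
    shares.to_csv(out / "gdp_shares.csv", index=False)

    log = {
        "config": config.canonical(),
        "config_hash": config.config_hash(),
        "seed": int(config.seed),
        "eligible_women": str(eligible),
        "warnings": warnings,
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")

    return RunReport(
        out_dir=out,
        grid=grid,
        eligible=eligible,
        warnings=warnings,
        fertility=fertility,
        alpha=alpha_tab,
        margins=margins,
        gdp_shares=shares,
    )


def format_cost_table(grid: pd.DataFrame, country: str) -> str:
    """Aligned-text cost grid: weeks blocks x measure rows x currencies."""
    sub = grid[grid["country"] == country]
    lines = [
        f"Estimated annual cost of a maternity cash transfer — {country}",
        f"Eligible women: {sub['eligible'].iloc[0] if len(sub) else 'n/a'}",
        "",
    ]
    header = f"{'Measure':<28}{'Currency':<10}{'Total cost':>16}{'Per woman':>12}"
    for weeks in sorted(sub["weeks"].unique()):
        lines.append(f"Annual cost per {weeks} weeks")
        lines.append(header)
        block = sub[sub["weeks"] == weeks]
        for _, row in block.iterrows():
            lines.append(
                f"{row['measure_title']:<28}{row['currency']:<10}"
                f"{row['total_rounded']:>16,}{row['per_woman_rounded']:>12,}"
            )
        lines.append("")
    return "\n".join(lines) + "\n"
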