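# Methods

## Model

The package prices one year of a maternity cash transfer for informally
employed women as

    ML_y = CT · IC_y · (α · Pop_y) + AdmCost_y

`CT` is the weekly transfer (money/woman/week), `IC_y` the weeks covered
per birth, `α · Pop_y` the expected number of annual claims, and
`AdmCost_y` the cost of operating the program. The model is static (one
intervention year, no behavioural response, no uptake model) and linear in
every lever: weeks, coverage, transfer level and eligible count. Those
linearity identities are asserted exactly in the test suite, which is why
money is carried as `decimal.Decimal` rather than binary floats; display
rounding is half-up (whole units for totals and per-woman costs, one
decimal for weekly amounts).

## Stratification and informality (Steps 1–2)

Women of reproductive and legal working age (16–49, both ends inclusive;
integer completed years) are stratified by age group (16–24, 25–29, 30–34,
35–39, 40–49), marital status (3 categories), education (6 in Brazil, 5 in
Ghana) and locality (urban/rural): 180 and 150 strata. Records with
missing or unmappable demographic fields are rejected and counted by
reason, never imputed.

Informality rules are country-specific and live in a registry so new
countries can add rules without touching core code:

- **Brazil** — no formal contract, and either in an informal occupation
  class (domestic workers, employers, self-employed, unpaid,
  own-consumption/own-use production) or not contributing to social
  security. "No formal contract" is treated as necessary; an employee
  without a contract who contributes to social security counts as formal.
- **Ghana** — lacks all three statutory benefits (maternity leave, sick
  leave, holidays) and has neither a written nor a verbal contract.

Birth proportions are unweighted: survey expansion factors are built for
other population subgroups and would inflate the error of stratum-level
parameters. Two denominator conventions are implemented —
`within_stratum` (births in stratum / women in stratum; the default used
throughout the pipeline) and `overall` (births in stratum / all women of
reproductive age). The within-stratum reading is the one consistent with
subgroup fertility rates at plausible stratum sizes, which is why it is
the default; the alternative is kept behind a flag because the method has
been described both ways. Proportions are carried at full precision; the
one-decimal percentages appear only in reports. α is the same computation
restricted to employed women the country rule classifies as informal.
Strata with no informal women contribute α = 0 (no claims expected there),
are flagged `empty_stratum`, and are reported in the run log; no pooling
or smoothing is applied.

## Eligible population (Step 3)

Population projections give women by age group only, while α varies over
the full stratification. Each age group's projected count is multiplied by
the survey's informal share within that group and split across the group's
strata by the survey's informal-worker composition — the survey is the
only source of that joint structure. The allocation method is pluggable.
Eligible totals stay fractional (expected claims) through the cost
computation; rounding to whole persons is display-only.

The reference configurations also carry the published eligible counts
(291,699 Brazil; 434,410 Ghana) as constants, because they derive from the
national microdata and cannot be re-estimated from synthetic data. Runs
with `use_printed_constants` skip Steps 1–3 and reproduce the published
cost grid; synthetic runs exercise the full pipeline and land in the same
order of magnitude (Ghana within ~1%, Brazil within ~35% of the published
count under the default assumptions — see limitations).

## Transfer pricing and costs (Steps 4–6)

Weekly transfers come from welfare measures: minimum wage or income
poverty line (PPP$5.50/day Brazil, PPP$3.20/day Ghana), optionally
doubled. Derivation standardises per-day bases ×7 and per-month bases
×12/52. The reference configurations instead carry the published weekly
amounts as overrides (e.g. Brazil minimum wage US$58.3, PPP$106.6/week),
because the published currency conversions are not reproducible from the
printed per-day lines (e.g. 7 × 5.50 = 38.5 ≠ the published PPP$43.2); an
override is the final weekly amount for its multiplier.

Administrative cost is a fixed fraction of the transfer outlay — 5.6%
(Brazil) and 5.8% (Ghana). The additive `AdmCost_y` term is realised as
this product: it is the only reading consistent with the published
per-woman values (58.3 × 12 × 1.056 → 739). A lump-sum option is accepted
in configuration for future use. Per-woman cost is therefore
`CT · weeks · coverage · (1 + admin_rate)`, independent of the eligible
count (property-tested). USD and PPP$ are parallel labelled columns; no
exchange-rate arithmetic is ever performed.

GDP shares divide the PPP totals by GDP reconstructed as per-capita PPP ×
total population (14,652 × 211.0 M for Brazil, 5,413 × 30.4 M for Ghana),
since no GDP level is published alongside the cost grid; the resulting
ranges (Brazil ≈ 0.005–0.028%, Ghana ≈ 0.063–0.274% of GDP) match the
published contrast in order of magnitude, not to the digit.

### Reproduction accuracy

From the printed weekly transfers and eligible counts, all 16 per-woman
cells documented as exactly reproducible do reproduce exactly after
half-up rounding. The remaining cells differ by 1 unit (one cell, the
Brazil 26-week minimum wage in PPP$, by 3) because the published grid was
computed with unrounded weekly transfers. For the same reason the
published totals are matched to within 0.5% everywhere and within 0.1%
for every PPP cell; the coarser one-decimal USD amounts for Ghana (e.g.
6.8 printed for an implied 6.768) dominate the residual.

## Synthetic survey generator

The generator stands in for the national household surveys. For each of
`n_women` records it draws a stratum (multinomial over per-stratum
weights), an age uniform within the stratum's interval (no within-group
age distribution is published), an employment flag, an informality flag
among the employed, and a birth flag — all Bernoulli with per-stratum
probabilities — then writes employment attributes that the informality
rules map back to exactly the drawn label (checked record-by-record in the
tests). One `numpy.random.default_rng(seed)` instance drives everything;
no global state, and identical (spec, seed) pairs are byte-identical.

Calibration (`calibrate_to_published_margins`) targets the published one-way margins
of informally employed women: shares of each age group, marital status,
education level and locality, and per-margin birth percentages. Only
one-way margins are published, so the four dimensions are drawn
independently (the joint is the product of margins) and the per-stratum
birth probability follows the age margin, the dimension along which
published fertility varies most. Consequences to keep in mind when
interpreting passing tests:

- joint-dependent statistics (e.g. fertility of young rural uneducated
  women specifically) are *not* calibrated and carry no information beyond
  the margins;
- the same birth probability is used for informal and non-informal women
  of a stratum, because only the informal-worker table is published;
- household structure, survey design effects and expansion factors are
  out of scope by design.

Two generator constants are not derivable from published tables and were
fixed once as typical values for the two countries: the female
employment-to-population ratio (0.55 Brazil, 0.65 Ghana). The informal
share among employed women uses the published country rates (38.27%,
83.18%). The Brazil education margin prints to 93.8%, not 100% (a
printed-table inconsistency); every margin is renormalised before use.
Default seeds are the survey years (2015, 2017).

## Problem sizes and numerics

Default analysis and test runs use 100,000 synthetic women per country
(≈550 per Brazilian stratum), enough for the 3-binomial-SE recovery checks
to be comfortably stable; unit tests use 2,000–50,000. The vectorised
stratum counting is bincount-based and is verified against a naive
per-record loop on 10,000-record datasets. Decimal arithmetic uses the
default 28-digit context, ample for exactness of all products appearing
here; divisions (per-woman, GDP shares) are correctly rounded at that
precision.

## Known limitations

- Synthetic eligible counts inherit every synthetic assumption
  (employment rate, projection stand-in built from female population ×
  working-age share split by the informal age margin); they are
  order-of-magnitude companions to the published constants, not estimates
  of them.
- One intervention year only; no multi-year projection, start-up costs, or
  uptake behaviour.
- No variance estimation for α (point estimates only, matching the
  method's design).
- Administrative rates are borrowed from analogous programs, not modelled.
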