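# Reference configuration: Brazil (survey year 2015).
# Weekly transfer amounts, administrative rate, eligible-women count and
# macro figures are published constants; employment_rate is a package
# default (see docs/methods.md).
name: brazil
survey_year: 2015
reproductive_age_range: [16, 49]
age_groups:
  - [16, 24]
  - [25, 29]
  - [30, 34]
  - [35, 39]
  - [40, 49]
marital_statuses:
  - single
  - married_or_cohabiting
  - widowed_divorced_separated
education_levels:
  - no_education
  - kindergarten_or_incomplete_primary
  - complete_primary_or_incomplete_middle
  - complete_middle_or_incomplete_high
  - complete_high_school
  - higher_or_technical
localities:
  - urban
  - rural
informal_rule: brazil_contract_and_social_security
admin_rate: 0.056
currency_bases: [USD, PPP]

# Published count of eligible women (annual expected claims); used when a
# run is configured with printed constants instead of survey-derived values.
eligible_women: 291699

macro:
  total_population: 211049527
  women_population: 107316363
  gdp_per_capita_ppp: 14652
  working_age_share: 0.6974

# Weekly cash-transfer amounts per welfare measure and currency base.
# override_weekly values are the published weekly amounts (2019 USD / PPP);
# they take precedence over any derivation from the base value.
welfare_measures:
  minimum_wage:
    kind: minimum_wage
    multiplier: 1
    override_weekly: {USD: "58.3", PPP: "106.6"}
  poverty_line:
    kind: poverty_line
    base_value_per_day_ppp: "5.50"
    multiplier: 1
    override_weekly: {USD: "23.6", PPP: "43.2"}
  twice_poverty_line:
    kind: poverty_line
    base_value_per_day_ppp: "5.50"
    multiplier: 2
    override_weekly: {USD: "47.3", PPP: "86.4"}

weeks_scenarios: [12, 14, 18, 26]

# One-way marginal composition of informally employed women of reproductive
# age, and the share of each margin category that gave birth in the previous
# 12 months (percent). Used to calibrate the synthetic survey generator.
informal_margins:
  age:
    share_pct: [20.1, 14.4, 16.9, 17.9, 30.8]
    birth_pct: [4.2, 4.5, 3.8, 2.1, 0.1]
  marital_status:
    share_pct: [35.4, 56.6, 7.9]
    birth_pct: [1.8, 3.3, 1.7]
  education_level:
    share_pct: [4.1, 10.1, 13.4, 20.5, 35.6, 10.1]
    birth_pct: [1.6, 2.3, 2.8, 3.0, 2.7, 2.6]
  locality:
    share_pct: [87.6, 12.4]
    birth_pct: [2.6, 2.9]

# Generator defaults not derivable from published tables.
employment_rate: 0.55
informal_share_employed: 0.3827
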