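# Reference configuration: Ghana (survey year 2017). See brazil.yaml for
# field semantics.
name: ghana
survey_year: 2017
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
  - primary_or_kindergarten
  - secondary_middle_or_incomplete_high
  - complete_high_or_incomplete_higher_or_technical
  - higher_complete_or_more
localities:
  - urban
  - rural
informal_rule: ghana_benefits_and_contract
admin_rate: 0.058
currency_bases: [USD, PPP]

eligible_women: 434410

macro:
  total_population: 30417856
  women_population: 15001771
  gdp_per_capita_ppp: 5413
  working_age_share: 0.5954

welfare_measures:
  minimum_wage:
    kind: minimum_wage
    multiplier: 1
    override_weekly: {USD: "11.7", PPP: "32.6"}
  poverty_line:
    kind: poverty_line
    base_value_per_day_ppp: "3.20"
    multiplier: 1
    override_weekly: {USD: "6.8", PPP: "18.9"}
  twice_poverty_line:
    kind: poverty_line
    base_value_per_day_ppp: "3.20"
    multiplier: 2
    override_weekly: {USD: "13.5", PPP: "37.8"}

weeks_scenarios: [12, 14, 18, 26]

informal_margins:
  age:
    share_pct: [25.9, 15.7, 16.4, 15.5, 26.5]
    birth_pct: [8.5, 16.3, 14.1, 7.3, 2.9]
  marital_status:
    share_pct: [23.6, 65.6, 10.8]
    birth_pct: [2.8, 12.2, 2.8]
  education_level:
    share_pct: [32.3, 19.9, 37.0, 10.6, 0.2]
    birth_pct: [10.7, 10.2, 7.6, 6.4, 4.7]
  locality:
    share_pct: [34.7, 65.3]
    birth_pct: [10.6, 5.9]

employment_rate: 0.65
informal_share_employed: 0.8318
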