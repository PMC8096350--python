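# Base-case inputs for the olaparib vs. placebo maintenance comparison in
# germline BRCA-mutated metastatic pancreatic cancer (POLO trial population),
# from the perspectives of the Chinese and US healthcare systems.
# All monetary values are USD; time in months unless stated.
meta:
  currency: USD
  exchange_rate_yuan_per_usd: 6.8985   # 2020 CNY/USD rate
  schema_version: 1

model:
  cycle_length_days: 21
  horizon_years: 5
  discount_rate_annual: 0.05

survival:
  # Log-logistic rate form S(t) = 1 / (1 + scale * t^shape), t in months.
  convention: rate_form_months
  as_published:
    pfs:
      olaparib: {family: loglogistic, shape: 1.138, scale: 0.010}
      placebo:  {family: loglogistic, shape: 1.888, scale: 0.072}
    os:
      olaparib: {family: loglogistic, shape: 1.403, scale: 0.014}
      placebo:  {family: loglogistic, shape: 1.757, scale: 0.006}
  # Identical except the olaparib-arm PFS scale. The published 0.010 implies a
  # ~57-month median PFS, longer than the same arm's ~21-month median OS and
  # inconsistent with the trial's ~7.4-month median PFS; 0.10 (one decimal
  # shift) reproduces ~7.6 months. Which value actually drove the published
  # totals cannot be determined, so both variants ship and the choice is an
  # explicit config key.
  corrected:
    pfs:
      olaparib: {family: loglogistic, shape: 1.138, scale: 0.10}
      placebo:  {family: loglogistic, shape: 1.888, scale: 0.072}
    os:
      olaparib: {family: loglogistic, shape: 1.403, scale: 0.014}
      placebo:  {family: loglogistic, shape: 1.757, scale: 0.006}

# Health-state utilities, identical across countries and arms; Beta
# distributions in the PSA, parameterized from the 95% credible intervals.
utilities:
  pfs: {value: 0.85, low: 0.68,  high: 1.00,  dist: beta}
  pd:  {value: 0.73, low: 0.584, high: 0.876, dist: beta}

# Cost inputs (USD). "dist: triangular" = triangular(low, mode=value, high)
# in the PSA; the same low/high bound the one-way sensitivity analysis.
costs:
  china:
    drug_olaparib_per_cycle: {value: 7515.2, low: 5636.4, high: 9394.0, dist: triangular}
    ae_unit:
      thrombocytopenia: {value: 23.25, low: 18.6,   high: 27.9,   dist: triangular}
      neutropenia:      {value: 58.07, low: 46.456, high: 69.684, dist: triangular}
      fatigue:          {value: 0.0,   low: 0.0,    high: 0.0,    dist: triangular}
      vomiting:         {value: 3.66,  low: 2.928,  high: 4.392,  dist: triangular}
      anemia:           {value: 0.0,   low: 0.0,    high: 0.0,    dist: triangular}
    followup_per_cycle:
      biochemical:    {value: 25.39, low: 20.312, high: 30.468, dist: triangular}
      blood_routine:  {value: 3.53,  low: 2.824,  high: 4.236,  dist: triangular}
      ct:             {value: 94.58, low: 75.664, high: 113.496, dist: triangular}
    bsc_per_cycle:    {value: 117.12, low: 93.69, high: 140.54, dist: triangular}
    terminal_care:    {value: 1948.42, low: 1558.74, high: 2338.10, dist: triangular}
  us:
    drug_olaparib_per_cycle: {value: 13886.0, low: 10414.5, high: 17357.5, dist: triangular}
    ae_unit:
      thrombocytopenia: {value: 732.3,  low: 585.84,  high: 878.76,   dist: triangular}
      neutropenia:      {value: 867.98, low: 694.384, high: 1041.576, dist: triangular}
      fatigue:          {value: 0.0,    low: 0.0,     high: 0.0,      dist: triangular}
      vomiting:         {value: 678.24, low: 525.592, high: 813.888,  dist: triangular}
      anemia:           {value: 755.92, low: 604.736, high: 907.104,  dist: triangular}
    followup_per_cycle:
      biochemical:    {value: 72.43, low: 50.70, high: 94.16, dist: triangular}
      blood_routine:  {value: 15.23, low: 9.85,  high: 21.75, dist: triangular}
      ct:             {value: 541.7, low: 350.56, high: 773.77, dist: triangular}
    bsc_per_cycle:    {value: 684.31, low: 547.448, high: 821.172, dist: triangular}
    terminal_care:    {value: 85904.0, low: 55592.0, high: 122705.0, dist: triangular}

# Trial-level adverse-event incidence (proportion of patients).
ae_rates:
  olaparib: {thrombocytopenia: 0.11, neutropenia: 0.23, fatigue: 0.60, vomiting: 0.20, anemia: 0.27}
  placebo:  {thrombocytopenia: 0.04, neutropenia: 0.12, fatigue: 0.35, vomiting: 0.15, anemia: 0.17}

wtp:
  us_threshold_usd: 50000
  china_gdp_per_capita_yuan: 70892   # 2019; Chinese threshold = 3x GDP in USD

# Externally reported per-arm discounted totals for the two strategies.
# Kept as reference inputs for incremental/ICER arithmetic and threshold
# verdicts only; the cohort model does not attempt to reproduce them (the
# QALY totals exceed the 4.25-QALY ceiling a 5-year horizon at utility
# <= 0.85 allows, so they are not internally consistent with the stated
# model settings).
reference_totals:
  china:
    olaparib: {cost: 61477.0, qaly: 13.99}
    placebo:  {cost: 2773.0,  qaly: 5.22}
  us:
    olaparib: {cost: 208504.0, qaly: 13.99}
    placebo:  {cost: 91623.0,  qaly: 5.22}
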