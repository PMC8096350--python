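# olacea

Cost-effectiveness analysis of **olaparib maintenance therapy vs.
placebo** for germline *BRCA*-mutated metastatic pancreatic cancer
(POLO trial population), from the perspectives of the Chinese and US
healthcare systems.

Maintenance olaparib prolongs progression-free survival in this
population, but at a high acquisition cost. The package answers the
health-economic question — is the gain worth the price at each
country's willingness-to-pay (WTP) threshold? — with a fully
reproducible pipeline:

1. **Parametric survival modelling** (`olacea.survival`): evaluate, fit
   and compare exponential, Weibull, Gompertz, log-logistic and
   log-normal curves against digitized Kaplan–Meier coordinates. The
   base case uses log-logistic curves in rate form,
   S(t) = 1 / (1 + λ·tᵞ) with t in months, selected by AIC.
2. **Three-state cohort model** (`olacea.markov`): progression-free
   (PFS) → progressed disease (PD) → dead, 21-day cycles over a 5-year
   horizon (86 cycles), 5 %/year discounting of costs and outcomes.
   Default structure is partitioned survival (occupancy read directly
   off the PFS and OS curves); a state-transition backend is available.
3. **Economics** (`olacea.economics`): per-cycle drug and follow-up
   costs during PFS, best-supportive-care costs after progression, a
   one-time terminal-care cost at death, one-time adverse-event costs
   (incidence × unit cost), QALYs as discounted utility-weighted
   life-years, and the incremental cost-effectiveness ratio
   ICER = ΔCost / ΔQALY compared against $50,000/QALY (US) and
   3 × GDP per capita (China).
4. **Sensitivity analysis** (`olacea.sensitivity`): one-way tornado
   analysis over every cost/utility input (±20 % or published ranges),
   and probabilistic sensitivity analysis — 1,000 Monte Carlo
   iterations with Beta-distributed utilities and triangular costs —
   summarized as a cost-effectiveness acceptability curve (CEAC) via
   net monetary benefit λ·ΔQALY − ΔCost.
5. **Synthetic data** (`olacea.synthetic`): digitized-KM-like
   coordinates and pseudo individual-patient event times generated from
   known parametric truths, so the whole fit→model→ICER chain is
   validated by parameter recovery without any external data.

All base-case inputs (survival shape/scale pairs, utilities
0.85 PFS / 0.73 PD, per-country costs, adverse-event incidence, the
6.8985 yuan/USD exchange rate) ship as a validated YAML fixture in
`src/olacea/data/parameters.yaml`.

## Worked example

```python
>>> import olacea as o

>>> # Incremental arithmetic from the reported per-arm totals
>>> o.reference_icers()["china"]
{'incremental_cost': 58704.0, 'incremental_qaly': 8.77, 'icer': 6694.0,
 'threshold': 30829.0, 'verdict': 'below threshold'}
>>> o.reference_icers()["us"]["icer"]
13327.0

>>> # Thresholds: China = 3 x GDP per capita (70,892 yuan) in USD
>>> o.wtp_threshold("china"), o.wtp_threshold("us")
(30829.0, 50000.0)

>>> # Median survival implied by the shipped log-logistic parameters
>>> round(o.median_survival(o.ParametricSurvival("loglogistic", 1.757, 0.006)), 1)
18.4   # placebo overall survival, months
>>> round(o.median_survival(o.ParametricSurvival("loglogistic", 1.888, 0.072)), 1)
4.0    # placebo progression-free survival, months

>>> # The cohort model's own base case (corrected survival variant)
>>> result = o.run_scenario(o.build_scenario("china", variant="corrected"))
>>> round(result.icer.incremental_cost), round(result.icer.incremental_qaly, 3)
(159209, 0.243)
```

The first block reproduces the published incremental comparison from
the reported per-arm totals: olaparib gains 8.77 QALYs at an extra
$58,704 (China) / $116,881 (US), i.e. ICERs of $6,694 and $13,327 per
QALY — both below the respective thresholds. The last block is this
package's own cohort model, which yields a much smaller QALY gain
(≈0.24): the reported absolute totals (13.99 / 5.22 QALYs) exceed the
4.25-QALY ceiling that a 5-year horizon at utility ≤ 0.85 permits, so
they cannot be produced by the stated model settings and are treated as
reference inputs only (see `docs/methods.md`).

A command-line interface wraps the same pipeline:

```bash
olacea run --country china --variant corrected --out results/
olacea report --country us --seed 1 --n 1000 --out results/
olacea synth --family loglogistic --shape 1.4 --scale 0.014 --mode ipd --n 5000 --out ipd.csv
olacea fit --km km.csv
olacea validate
```

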