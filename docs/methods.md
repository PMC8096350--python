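# Methods

## The decision problem

Maintenance olaparib (300 mg b.i.d. until progression) is compared with
placebo in patients with germline BRCA-mutated metastatic pancreatic
cancer whose disease had not progressed on first-line platinum-based
chemotherapy. The analysis is a cohort-level cost-utility model run
separately from the Chinese and the US healthcare perspective. Outcomes
are discounted lifetime costs (USD), discounted quality-adjusted life
years (QALYs), and their ratio for olaparib vs. placebo — the
incremental cost-effectiveness ratio (ICER) — judged against a
willingness-to-pay (WTP) threshold of $50,000/QALY in the US and
3 × GDP per capita (212,676 yuan ≈ $30,829 at 6.8985 yuan/USD) in
China.

## Survival model

State transitions are driven by parametric survival curves for
progression-free survival (PFS) and overall survival (OS), one pair per
arm. All five supported families are kept in *rate form* with a shape
γ and a rate-like scale λ:

| family | S(t) | free parameters |
|---|---|---|
| exponential | exp(−λt) | 1 |
| Weibull | exp(−λtᵞ) | 2 |
| Gompertz | exp(−λ/γ·(e^{γt} − 1)) | 2 (γ may be any real) |
| log-logistic | 1/(1 + λtᵞ) | 2 |
| log-normal | 1 − Φ((ln t − ln λ*)/γ) | 2 (λ* is the median time) |

The base case uses log-logistic curves with **time in months**. This
convention is load-bearing: with it, the shipped (γ, λ) pairs imply
median placebo PFS ≈ 4.0 months, median placebo OS ≈ 18.4 months and
median olaparib OS ≈ 21.0 months — the medians the source trial
reported — whereas reading λ as a characteristic *time* would imply
sub-day medians. The convention is carried as an explicit `time_unit`
field on every curve, and all time conversions (21-day cycle,
30.4375-day month, 365-day year) go through one constants table.

One shipped value deserves a flag: the published olaparib-arm PFS scale
(0.010) implies a ~57-month median PFS, *longer* than the same arm's
~21-month median OS and far from the trial's ~7.4 months. A one-decimal
shift (0.10) reproduces ~7.6 months. Both variants ship in the fixture;
`build_scenario(..., variant=...)` selects one explicitly, the
as-published default emits a warning, and which value produced the
published totals is unknowable. Under the as-published variant the
partitioned-survival engine clamps PD occupancy to zero in the olaparib
arm (PFS curve above OS curve) and counts the clamped boundaries.

### Fitting and model selection

Digitized Kaplan–Meier coordinates are monotonicity-repaired by a
running minimum (raw points preserved), then fitted in two stages:
the family's exact linearizing transform — logit(1 − S) vs ln t for
log-logistic, ln(−ln S) vs ln t for Weibull, probit for log-normal —
gives starting values, refined by Levenberg–Marquardt least squares on
the survival scale (log-parameter space, so positivity is structural).
Points with t = 0 or S ∈ {0, 1} carry no information on the linearized
scale and are excluded; at least three usable points are required.
Noise-free coordinates are recovered exactly (the linearization is an
identity there), which the tests assert at 1e−6 relative.

Families are compared by the Gaussian least-squares AIC,
n·ln(SSE/n) + 2k, minimum wins; exact ties go to fewer parameters, then
to a fixed family order. A maximum-likelihood backend on (pseudo)
individual-patient data, backed by lifelines, is provided as an
independent cross-check of the default route, not as the default.

On pseudo individual-patient data at n = 5,000 with 10 % censoring, the
fit recovers the generating log-logistic parameters within
pilot-calibrated bands of ±0.10 on the shape and ±35 % relative on the
scale (20 seeds; observed pilot maxima were about half each band).
Family *discrimination* is a harder problem than parameter recovery:
log-logistic and log-normal differ only in a logistic-vs-normal kernel
on log-time, and at n = 200 the AIC comparison identifies the
generating log-logistic in roughly two-thirds of seeded replicates
(32/50 in the suite's own run). The selection rate is invariant to the
generating (γ, λ) — both merely relocate/rescale log-time, under which
every competing family is closed — so only larger samples sharpen it.

## Cohort model

Three mutually exclusive states: progression-free (PFS, everyone starts
here), progressed disease (PD), dead (absorbing; no return from PD to
PFS). Cycles are 21 days; the 5-year horizon gives ⌊1825/21⌋ = 86 full
cycles, and a trace holds the 87 cycle boundaries.

The default structure is **partitioned survival**: at each boundary t,
PFS = min(S_pfs(t), S_os(t)), Dead = 1 − S_os(t), PD is the remainder
(≥ 0 by construction). This uses exactly the two published curves and
avoids inventing the unidentified split of PFS exits between
progression and death. A conventional **state-transition** backend
(per-cycle conditional probabilities; PFS exits split into death at the
OS hazard and progression as the remainder) is retained to probe that
structural choice; for exponential curves the two coincide identically,
which the tests exploit at 1-day cycles.

Discounting is continuous in fractional years, (1 + r)^(−c·21/365)
with r = 0.05/year, rather than annual steps — smooth, and stated
rather than implied. Conservation (occupancies summing to 1 within
1e−12) is asserted both at trace construction and across 1,000
randomized curve pairs in the acceptance suite.

## Economics

Per cycle, full occupancy of a state accrues:

* **PFS**: drug acquisition cost (olaparib arm only — maintenance runs
  until progression) + follow-up tests (biochemistry, blood routine,
  CT). The "follow-up throughout treatment" rule is read as "for the
  duration of maintenance, i.e. while progression-free".
* **PD**: best supportive care only.
* **utility**: 0.85 (PFS) or 0.73 (PD), × 21/365 years, identical
  across arms and countries.

One-time costs: adverse-event management (trial-level incidence × unit
cost, summed over thrombocytopenia, neutropenia, fatigue, vomiting and
anemia) charged to the whole cohort at model entry in both arms — the
incidence rates are per-patient-per-trial, not per-cycle hazards — and
terminal care paid for the newly dead fraction at each boundary,
discounted at that boundary (end-of-cycle convention; the alternative
conventions differ by under one cycle of discounting). Payoffs accrue
on start-of-cycle occupancy discounted at the cycle-start factor; a
half-cycle correction (boundary-mean occupancy) is available as a flag
and off by default. Reported dollars round half-up to whole dollars;
yuan enters only through the explicit conversion at 6.8985 yuan/USD.

Dominance handling in `compute_icer`: positive ΔQALY at non-positive
ΔCost → dominant; non-positive ΔQALY at non-negative ΔCost →
dominated; both increments zero → undefined; otherwise the ratio.

### Why the published absolute totals are not a target

The published per-arm totals (13.99 / 5.22 QALYs) exceed the hard
ceiling 5 years × 0.85 = 4.25 QALYs that the stated horizon and
utilities permit, so no parameterization of the stated model can
produce them. The package therefore treats them as *reference inputs*:
the incremental arithmetic computed from them (ΔCost $58,704 China /
$116,881 US, ΔQALY 8.77, ICERs $6,694 and $13,327) is reproduced
exactly, while the cohort model's own totals (≈1.4–1.8 QALYs per arm,
ΔQALY ≈ 0.24 under the corrected variant) are reported as what the
stated settings actually yield. The model's validity rests on the
property checks (conservation, closed-form discounting, parameter
recovery, CEAC enumeration, determinism) rather than on matching
unreachable totals; PSA percentages conditioned on those totals are
likewise reported but not matched.

## Sensitivity analysis

**One-way (tornado)**: every cost and utility entry plus the discount
rate is set to its lower and upper bound in turn (published ranges
where given, ±20 % otherwise — the discount rate uses 0.04–0.06), the
pipeline reruns, and entries are sorted by descending ICER spread with
name as tie-break. A failing bound run flags its entry and the analysis
continues.

**Probabilistic**: 1,000 iterations by default. Utilities draw from
Beta distributions matched by method of moments to the published mean
and 95 % interval — σ = (high − low)/3.92, α = mean·(mean(1−mean)/σ² − 1)
— which preserves the mean exactly; if the implied variance exceeds the
Beta-attainable maximum, it is shrunk to 99 % of that maximum (mean
still exact). Costs draw from triangular(low, mode = base, high); the
"T" distribution code on cost inputs is read as triangular. Utilities
are drawn once per iteration and shared across arms (the arms carry
identical utilities), and per-country unit costs are shared likewise,
so each draw moves both arms coherently. Parameters are independent (no
correlation structure is published); survival parameters stay fixed in
the PSA, and the discount rate enters the one-way analysis only.
Draw i uses the substream `SeedSequence(seed).spawn()[i]`, making the
sample file byte-identical across runs and independent of execution
order. The CEAC reports, per WTP value on a $0–60,000 grid (both
thresholds covered), the fraction of draws with strictly positive net
monetary benefit λ·ΔQALY − ΔCost; ties count as not cost-effective.

## Synthetic data

The original analysis digitized published KM figures; no patient-level
data exists to ship. The generator therefore emulates both input kinds
from a known truth: (a) *digitized coordinates* — the true S(t) on a
monthly 1–36-month grid (the published follow-up span) plus Gaussian
jitter of sd 0.01 survival units (a typical digitization error),
clipped and monotonicity-repaired; (b) *pseudo individual-patient
times* — inverse-CDF draws (closed forms for log-logistic, Weibull,
exponential), with a Bernoulli-selected fraction of subjects censored
uniformly before their event. Kaplan–Meier estimation of pseudo-IPD
uses lifelines. Everything is a pure function of (truth, seed).

What passing these checks shows — and does not: recovery from jitter-0
or large-n synthetic data validates the estimators and the pipeline
plumbing, under exactly-true parametric forms, independent censoring
and known grids. Real digitized curves add correlated reading errors,
step-function coarseness at risk-set depletion, and model
misspecification, none of which the generator emulates.

## Problem sizes and numerical choices

The suite runs the conservation sweep at 1,000 random curve pairs,
parameter recovery at 20 seeds × n = 5,000, model selection at 50 seeds
× n = 200, and PSA determinism at 1,000 iterations — a few seconds in
total, chosen as the smallest sizes at which the Monte Carlo bands are
meaningful. Other numerics: SSE is floored at 1e−300 inside the AIC so
machine-perfect fits stay finite; medians use closed forms (the
defective Gompertz case returns ∞); conditional transition
probabilities clamp to [0, 1] and raise on an exhausted cohort
(S(t_start) = 0); PD clamping in partitioned survival is counted and
warned, never silent.

## Known limitations

* Cohort-level model with memory only through the survival curves; no
  tunnel states, time-varying utilities or AE disutilities (the source
  analysis excluded them too).
* The published totals' internal inconsistency means the model's own
  absolute results are *not* comparable to them; only the incremental
  arithmetic from the reported totals is reproduced.
* Family selection at digitized-curve sample sizes has limited power
  against the log-normal alternative (see above).
* Indirect/societal costs are out of scope; costs are 2020 USD with no
  price-year re-indexing.
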