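"""Costs, utilities and incremental cost-effectiveness.

Costing rules
-------------
* Progression-free state: drug acquisition cost (olaparib arm only —
  maintenance runs until progression) plus follow-up tests
  (biochemistry, blood routine, CT), per cycle.
* Progressed state: best supportive care (BSC) is the only cost.
* Death: a one-time terminal-care cost paid for the fraction newly dead
  each cycle, discounted at that cycle (end-of-cycle convention).
* Adverse events: trial-level incidence rates x unit management costs,
  charged once to the whole cohort at model entry in both arms (the
  rates are per patient over the trial, not per-cycle hazards).

QALYs accrue as occupancy x state utility x cycle length in years,
discounted with the same factors as costs.  All amounts are USD; yuan
appears only at the explicit conversion boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping

import numpy as np

from . import constants
from .markov import CohortTrace, ModelSpec

__all__ = [
    "AE_NAMES",
    "CountryArmInputs",
    "CEAResult",
    "ICERResult",
    "ae_onetime_cost",
    "cycle_payoffs",
    "accumulate",
    "compute_icer",
    "convert_currency",
    "wtp_threshold",
    "round_half_up",
]

#: The adverse events tracked by the model.
AE_NAMES = ("thrombocytopenia", "neutropenia", "fatigue", "vomiting", "anemia")


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal half-up rounding (matches whole-dollar reporting)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CountryArmInputs:
    """Cost, adverse-event and utility inputs for one (country, arm) pair.

    All monetary fields are USD.  ``drug_cost_per_cycle`` is zero by
    construction in the placebo arm; ``followup_cost_per_cycle`` is the
    sum of the biochemistry, blood-routine and CT charges per cycle.
    """

    country: str  # "china" | "us"
    arm: str  # "olaparib" | "placebo"
    drug_cost_per_cycle: float
    followup_cost_per_cycle: float
    bsc_cost_per_cycle: float
    terminal_care_cost: float
    ae_unit_costs: Mapping[str, float]
    ae_rates: Mapping[str, float]
    utility_pfs: float
    utility_pd: float

    def __post_init__(self) -> None:
        for name in (
            "drug_cost_per_cycle",
            "followup_cost_per_cycle",
            "bsc_cost_per_cycle",
            "terminal_care_cost",
        ):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        for name in ("utility_pfs", "utility_pd"):
            u = getattr(self, name)
            if not 0.0 <= u <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {u}")
        for ae, c in self.ae_unit_costs.items():
            if c < 0:
                raise ValueError(f"AE unit cost for {ae} must be >= 0")
        for ae, r in self.ae_rates.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"AE rate for {ae} must lie in [0, 1]")

    def utility(self, state: str) -> float:
        if state == "pfs":
            return self.utility_pfs
        if state == "pd":
            return self.utility_pd
        raise ValueError(f"no utility for state {state!r}")


@dataclass(frozen=True)
class CEAResult:
    """Discounted totals for one arm, with the cost breakdown."""

    arm: str
    total_cost: float
    total_qaly: float
    breakdown: Mapping[str, float]  # drug, followup, ae, bsc, terminal

    def __post_init__(self) -> None:
        if abs(sum(self.breakdown.values()) - self.total_cost) > 1e-8:
            raise ValueError("cost breakdown must sum to the total cost")


@dataclass(frozen=True)
class ICERResult:
    """Pairwise incremental comparison: intervention minus comparator."""

    incremental_cost: float
    incremental_qaly: float
    icer: float  # NaN unless status == "defined"
    status: str  # "defined" | "dominant" | "dominated" | "undefined"

    @property
    def icer_rounded(self) -> float:
        """Whole-dollar ICER as reported."""
        if self.status != "defined":
            return math.nan
        return round_half_up(self.icer)


def ae_onetime_cost(inputs: CountryArmInputs) -> float:
    """Sum over adverse events of incidence rate x unit management cost,
    applied once at model entry."""
    if set(inputs.ae_rates) != set(inputs.ae_unit_costs):
        raise ValueError(
            "AE rate and unit-cost tables must cover the same adverse events; "
            f"got {sorted(inputs.ae_rates)} vs {sorted(inputs.ae_unit_costs)}"
        )
    return float(sum(inputs.ae_rates[ae] * inputs.ae_unit_costs[ae] for ae in inputs.ae_rates))


def cycle_payoffs(state: str, inputs: CountryArmInputs, spec: ModelSpec) -> dict[str, float]:
    """Per-cycle cost (USD) and QALY accrued by full occupancy of a living state."""
    if state == "pfs":
        cost = inputs.drug_cost_per_cycle + inputs.followup_cost_per_cycle
    elif state == "pd":
        cost = inputs.bsc_cost_per_cycle
    else:
        raise ValueError(
            "cycle payoffs are defined for living states only; "
            "terminal care is a one-time cost at death"
        )
    qaly = inputs.utility(state) * spec.cycle_length_years
    return {"cost": cost, "qaly": qaly}


def accumulate(trace: CohortTrace, inputs: CountryArmInputs, spec: ModelSpec) -> CEAResult:
    """Discounted lifetime cost and QALY totals for one arm.

    Living-state payoffs accrue on start-of-cycle occupancy discounted
    at the cycle-start factor (boundary-mean occupancy instead when the
    half-cycle correction is on); the terminal-care cost is paid for the
    newly dead at each boundary, discounted there.
    """
    n = spec.n_cycles
    df_start = trace.discount[:n]

    def exposure(state: str) -> float:
        occ = trace.occupancy(state)
        if spec.half_cycle_correction:
            per_cycle = 0.5 * (occ[:n] + occ[1 : n + 1])
        else:
            per_cycle = occ[:n]
        return float(np.sum(per_cycle * df_start))

    pfs_exp = exposure("pfs")
    pd_exp = exposure("pd")

    drug = pfs_exp * inputs.drug_cost_per_cycle
    followup = pfs_exp * inputs.followup_cost_per_cycle
    bsc = pd_exp * inputs.bsc_cost_per_cycle
    terminal = float(
        np.sum(trace.newly_dead[1 : n + 1] * trace.discount[1 : n + 1])
        * inputs.terminal_care_cost
    )
    ae = ae_onetime_cost(inputs)

    qaly = (pfs_exp * inputs.utility_pfs + pd_exp * inputs.utility_pd) * spec.cycle_length_years

    breakdown = {"drug": drug, "followup": followup, "ae": ae, "bsc": bsc, "terminal": terminal}
    return CEAResult(inputs.arm, float(sum(breakdown.values())), qaly, breakdown)


def compute_icer(a: CEAResult, b: CEAResult) -> ICERResult:
    """Incremental comparison of intervention ``a`` against comparator ``b``."""
    dc = a.total_cost - b.total_cost
    dq = a.total_qaly - b.total_qaly
    if dc == 0.0 and dq == 0.0:
        return ICERResult(dc, dq, math.nan, "undefined")
    if dq > 0.0 and dc <= 0.0:
        return ICERResult(dc, dq, math.nan, "dominant")
    if dq <= 0.0 and dc >= 0.0:
        return ICERResult(dc, dq, math.nan, "dominated")
    return ICERResult(dc, dq, dc / dq, "defined")


def convert_currency(amount_yuan: float, rate: float = constants.YUAN_PER_USD) -> float:
    """Yuan to USD at ``rate`` yuan per dollar (unrounded; round when reporting)."""
    if rate <= 0:
        raise ValueError("exchange rate must be > 0")
    return amount_yuan / rate


def wtp_threshold(
    country: str,
    gdp_per_capita_yuan: float = constants.CHINA_GDP_PER_CAPITA_YUAN,
    rate: float = constants.YUAN_PER_USD,
) -> float:
    """Willingness-to-pay threshold in $/QALY.

    US: fixed $50,000.  China: 3x GDP per capita (WHO convention),
    converted to USD and rounded to whole dollars.
    """
    if country == "us":
        return constants.US_WTP_USD_PER_QALY
    if country == "china":
        if gdp_per_capita_yuan < 0 or rate <= 0:
            raise ValueError("GDP and exchange rate must be positive")
        return round_half_up(convert_currency(3.0 * gdp_per_capita_yuan, rate))
    raise ValueError(f"unknown country {country!r}")
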