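"""Three-state cohort model: progression-free (PFS), progressed disease
(PD, the post-progression "progression survival" state) and death.

The whole cohort starts progression-free; patients progress and die but
never return to the progression-free state.  By default the trace is
built by *partitioned survival*: state occupancy is read directly off
the fitted PFS and OS curves at each cycle boundary

    PFS(t) = min(S_pfs(t), S_os(t)),   Dead(t) = 1 - S_os(t),
    PD(t)  = 1 - PFS(t) - Dead(t)  (>= 0 by construction),

which uses exactly the two published curves and needs no assumption
about how progression-free exits split between progression and death.
A conventional state-transition backend (per-cycle conditional
probabilities, no PD -> PFS edge) is kept to probe sensitivity to that
structural choice; with exponential curves the two coincide.

Discounting uses continuous fractional-year exponents,
``(1 + r)**(-cycle * 21/365)``, rather than annual steps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import constants
from .survival import CohortExhaustedError, ParametricSurvival

__all__ = ["ModelSpec", "CohortTrace", "build_trace", "discount_factor", "occupancy_time"]

STATES = ("pfs", "pd", "dead")

_UNIT_TO_DAYS = {"days": 1.0, "months": constants.DAYS_PER_MONTH, "years": constants.DAYS_PER_YEAR}


@dataclass(frozen=True)
class ModelSpec:
    """Structural settings of the cohort model.

    Defaults are the base case: 21-day cycles over a 5-year horizon,
    5%/year discounting of costs and outcomes, partitioned survival,
    no half-cycle correction.
    """

    cycle_length_days: float = constants.CYCLE_LENGTH_DAYS
    horizon_years: float = constants.HORIZON_YEARS
    discount_rate_annual: float = constants.DISCOUNT_RATE_ANNUAL
    structure: str = "partitioned_survival"
    half_cycle_correction: bool = False

    def __post_init__(self) -> None:
        if self.cycle_length_days <= 0 or self.horizon_years <= 0:
            raise ValueError("cycle length and horizon must be positive")
        if not 0.0 <= self.discount_rate_annual < 1.0:
            raise ValueError("discount rate must lie in [0, 1)")
        if self.structure not in ("partitioned_survival", "state_transition"):
            raise ValueError(f"unknown structure {self.structure!r}")
        if self.n_cycles < 1:
            raise ValueError("horizon must cover at least one full cycle")

    @property
    def n_cycles(self) -> int:
        return int(self.horizon_years * constants.DAYS_PER_YEAR // self.cycle_length_days)

    @property
    def cycle_length_years(self) -> float:
        return self.cycle_length_days / constants.DAYS_PER_YEAR

    def cycle_times(self, unit: str) -> np.ndarray:
        """Cycle-boundary times 0..n_cycles in the requested unit."""
        cycles = np.arange(self.n_cycles + 1)
        return cycles * self.cycle_length_days / _UNIT_TO_DAYS[unit]


def discount_factor(spec: ModelSpec, cycle) -> float | np.ndarray:
    """(1+r)^(-t) with t the fractional years elapsed at a cycle boundary."""
    cycle_arr = np.asarray(cycle)
    if np.any(cycle_arr < 0):
        raise ValueError("cycle must be >= 0")
    t_years = cycle_arr * spec.cycle_length_years
    out = (1.0 + spec.discount_rate_annual) ** (-t_years)
    return float(out) if np.ndim(cycle) == 0 else out


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle state occupancy at cycle boundaries 0..n_cycles.

    ``newly_dead[c]`` is the fraction dying during cycle c (between
    boundaries c-1 and c); it is 0 at cycle 0 and sums to the final
    dead fraction.
    """

    spec: ModelSpec
    pfs: np.ndarray
    pd: np.ndarray
    dead: np.ndarray
    n_clamped: int = 0  # boundaries where S_pfs > S_os forced PD to 0

    def __post_init__(self) -> None:
        for name in ("pfs", "pd", "dead"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.spec.n_cycles + 1
        if not (len(self.pfs) == len(self.pd) == len(self.dead) == n):
            raise ValueError("trace arrays must have n_cycles + 1 boundary rows")
        total = self.pfs + self.pd + self.dead
        if np.max(np.abs(total - 1.0)) > 1e-9:
            raise ValueError("state occupancies must sum to 1 at every cycle")
        if np.any(np.diff(self.dead) < -1e-12):
            raise ValueError("dead occupancy must be non-decreasing")

    @property
    def cycles(self) -> np.ndarray:
        return np.arange(self.spec.n_cycles + 1)

    @property
    def time_years(self) -> np.ndarray:
        return self.cycles * self.spec.cycle_length_years

    @property
    def newly_dead(self) -> np.ndarray:
        return np.concatenate([[0.0], np.maximum(np.diff(self.dead), 0.0)])

    @property
    def discount(self) -> np.ndarray:
        return discount_factor(self.spec, self.cycles)

    def occupancy(self, state: str) -> np.ndarray:
        if state not in STATES:
            raise ValueError(f"unknown state {state!r}; expected one of {STATES}")
        return getattr(self, state)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cycle": self.cycles,
                "time_years": self.time_years,
                "pfs": self.pfs,
                "pd": self.pd,
                "dead": self.dead,
                "newly_dead": self.newly_dead,
                "discount_factor": self.discount,
            }
        )


def _curve_times(spec: ModelSpec, curve: ParametricSurvival) -> np.ndarray:
    return spec.cycle_times(curve.time_unit)


def build_trace(
    spec: ModelSpec, s_pfs: ParametricSurvival, s_os: ParametricSurvival
) -> CohortTrace:
    """Run the cohort model and return the boundary-by-boundary trace.

    With fit or digitization noise the PFS curve can sit above the OS
    curve; the partitioned-survival backend then clamps PD at zero
    (PFS = S_os there) and counts the affected boundaries in
    ``n_clamped``, warning once per trace.
    """
    if spec.structure == "partitioned_survival":
        s_p = np.asarray(s_pfs.survival(_curve_times(spec, s_pfs)))
        s_o = np.asarray(s_os.survival(_curve_times(spec, s_os)))
        n_clamped = int(np.sum(s_p > s_o + 1e-15))
        if n_clamped:
            warnings.warn(
                f"PFS curve exceeds OS curve at {n_clamped} cycle boundaries; "
                "PD occupancy clamped to 0 there",
                stacklevel=2,
            )
        pfs = np.minimum(s_p, s_o)
        dead = 1.0 - s_o
        pd_ = 1.0 - pfs - dead
        return CohortTrace(spec, pfs, pd_, dead, n_clamped)

    # state-transition backend
    t_p = _curve_times(spec, s_pfs)
    t_o = _curve_times(spec, s_os)
    n = spec.n_cycles
    pfs = np.empty(n + 1)
    pd_ = np.empty(n + 1)
    dead = np.empty(n + 1)
    pfs[0], pd_[0], dead[0] = 1.0, 0.0, 0.0
    for c in range(n):
        try:
            q_die = s_os.transition_probability(t_o[c], t_o[c + 1])
        except CohortExhaustedError:
            q_die = 1.0
        try:
            q_exit = s_pfs.transition_probability(t_p[c], t_p[c + 1])
        except CohortExhaustedError:
            q_exit = 1.0
        # exits from PFS split into death (OS hazard applies to everyone
        # alive) and progression (the remainder of PFS attrition)
        q_prog = min(max(q_exit - q_die, 0.0), 1.0 - q_die)
        pfs[c + 1] = pfs[c] * (1.0 - q_die - q_prog)
        pd_[c + 1] = pd_[c] * (1.0 - q_die) + pfs[c] * q_prog
        dead[c + 1] = dead[c] + (pfs[c] + pd_[c]) * q_die
    return CohortTrace(spec, pfs, pd_, dead)


def occupancy_time(trace: CohortTrace, state: str, discounted: bool = False) -> float:
    """Time spent in a state over the horizon, in years.

    Start-of-cycle occupancy accrues for the whole cycle (discounted at
    the cycle-start factor when requested); with the half-cycle
    correction enabled in the spec, the mean of the two boundary
    occupancies is used instead.
    """
    occ = trace.occupancy(state)
    n = trace.spec.n_cycles
    if trace.spec.half_cycle_correction:
        per_cycle = 0.5 * (occ[:n] + occ[1 : n + 1])
    else:
        per_cycle = occ[:n]
    weights = trace.discount[:n] if discounted else np.ones(n)
    return float(np.sum(per_cycle * weights) * trace.spec.cycle_length_years)
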