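"""Synthetic inputs: digitized-KM-like coordinates and pseudo
individual-patient data (IPD) from known parametric truths.

No patient-level data from the source trial is available — the original
analysis digitized published Kaplan-Meier figures.  This module
generates the same kinds of input from a *known* survival curve so the
whole pipeline (digitize -> fit -> select -> model) can be validated by
parameter recovery:

* :func:`generate_km_points` evaluates the true curve on a time grid and
  adds Gaussian digitization jitter (clipped to [0, 1] and
  monotonicity-repaired), emulating coordinates read off a figure.
* :func:`simulate_ipd` draws event times by inverse-CDF sampling with
  optional uniform censoring, giving pseudo-IPD whose Kaplan-Meier
  estimate can be fed back into the fitting route.

Every generator is a pure function of its inputs and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .survival import KMCurvePoints, ParametricSurvival, SurvivalFamily

__all__ = ["SyntheticTruth", "generate_km_points", "simulate_ipd", "km_from_ipd"]

#: Default digitization grid: monthly points over a 36-month follow-up
#: span (the span of the source trial's published curves).
DEFAULT_GRID_MONTHS = np.arange(1.0, 37.0)

#: Default digitization error, in survival-probability units.
DEFAULT_JITTER_SD = 0.01


@dataclass(frozen=True)
class SyntheticTruth:
    """A known generating curve plus sampling settings.

    ``grid`` drives the digitized-coordinate mode; ``n_subjects`` and
    ``censoring_rate`` drive the pseudo-IPD mode.
    """

    model: ParametricSurvival
    n_subjects: int = 500
    censoring_rate: float = 0.0
    grid: np.ndarray = field(default_factory=lambda: DEFAULT_GRID_MONTHS.copy())
    jitter_sd: float = DEFAULT_JITTER_SD
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "grid", np.asarray(self.grid, dtype=float))
        if self.grid.size and np.any(self.grid < 0):
            raise ValueError("grid times must be >= 0")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ValueError("censoring rate must lie in [0, 1)")
        if self.jitter_sd < 0:
            raise ValueError("jitter sd must be >= 0")
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")


def generate_km_points(
    truth: SyntheticTruth, endpoint: str = "PFS", arm: str = "olaparib"
) -> KMCurvePoints:
    """Digitized-coordinate emulation: S(t) on the grid plus clipped
    Gaussian jitter, monotonicity-repaired.  Deterministic under the
    truth's seed."""
    if truth.grid.size == 0:
        raise ValueError("digitized-coordinate generation requires a non-empty grid")
    rng = np.random.default_rng(truth.seed)
    s = np.asarray(truth.model.survival(truth.grid), dtype=float)
    if truth.jitter_sd > 0:
        s = np.clip(s + rng.normal(0.0, truth.jitter_sd, size=s.shape), 0.0, 1.0)
    return KMCurvePoints(endpoint, arm, truth.grid, s).repair_monotonic()


_INVERTIBLE = (SurvivalFamily.LOGLOGISTIC, SurvivalFamily.WEIBULL, SurvivalFamily.EXPONENTIAL)


def simulate_ipd(truth: SyntheticTruth) -> pd.DataFrame:
    """Pseudo individual-patient event times by inverse-CDF sampling.

    Draw a survival quantile u ~ U(0,1) per subject and invert S:
    log-logistic ``t = ((1-u)/(u*lam))**(1/gamma)``, Weibull
    ``t = (-ln(u)/lam)**(1/gamma)``, exponential ``t = -ln(u)/lam``.
    A ``censoring_rate`` fraction of subjects (Bernoulli per subject) is
    administratively censored at a uniform time before their event.

    Returns a frame with columns ``id``, ``time``, ``event``.
    """
    model = truth.model
    if model.family not in _INVERTIBLE:
        raise NotImplementedError(
            f"inverse-CDF sampling is not implemented for {model.family.value}"
        )
    rng = np.random.default_rng(truth.seed)
    n = truth.n_subjects
    u = rng.uniform(size=n)
    gamma, lam = model.shape, model.scale
    if model.family is SurvivalFamily.LOGLOGISTIC:
        t = ((1.0 - u) / (u * lam)) ** (1.0 / gamma)
    elif model.family is SurvivalFamily.WEIBULL:
        t = (-np.log(u) / lam) ** (1.0 / gamma)
    else:
        t = -np.log(u) / lam
    event = np.ones(n, dtype=int)
    if truth.censoring_rate > 0:
        censored = rng.uniform(size=n) < truth.censoring_rate
        t = np.where(censored, rng.uniform(0.0, t), t)
        event = np.where(censored, 0, 1)
    return pd.DataFrame({"id": np.arange(n), "time": t, "event": event})


def km_from_ipd(
    ipd: pd.DataFrame, endpoint: str = "PFS", arm: str = "olaparib"
) -> KMCurvePoints:
    """Kaplan-Meier estimate of (pseudo) IPD as digitized-style points.

    Uses the lifelines product-limit estimator; the step values at the
    observed event times become the coordinate set (the t = 0, S = 1
    anchor is dropped since it carries no fitting information).
    """
    from lifelines import KaplanMeierFitter

    km = KaplanMeierFitter()
    km.fit(ipd["time"], event_observed=ipd["event"])
    sf = km.survival_function_.iloc[:, 0]
    t = sf.index.to_numpy(dtype=float)
    s = sf.to_numpy(dtype=float)
    mask = t > 0
    return KMCurvePoints(endpoint, arm, t[mask], s[mask])
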