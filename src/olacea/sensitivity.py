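"""Deterministic and probabilistic sensitivity analysis.

One-way (tornado) analysis reruns the full pipeline with each parameter
at its lower and upper bound while everything else stays at base.  The
probabilistic analysis draws every uncertain parameter jointly — Beta
for utilities (method-of-moments on the published mean and 95% credible
interval), triangular(low, mode=base, high) for costs — over 1,000
Monte Carlo iterations by default, and summarizes the draws as a
cost-effectiveness acceptability curve via net monetary benefit.

Utilities are drawn once per iteration and shared across arms (the two
arms carry identical state utilities); per-country unit costs are
likewise shared, so a single draw moves both arms coherently.
Reproducibility comes from one master seed with per-draw substreams
spawned through :class:`numpy.random.SeedSequence`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fixtures import FOLLOWUP_COMPONENTS
from .scenario import BaseCaseResult, run_scenario, set_path

__all__ = [
    "ParamSpec",
    "TornadoEntry",
    "CEACPoint",
    "make_beta_from_mean_interval",
    "build_param_specs",
    "sample_params",
    "one_way_dsa",
    "run_psa",
    "ceac",
    "default_wtp_grid",
]


@dataclass(frozen=True)
class ParamSpec:
    """One uncertain model input.

    ``targets`` are the dotted scenario paths the parameter binds; a
    single draw is written to every target, so quantities shared across
    arms (utilities, unit costs) move together.
    """

    name: str
    base: float
    low: float
    high: float
    dist: str  # "beta" | "triangular" | "fixed"
    targets: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.low <= self.base <= self.high:
            raise ValueError(f"{self.name}: need low <= base <= high")
        if self.dist not in ("beta", "triangular", "fixed"):
            raise ValueError(f"{self.name}: unknown distribution {self.dist!r}")
        if self.dist == "beta" and not (0.0 <= self.low and self.high <= 1.0):
            raise ValueError(f"{self.name}: beta requires values in [0, 1]")
        if not self.targets:
            raise ValueError(f"{self.name}: at least one target path required")


@dataclass(frozen=True)
class TornadoEntry:
    """One bar of the tornado diagram."""

    name: str
    low: float
    high: float
    icer_low: float
    icer_high: float
    failed: bool = False

    @property
    def spread(self) -> float:
        if self.failed:
            return 0.0
        return abs(self.icer_high - self.icer_low)


@dataclass(frozen=True)
class CEACPoint:
    wtp: float
    probability: float


def make_beta_from_mean_interval(mean: float, low: float, high: float) -> tuple[float, float]:
    """Beta(alpha, beta) matching a mean and a 95% interval.

    The interval width estimates the standard deviation as
    ``(high - low)/3.92`` (normal 95% convention); method of moments
    then gives ``alpha = mean*(mean*(1-mean)/sigma**2 - 1)``.  If the
    implied variance is not attainable by a Beta with that mean
    (``sigma**2 >= mean*(1-mean)``), the variance is shrunk to 99% of
    the attainable maximum so the mean is always preserved exactly.
    """
    if not 0.0 < mean < 1.0:
        raise ValueError("mean must lie strictly inside (0, 1)")
    if not low < mean < high <= 1.0:
        raise ValueError("need low < mean < high <= 1")
    sigma = (high - low) / 3.92
    var = sigma * sigma
    var_max = mean * (1.0 - mean)
    if var >= var_max:
        var = 0.99 * var_max
    alpha = mean * (var_max / var - 1.0)
    beta = alpha * (1.0 - mean) / mean
    return alpha, beta


def build_param_specs(
    fixture: dict, country: str, include_discount_rate: bool = True
) -> list[ParamSpec]:
    """The standard uncertain-parameter set for one country.

    Every cost and utility entry of the fixture, each with its printed
    range, plus (for the one-way analysis) the annual discount rate at
    +/-20% of base.  Entries with a degenerate range (zero-cost adverse
    events) are carried as fixed.
    """
    cc = fixture["costs"][country]
    specs: list[ParamSpec] = []

    def cost_spec(name: str, entry: Mapping, *targets: str) -> ParamSpec:
        dist = entry["dist"] if entry["low"] < entry["high"] else "fixed"
        return ParamSpec(name, entry["value"], entry["low"], entry["high"], dist, targets)

    specs.append(
        cost_spec("drug_olaparib", cc["drug_olaparib_per_cycle"], "costs.drug_olaparib_per_cycle")
    )
    for ae, entry in cc["ae_unit"].items():
        specs.append(cost_spec(f"ae_unit_{ae}", entry, f"costs.ae_unit.{ae}"))
    for comp in FOLLOWUP_COMPONENTS:
        specs.append(
            cost_spec(
                f"followup_{comp}",
                cc["followup_per_cycle"][comp],
                f"costs.followup_per_cycle.{comp}",
            )
        )
    specs.append(cost_spec("bsc", cc["bsc_per_cycle"], "costs.bsc_per_cycle"))
    specs.append(cost_spec("terminal_care", cc["terminal_care"], "costs.terminal_care"))

    for state in ("pfs", "pd"):
        u = fixture["utilities"][state]
        specs.append(
            ParamSpec(
                f"utility_{state}",
                u["value"],
                u["low"],
                u["high"],
                u["dist"],
                (f"utilities.{state}",),
            )
        )
    if include_discount_rate:
        r = fixture["model"]["discount_rate_annual"]
        specs.append(
            ParamSpec("discount_rate", r, 0.8 * r, 1.2 * r, "fixed", ("model.discount_rate_annual",))
        )
    return specs


def _apply(scenario: dict, values: Mapping[str, float], specs: Sequence[ParamSpec]) -> dict:
    import copy

    out = copy.deepcopy(scenario)
    by_name = {s.name: s for s in specs}
    for name, value in values.items():
        for target in by_name[name].targets:
            set_path(out, target, float(value))
    return out


def sample_params(
    specs: Sequence[ParamSpec], seed: int | np.random.Generator
) -> dict[str, float]:
    """One joint draw of all uncertain parameters.

    Beta parameters are drawn from the interval-matched Beta; triangular
    from triangular(low, mode=base, high); fixed pass through at base.
    Identical seeds yield identical draws.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draw: dict[str, float] = {}
    for spec in specs:
        if spec.dist == "fixed" or spec.low == spec.high:
            draw[spec.name] = spec.base
        elif spec.dist == "beta":
            alpha, beta = make_beta_from_mean_interval(spec.base, spec.low, spec.high)
            draw[spec.name] = float(rng.beta(alpha, beta))
        else:
            draw[spec.name] = float(rng.triangular(spec.low, spec.base, spec.high))
    return draw


def _icer_value(result: BaseCaseResult) -> float:
    """ICER as a signed ratio for tornado ordering (NaN when both
    increments vanish)."""
    if result.icer.status == "defined":
        return result.icer.icer
    if result.icer.incremental_qaly == 0.0:
        return math.nan
    return result.icer.incremental_cost / result.icer.incremental_qaly


def one_way_dsa(scenario: dict, specs: Sequence[ParamSpec]) -> list[TornadoEntry]:
    """One-way deterministic sensitivity analysis.

    Each parameter in turn is set to its low and to its high bound (all
    others at base) and the pipeline is rerun; entries come back sorted
    by descending ICER spread, ties broken by parameter name.  A failing
    low/high run flags the entry rather than aborting the analysis.
    """
    entries: list[TornadoEntry] = []
    for spec in specs:
        try:
            icer_low = _icer_value(run_scenario(_apply(scenario, {spec.name: spec.low}, [spec])))
            icer_high = _icer_value(run_scenario(_apply(scenario, {spec.name: spec.high}, [spec])))
            entries.append(TornadoEntry(spec.name, spec.low, spec.high, icer_low, icer_high))
        except Exception:
            entries.append(TornadoEntry(spec.name, spec.low, spec.high, math.nan, math.nan, True))
    entries.sort(key=lambda e: (-e.spread, e.name))
    return entries


def tornado_frame(entries: Sequence[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "param": [e.name for e in entries],
            "low": [e.low for e in entries],
            "high": [e.high for e in entries],
            "icer_low": [e.icer_low for e in entries],
            "icer_high": [e.icer_high for e in entries],
            "spread": [e.spread for e in entries],
            "failed": [e.failed for e in entries],
        }
    )


def run_psa(
    scenario: dict,
    specs: Sequence[ParamSpec],
    n: int = 1000,
    seed: int = 0,
    max_failure_fraction: float = 0.01,
) -> pd.DataFrame:
    """Probabilistic sensitivity analysis: ``n`` joint draws, full
    pipeline per draw.

    Returns one row per draw with per-arm discounted totals and the
    incremental outcomes.  Draw ``i`` uses the deterministic substream
    ``SeedSequence(seed).spawn()[i]``, so results are exactly
    reproducible and independent of execution order.  Draws whose model
    run fails are skipped; more than ``max_failure_fraction`` failures
    aborts.

    The discount rate is deliberately excluded from the default PSA
    parameter set (pass ``include_discount_rate=False`` to
    :func:`build_param_specs`); it enters the one-way analysis only.
    """
    psa_specs = [s for s in specs if s.name != "discount_rate"]
    substreams = np.random.SeedSequence(seed).spawn(n)
    rows: list[dict] = []
    failures = 0
    for i in range(n):
        rng = np.random.default_rng(substreams[i])
        draw = sample_params(psa_specs, rng)
        try:
            result = run_scenario(_apply(scenario, draw, psa_specs))
        except Exception:
            failures += 1
            if failures > max_failure_fraction * n:
                raise RuntimeError(
                    f"more than {max_failure_fraction:.0%} of PSA draws failed"
                )
            continue
        ola, pla = result.arms["olaparib"], result.arms["placebo"]
        rows.append(
            {
                "draw": i,
                "cost_olaparib": ola.total_cost,
                "qaly_olaparib": ola.total_qaly,
                "cost_placebo": pla.total_cost,
                "qaly_placebo": pla.total_qaly,
                "dcost": ola.total_cost - pla.total_cost,
                "dqaly": ola.total_qaly - pla.total_qaly,
            }
        )
    return pd.DataFrame(rows)


def psa_summary(samples: pd.DataFrame) -> dict:
    """Means and covariance of the incremental cloud (95%-ellipse inputs)."""
    inc = samples[["dcost", "dqaly"]].to_numpy()
    return {
        "n": len(samples),
        "mean_dcost": float(inc[:, 0].mean()),
        "mean_dqaly": float(inc[:, 1].mean()),
        "cov": np.cov(inc, rowvar=False).tolist(),
    }


def default_wtp_grid() -> np.ndarray:
    """$0 to $60,000 per QALY in $1,000 steps (covers both thresholds)."""
    return np.arange(0, 60_001, 1000, dtype=float)


def ceac(samples: pd.DataFrame, wtp_grid: Sequence[float] | None = None) -> list[CEACPoint]:
    """Cost-effectiveness acceptability curve.

    At each willingness-to-pay ``lam`` the probability cost-effective is
    the fraction of draws with strictly positive net monetary benefit
    ``lam * dQALY - dCost`` (ties count as not cost-effective).
    """
    if len(samples) == 0:
        raise ValueError("CEAC requires at least one PSA sample")
    if wtp_grid is None:
        wtp_grid = default_wtp_grid()
    grid = np.asarray(wtp_grid, dtype=float)
    if np.any(grid < 0):
        raise ValueError("WTP grid must be non-negative")
    dc = samples["dcost"].to_numpy()
    dq = samples["dqaly"].to_numpy()
    points = []
    for lam in grid:
        nmb = lam * dq - dc
        points.append(CEACPoint(float(lam), float(np.mean(nmb > 0.0))))
    return points


def ceac_frame(points: Sequence[CEACPoint]) -> pd.DataFrame:
    return pd.DataFrame(
        {"wtp": [p.wtp for p in points], "probability": [p.probability for p in points]}
    )
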