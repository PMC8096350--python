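"""Scenario assembly and the end-to-end base-case pipeline.

A *scenario* is a plain nested dict carrying everything one model run
needs for one country: model settings, the four survival curves, costs,
utilities and adverse-event rates.  Keeping it a dict makes sensitivity
analysis straightforward — any scalar can be addressed by a dotted path
(e.g. ``costs.ae_unit.vomiting``) and replaced without touching the
engine.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass
from typing import Any, Mapping

from .economics import (
    CEAResult,
    CountryArmInputs,
    ICERResult,
    compute_icer,
    round_half_up,
    wtp_threshold,
)
from .fixtures import ARMS, FOLLOWUP_COMPONENTS, load_fixture
from .markov import CohortTrace, ModelSpec, build_trace
from .survival import ParametricSurvival

__all__ = [
    "build_scenario",
    "run_scenario",
    "BaseCaseResult",
    "get_path",
    "set_path",
    "with_value",
    "reference_icers",
]


def get_path(d: Mapping[str, Any], path: str):
    node: Any = d
    for key in path.split("."):
        node = node[key]
    return node


def set_path(d: dict, path: str, value) -> None:
    keys = path.split(".")
    node: Any = d
    for key in keys[:-1]:
        node = node[key]
    if keys[-1] not in node:
        raise KeyError(f"path {path!r} does not resolve in the scenario")
    node[keys[-1]] = value


def with_value(scenario: dict, path: str, value) -> dict:
    """A deep copy of ``scenario`` with one dotted path replaced."""
    out = copy.deepcopy(scenario)
    set_path(out, path, value)
    return out


def build_scenario(
    country: str,
    variant: str = "as_published",
    fixture: dict | None = None,
    fixture_path=None,
    **model_overrides,
) -> dict:
    """Assemble the full model configuration for one country.

    ``variant`` selects the survival parameter set: ``"as_published"``
    (default; emits a warning because the published olaparib-arm PFS
    scale implies a median PFS far beyond the same arm's median OS) or
    ``"corrected"`` (scale 0.10 in that single cell).
    ``model_overrides`` are passed through to :class:`ModelSpec` fields
    (e.g. ``structure="state_transition"``).
    """
    if fixture is None:
        fixture = load_fixture(fixture_path)
    if country not in fixture["costs"]:
        raise ValueError(f"unknown country {country!r}")
    if variant not in fixture["survival"]:
        raise ValueError(f"unknown survival variant {variant!r}")
    if variant == "as_published":
        warnings.warn(
            "using the as-published survival parameters: the olaparib-arm PFS "
            "scale 0.010 implies a ~57-month median PFS (beyond the arm's "
            "~21-month median OS); pass variant='corrected' for the "
            "0.10 variant",
            stacklevel=2,
        )
    model = dict(fixture["model"])
    model.setdefault("structure", "partitioned_survival")
    model.setdefault("half_cycle_correction", False)
    model.update(model_overrides)
    surv = fixture["survival"][variant]
    return {
        "country": country,
        "model": model,
        "survival": {
            endpoint: {
                arm: dict(surv[endpoint][arm]) for arm in ARMS
            }
            for endpoint in ("pfs", "os")
        },
        "costs": {
            "drug_olaparib_per_cycle": fixture["costs"][country]["drug_olaparib_per_cycle"]["value"],
            "ae_unit": {
                ae: entry["value"] for ae, entry in fixture["costs"][country]["ae_unit"].items()
            },
            "followup_per_cycle": {
                comp: fixture["costs"][country]["followup_per_cycle"][comp]["value"]
                for comp in FOLLOWUP_COMPONENTS
            },
            "bsc_per_cycle": fixture["costs"][country]["bsc_per_cycle"]["value"],
            "terminal_care": fixture["costs"][country]["terminal_care"]["value"],
        },
        "utilities": {state: fixture["utilities"][state]["value"] for state in ("pfs", "pd")},
        "ae_rates": {arm: dict(fixture["ae_rates"][arm]) for arm in ARMS},
        "wtp": {
            "us_threshold_usd": fixture["wtp"]["us_threshold_usd"],
            "china_gdp_per_capita_yuan": fixture["wtp"]["china_gdp_per_capita_yuan"],
            "exchange_rate_yuan_per_usd": fixture["meta"]["exchange_rate_yuan_per_usd"],
        },
    }


def _arm_inputs(scenario: dict, arm: str) -> CountryArmInputs:
    costs = scenario["costs"]
    return CountryArmInputs(
        country=scenario["country"],
        arm=arm,
        drug_cost_per_cycle=costs["drug_olaparib_per_cycle"] if arm == "olaparib" else 0.0,
        followup_cost_per_cycle=float(sum(costs["followup_per_cycle"].values())),
        bsc_cost_per_cycle=costs["bsc_per_cycle"],
        terminal_care_cost=costs["terminal_care"],
        ae_unit_costs=dict(costs["ae_unit"]),
        ae_rates=dict(scenario["ae_rates"][arm]),
        utility_pfs=scenario["utilities"]["pfs"],
        utility_pd=scenario["utilities"]["pd"],
    )


@dataclass(frozen=True)
class BaseCaseResult:
    """Full-pipeline output for one country: per-arm totals, the
    incremental comparison and the threshold verdict."""

    country: str
    spec: ModelSpec
    arms: Mapping[str, CEAResult]
    traces: Mapping[str, CohortTrace]
    icer: ICERResult
    threshold: float

    @property
    def verdict(self) -> str:
        if self.icer.status == "dominant":
            return "dominant"
        if self.icer.status == "dominated":
            return "dominated"
        if self.icer.status == "undefined":
            return "undefined"
        return (
            "below threshold" if self.icer.icer_rounded <= self.threshold else "above threshold"
        )


def run_scenario(scenario: dict) -> BaseCaseResult:
    """Fitted curves -> cohort traces -> discounted totals -> ICER."""
    from .economics import accumulate  # local to keep import graph flat

    spec = ModelSpec(**scenario["model"])
    arms: dict[str, CEAResult] = {}
    traces: dict[str, CohortTrace] = {}
    for arm in ARMS:
        s_pfs = ParametricSurvival(time_unit="months", **scenario["survival"]["pfs"][arm])
        s_os = ParametricSurvival(time_unit="months", **scenario["survival"]["os"][arm])
        trace = build_trace(spec, s_pfs, s_os)
        traces[arm] = trace
        arms[arm] = accumulate(trace, _arm_inputs(scenario, arm), spec)
    icer = compute_icer(arms["olaparib"], arms["placebo"])
    threshold = wtp_threshold(
        scenario["country"],
        gdp_per_capita_yuan=scenario["wtp"]["china_gdp_per_capita_yuan"],
        rate=scenario["wtp"]["exchange_rate_yuan_per_usd"],
    )
    return BaseCaseResult(scenario["country"], spec, arms, traces, icer, threshold)


def reference_icers(fixture: dict | None = None) -> dict[str, dict]:
    """Incremental arithmetic from the externally reported per-arm totals.

    The reported totals are treated as inputs; incremental cost and
    QALYs, the ICER and the threshold verdict are recomputed.
    """
    if fixture is None:
        fixture = load_fixture()
    ref = fixture["reference_totals"]
    out: dict[str, dict] = {}
    for country, arms in ref.items():
        a = CEAResult(
            "olaparib",
            arms["olaparib"]["cost"],
            arms["olaparib"]["qaly"],
            {"drug": arms["olaparib"]["cost"], "followup": 0, "ae": 0, "bsc": 0, "terminal": 0},
        )
        b = CEAResult(
            "placebo",
            arms["placebo"]["cost"],
            arms["placebo"]["qaly"],
            {"drug": arms["placebo"]["cost"], "followup": 0, "ae": 0, "bsc": 0, "terminal": 0},
        )
        icer = compute_icer(a, b)
        threshold = wtp_threshold(
            country,
            gdp_per_capita_yuan=fixture["wtp"]["china_gdp_per_capita_yuan"],
            rate=fixture["meta"]["exchange_rate_yuan_per_usd"],
        )
        out[country] = {
            "incremental_cost": round_half_up(icer.incremental_cost),
            "incremental_qaly": round(icer.incremental_qaly, 10),
            "icer": icer.icer_rounded,
            "threshold": threshold,
            "verdict": "below threshold" if icer.icer_rounded <= threshold else "above threshold",
        }
    return out
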