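"""Loading and validation of the shipped parameter fixture.

The fixture (``data/parameters.yaml``) carries the complete base-case
parameter set — survival shape/scale pairs, health-state utilities,
per-country costs with sensitivity ranges, adverse-event incidence,
willingness-to-pay inputs and the externally reported per-arm totals.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import yaml

from .economics import AE_NAMES

__all__ = ["load_fixture", "validate_fixtures", "default_fixture_path"]

COUNTRIES = ("china", "us")
ARMS = ("olaparib", "placebo")
SURVIVAL_VARIANTS = ("as_published", "corrected")
FOLLOWUP_COMPONENTS = ("biochemical", "blood_routine", "ct")
_FAMILIES = {"exponential", "weibull", "gompertz", "loglogistic", "lognormal"}


def default_fixture_path() -> Path:
    return Path(importlib.resources.files("olacea").joinpath("data/parameters.yaml"))


def load_fixture(path=None) -> dict:
    """Load the parameter fixture (the shipped one if ``path`` is None)."""
    p = Path(path) if path is not None else default_fixture_path()
    with open(p) as fh:
        fixture = yaml.safe_load(fh)
    violations = validate_fixtures(fixture)
    if violations:
        raise ValueError(
            "invalid parameter fixture:\n" + "\n".join(f"  - {v}" for v in violations)
        )
    return fixture


def validate_fixtures(fixture_or_path) -> list[str]:
    """Check a fixture against the full input schema.

    Returns a list of human-readable violations (empty = valid): type and
    range checks on every entry plus completeness against the expected
    country/arm/adverse-event/follow-up structure.
    """
    if isinstance(fixture_or_path, (str, Path)):
        with open(fixture_or_path) as fh:
            fx = yaml.safe_load(fh)
    else:
        fx = fixture_or_path
    v: list[str] = []
    if not isinstance(fx, dict):
        return ["fixture root must be a mapping"]

    for section in ("meta", "model", "survival", "utilities", "costs", "ae_rates", "wtp"):
        if section not in fx:
            v.append(f"missing section {section!r}")
    if v:
        return v

    def num(x) -> bool:
        return isinstance(x, (int, float)) and not isinstance(x, bool)

    # meta / model
    rate = fx["meta"].get("exchange_rate_yuan_per_usd")
    if not (num(rate) and rate > 0):
        v.append("meta.exchange_rate_yuan_per_usd must be > 0")
    model = fx["model"]
    if not (num(model.get("cycle_length_days")) and model["cycle_length_days"] > 0):
        v.append("model.cycle_length_days must be > 0")
    if not (num(model.get("horizon_years")) and model["horizon_years"] > 0):
        v.append("model.horizon_years must be > 0")
    r = model.get("discount_rate_annual")
    if not (num(r) and 0 <= r < 1):
        v.append("model.discount_rate_annual must lie in [0, 1)")

    # survival variants
    for variant in SURVIVAL_VARIANTS:
        block = fx["survival"].get(variant)
        if block is None:
            v.append(f"missing survival variant {variant!r}")
            continue
        for endpoint in ("pfs", "os"):
            for arm in ARMS:
                entry = block.get(endpoint, {}).get(arm)
                if entry is None:
                    v.append(f"survival.{variant}.{endpoint}.{arm} missing")
                    continue
                if entry.get("family") not in _FAMILIES:
                    v.append(f"survival.{variant}.{endpoint}.{arm}.family unknown")
                for p in ("shape", "scale"):
                    if not (num(entry.get(p)) and entry[p] > 0):
                        v.append(f"survival.{variant}.{endpoint}.{arm}.{p} must be > 0")

    # utilities
    for state in ("pfs", "pd"):
        entry = fx["utilities"].get(state)
        if entry is None:
            v.append(f"utilities.{state} missing")
            continue
        for p in ("value", "low", "high"):
            if not (num(entry.get(p)) and 0 <= entry[p] <= 1):
                v.append(f"utilities.{state}.{p} must lie in [0, 1]")
        if all(num(entry.get(p)) for p in ("value", "low", "high")) and not (
            entry["low"] <= entry["value"] <= entry["high"]
        ):
            v.append(f"utilities.{state}: need low <= value <= high")

    # costs
    def check_cost(label: str, entry) -> None:
        if not isinstance(entry, dict):
            v.append(f"{label} must be a mapping with value/low/high")
            return
        for p in ("value", "low", "high"):
            if not (num(entry.get(p)) and entry[p] >= 0):
                v.append(f"{label}.{p} must be >= 0")
                return
        if not entry["low"] <= entry["value"] <= entry["high"]:
            v.append(f"{label}: need low <= value <= high")

    for country in COUNTRIES:
        cc = fx["costs"].get(country)
        if cc is None:
            v.append(f"costs.{country} missing")
            continue
        check_cost(f"costs.{country}.drug_olaparib_per_cycle", cc.get("drug_olaparib_per_cycle"))
        for ae in AE_NAMES:
            if ae not in cc.get("ae_unit", {}):
                v.append(f"costs.{country}.ae_unit.{ae} missing")
            else:
                check_cost(f"costs.{country}.ae_unit.{ae}", cc["ae_unit"][ae])
        for comp in FOLLOWUP_COMPONENTS:
            if comp not in cc.get("followup_per_cycle", {}):
                v.append(f"costs.{country}.followup_per_cycle.{comp} missing")
            else:
                check_cost(f"costs.{country}.followup_per_cycle.{comp}", cc["followup_per_cycle"][comp])
        check_cost(f"costs.{country}.bsc_per_cycle", cc.get("bsc_per_cycle"))
        check_cost(f"costs.{country}.terminal_care", cc.get("terminal_care"))

    # AE incidence
    for arm in ARMS:
        rates = fx["ae_rates"].get(arm)
        if rates is None:
            v.append(f"ae_rates.{arm} missing")
            continue
        for ae in AE_NAMES:
            if ae not in rates:
                v.append(f"ae_rates.{arm}.{ae} missing")
            elif not (num(rates[ae]) and 0 <= rates[ae] <= 1):
                v.append(f"ae_rates.{arm}.{ae} must lie in [0, 1]")

    # WTP inputs
    if not (num(fx["wtp"].get("us_threshold_usd")) and fx["wtp"]["us_threshold_usd"] > 0):
        v.append("wtp.us_threshold_usd must be > 0")
    if not (
        num(fx["wtp"].get("china_gdp_per_capita_yuan"))
        and fx["wtp"]["china_gdp_per_capita_yuan"] > 0
    ):
        v.append("wtp.china_gdp_per_capita_yuan must be > 0")

    # reference totals (optional section, but if present must be complete)
    ref = fx.get("reference_totals")
    if ref is not None:
        for country in COUNTRIES:
            for arm in ARMS:
                entry = ref.get(country, {}).get(arm)
                if entry is None:
                    v.append(f"reference_totals.{country}.{arm} missing")
                    continue
                for p in ("cost", "qaly"):
                    if not (num(entry.get(p)) and entry[p] >= 0):
                        v.append(f"reference_totals.{country}.{arm}.{p} must be >= 0")
    return v
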