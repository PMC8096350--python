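"""Run configuration, publication-style result tables and file output.

Every output file starts with provenance comment lines (package
version, a hash of the resolved configuration and the master seed) so
that an unchanged configuration reproduces byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .fixtures import load_fixture
from .scenario import BaseCaseResult, build_scenario, reference_icers, run_scenario
from .sensitivity import (
    TornadoEntry,
    build_param_specs,
    ceac,
    ceac_frame,
    default_wtp_grid,
    one_way_dsa,
    psa_summary,
    run_psa,
    tornado_frame,
)

__all__ = ["RunConfig", "ReportBundle", "run_base_case", "run_report", "write_bundle"]


@dataclass(frozen=True)
class RunConfig:
    """Settings for one reporting run."""

    country: str = "china"
    variant: str = "as_published"  # survival parameter set
    fixture_path: str | None = None
    structure: str = "partitioned_survival"
    half_cycle_correction: bool = False
    run_dsa: bool = True
    run_psa: bool = True
    psa_n: int = 1000
    seed: int = 0
    wtp_grid: tuple[float, ...] = field(default_factory=lambda: tuple(default_wtp_grid()))

    def scenario(self) -> dict:
        fixture = load_fixture(self.fixture_path)
        return build_scenario(
            self.country,
            variant=self.variant,
            fixture=fixture,
            structure=self.structure,
            half_cycle_correction=self.half_cycle_correction,
        )


def config_hash(config: RunConfig, scenario: dict) -> str:
    payload = json.dumps(
        {"config": config.__dict__, "scenario": scenario}, sort_keys=True, default=str
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class ReportBundle:
    """Everything one run produces, table-shaped."""

    config: RunConfig
    provenance: Mapping[str, str]
    base_case: pd.DataFrame
    reference_case: pd.DataFrame
    dsa: pd.DataFrame | None
    psa_samples: pd.DataFrame | None
    psa_stats: Mapping | None
    ceac_table: pd.DataFrame | None
    result: BaseCaseResult


def _base_case_table(result: BaseCaseResult) -> pd.DataFrame:
    rows = []
    for arm, res in result.arms.items():
        row = {"arm": arm, "total_cost": res.total_cost, "total_qaly": res.total_qaly}
        row.update({f"cost_{k}": v for k, v in res.breakdown.items()})
        rows.append(row)
    df = pd.DataFrame(rows)
    df["incremental_cost"] = [result.icer.incremental_cost, None]
    df["incremental_qaly"] = [result.icer.incremental_qaly, None]
    df["icer"] = [result.icer.icer if result.icer.status == "defined" else None, None]
    df["threshold"] = [result.threshold, None]
    df["verdict"] = [result.verdict, None]
    return df


def _reference_table(fixture_path=None) -> pd.DataFrame:
    ref = reference_icers(load_fixture(fixture_path))
    return pd.DataFrame(
        [{"country": country, **vals} for country, vals in ref.items()]
    )


def run_base_case(config: RunConfig) -> ReportBundle:
    """Execute the configured pipeline and assemble the report tables.

    The base-case table holds the model-computed per-arm totals and
    incremental comparison; the reference table re-derives the
    incremental arithmetic and threshold verdicts from the externally
    reported per-arm totals (model bypassed).
    """
    scenario = config.scenario()
    result = run_scenario(scenario)
    provenance = {
        "package": f"olacea {__version__}",
        "config_hash": config_hash(config, scenario),
        "seed": str(config.seed),
    }
    dsa_table = psa_samples = stats = ceac_table = None
    if config.run_dsa or config.run_psa:
        fixture = load_fixture(config.fixture_path)
        specs = build_param_specs(fixture, config.country)
        if config.run_dsa:
            dsa_table = tornado_frame(one_way_dsa(scenario, specs))
        if config.run_psa:
            psa_samples = run_psa(scenario, specs, n=config.psa_n, seed=config.seed)
            stats = psa_summary(psa_samples)
            ceac_table = ceac_frame(ceac(psa_samples, config.wtp_grid))
    return ReportBundle(
        config=config,
        provenance=provenance,
        base_case=_base_case_table(result),
        reference_case=_reference_table(config.fixture_path),
        dsa=dsa_table,
        psa_samples=psa_samples,
        psa_stats=stats,
        ceac_table=ceac_table,
        result=result,
    )


run_report = run_base_case  # full bundle and base case share one entry point


def _write_csv(df: pd.DataFrame, path: Path, provenance: Mapping[str, str]) -> None:
    header = "".join(f"# {k}={v}\n" for k, v in provenance.items())
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def write_bundle(bundle: ReportBundle, outdir) -> list[Path]:
    """Write every table of the bundle as provenance-stamped CSV/JSON."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(df: pd.DataFrame | None, name: str) -> None:
        if df is None:
            return
        path = out / name
        _write_csv(df, path, bundle.provenance)
        written.append(path)

    emit(bundle.base_case, "base_case.csv")
    emit(bundle.reference_case, "reference_case.csv")
    emit(bundle.dsa, "dsa_tornado.csv")
    emit(bundle.psa_samples, "psa_samples.csv")
    emit(bundle.ceac_table, "ceac.csv")
    if bundle.psa_stats is not None:
        path = out / "psa_summary.json"
        with open(path, "w") as fh:
            json.dump({**bundle.provenance, **bundle.psa_stats}, fh, indent=2)
        written.append(path)
    return written
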