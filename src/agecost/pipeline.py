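"""End-to-end run orchestration: inputs -> visit table -> cost table -> reports.

A run is described by :class:`RunConfig`; :func:`run_pipeline` executes it
and writes a fixed set of artifacts plus a manifest recording the config
hash, fee provenance and package version, so identical inputs reproduce
identical outputs. Outputs are written atomically (to a temp name, then
renamed) so a failed stage leaves no partial artifacts behind.
"""

from __future__ import annotations

import hashlib
import json
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .costs import (
    CostTable,
    ScenarioSpec,
    aggregate_costs,
    compute_costs,
    format_report,
    per_person_cost,
)
from .errors import AgecostError, ConfigurationError
from .fees import CategoryFee, load_fee_schedule
from .population import PopulationTable, load_population
from .services import ServiceMix, project_service_visits


@dataclass(frozen=True)
class RunConfig:
    """Paths and options for one pipeline run."""

    population_path: str
    out_dir: str
    mix_path: str | None = None
    fees_path: str | None = None
    fee_overrides_path: str | None = None
    denominator_rule: str = "per_line_entry"
    scenario_multiplier: float = 1.0
    group_by: tuple[str, ...] = ("jurisdiction",)
    report_style: str = "millions"
    round_visit_totals: bool = False

    def digest(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_atomic(df: pd.DataFrame, path: Path, **kwargs) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    os.close(fd)
    try:
        df.to_csv(tmp, **kwargs)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def run_pipeline(cfg: RunConfig) -> dict[str, Path]:
    """Execute a configured run and write its artifacts.

    Returns a mapping from artifact name to written path:
    ``visits`` (long visit table), ``costs`` (long cost table),
    ``report_wide`` (area x group display matrix), ``per_person``
    (per-person cost per group) and ``manifest``.
    """
    if cfg.scenario_multiplier <= 0:
        raise ConfigurationError(
            f"scenario multiplier must be > 0, got {cfg.scenario_multiplier}"
        )
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    try:
        pop = load_population(cfg.population_path)
    except AgecostError as exc:
        raise type(exc)(f"[population stage] {exc}") from exc

    mix = ServiceMix.from_file(cfg.mix_path) if cfg.mix_path else ServiceMix()

    try:
        fees = load_fee_schedule(
            cfg.fees_path,
            overrides=cfg.fee_overrides_path,
            areas=tuple(mix.per_visit_mean),
            denominator_rule=cfg.denominator_rule,
        )
    except AgecostError as exc:
        raise type(exc)(f"[fee stage] {exc}") from exc

    scenario = ScenarioSpec(multiplier=cfg.scenario_multiplier)
    vt = project_service_visits(
        pop, mix, areas=tuple(mix.per_visit_mean), round_totals=cfg.round_visit_totals
    )
    ct = compute_costs(vt, fees, scenario)

    primary_key = cfg.group_by[0] if cfg.group_by else "jurisdiction"
    report = format_report(ct, cfg.report_style, by=primary_key)
    per_person = per_person_cost(ct, pop, by=list(cfg.group_by))

    paths = {
        "visits": out_dir / "visits.csv",
        "costs": out_dir / "costs.csv",
        "report_wide": out_dir / "report_wide.csv",
        "per_person": out_dir / "per_person.csv",
        "manifest": out_dir / "manifest.json",
    }
    _write_atomic(vt.data, paths["visits"], index=False)
    _write_atomic(ct.data, paths["costs"], index=False)
    _write_atomic(report, paths["report_wide"])
    _write_atomic(per_person.reset_index(), paths["per_person"], index=False)

    manifest = {
        "agecost_version": __version__,
        "config_digest": cfg.digest(),
        "config": {**cfg.__dict__, "group_by": list(cfg.group_by)},
        "fee_provenance": {a: f.provenance for a, f in fees.items()},
        "scenario_multiplier": cfg.scenario_multiplier,
        "n_strata": len(pop),
        "total_population_65plus": pop.total_population(),
        "total_cost_aud": ct.total,
    }
    tmp = paths["manifest"].with_suffix(".json.tmp")
    tmp.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    os.replace(tmp, paths["manifest"])
    return paths
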