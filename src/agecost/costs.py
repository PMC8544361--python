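"""Expenditure engine: visits x fees, aggregation and reporting views.

Cost of a cell = projected visits for (stratum, area) x per-visit fee of
the area x scenario multiplier, in AUD per year. All aggregation uses
unrounded values; rounding to millions happens only at report time. (The
published grand total differs from the sum of its rounded per-cell
display values by a couple of million, so rounded-cell arithmetic cannot
be the internal representation.)

The scenario multiplier models alternative price schedules as a flat
factor on final costs. The government veterans'-schedule scenario, whose
prices run about 21% below private general-practice fees, is the
multiplier 0.79.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .fees import CategoryFee
from .population import GROUP_KEYS, PopulationTable
from .services import STRATUM_KEYS, VisitTable


@dataclass(frozen=True)
class ScenarioSpec:
    """Flat multiplier applied to every cost cell (default 1.0).

    ``DVA_SCENARIO`` prices the model at the government veterans'
    schedule, roughly 21% below private fees.
    """

    multiplier: float = 1.0
    name: str = "baseline"

    def __post_init__(self) -> None:
        if self.multiplier <= 0:
            raise ValidationError(
                f"scenario multiplier must be > 0, got {self.multiplier}"
            )


DVA_SCENARIO = ScenarioSpec(multiplier=0.79, name="dva_schedule")


class CostTable:
    """Annual expenditure per stratum and service area (long format).

    ``data`` columns: stratum keys, ``area``, ``cost`` (AUD/year).
    ``fee_provenance`` records, per area, how its fee was obtained;
    ``scenario`` the multiplier applied.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        fee_provenance: Mapping[str, str],
        scenario: ScenarioSpec,
    ) -> None:
        self.data = data
        self.fee_provenance = dict(fee_provenance)
        self.scenario = scenario

    @property
    def total(self) -> float:
        return float(self.data["cost"].sum())

    def to_file(self, path: str | Path, *, delimiter: str = ",") -> None:
        self.data.to_csv(path, sep=delimiter, index=False)

    def to_wide(self, *, by: str = "jurisdiction", margins: bool = True) -> pd.DataFrame:
        """Area x group matrix of unrounded AUD (report-table shape)."""
        wide = self.data.pivot_table(
            index="area", columns=by, values="cost", aggfunc="sum", observed=True
        )
        order = self.data["area"].unique()
        wide = wide.reindex(order)
        if margins:
            wide["Total"] = wide.sum(axis=1)
        return wide


def compute_costs(
    vt: VisitTable,
    fees: Mapping[str, CategoryFee],
    scenario: ScenarioSpec | None = None,
) -> CostTable:
    """Price a visit table: cost = visits x fee_per_visit x multiplier."""
    scenario = scenario or ScenarioSpec()
    missing = [a for a in vt.areas if a not in fees]
    if missing:
        raise ConfigurationError(f"no fee for service area(s): {missing}")
    if not np.isfinite(vt.data["visits"]).all():
        raise ValidationError("visit table contains non-finite visit counts")

    fee_map = {a: fees[a].fee_per_visit for a in vt.areas}
    data = vt.data.copy()
    data["cost"] = (
        data["visits"] * data["area"].map(fee_map) * scenario.multiplier
    )
    data = data[list(STRATUM_KEYS) + ["area", "cost"]]
    provenance = {a: fees[a].provenance for a in vt.areas}
    return CostTable(data, provenance, scenario)


def aggregate_costs(
    ct: CostTable,
    by: Sequence[str] | None = None,
    *,
    margins: bool = False,
) -> pd.Series | pd.DataFrame:
    """Cost sums per service area, optionally per group, from unrounded cells.

    With ``margins=True`` an ``All`` level is appended on each grouping
    axis; margin values equal the sums of their groups exactly (they are
    recomputed from the same unrounded cells).
    """
    keys = list(by) if by else []
    bad = [k for k in keys if k not in GROUP_KEYS]
    if bad:
        raise ValidationError(
            f"unknown grouping key(s) {bad}; valid keys are {GROUP_KEYS}"
        )
    grouped = ct.data.groupby(keys + ["area"], observed=True)["cost"].sum()
    if not margins:
        return grouped
    # area margins per group, then grand margins
    frame = grouped.reset_index()
    pieces = [frame]
    totals = ct.data.groupby(keys, observed=True)["cost"].sum().reset_index() if keys else pd.DataFrame({"cost": [ct.total]})
    totals["area"] = "All"
    pieces.append(totals)
    if keys:
        area_tot = ct.data.groupby("area", observed=True)["cost"].sum().reset_index()
        for k in keys:
            area_tot[k] = "All"
        pieces.append(area_tot)
        grand = pd.DataFrame({"area": ["All"], "cost": [ct.total]})
        for k in keys:
            grand[k] = "All"
        pieces.append(grand)
    out = pd.concat(pieces, ignore_index=True)
    return out.set_index(keys + ["area"])["cost"]


def per_person_cost(
    ct: CostTable,
    pt: PopulationTable,
    by: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Average annual cost per 65+ person, per group.

    Returns columns ``cost``, ``population``, ``cost_per_person`` and a
    boolean ``undefined`` flag. Groups with zero population are reported
    with ``cost_per_person = NaN`` and ``undefined = True`` rather than
    silently as zero.
    """
    keys = list(by) if by else []
    bad = [k for k in keys if k not in GROUP_KEYS]
    if bad:
        raise ValidationError(
            f"unknown grouping key(s) {bad}; valid keys are {GROUP_KEYS}"
        )
    if keys:
        cost = ct.data.groupby(keys, observed=True)["cost"].sum()
        popn = pt.data.groupby(keys, observed=True)["pop_65plus"].sum()
    else:
        cost = pd.Series({"All": ct.total})
        popn = pd.Series({"All": pt.total_population()})
    out = pd.DataFrame({"cost": cost, "population": popn}).fillna({"cost": 0.0})
    out["cost_per_person"] = np.where(
        out["population"] > 0, out["cost"] / out["population"], np.nan
    )
    out["undefined"] = out["population"] <= 0
    return out


def format_cell(value: float) -> str:
    """Render one AUD amount in the millions report style.

    >= 1M rounds to the nearest whole million ("$246"); positive values
    below 1M keep one decimal ("$0.4"); exact zero is "$0".
    """
    if value == 0:
        return "$0"
    millions = value / 1e6
    if abs(value) < 1e6:
        return f"${millions:.1f}"
    return f"${round(millions):d}"


def format_report(
    ct: CostTable,
    style: str = "millions",
    *,
    by: str = "jurisdiction",
    margins: bool = True,
) -> pd.DataFrame:
    """Display-ready area x group cost matrix.

    ``style="millions"`` applies :func:`format_cell` to every cell (the
    published table style); ``style="whole_aud"`` leaves unrounded floats.
    Totals are computed from unrounded values before any formatting.
    """
    wide = ct.to_wide(by=by, margins=margins)
    if style == "whole_aud":
        return wide
    if style != "millions":
        raise ConfigurationError(
            f"unknown report style {style!r}; choose 'millions' or 'whole_aud'"
        )
    return wide.map(format_cell)
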