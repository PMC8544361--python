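"""Projection of annual dental visits and their service-area decomposition.

The demand model is deliberately simple and fully deterministic: a single
national visit rate (mean annual dental visits per person aged 65+,
default 2.58, from the 2013 national dental telephone interview survey of
dentate adults) is applied to every stratum's 65+ count, and the resulting
visit total is decomposed into nine clinical service areas by the mean
number of services of each area delivered per visit (the *service mix*,
from the 2003-04 wave of the longitudinal dentists' practice activity
study). Orthodontics is absent from the default service set: no utilisation
data exist for the 65+ cohort, so it is excluded from the model.

The per-visit means are services per visit, not shares of a visit: summed
over areas they exceed 1 (2.241 with the defaults) because a single visit
typically delivers more than one service.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .errors import ConfigurationError, ValidationError
from .population import GROUP_KEYS, PopulationTable

#: The nine clinical service areas of the schedule of dental services used
#: by the model. Orthodontics is intentionally absent (no 65+ utilisation
#: data); the set is configurable for sensitivity work.
DEFAULT_SERVICE_AREAS: tuple[str, ...] = (
    "Diagnostic",
    "Preventive",
    "Periodontics",
    "OralSurgery",
    "Endodontics",
    "Restorative",
    "CrownBridge",
    "Prosthodontics",
    "General",
)

#: Mean services of each area delivered per dental visit, 65+ patients.
DEFAULT_PER_VISIT_MEAN: dict[str, float] = {
    "Diagnostic": 0.671,
    "Restorative": 0.641,
    "Preventive": 0.343,
    "Prosthodontics": 0.257,
    "CrownBridge": 0.097,
    "Endodontics": 0.096,
    "OralSurgery": 0.091,
    "General": 0.029,
    "Periodontics": 0.016,
}

#: Mean annual dental visits per person aged 65+.
DEFAULT_VISIT_RATE = 2.58

STRATUM_KEYS = ("unit_id", "jurisdiction", "decile", "remoteness")


@dataclass(frozen=True)
class ServiceMix:
    """Visit rate and per-visit service means.

    Parameters
    ----------
    mean_visits_per_person
        Annual dental visits per person aged 65+ (visits/person/year).
    per_visit_mean
        Mean services per visit for each service area (dimensionless;
        values need not sum to 1).
    dentate_fraction
        Optional sensitivity multiplier for the fraction of the cohort
        assumed dentate. The reference model applies the dentate visit
        rate to the whole 65+ population, so the default is 1.0.
    """

    mean_visits_per_person: float = DEFAULT_VISIT_RATE
    per_visit_mean: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PER_VISIT_MEAN)
    )
    dentate_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.mean_visits_per_person <= 0:
            raise ValidationError(
                f"mean_visits_per_person must be > 0, "
                f"got {self.mean_visits_per_person}"
            )
        if not 0 < self.dentate_fraction <= 1:
            raise ValidationError(
                f"dentate_fraction must be in (0, 1], got {self.dentate_fraction}"
            )
        for area, m in self.per_visit_mean.items():
            if m < 0:
                raise ValidationError(
                    f"per_visit_mean[{area!r}] must be >= 0, got {m}"
                )

    @property
    def areas(self) -> tuple[str, ...]:
        return tuple(self.per_visit_mean)

    @property
    def services_per_visit(self) -> float:
        """Total mean services delivered per visit (2.241 with defaults)."""
        return float(sum(self.per_visit_mean.values()))

    @classmethod
    def from_file(cls, path: str | Path) -> "ServiceMix":
        """Read a mix from a flat YAML mapping.

        Recognised keys: ``mean_visits_per_person``, ``dentate_fraction``
        (optional) and one entry per service area under ``per_visit_mean``.
        """
        with open(path, encoding="utf-8") as fh:
            cfg = yaml.safe_load(fh) or {}
        if "per_visit_mean" not in cfg:
            raise ConfigurationError(f"{path}: missing 'per_visit_mean' mapping")
        return cls(
            mean_visits_per_person=float(
                cfg.get("mean_visits_per_person", DEFAULT_VISIT_RATE)
            ),
            per_visit_mean={k: float(v) for k, v in cfg["per_visit_mean"].items()},
            dentate_fraction=float(cfg.get("dentate_fraction", 1.0)),
        )

    def to_file(self, path: str | Path) -> None:
        payload = {
            "mean_visits_per_person": self.mean_visits_per_person,
            "dentate_fraction": self.dentate_fraction,
            "per_visit_mean": dict(self.per_visit_mean),
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


class VisitTable:
    """Projected annual visits per stratum and service area (long format).

    ``data`` columns: the stratum keys, ``area`` and ``visits`` (annual
    visits, non-negative real). ``totals`` holds the all-services visit
    total per stratum, the quantity the decomposition multiplied.
    By construction ``visits(stratum, area) ==
    totals(stratum) * per_visit_mean(area)`` exactly.
    """

    def __init__(self, data: pd.DataFrame, totals: pd.DataFrame) -> None:
        self.data = data
        self.totals = totals

    @property
    def areas(self) -> tuple[str, ...]:
        return tuple(self.data["area"].unique())

    def profile(self, by: Sequence[str] | None = None) -> pd.Series:
        """Visit sums per service area, optionally per group."""
        keys = list(by) if by else []
        bad = [k for k in keys if k not in GROUP_KEYS]
        if bad:
            raise ValidationError(
                f"unknown grouping key(s) {bad}; valid keys are {GROUP_KEYS}"
            )
        return self.data.groupby(keys + ["area"], observed=True)["visits"].sum()

    def to_file(self, path: str | Path, *, delimiter: str = ",") -> None:
        self.data.to_csv(path, sep=delimiter, index=False)


def project_visits(table: PopulationTable, mix: ServiceMix) -> pd.DataFrame:
    """Annual all-services dental visits per stratum.

    Returns a frame with the stratum keys plus ``total_visits``, where
    ``total_visits = pop_65plus * mean_visits_per_person *
    dentate_fraction``. The value is carried unrounded; rounding the
    projected count to whole visits is a presentation choice made by
    :func:`split_by_service` when reproducing published two-step tables.
    """
    out = table.data[list(STRATUM_KEYS) + ["pop_65plus"]].copy()
    out["total_visits"] = (
        out["pop_65plus"].astype(float)
        * mix.mean_visits_per_person
        * mix.dentate_fraction
    )
    return out.drop(columns="pop_65plus")


def split_by_service(
    total_visits: pd.DataFrame,
    mix: ServiceMix,
    *,
    areas: Sequence[str] = DEFAULT_SERVICE_AREAS,
    round_totals: bool = False,
) -> VisitTable:
    """Decompose per-stratum visit totals into service areas.

    Each area's visits are ``total_visits * per_visit_mean(area)``,
    at full floating precision.

    ``round_totals=True`` first rounds each stratum's visit total to a
    whole number of visits, matching the published two-step worked
    example (which decomposes the rounded annual count). Leave it off for
    pipeline use so that stratum-level and aggregate-level computations
    agree to floating round-off.
    """
    unknown = [a for a in mix.per_visit_mean if a not in set(areas)]
    if unknown:
        raise ConfigurationError(
            f"service mix names area(s) {unknown} absent from the configured "
            f"service-area set {list(areas)}"
        )
    totals = total_visits.copy()
    if (totals["total_visits"] < 0).any():
        raise ValidationError("total_visits must be >= 0")
    if round_totals:
        totals["total_visits"] = totals["total_visits"].round().astype(float)

    long = totals.merge(
        pd.DataFrame(
            {"area": list(mix.per_visit_mean), "per_visit_mean": list(mix.per_visit_mean.values())}
        ),
        how="cross",
    )
    long["visits"] = long["total_visits"] * long["per_visit_mean"]
    data = long[list(STRATUM_KEYS) + ["area", "visits"]]
    return VisitTable(data, totals)


def project_service_visits(
    table: PopulationTable,
    mix: ServiceMix,
    *,
    areas: Sequence[str] = DEFAULT_SERVICE_AREAS,
    round_totals: bool = False,
) -> VisitTable:
    """Convenience composition of projection and decomposition."""
    return split_by_service(
        project_visits(table, mix), mix, areas=areas, round_totals=round_totals
    )


def national_visit_profile(
    vt: VisitTable, by: Sequence[str] | None = None
) -> pd.Series:
    """Grouped visit sums per service area (functional alias)."""
    return vt.profile(by)
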