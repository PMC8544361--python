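"""Synthetic small-area census inputs.

Real runs of the model consume census small-area counts (units of 200-800
residents), an area-level disadvantage decile and a remoteness class —
all closed or download-heavy sources. This module generates population
tables with the same structure so every pipeline stage is testable end to
end:

* unit totals uniform on ``unit_pop_range`` (default 200-800 residents,
  the small-area census size band);
* the 65+ count per unit drawn as ``round(total * aged_fraction)`` with
  the aged fraction from a normal truncated to [0, 1] (no within-area age
  structure is published; any bounded unimodal choice serves, and both
  moments are configurable);
* jurisdiction and remoteness sampled from configurable weight vectors;
* disadvantage deciles assigned the way population-share indices are
  constructed: units are ranked by a reproducible shuffle (standing in
  for the disadvantage score) and greedily filled so each decile holds as
  near 10% of the table's population as whole-unit assignment allows,
  decile 1 first (most disadvantaged). Real disadvantage indices
  partition on total residents; here the partition uses the 65+ counts
  the model consumes, so the 10%-per-decile property holds exactly (to
  one unit) for the modelled population.

Generation is fully reproducible from ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .fees import FeeItem, write_fee_items
from .population import (
    DEFAULT_JURISDICTIONS,
    DEFAULT_REMOTENESS,
    PopulationTable,
)
from .services import DEFAULT_SERVICE_AREAS

#: Share of Australia's 65+ population by jurisdiction (approximate census
#: distribution; configurable).
DEFAULT_JURISDICTION_WEIGHTS: dict[str, float] = {
    "NSW": 0.33,
    "Vic": 0.25,
    "Qld": 0.20,
    "WA": 0.09,
    "SA": 0.08,
    "Tas": 0.03,
    "ACT": 0.013,
    "NT": 0.007,
}

#: Remoteness profile applied to every jurisdiction by default: mostly
#: major cities, thinning toward very remote.
DEFAULT_REMOTENESS_WEIGHTS: dict[str, float] = {
    "MajorCity": 0.70,
    "InnerRegional": 0.18,
    "OuterRegional": 0.09,
    "Remote": 0.02,
    "VeryRemote": 0.01,
}


def _check_weights(weights: Mapping[str, float], what: str) -> None:
    total = sum(weights.values())
    if abs(total - 1.0) > 1e-9:
        raise ValidationError(f"{what} weights sum to {total}, expected 1")
    if any(w < 0 for w in weights.values()):
        raise ValidationError(f"{what} weights must be non-negative")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic census generator."""

    n_units: int = 1000
    unit_pop_range: tuple[int, int] = (200, 800)
    aged_fraction_mean: float = 0.15
    aged_fraction_sd: float = 0.05
    jurisdiction_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_JURISDICTION_WEIGHTS)
    )
    remoteness_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REMOTENESS_WEIGHTS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise ValidationError(f"n_units must be >= 1, got {self.n_units}")
        lo, hi = self.unit_pop_range
        if not (0 < lo <= hi):
            raise ValidationError(
                f"invalid unit_pop_range {self.unit_pop_range}"
            )
        if not 0 <= self.aged_fraction_mean <= 1:
            raise ValidationError(
                f"aged_fraction_mean must be in [0, 1], "
                f"got {self.aged_fraction_mean}"
            )
        if self.aged_fraction_sd < 0:
            raise ValidationError("aged_fraction_sd must be >= 0")
        _check_weights(self.jurisdiction_weights, "jurisdiction")
        _check_weights(self.remoteness_weights, "remoteness")


def _assign_deciles(unit_pops: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Greedy population-share decile assignment.

    Units are visited in a reproducibly shuffled order (the shuffle stands
    in for ranking by a disadvantage score) and poured into deciles 1..10,
    moving to the next decile once its cumulative population reaches the
    k/10 quantile of the total. Each decile's population share is then
    within one unit's population of 10%.
    """
    n = len(unit_pops)
    order = rng.permutation(n)
    total = int(unit_pops.sum())
    deciles = np.empty(n, dtype=int)
    cum = 0
    current = 1
    for idx in order:
        # advance while this decile already holds its share
        while current < 10 and cum >= total * current / 10:
            current += 1
        deciles[idx] = current
        cum += int(unit_pops[idx])
    return deciles


def generate_population(spec: SyntheticSpec) -> PopulationTable:
    """Generate a validated synthetic population table from ``spec``."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_units
    lo, hi = spec.unit_pop_range

    unit_total = rng.integers(lo, hi + 1, size=n)
    frac = rng.normal(spec.aged_fraction_mean, spec.aged_fraction_sd, size=n)
    frac = np.clip(frac, 0.0, 1.0)
    pop65 = np.rint(unit_total * frac).astype(int)

    jur_labels = list(spec.jurisdiction_weights)
    jur = rng.choice(jur_labels, size=n, p=list(spec.jurisdiction_weights.values()))
    rem_labels = list(spec.remoteness_weights)
    rem = rng.choice(rem_labels, size=n, p=list(spec.remoteness_weights.values()))

    deciles = _assign_deciles(pop65, rng)

    width = len(str(n))
    df = pd.DataFrame(
        {
            "unit_id": [f"U{i:0{width}d}" for i in range(n)],
            "jurisdiction": jur,
            "decile": deciles,
            "remoteness": rem,
            "pop_65plus": pop65,
        }
    )
    return PopulationTable(
        df,
        jurisdictions=tuple(jur_labels),
        remoteness_classes=tuple(
            dict.fromkeys(list(DEFAULT_REMOTENESS) + rem_labels)
        ),
    )


def generate_fixture_fees(
    seed: int = 0, path: str | Path | None = None
) -> list[FeeItem]:
    """Fee-schedule items covering all nine service areas.

    The diagnostic category carries the published 2017 high-frequency
    items verbatim so fee derivation can be exercised against real
    numbers; the other categories get synthetic items with plausible fee
    scales. Optionally written to ``path`` as delimited text.
    """
    from .baseline import DIAGNOSTIC_ITEMS, reference_fee_schedule

    rng = np.random.default_rng(seed)
    items: list[FeeItem] = list(DIAGNOSTIC_ITEMS)
    reference = reference_fee_schedule()
    counter = 100
    for area in DEFAULT_SERVICE_AREAS:
        if area == "Diagnostic":
            continue
        base = reference[area].fee_per_visit
        n_items = int(rng.integers(2, 5))
        for j in range(n_items):
            fee = round(float(base * rng.uniform(0.7, 1.3)), 2)
            weight = int(rng.integers(1, 3))
            items.append(
                FeeItem(
                    item_number=str(counter),
                    description=f"{area} service {j + 1} (synthetic)",
                    category=area,
                    mean_fee=fee,
                    frequency_weight=weight,
                )
            )
            counter += 1
    if path is not None:
        write_fee_items(items, path)
    return items
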