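"""Fee-schedule pricing of service areas.

A category's per-visit fee is derived from the high-frequency schedule
items billed in that category: the episode total (sum of mean item fee x
billing frequency) divided by a denominator whose definition is genuinely
ambiguous in published fee tables, so both readings are first-class:

``per_line_entry`` (default)
    Divide by the number of line entries in the item list. This
    reproduces the printed diagnostic example: an episode of
    comprehensive/periodic/limited examination plus two bitewing
    exposures totals 206.65 AUD across four line entries -> 51.66.

``per_distinct_item``
    Divide by the number of items billed once per episode, treating
    repeat-billed items (e.g. "per exposure" radiographs) as add-on
    services that contribute to the episode total but not to the item
    count. On the same diagnostic items this gives 206.65 / 3 = 68.88,
    which is close to the effective diagnostic fee implied by the
    published jurisdiction cost table (~68.5), suggesting the published
    downstream costs used this reading.

Fees are stored to cent precision; intermediate sums are unrounded.

Where a category's items are not published, its fee can instead be
*calibrated*: back-derived as published cost divided by projected visits
for that category. Calibrated fees carry ``provenance="calibrated"`` so
reports can flag that they are reconstructed, not survey-published,
values.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .errors import ConfigurationError, SchemaError, ValidationError
from .services import DEFAULT_SERVICE_AREAS

DENOMINATOR_RULES = ("per_line_entry", "per_distinct_item")

FEE_COLUMNS = ("item_number", "description", "category", "mean_fee", "frequency_weight")


@dataclass(frozen=True)
class FeeItem:
    """One schedule item with its mean billed fee.

    ``frequency_weight`` is the number of times the item is billed in a
    representative episode (e.g. 2 for a per-exposure radiograph billed
    twice); it scales the item's contribution to the episode total.
    """

    item_number: str
    description: str
    category: str
    mean_fee: float
    frequency_weight: int = 1

    def __post_init__(self) -> None:
        if self.mean_fee < 0:
            raise ValidationError(
                f"item {self.item_number}: mean_fee must be >= 0, got {self.mean_fee}"
            )
        if self.frequency_weight < 1:
            raise ValidationError(
                f"item {self.item_number}: frequency_weight must be >= 1, "
                f"got {self.frequency_weight}"
            )

    @property
    def line_total(self) -> float:
        return self.mean_fee * self.frequency_weight


@dataclass(frozen=True)
class CategoryFee:
    """Average fee charged per visit in one service area.

    ``provenance`` records how the number was obtained:
    ``derived_from_items`` (averaged from schedule items), ``supplied``
    (given directly in a config file), or ``calibrated`` (back-derived
    from a published cost and projected visits).
    """

    category: str
    fee_per_visit: float
    provenance: str = "supplied"

    def __post_init__(self) -> None:
        if self.fee_per_visit < 0:
            raise ValidationError(
                f"{self.category}: fee_per_visit must be >= 0, "
                f"got {self.fee_per_visit}"
            )
        if self.provenance not in ("derived_from_items", "supplied", "calibrated"):
            raise ValidationError(f"unknown provenance {self.provenance!r}")


def derive_category_fee(
    items: Sequence[FeeItem],
    denominator_rule: str = "per_line_entry",
) -> CategoryFee:
    """Average the high-frequency items of one category into a per-visit fee.

    total = sum(mean_fee * frequency_weight); fee = total / D, with D per
    the module docstring. The result is rounded to cents.
    """
    if denominator_rule not in DENOMINATOR_RULES:
        raise ConfigurationError(
            f"unknown denominator rule {denominator_rule!r}; "
            f"choose from {DENOMINATOR_RULES}"
        )
    items = list(items)
    if not items:
        raise ValidationError("cannot derive a category fee from an empty item list")
    categories = {it.category for it in items}
    if len(categories) > 1:
        raise ValidationError(
            f"items span multiple categories: {sorted(categories)}"
        )
    total = sum(it.line_total for it in items)
    if denominator_rule == "per_line_entry":
        denom = len(items)
    else:  # per_distinct_item: repeat-billed items don't count as services
        denom = sum(1 for it in items if it.frequency_weight == 1)
        if denom == 0:
            raise ValidationError(
                "per_distinct_item rule needs at least one single-billed item"
            )
    return CategoryFee(
        category=items[0].category,
        fee_per_visit=round(total / denom, 2),
        provenance="derived_from_items",
    )


def calibrate_implied_fee(
    cost: float, visits: float, category: str = ""
) -> CategoryFee:
    """Back-derive the per-visit fee implied by a cost and a visit count.

    ``fee = cost / visits`` (AUD per category visit). Used to reconstruct
    fees for categories whose schedule items are not published, from a
    published annual cost for one region and the projected visits for the
    same category and region.
    """
    if visits <= 0:
        raise ValidationError(
            f"cannot calibrate a fee from {visits} visits (must be > 0)"
        )
    return CategoryFee(
        category=category,
        fee_per_visit=cost / visits,
        provenance="calibrated",
    )


# ----------------------------------------------------------------------
# schedule I/O
# ----------------------------------------------------------------------

def load_fee_items(path: str | Path, *, delimiter: str | None = None) -> list[FeeItem]:
    """Read schedule items from delimited text.

    Columns: ``item_number, description, category, mean_fee,
    frequency_weight``.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"fee schedule file not found: {path}")
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    raw = pd.read_csv(path, sep=delimiter, dtype=str, encoding="utf-8")
    missing = [c for c in FEE_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: missing fee column(s) {missing}")
    items = []
    for idx, row in raw.iterrows():
        try:
            items.append(
                FeeItem(
                    item_number=str(row["item_number"]),
                    description=str(row["description"]),
                    category=str(row["category"]),
                    mean_fee=float(row["mean_fee"]),
                    frequency_weight=int(row["frequency_weight"]),
                )
            )
        except (TypeError, ValueError, ValidationError) as exc:
            raise ValidationError(f"{path} row {idx}: {exc}") from exc
    return items


def write_fee_items(
    items: Iterable[FeeItem], path: str | Path, *, delimiter: str = ","
) -> None:
    df = pd.DataFrame(
        [
            (it.item_number, it.description, it.category, it.mean_fee, it.frequency_weight)
            for it in items
        ],
        columns=list(FEE_COLUMNS),
    )
    df.to_csv(path, sep=delimiter, index=False)


def load_fee_schedule(
    path: str | Path | None = None,
    *,
    overrides: str | Path | Mapping[str, float] | None = None,
    areas: Sequence[str] = DEFAULT_SERVICE_AREAS,
    denominator_rule: str = "per_line_entry",
) -> dict[str, CategoryFee]:
    """Assemble the per-category fee map the cost engine consumes.

    Items in ``path`` are grouped by category and averaged with
    :func:`derive_category_fee`. ``overrides`` (a YAML key->value file or
    a mapping) supplies fees for categories without items, or replaces
    derived ones; override fees carry ``provenance="supplied"``. With no
    arguments, returns the package's reference schedule (see
    :mod:`agecost.baseline`).

    Raises :class:`ConfigurationError` listing every configured area left
    without a fee.
    """
    if path is None and overrides is None:
        from .baseline import reference_fee_schedule

        return reference_fee_schedule()

    fees: dict[str, CategoryFee] = {}
    if path is not None:
        items = load_fee_items(path)
        by_cat: dict[str, list[FeeItem]] = {}
        for it in items:
            by_cat.setdefault(it.category, []).append(it)
        for cat, cat_items in by_cat.items():
            fees[cat] = derive_category_fee(cat_items, denominator_rule)

    if overrides is not None:
        if isinstance(overrides, (str, Path)):
            with open(overrides, encoding="utf-8") as fh:
                overrides = yaml.safe_load(fh) or {}
        for cat, fee in overrides.items():
            fees[cat] = CategoryFee(cat, float(fee), provenance="supplied")

    missing = [a for a in areas if a not in fees]
    if missing:
        raise ConfigurationError(
            f"fee schedule is missing categories: {missing}"
        )
    return {a: fees[a] for a in areas}
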