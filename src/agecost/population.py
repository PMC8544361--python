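"""Population strata for the 65+ cohort.

The unit of account is a *stratum*: an aggregation cell holding the count
of persons aged 65 and over for one combination of geographic unit,
jurisdiction, socioeconomic disadvantage decile and remoteness class.
Strata are generic cells, not census polygons: the projection arithmetic
only ever consumes counts per label combination, so geography enters the
model purely through these labels.

Decile semantics follow the IRSD convention throughout the package:
**decile 1 is the most disadvantaged 10% of the population, decile 10 the
least disadvantaged**. A missing decile (recorded as NA) is permitted so
that jurisdiction-level tables without small-area joins still validate;
such rows are excluded from decile groupings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import SchemaError, ValidationError

DEFAULT_JURISDICTIONS: tuple[str, ...] = (
    "NSW", "Vic", "Qld", "WA", "SA", "Tas", "ACT", "NT",
)

#: Ordered remoteness classes, capital-city access decreasing left to right.
DEFAULT_REMOTENESS: tuple[str, ...] = (
    "MajorCity", "InnerRegional", "OuterRegional", "Remote", "VeryRemote",
)

#: Label accepted for units whose remoteness class is unknown, so partial
#: tables aggregate cleanly instead of being rejected.
UNCLASSIFIED = "Unclassified"

#: Canonical column order of a population table.
COLUMNS = ("unit_id", "jurisdiction", "decile", "remoteness", "pop_65plus")

GROUP_KEYS = ("jurisdiction", "decile", "remoteness")


@dataclass(frozen=True)
class PopulationStratum:
    """One aggregation cell of the 65+ population."""

    unit_id: str
    jurisdiction: str
    decile: int | None
    remoteness: str
    pop_65plus: int

    def __post_init__(self) -> None:
        if self.pop_65plus < 0:
            raise ValidationError(
                f"stratum {self.unit_id!r}: pop_65plus must be >= 0, "
                f"got {self.pop_65plus}"
            )
        if self.decile is not None and not 1 <= int(self.decile) <= 10:
            raise ValidationError(
                f"stratum {self.unit_id!r}: decile must be in 1..10, "
                f"got {self.decile}"
            )


class PopulationTable:
    """Validated collection of population strata.

    Wraps a :class:`pandas.DataFrame` with columns
    ``unit_id, jurisdiction, decile, remoteness, pop_65plus``.
    Invariants enforced on construction: unique ``unit_id``, counts are
    non-negative integers, deciles in 1..10 or NA. Each person belongs to
    exactly one stratum, so any partition of the strata sums to the grand
    total exactly (integer arithmetic).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        *,
        jurisdictions: Sequence[str] = DEFAULT_JURISDICTIONS,
        remoteness_classes: Sequence[str] = DEFAULT_REMOTENESS,
    ) -> None:
        self.jurisdictions = tuple(jurisdictions)
        self.remoteness_classes = tuple(remoteness_classes)
        self.data = _validate(data, self.jurisdictions, self.remoteness_classes)

    # ------------------------------------------------------------------
    # construction
    # ------------------------------------------------------------------
    @classmethod
    def from_strata(
        cls, strata: Iterable[PopulationStratum], **kwargs
    ) -> "PopulationTable":
        rows = [
            (s.unit_id, s.jurisdiction, s.decile, s.remoteness, s.pop_65plus)
            for s in strata
        ]
        df = pd.DataFrame(rows, columns=list(COLUMNS))
        if not rows:
            df = _empty_frame()
        return cls(df, **kwargs)

    @classmethod
    def from_file(
        cls,
        path: str | Path,
        *,
        schema: Mapping[str, str] | None = None,
        delimiter: str | None = None,
        **kwargs,
    ) -> "PopulationTable":
        """Read a delimited-text population table.

        Parameters
        ----------
        path
            CSV (default) or TSV file with a header row, UTF-8 encoded.
        schema
            Optional mapping from canonical column name to the column name
            used in the file, e.g. ``{"pop_65plus": "persons_65_over"}``.
        delimiter
            Field separator; inferred from the extension when ``None``
            (``.tsv``/``.tab`` -> tab, otherwise comma).
        """
        path = Path(path)
        if not path.exists():
            raise SchemaError(f"population file not found: {path}")
        if delimiter is None:
            delimiter = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
        raw = pd.read_csv(path, sep=delimiter, dtype=str, encoding="utf-8")
        rename = {v: k for k, v in (schema or {}).items()}
        raw = raw.rename(columns=rename)
        missing = [c for c in COLUMNS if c not in raw.columns and c != "decile"]
        if "decile" not in raw.columns:
            raw["decile"] = pd.NA
        if missing:
            raise SchemaError(
                f"{path}: missing required column(s) {missing}; "
                f"found {list(raw.columns)}"
            )
        return cls(raw[list(COLUMNS)].copy(), **kwargs)

    def to_file(self, path: str | Path, *, delimiter: str = ",") -> None:
        self.data.to_csv(path, sep=delimiter, index=False)

    # ------------------------------------------------------------------
    # queries
    # ------------------------------------------------------------------
    def __len__(self) -> int:
        return len(self.data)

    @property
    def strata(self) -> list[PopulationStratum]:
        return [
            PopulationStratum(
                unit_id=r.unit_id,
                jurisdiction=r.jurisdiction,
                decile=None if pd.isna(r.decile) else int(r.decile),
                remoteness=r.remoteness,
                pop_65plus=int(r.pop_65plus),
            )
            for r in self.data.itertuples(index=False)
        ]

    def total_population(self, by: Sequence[str] | None = None):
        """Total 65+ persons, optionally grouped.

        ``by`` draws from ``jurisdiction``, ``decile``, ``remoteness``.
        With ``by=None`` returns the integer grand total; otherwise a
        Series of group sums. Strata with NA decile are dropped from
        decile groupings (and only from those).
        """
        if not by:
            return int(self.data["pop_65plus"].sum())
        bad = [k for k in by if k not in GROUP_KEYS]
        if bad:
            raise ValidationError(
                f"unknown grouping key(s) {bad}; valid keys are {GROUP_KEYS}"
            )
        return self.data.groupby(list(by), observed=True)["pop_65plus"].sum()


def load_population(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    **kwargs,
) -> PopulationTable:
    """Load and validate a population table from delimited text."""
    return PopulationTable.from_file(path, schema=schema, **kwargs)


def total_population(table: PopulationTable, by: Sequence[str] | None = None):
    """Functional alias for :meth:`PopulationTable.total_population`."""
    return table.total_population(by)


# ----------------------------------------------------------------------
# validation internals
# ----------------------------------------------------------------------

def _empty_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "unit_id": pd.Series(dtype=str),
            "jurisdiction": pd.Series(dtype=str),
            "decile": pd.Series(dtype="Int64"),
            "remoteness": pd.Series(dtype=str),
            "pop_65plus": pd.Series(dtype="int64"),
        }
    )


def _validate(
    df: pd.DataFrame,
    jurisdictions: tuple[str, ...],
    remoteness_classes: tuple[str, ...],
) -> pd.DataFrame:
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"population table missing column(s) {missing}")
    df = df[list(COLUMNS)].copy()
    if df.empty:
        return _empty_frame()

    problems: list[str] = []

    counts = pd.to_numeric(df["pop_65plus"], errors="coerce")
    for idx in df.index[counts.isna()]:
        problems.append(
            f"row {idx}: pop_65plus {df.at[idx, 'pop_65plus']!r} is not numeric"
        )
    neg = counts < 0
    for idx in df.index[neg.fillna(False)]:
        problems.append(f"row {idx}: pop_65plus {counts[idx]} is negative")
    frac = (counts % 1 != 0) & counts.notna()
    for idx in df.index[frac]:
        problems.append(f"row {idx}: pop_65plus {counts[idx]} is not an integer")

    deciles = pd.to_numeric(df["decile"], errors="coerce")
    has_decile = df["decile"].notna()
    bad_dec = has_decile & (deciles.isna() | (deciles < 1) | (deciles > 10))
    for idx in df.index[bad_dec]:
        problems.append(
            f"row {idx}: decile {df.at[idx, 'decile']!r} not in 1..10"
        )

    known = set(jurisdictions)
    bad_jur = ~df["jurisdiction"].isin(known)
    for idx in df.index[bad_jur]:
        problems.append(
            f"row {idx}: unknown jurisdiction {df.at[idx, 'jurisdiction']!r}"
        )

    allowed_rem = set(remoteness_classes) | {UNCLASSIFIED}
    bad_rem = ~df["remoteness"].isin(allowed_rem)
    for idx in df.index[bad_rem]:
        problems.append(
            f"row {idx}: unknown remoteness {df.at[idx, 'remoteness']!r}"
        )

    dup = df["unit_id"].duplicated(keep=False)
    if dup.any():
        dupes = sorted(df.loc[dup, "unit_id"].unique())
        problems.append(f"duplicate unit_id values: {dupes}")

    if problems:
        raise ValidationError(
            "population table validation failed:\n  " + "\n  ".join(problems)
        )

    out = df.copy()
    out["unit_id"] = out["unit_id"].astype(str)
    out["jurisdiction"] = out["jurisdiction"].astype(str)
    out["decile"] = deciles.astype("Int64")
    out["remoteness"] = out["remoteness"].astype(str)
    out["pop_65plus"] = counts.astype("int64")
    return out.reset_index(drop=True)
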