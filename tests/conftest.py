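import pandas as pd
import pytest

from agecost import PopulationTable, ServiceMix
from agecost.baseline import (
    reference_fee_schedule,
    reference_population,
    reference_service_mix,
)


@pytest.fixture(scope="session")
def mix() -> ServiceMix:
    return reference_service_mix()


@pytest.fixture(scope="session")
def ref_population() -> PopulationTable:
    return reference_population()


@pytest.fixture(scope="session")
def ref_fees():
    return reference_fee_schedule()


@pytest.fixture()
def wa_population() -> PopulationTable:
    """Single-stratum table holding the printed WA 65+ count."""
    return PopulationTable(
        pd.DataFrame(
            {
                "unit_id": ["WA"],
                "jurisdiction": ["WA"],
                "decile": [5],
                "remoteness": ["MajorCity"],
                "pop_65plus": [342_652],
            }
        )
    )


def make_population(rows) -> PopulationTable:
    """rows: iterable of (unit_id, jurisdiction, decile, remoteness, pop)."""
    return PopulationTable(
        pd.DataFrame(
            rows,
            columns=["unit_id", "jurisdiction", "decile", "remoteness", "pop_65plus"],
        )
    )
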