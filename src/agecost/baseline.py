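"""Reference inputs: the published 2016 Australian 65+ baseline.

This module bundles the printed inputs of the published national model so
the pipeline can regenerate its tables without access to the original
closed sources (census extracts, the private dental fees survey):

* the national visit rate and per-visit service mix (Table defaults in
  :mod:`agecost.services`);
* the four high-frequency diagnostic schedule items with their 2017 mean
  fees;
* the published jurisdiction x service-area cost table (millions of AUD),
  used to calibrate implied per-visit fees for the eight categories whose
  items were not published;
* jurisdiction 65+ population counts. Only the WA count was printed
  directly; the other seven are **reconstructed**: ACT, NT and Tas from
  their printed annual visit totals divided by the visit rate, and NSW,
  Vic, Qld and SA from their published prosthodontics cost divided by the
  published implied prosthodontics fee (1083 AUD/visit), the
  prosthodontics share of the mix and the visit rate. Reconstructed
  counts are good to the rounding of the published figures (roughly 0.1%)
  and are flagged as derived in the run manifest.

Everything here is data plus small deterministic derivations; nothing is
fitted.
"""

from __future__ import annotations

import pandas as pd

from .fees import CategoryFee, FeeItem, derive_category_fee
from .population import PopulationTable
from .services import DEFAULT_PER_VISIT_MEAN, DEFAULT_VISIT_RATE, ServiceMix

#: High-frequency diagnostic items, 2017 private GDP mean fees (AUD).
#: The bitewing radiograph is billed per exposure, twice per episode.
DIAGNOSTIC_ITEMS: tuple[FeeItem, ...] = (
    FeeItem("011", "Comprehensive oral examination", "Diagnostic", 55.20, 1),
    FeeItem("012", "Periodic oral examination", "Diagnostic", 45.85, 1),
    FeeItem("013", "Oral examination - limited", "Diagnostic", 28.00, 1),
    FeeItem(
        "022",
        "Intraoral periapical or bitewing radiograph - per exposure",
        "Diagnostic",
        38.80,
        2,
    ),
)

#: Published jurisdiction x service-area annual costs, millions of AUD.
REFERENCE_COSTS_MILLIONS: pd.DataFrame = pd.DataFrame(
    {
        "NSW": [866, 429, 369, 143, 102, 76, 74, 48, 10],
        "Vic": [656, 325, 279, 108, 77, 57, 56, 36, 8],
        "Qld": [510, 253, 217, 84, 60, 45, 44, 28, 6],
        "WA": [246, 122, 105, 40, 29, 22, 21, 14, 3],
        "SA": [218, 108, 93, 36, 26, 19, 19, 12, 3],
        "Tas": [70, 35, 30, 12, 8, 6, 6, 4, 1],
        "ACT": [35, 17, 15, 6, 4, 3, 3, 2, 0.4],
        "NT": [11, 6, 5, 2, 1, 1, 1, 1, 0.1],
    },
    index=pd.Index(
        [
            "Prosthodontics",
            "Restorative",
            "CrownBridge",
            "Diagnostic",
            "Preventive",
            "OralSurgery",
            "Endodontics",
            "General",
            "Periodontics",
        ],
        name="area",
    ),
)

#: Published row totals of the same table (computed before per-cell
#: rounding, so they differ from the sum of the cells above by up to 1).
REFERENCE_ROW_TOTALS_MILLIONS: dict[str, float] = {
    "Prosthodontics": 2612,
    "Restorative": 1295,
    "CrownBridge": 1112,
    "Diagnostic": 430,
    "Preventive": 308,
    "OralSurgery": 228,
    "Endodontics": 223,
    "General": 145,
    "Periodontics": 30,
}

#: Published implied annual cost per category visit (AUD), NSW column.
PROSTHODONTICS_FEE_AUD = 1083.0
PERIODONTICS_FEE_AUD = 203.0

#: Printed 65+ population (WA) and printed annual visit totals (ACT, NT,
#: Tas) used to reconstruct jurisdiction populations.
WA_POPULATION_65PLUS = 342_652
REFERENCE_VISIT_TOTALS: dict[str, int] = {
    "ACT": 126_466,
    "NT": 40_862,
    "Tas": 251_958,
}


def reference_service_mix() -> ServiceMix:
    """The published visit rate (2.58) and 2003-04 per-visit service mix."""
    return ServiceMix(
        mean_visits_per_person=DEFAULT_VISIT_RATE,
        per_visit_mean=dict(DEFAULT_PER_VISIT_MEAN),
    )


def reference_population() -> PopulationTable:
    """Jurisdiction-level 65+ counts for the published baseline.

    One stratum per jurisdiction. Decile and remoteness are not resolved
    at jurisdiction level, so decile is NA and remoteness Unclassified;
    jurisdiction-level groupings are unaffected.
    """
    rate = DEFAULT_VISIT_RATE
    prostho_share = DEFAULT_PER_VISIT_MEAN["Prosthodontics"]
    aud_per_person = PROSTHODONTICS_FEE_AUD * prostho_share * rate

    pops: dict[str, int] = {"WA": WA_POPULATION_65PLUS}
    for jur, visits in REFERENCE_VISIT_TOTALS.items():
        pops[jur] = round(visits / rate)
    for jur in ("NSW", "Vic", "Qld", "SA"):
        cost = REFERENCE_COSTS_MILLIONS.loc["Prosthodontics", jur] * 1e6
        pops[jur] = round(cost / aud_per_person)

    rows = [
        {
            "unit_id": jur,
            "jurisdiction": jur,
            "decile": pd.NA,
            "remoteness": "Unclassified",
            "pop_65plus": pops[jur],
        }
        for jur in REFERENCE_COSTS_MILLIONS.columns
    ]
    return PopulationTable(pd.DataFrame(rows))


def reference_fee_schedule(
    *, diagnostic_from_items: bool = False
) -> dict[str, CategoryFee]:
    """Per-category fees that reproduce the published cost table.

    Prosthodontics (1083 AUD) and periodontics (203 AUD) use the
    published implied per-visit costs. The remaining categories are
    calibrated from the NSW column: published cost divided by projected
    NSW visits in the category (NSW is the largest column, so its printed
    millions carry the least relative rounding error). Fees are held to
    cent precision.

    ``diagnostic_from_items=True`` instead averages the published
    diagnostic schedule items (51.66 AUD under the line-entry rule);
    note this is about 25% below the fee implied by the published cost
    table (~68.5), a documented inconsistency between the two published
    derivations.
    """
    mix = reference_service_mix()
    pop = reference_population()
    nsw_pop = int(pop.data.set_index("jurisdiction").loc["NSW", "pop_65plus"])
    nsw_visits = nsw_pop * mix.mean_visits_per_person

    fees: dict[str, CategoryFee] = {
        "Prosthodontics": CategoryFee(
            "Prosthodontics", PROSTHODONTICS_FEE_AUD, "calibrated"
        ),
        "Periodontics": CategoryFee(
            "Periodontics", PERIODONTICS_FEE_AUD, "calibrated"
        ),
    }
    for area, share in mix.per_visit_mean.items():
        if area in fees:
            continue
        if area == "Diagnostic" and diagnostic_from_items:
            fees[area] = derive_category_fee(list(DIAGNOSTIC_ITEMS))
            continue
        cost = REFERENCE_COSTS_MILLIONS.loc[area, "NSW"] * 1e6
        fees[area] = CategoryFee(
            area, round(cost / (nsw_visits * share), 2), "calibrated"
        )
    return {a: fees[a] for a in REFERENCE_COSTS_MILLIONS.index}
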