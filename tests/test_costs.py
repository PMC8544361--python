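"""Cost computation, aggregation, per-person averages and report formatting."""

import numpy as np
import pandas as pd
import pytest

from agecost import (
    ConfigurationError,
    ScenarioSpec,
    ValidationError,
    aggregate_costs,
    compute_costs,
    format_report,
    per_person_cost,
    project_service_visits,
)
from agecost.costs import DVA_SCENARIO, format_cell
from conftest import make_population


@pytest.fixture()
def wa_costs(wa_population, mix, ref_fees):
    vt = project_service_visits(wa_population, mix, round_totals=True)
    return compute_costs(vt, ref_fees)


def test_wa_prosthodontics_cell(wa_costs):
    """227,198.794 prosthodontic visits at 1083 AUD display as $246M."""
    cost = wa_costs.data.set_index("area")["cost"]
    assert cost["Prosthodontics"] == pytest.approx(227_198.794 * 1083)
    assert format_cell(cost["Prosthodontics"]) == "$246"


def test_wa_periodontics_cell(wa_costs):
    cost = wa_costs.data.set_index("area")["cost"]
    assert cost["Periodontics"] == pytest.approx(14_144.672 * 203)
    assert format_cell(cost["Periodontics"]) == "$3"


@pytest.mark.parametrize(
    "value, shown",
    [
        (2_871_368.4, "$3"),
        (246_056_295.9, "$246"),
        (412_000, "$0.4"),
        (120_000, "$0.1"),
        (0, "$0"),
        (1_000_000, "$1"),
        (999_999, "$1.0"),
    ],
)
def test_millions_display_rule(value, shown):
    assert format_cell(value) == shown


def test_missing_fee_rejected_before_computation(wa_population, mix, ref_fees):
    vt = project_service_visits(wa_population, mix)
    partial = {k: v for k, v in ref_fees.items() if k != "Endodontics"}
    with pytest.raises(ConfigurationError, match="Endodontics"):
        compute_costs(vt, partial)


def test_non_finite_visits_rejected(wa_population, mix, ref_fees):
    vt = project_service_visits(wa_population, mix)
    vt.data.loc[0, "visits"] = np.nan
    with pytest.raises(ValidationError, match="non-finite"):
        compute_costs(vt, ref_fees)


def test_scenario_multiplier_scales_every_cell(wa_population, mix, ref_fees):
    vt = project_service_visits(wa_population, mix)
    base = compute_costs(vt, ref_fees).data["cost"]
    dva = compute_costs(vt, ref_fees, DVA_SCENARIO).data["cost"]
    assert np.allclose(dva, 0.79 * base, rtol=1e-12)
    with pytest.raises(ValidationError):
        ScenarioSpec(multiplier=0.0)


def test_aggregation_conserves_and_margins_match(ref_population, mix, ref_fees):
    ct = compute_costs(project_service_visits(ref_population, mix), ref_fees)
    grand = ct.total
    by_jur = aggregate_costs(ct, by=["jurisdiction"])
    assert by_jur.sum() == pytest.approx(grand, rel=1e-12)
    with_margins = aggregate_costs(ct, by=["jurisdiction"], margins=True)
    assert with_margins.loc[("All", "All")] == pytest.approx(grand, rel=1e-12)
    for jur in ref_population.data["jurisdiction"]:
        got = with_margins.loc[(jur, "All")]
        want = by_jur.loc[jur].sum()
        assert got == pytest.approx(want, rel=1e-12)


def test_single_stratum_aggregation_is_identity(wa_costs):
    agg = aggregate_costs(wa_costs, by=["jurisdiction"])
    cell = wa_costs.data.set_index("area")["cost"]
    for area in wa_costs.data["area"]:
        assert agg.loc[("WA", area)] == cell[area]


def test_stratum_order_never_changes_aggregates(mix, ref_fees):
    rows = [
        ("A", "NSW", 1, "MajorCity", 1000),
        ("B", "WA", 5, "Remote", 2000),
        ("C", "Vic", 9, "InnerRegional", 1500),
    ]
    fwd = compute_costs(project_service_visits(make_population(rows), mix), ref_fees)
    rev = compute_costs(
        project_service_visits(make_population(rows[::-1]), mix), ref_fees
    )
    pd.testing.assert_series_equal(
        aggregate_costs(fwd, by=["jurisdiction"]),
        aggregate_costs(rev, by=["jurisdiction"]),
        rtol=1e-15,
    )


def test_per_person_cost_simple_and_proportional(mix, ref_fees):
    table = make_population(
        [("A", "NSW", 1, "MajorCity", 1000), ("B", "WA", 2, "MajorCity", 1000)]
    )
    ct = compute_costs(project_service_visits(table, mix), ref_fees)
    pp = per_person_cost(ct, table, by=["jurisdiction"])
    # equal populations -> per-person ratio equals cost ratio (here 1:1)
    assert pp.loc["NSW", "cost_per_person"] == pytest.approx(
        pp.loc["WA", "cost_per_person"]
    )
    national = per_person_cost(ct, table)
    assert national["cost_per_person"].iloc[0] == pytest.approx(
        ct.total / 2000
    )


def test_per_person_cost_exact_division():
    import agecost

    table = make_population([("A", "NSW", 1, "MajorCity", 1000)])
    one_area = agecost.ServiceMix(
        mean_visits_per_person=1.0, per_visit_mean={"X": 1.0}
    )
    fees = {"X": agecost.CategoryFee("X", 1000.0)}
    vt = project_service_visits(table, one_area, areas=("X",))
    ct = compute_costs(vt, fees)
    pp = per_person_cost(ct, table)
    assert pp["cost_per_person"].iloc[0] == pytest.approx(1000.0)


def test_zero_population_group_flagged_undefined(mix, ref_fees):
    table = make_population(
        [("A", "NSW", 1, "MajorCity", 1000), ("B", "WA", 2, "MajorCity", 0)]
    )
    ct = compute_costs(project_service_visits(table, mix), ref_fees)
    pp = per_person_cost(ct, table, by=["jurisdiction"])
    assert bool(pp.loc["WA", "undefined"]) is True
    assert np.isnan(pp.loc["WA", "cost_per_person"])
    assert bool(pp.loc["NSW", "undefined"]) is False


def test_decile_weighted_mean_equals_national(mix, ref_fees):
    """Population-weighted decile per-person costs recover the national value."""
    rng = np.random.default_rng(11)
    rows = [
        (f"U{i}", "NSW", (i % 10) + 1, "MajorCity", int(rng.integers(50, 150)))
        for i in range(200)
    ]
    table = make_population(rows)
    ct = compute_costs(project_service_visits(table, mix), ref_fees)
    pp = per_person_cost(ct, table, by=["decile"])
    weighted = (pp["cost_per_person"] * pp["population"]).sum() / pp["population"].sum()
    national = per_person_cost(ct, table)["cost_per_person"].iloc[0]
    assert weighted == pytest.approx(national, rel=1e-12)


def test_report_styles(wa_costs):
    shown = format_report(wa_costs, "millions")
    assert shown.loc["Prosthodontics", "WA"] == "$246"
    assert shown.loc["Prosthodontics", "Total"] == "$246"
    raw = format_report(wa_costs, "whole_aud")
    assert raw.loc["Periodontics", "WA"] == pytest.approx(14_144.672 * 203)
    with pytest.raises(ConfigurationError):
        format_report(wa_costs, "billions")
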