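"""Fee derivation, calibration and schedule loading."""

import pytest
import yaml
from hypothesis import given, settings
from hypothesis import strategies as st

from agecost import (
    CategoryFee,
    ConfigurationError,
    FeeItem,
    ValidationError,
    calibrate_implied_fee,
    derive_category_fee,
    load_fee_schedule,
)
from agecost.baseline import DIAGNOSTIC_ITEMS
from agecost.fees import load_fee_items, write_fee_items


def test_diagnostic_average_per_line_entry():
    """Four published diagnostic line entries average to 51.66 AUD."""
    fee = derive_category_fee(list(DIAGNOSTIC_ITEMS))
    assert fee.fee_per_visit == 51.66  # 206.65 / 4, to cents
    assert fee.provenance == "derived_from_items"
    assert fee.category == "Diagnostic"


def test_diagnostic_average_per_distinct_item():
    """Repeat-billed exposures drop from the denominator: 206.65 / 3."""
    fee = derive_category_fee(list(DIAGNOSTIC_ITEMS), "per_distinct_item")
    assert fee.fee_per_visit == 68.88


def test_single_item_identity():
    item = FeeItem("111", "x", "Preventive", 57.30, 1)
    assert derive_category_fee([item]).fee_per_visit == 57.30


def test_empty_and_mixed_item_lists_rejected():
    with pytest.raises(ValidationError, match="empty"):
        derive_category_fee([])
    mixed = [
        FeeItem("1", "a", "Preventive", 10.0, 1),
        FeeItem("2", "b", "Diagnostic", 20.0, 1),
    ]
    with pytest.raises(ValidationError, match="multiple categories"):
        derive_category_fee(mixed)


def test_unknown_denominator_rule_rejected():
    with pytest.raises(ConfigurationError, match="denominator rule"):
        derive_category_fee(list(DIAGNOSTIC_ITEMS), "per_episode")


def test_item_validation():
    with pytest.raises(ValidationError):
        FeeItem("1", "a", "Diagnostic", -1.0, 1)
    with pytest.raises(ValidationError):
        FeeItem("1", "a", "Diagnostic", 1.0, 0)


def test_calibrated_prosthodontics_fee():
    """246M AUD over the WA prosthodontic visits implies ~1083 AUD/visit."""
    fee = calibrate_implied_fee(246_000_000, 227_198.794, "Prosthodontics")
    assert round(fee.fee_per_visit, 2) == 1082.75
    assert fee.provenance == "calibrated"


def test_calibrate_zero_cost_gives_zero_fee():
    assert calibrate_implied_fee(0.0, 100.0).fee_per_visit == 0.0


def test_calibrate_zero_visits_rejected():
    with pytest.raises(ValidationError, match="visits"):
        calibrate_implied_fee(1000.0, 0.0)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    fee=st.floats(0.01, 5000, allow_nan=False),
    visits=st.floats(0.5, 1e7, allow_nan=False),
)
def test_calibration_round_trip_identity(fee, visits):
    """fee -> cost = fee*v -> calibrate -> fee, to machine precision."""
    cost = fee * visits
    back = calibrate_implied_fee(cost, visits)
    assert back.fee_per_visit == pytest.approx(fee, rel=1e-12)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    fees=st.lists(st.floats(0.5, 500), min_size=1, max_size=8),
    weights=st.lists(st.integers(1, 4), min_size=8, max_size=8),
    scale=st.floats(0.1, 10),
)
def test_derived_fee_homogeneous_in_item_fees(fees, weights, scale):
    """Scaling all item fees by c scales the category fee by c."""
    items = [
        FeeItem(str(i), "x", "General", round(f, 2), w)
        for i, (f, w) in enumerate(zip(fees, weights))
    ]
    scaled = [
        FeeItem(str(i), "x", "General", round(f * scale, 2), w)
        for i, (f, w) in enumerate(zip(fees, weights))
    ]
    base = derive_category_fee(items).fee_per_visit
    up = derive_category_fee(scaled).fee_per_visit
    # cent-rounding of item fees and results bounds the drift
    assert up == pytest.approx(base * scale, abs=0.03 * (1 + scale))


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    fees=st.lists(st.floats(1, 500), min_size=1, max_size=6),
    extra=st.floats(1, 400),
)
def test_adding_above_average_item_raises_average(fees, extra):
    items = [
        FeeItem(str(i), "x", "General", round(f, 2), 1)
        for i, f in enumerate(fees)
    ]
    avg = derive_category_fee(items).fee_per_visit
    richer = items + [FeeItem("z", "x", "General", round(avg + extra, 2), 1)]
    assert derive_category_fee(richer).fee_per_visit >= avg


def test_default_schedule_has_all_nine_categories(ref_fees):
    assert len(ref_fees) == 9
    assert ref_fees["Periodontics"].fee_per_visit == 203.0
    assert ref_fees["Prosthodontics"].fee_per_visit == 1083.0
    assert all(isinstance(f, CategoryFee) for f in ref_fees.values())


def test_schedule_missing_category_error_names_it(tmp_path):
    write_fee_items(list(DIAGNOSTIC_ITEMS), tmp_path / "fees.csv")
    with pytest.raises(ConfigurationError, match="Prosthodontics"):
        load_fee_schedule(tmp_path / "fees.csv")


def test_schedule_negative_fee_rejected(tmp_path):
    p = tmp_path / "fees.csv"
    p.write_text(
        "item_number,description,category,mean_fee,frequency_weight\n"
        "011,exam,Diagnostic,-5.0,1\n"
    )
    with pytest.raises(ValidationError, match="row 0"):
        load_fee_items(p)


def test_overrides_supply_missing_categories(tmp_path):
    write_fee_items(list(DIAGNOSTIC_ITEMS), tmp_path / "fees.csv")
    others = {
        a: 100.0
        for a in (
            "Preventive", "Periodontics", "OralSurgery", "Endodontics",
            "Restorative", "CrownBridge", "Prosthodontics", "General",
        )
    }
    override_path = tmp_path / "override.yaml"
    override_path.write_text(yaml.safe_dump(others))
    fees = load_fee_schedule(tmp_path / "fees.csv", overrides=override_path)
    assert fees["Diagnostic"].fee_per_visit == 51.66
    assert fees["Diagnostic"].provenance == "derived_from_items"
    assert fees["Prosthodontics"].provenance == "supplied"


def test_item_file_round_trip(tmp_path):
    path = tmp_path / "items.csv"
    write_fee_items(list(DIAGNOSTIC_ITEMS), path)
    again = load_fee_items(path)
    assert again == list(DIAGNOSTIC_ITEMS)
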