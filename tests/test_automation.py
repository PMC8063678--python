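"""Plates, picklists, simulation and liquid-handler export."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from synbiokit.automation import (
    PickList,
    Transfer,
    add_transfer,
    create_plate,
    export_picklist,
    fill_well,
    import_picklist,
    normalize_well_name,
    scenario_from_json,
    scenario_to_json,
    simulate_picklist,
    well_names,
)
from synbiokit.errors import SynbioValidationError


def test_96_well_plate_has_expected_names():
    plate = create_plate("src", 96)
    assert len(plate.wells) == 96
    names = well_names(96)
    assert names[0] == "A1" and names[-1] == "H12"
    assert all(w.is_empty for w in plate.wells.values())


def test_384_well_plate_spans_A1_to_P24():
    plate = create_plate("dst", 384)
    assert len(plate.wells) == 384
    assert well_names(384)[-1] == "P24"


def test_unsupported_format_is_rejected():
    with pytest.raises(SynbioValidationError, match="97"):
        create_plate("bad", 97)


def test_fill_accumulates_volume():
    plate = create_plate("p", 96)
    fill_well(plate, "A1", "dna", 50.0)
    assert plate.well("A1").volume == 50.0
    fill_well(plate, "A1", "dna", 25.0)
    assert plate.well("A1").contents == {"dna": 75.0}


def test_fill_over_capacity_names_the_well():
    plate = create_plate("p", 96, capacity=50.0)
    fill_well(plate, "A1", "water", 30.0)
    with pytest.raises(SynbioValidationError, match="A1"):
        fill_well(plate, "A1", "water", 30.0)


def test_zero_padded_well_names_accepted_but_normalized():
    plate = create_plate("p", 96)
    fill_well(plate, "A01", "x", 1.0)
    assert plate.well("A1").volume == 1.0
    assert normalize_well_name("B09") == "B9"


def test_add_transfer_appends_in_order():
    pl = PickList()
    add_transfer(pl, Transfer("s", "A1", "d", "B2", 10.0))
    add_transfer(pl, Transfer("s", "A2", "d", "B3", 5.0))
    assert len(pl) == 2
    assert pl.transfers[0].source_well == "A1"


def test_zero_volume_transfer_rejected():
    with pytest.raises(SynbioValidationError):
        Transfer("s", "A1", "d", "B2", 0.0)


def test_simple_transfer_moves_volume():
    src = create_plate("src", 96)
    dst = create_plate("dst", 96)
    fill_well(src, "A1", "dna", 50.0)
    pl = PickList([Transfer("src", "A1", "dst", "B2", 10.0)])
    state, report = simulate_picklist(pl, [src, dst])
    assert report[0].ok
    assert state["src"].well("A1").volume == pytest.approx(40.0)
    assert state["dst"].well("B2").volume == pytest.approx(10.0)
    # inputs untouched
    assert src.well("A1").volume == 50.0 and dst.well("B2").is_empty


def test_insufficient_volume_fails_at_index_0():
    src = create_plate("src", 96)
    fill_well(src, "A1", "dna", 50.0)
    pl = PickList([Transfer("src", "A1", "src", "B1", 60.0)])
    _, report = simulate_picklist(pl, [src])
    assert not report[0].ok and report[0].index == 0


def test_proportional_mixing():
    src = create_plate("src", 96)
    fill_well(src, "A1", "water", 40.0)
    fill_well(src, "A1", "dye", 10.0)
    pl = PickList([Transfer("src", "A1", "src", "B1", 10.0)])
    state, report = simulate_picklist(pl, [src])
    assert report[0].ok
    assert state["src"].well("B1").contents == pytest.approx({"water": 8.0, "dye": 2.0})
    assert state["src"].well("A1").contents == pytest.approx({"water": 32.0, "dye": 8.0})


def test_on_error_abort_vs_skip():
    src = create_plate("src", 96)
    fill_well(src, "A1", "x", 20.0)
    pl = PickList(
        [
            Transfer("src", "A1", "src", "B1", 50.0),  # fails
            Transfer("src", "A1", "src", "B2", 5.0),
        ]
    )
    _, abort_report = simulate_picklist(pl, [src], on_error="abort")
    assert len(abort_report) == 1
    state, skip_report = simulate_picklist(pl, [src], on_error="skip")
    assert [r.ok for r in skip_report] == [False, True]
    assert state["src"].well("B2").volume == pytest.approx(5.0)


def test_demo_scenario_counts_and_conservation(demo_picklist):
    source, dest, picklist = demo_picklist
    assert source.format == 96 and dest.format == 384
    assert len(picklist) == 2
    before = source.total_volume + dest.total_volume
    state, report = simulate_picklist(picklist, [source, dest])
    assert all(r.ok for r in report)
    after = sum(p.total_volume for p in state.values())
    assert after == pytest.approx(before, abs=1e-12)


def test_echo_export_converts_to_nanoliters(demo_picklist):
    _, _, picklist = demo_picklist
    csv_text = export_picklist(picklist, "echo_csv")
    lines = csv_text.strip().splitlines()
    assert lines[0] == (
        "Source Plate Name,Source Well,Destination Plate Name,"
        "Destination Well,Transfer Volume"
    )
    assert len(lines) == 3
    assert lines[1].endswith(",10000")


def test_echo_rejects_off_grid_volume_when_strict():
    pl = PickList([Transfer("s", "A1", "d", "B1", 0.0014)])  # 1.4 nL
    with pytest.raises(SynbioValidationError, match="2.5"):
        export_picklist(pl, "echo_csv", strict=True)
    with pytest.warns(UserWarning, match="rounded"):
        out = export_picklist(pl, "echo_csv", strict=False)
    assert out.strip().splitlines()[1].endswith(",2.5")


def test_empty_picklist_exports_header_only():
    assert export_picklist(PickList(), "echo_csv").strip().count("\n") == 0


def test_generic_csv_round_trip(demo_picklist):
    _, _, picklist = demo_picklist
    back = import_picklist(export_picklist(picklist, "generic_csv"))
    assert back.transfers == picklist.transfers


def test_scenario_json_round_trip(demo_picklist):
    source, dest, picklist = demo_picklist
    plates, pl = scenario_from_json(scenario_to_json([source, dest], picklist))
    assert pl.transfers == picklist.transfers
    assert plates[0].well("A1").contents == source.well("A1").contents


@settings(max_examples=50, deadline=None, derandomize=True)
@given(data=st.data())
def test_volume_conservation_property(data):
    """Total volume across all plates is invariant under simulation, and no
    well goes negative or above capacity."""
    plate = create_plate("p", 96)
    wells = well_names(96)[:8]
    for w in wells:
        vol = data.draw(st.floats(0.0, 150.0), label=f"fill {w}")
        if vol > 0:
            fill_well(plate, w, "mix", vol)
    pl = PickList()
    for _ in range(data.draw(st.integers(0, 6), label="n transfers")):
        src = data.draw(st.sampled_from(wells), label="src")
        dst = data.draw(st.sampled_from(wells), label="dst")
        if src == dst:
            continue
        add_transfer(pl, Transfer("p", src, "p", dst, data.draw(st.floats(0.1, 60.0))))
    before = plate.total_volume
    state, report = simulate_picklist(pl, [plate], on_error="skip")
    after = state["p"].total_volume
    assert after == pytest.approx(before, rel=1e-12, abs=1e-9)
    for w in state["p"].wells.values():
        assert w.volume >= 0.0
        assert w.volume <= w.capacity + 1e-9
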