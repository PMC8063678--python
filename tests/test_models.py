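"""SBML/SED-ML/OMEX codec and the built-in integrator."""

import io
import math
import zipfile

import numpy as np
import pytest
from lxml import etree

from synbiokit import fixtures as fx
from synbiokit.errors import SynbioError, SynbioValidationError
from synbiokit.models import (
    FORMAT_SBML,
    FORMAT_SEDML,
    OdeModel,
    Parameter,
    TimeCourseSpec,
    execute_omex,
    export_omex,
    export_sbml,
    export_sedml,
    model_from_json,
    model_to_json,
    pack_omex,
    parse_sedml,
    read_omex,
    read_sbml,
    rk4_fixed_step,
    simulate,
)


@pytest.fixture
def decay():
    return fx.make_decay_model()


# ---------------------------------------------------------------------------
# SBML


def test_decay_model_sbml_structure(decay):
    model, _ = decay
    root = etree.fromstring(export_sbml(model).encode())
    ns = {"s": "http://www.sbml.org/sbml/level3/version1/core"}
    assert len(root.findall(".//s:species", ns)) == 1
    assert len(root.findall(".//s:parameter", ns)) == 1
    assert len(root.findall(".//s:rateRule", ns)) == 1
    assert len(root.findall(".//s:compartment", ns)) == 1


def test_and_gate_model_has_four_rate_rules():
    root = etree.fromstring(export_sbml(fx.make_and_gate_model()).encode())
    ns = {"s": "http://www.sbml.org/sbml/level3/version1/core"}
    assert len(root.findall(".//s:rateRule", ns)) == 4


def test_empty_model_is_rejected():
    with pytest.raises(SynbioValidationError):
        OdeModel(variables=[], odes=[], init={})


def test_duplicate_names_across_variables_and_params_rejected():
    with pytest.raises(SynbioValidationError, match="duplicate"):
        OdeModel(
            variables=["X"], odes=["-X*X"], init={"X": 1.0}, params=[Parameter("X", 2.0)]
        )


def test_unknown_unit_token_becomes_dimensionless_with_warning():
    model = OdeModel(
        variables=["X"], odes=["-k*X"], init={"X": 1.0},
        params=[Parameter("k", 0.1, "furlongs")],
    )
    with pytest.warns(UserWarning, match="furlongs"):
        sbml = export_sbml(model)
    assert 'units="dimensionless"' in sbml


def test_sbml_round_trip_simulates_identically(decay):
    model, spec = decay
    ts1 = simulate(model, spec)
    ts2 = simulate(read_sbml(export_sbml(model)), spec)
    assert np.max(np.abs(ts1.values["X"] - ts2.values["X"])) < 1e-9


def test_and_gate_sbml_round_trip_simulates_identically():
    model = fx.make_and_gate_model()
    spec = TimeCourseSpec(0.0, 100.0, 51, ["R"])
    ts1 = simulate(model, spec)
    ts2 = simulate(read_sbml(export_sbml(model)), spec)
    assert np.max(np.abs(ts1.values["R"] - ts2.values["R"])) < 1e-9


def test_model_json_round_trip(decay):
    model, _ = decay
    back = model_from_json(model_to_json(model))
    assert back.variables == model.variables
    assert back.odes == model.odes
    assert [p.name for p in back.params] == [p.name for p in model.params]


# ---------------------------------------------------------------------------
# integrator


def test_decay_matches_closed_form(decay):
    model, spec = decay
    ts = simulate(model, spec)
    assert abs(ts.values["X"][-1] - 10 * math.exp(-1)) < 1e-4


def test_zero_rhs_gives_constant_trajectory():
    model = OdeModel(variables=["Y"], odes=["0*Y"], init={"Y": 3.5})
    ts = simulate(model, TimeCourseSpec(0, 5, 11, ["Y"]))
    assert np.allclose(ts.values["Y"], 3.5)


def test_integration_blowup_reports_failure_time():
    model = OdeModel(variables=["X"], odes=["X*X"], init={"X": 1.0})
    with pytest.raises(SynbioError, match="t="):
        simulate(model, TimeCourseSpec(0, 10, 11, ["X"]))


def test_and_gate_is_an_and_gate_against_rk4_oracle():
    """State 11 reporter dominates each single-input state by >=10x, and the
    adaptive integrator agrees with a fixed-step RK4 reference."""
    spec = TimeCourseSpec(0.0, 200.0, 41, ["R"])
    finals = {}
    for state in fx.INPUT_STATES:
        u1 = 1.0 if state[0] == "1" else fx.INPUT_OFF
        u2 = 1.0 if state[1] == "1" else fx.INPUT_OFF
        model = fx.make_and_gate_model(u1, u2)
        ts = simulate(model, spec)
        finals[state] = ts.values["R"][-1]
        oracle = rk4_fixed_step(model, spec, h=0.01)
        assert np.max(np.abs(ts.values["R"] - oracle.values["R"])) < 1e-3 * max(
            1.0, np.max(np.abs(oracle.values["R"]))
        )
    assert finals["11"] >= 10 * finals["01"]
    assert finals["11"] >= 10 * finals["10"]


def test_adaptive_solver_vs_rk4_on_random_linear_systems():
    """Dormand-Prince at rtol 1e-6 stays within 1e-5 relative of brute-force
    fixed-step RK4 (h=1e-4) on random stable 3-species linear systems."""
    rng = np.random.default_rng(42)
    for _ in range(4):
        A = rng.uniform(-1.0, 1.0, size=(3, 3))
        A -= 2.0 * np.eye(3)  # keep it stable
        variables = ["x1", "x2", "x3"]
        odes = [
            " + ".join(f"({float(A[i, j])!r})*{variables[j]}" for j in range(3)) for i in range(3)
        ]
        model = OdeModel(
            variables=variables, odes=odes,
            init={v: float(rng.uniform(0.5, 2.0)) for v in variables},
        )
        spec = TimeCourseSpec(0.0, 1.0, 11, variables)
        fast = simulate(model, spec)
        slow = rk4_fixed_step(model, spec, h=1e-4)
        for v in variables:
            scale = np.maximum(1.0, np.abs(slow.values[v]))
            assert np.max(np.abs(fast.values[v] - slow.values[v]) / scale) < 1e-5


# ---------------------------------------------------------------------------
# SED-ML / OMEX


def test_sedml_round_trip(decay):
    model, spec = decay
    tasks = parse_sedml(export_sedml("model.xml", spec))
    assert len(tasks) == 1
    assert tasks[0].model_source == "model.xml"
    assert tasks[0].spec.start == spec.start
    assert tasks[0].spec.end == spec.end
    assert tasks[0].spec.points == spec.points
    assert tasks[0].spec.outputs == spec.outputs


def test_pack_then_list_names_model_and_simulation(decay):
    model, spec = decay
    archive = export_omex(model, spec)
    contents = read_omex(archive)
    assert set(contents) == {"model.xml", "simulation.sedml"}
    assert contents["model.xml"][1] == FORMAT_SBML
    assert contents["simulation.sedml"][1] == FORMAT_SEDML


def test_manifest_entry_count_is_file_count_plus_one(decay):
    model, spec = decay
    archive = export_omex(model, spec)
    with zipfile.ZipFile(io.BytesIO(archive)) as zf:
        man = etree.fromstring(zf.read("manifest.xml"))
        n_files = len(zf.namelist())
    assert len(man) == n_files  # = (files except manifest) + manifest entry


def test_omex_re_extracts_byte_identically(decay):
    model, spec = decay
    archive = export_omex(model, spec)
    assert archive == export_omex(model, spec)
    sbml = export_sbml(model)
    with zipfile.ZipFile(io.BytesIO(archive)) as zf:
        assert zf.read("model.xml").decode() == sbml


def test_execute_decay_archive_matches_closed_form(decay):
    model, spec = decay
    (ts,) = execute_omex(export_omex(model, spec))
    assert abs(ts.values["X"][-1] - 10 * math.exp(-1)) < 1e-4


def test_missing_manifest_is_rejected():
    buf = io.BytesIO()
    with zipfile.ZipFile(buf, "w") as zf:
        zf.writestr("model.xml", "<sbml/>")
    with pytest.raises(SynbioValidationError, match="manifest"):
        read_omex(buf.getvalue())


def test_sedml_referencing_absent_model_is_rejected(decay):
    model, spec = decay
    sedml = export_sedml("nowhere.xml", spec)
    archive = pack_omex([("simulation.sedml", sedml, FORMAT_SEDML)])
    with pytest.raises(SynbioValidationError, match="nowhere.xml"):
        execute_omex(archive)


def test_and_gate_archive_returns_four_time_series():
    results = execute_omex(fx.make_and_gate_omex())
    assert len(results) == 4
    assert [ts.task for ts in results] == [f"task_{s}" for s in fx.INPUT_STATES]
    finals = {ts.task: ts.values["R"][-1] for ts in results}
    assert finals["task_11"] > finals["task_01"]
    assert finals["task_11"] > finals["task_10"]
    assert finals["task_01"] > finals["task_00"]
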