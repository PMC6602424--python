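"""I/O round-trips for the SBML subset and the bundled text format."""

import io

import pytest
import sympy as sp

import sbkernel as sk
from sbkernel.model_io import (
    SbmlExportError,
    SbmlImportError,
    TextSyntaxError,
    read_sbml,
    read_text,
    read_timecourse,
    write_sbml,
    write_text,
)

from conftest import flat_catalogue_names, models_equal

MINIMAL_SBML = b"""<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level3/version2/core" level="3" version="2">
  <model id="minimal">
    <listOfCompartments><compartment id="cell" size="1" constant="true"/></listOfCompartments>
    <listOfSpecies>
      <species id="A" compartment="cell" initialAmount="2" hasOnlySubstanceUnits="true"
               boundaryCondition="false" constant="false"/>
    </listOfSpecies>
  </model>
</sbml>
"""


def test_minimal_sbml_reads_one_species_no_reactions():
    _, model = read_sbml(MINIMAL_SBML)
    assert len(model.variables) == 1
    assert model.variables[0].id == "A"
    assert model.variables[0].initial_value == 2.0
    assert model.reactions == []


def test_kinetic_law_ast_survives_sbml(decay):
    diagram, model = decay
    _, model2 = read_sbml(write_sbml(diagram, model))
    assert model2.reactions[0].kinetic_law == sp.Symbol("k") * sp.Symbol("A")


def test_comp_package_raises_import_error():
    doc = MINIMAL_SBML.replace(
        b'xmlns="http://www.sbml.org/sbml/level3/version2/core"',
        b'xmlns="http://www.sbml.org/sbml/level3/version2/core" '
        b'xmlns:comp="http://www.sbml.org/sbml/level3/version1/comp/version1"',
    )
    with pytest.raises(SbmlImportError, match="comp"):
        read_sbml(doc)


def test_malformed_xml_raises():
    with pytest.raises(SbmlImportError, match="malformed"):
        read_sbml(b"<sbml><unclosed>")


@pytest.mark.parametrize("name", flat_catalogue_names())
def test_sbml_round_trip_is_identical(name):
    diagram, model = sk.canonical(name)
    _, model2 = read_sbml(write_sbml(diagram, model))
    assert models_equal(model, model2)


@pytest.mark.parametrize("name", flat_catalogue_names())
def test_text_round_trip_is_identical(name):
    diagram, model = sk.canonical(name)
    _, model2 = read_text(write_text(diagram, model))
    assert models_equal(model, model2)


@pytest.mark.parametrize("name", flat_catalogue_names())
def test_cross_format_consistency(name):
    """text -> model equals text -> model -> SBML -> model, element-wise."""
    diagram, model = sk.canonical(name)
    _, model2 = read_sbml(write_sbml(diagram, model))
    assert models_equal(model, model2)
    _, model3 = read_sbml(write_sbml(*read_text(write_text(diagram, model))))
    assert models_equal(model, model3)


def test_modular_model_cannot_export_to_sbml():
    mm = sk.canonical("decay_chain_modular")
    with pytest.raises(SbmlExportError, match="flatten"):
        write_sbml(None, mm)


def test_simple_text_model_parses():
    _, model = read_text("model t\nA = 1\nk = 1\nJ1: A -> B; k*A\n")
    assert len(model.variables) == 2
    assert len(model.reactions) == 1
    assert [p.id for p in model.parameters] == ["k"]


def test_text_modifiers_are_detected():
    _, model = read_text(
        "model t\nspecies A = 1\nspecies B = 0\nspecies E = 1\nconst k = 1\n"
        "J1: A -> B; k*A*E\n"
    )
    assert model.reactions[0].modifiers == ["E"]


def test_two_module_file_produces_modular_model():
    mm = read_text(
        "module M1\n  species A = 1\n  const k = 1\n  J1: A -> ; k*A\nend\n"
        "module M2\n  species B = 0\n  const k = 2\n  J1: B -> ; k*B\nend\n"
        "connect M1.A -> M2.B\n"
    )
    assert len(mm.modules) == 2
    assert len(mm.connections) == 1
    assert mm.connections[0].kind == "directed"


def test_syntax_error_reports_line_number():
    with pytest.raises(TextSyntaxError, match="line 3"):
        read_text("model t\nspecies A = 1\n???bogus???\n")


def test_event_with_delay_round_trips():
    src = (
        "model ev\nspecies A = 1\nconst y = 0\nconst k = 1\nJ1: A -> ; k*A\n"
        "at (A < 0.5) delay 1.5: y = 2*A\n"
    )
    d, m = read_text(src)
    assert m.events[0].delay == sp.Float(1.5)
    _, m2 = read_text(write_text(d, m))
    assert models_equal(m, m2)
    _, m3 = read_sbml(write_sbml(d, m))
    assert models_equal(m, m3)


def test_timecourse_table_reads_three_points():
    exp = read_timecourse(io.StringIO("time,A\n0,1.0\n0.5,0.61\n1.0,0.37\n"))
    assert exp.kind == "time_course"
    assert len(exp.times()) == 3
    assert exp.symbols() == ["A"]


def test_blank_cell_is_marked_missing_row_kept():
    exp = read_timecourse(io.StringIO("time,A,B\n0,1.0,2.0\n1,,1.5\n"))
    missing = [o for o in exp.observations if o.missing]
    assert len(missing) == 1
    assert missing[0].symbol == "A"
    assert len(exp.times()) == 2


def test_steady_state_table():
    exp = read_timecourse(io.StringIO("A,B\n1.0,2.0\n"), steady_state=True)
    assert exp.kind == "steady_state"
    assert all(o.time is None for o in exp.observations)


def test_duplicate_time_rejected():
    with pytest.raises(ValueError, match="duplicate"):
        read_timecourse(io.StringIO("time,A\n0,1\n0,2\n"))


def test_non_numeric_cell_rejected():
    with pytest.raises(ValueError, match="non-numeric"):
        read_timecourse(io.StringIO("time,A\n0,oops\n"))


def test_tab_delimiter_autodetected():
    exp = read_timecourse(io.StringIO("time\tA\n0\t1.0\n1\t0.4\n"))
    assert len(exp.times()) == 2
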