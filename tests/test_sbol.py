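"""SBOL conversion, role mapping and RDF/XML serialization."""

import re

import pytest
from hypothesis import given, settings

from synbiokit import fixtures as fx
from synbiokit.errors import SynbioValidationError
from synbiokit.records import Feature, GeneticRecord, Span
from synbiokit.sbol import (
    FEATURE_BY_ROLE,
    ROLE_BY_FEATURE,
    SbolDocument,
    convert,
    feature_for_role,
    read_sbol_xml,
    record_to_sbol,
    role_for_feature,
    sanitize_display_id,
    sbol_to_record,
    sniff_format,
    write_sbol_xml,
)
from tests.conftest import genetic_records


def test_and_gate_converts_to_one_component_five_annotations(and_gate_record):
    doc = record_to_sbol(and_gate_record)
    assert len(doc.components) == 1
    assert len(doc.sequences) == 1
    assert len(doc.components[0].annotations) == 5


def test_featureless_record_gives_component_without_annotations():
    doc = record_to_sbol(GeneticRecord(id="bare", sequence="ACGT"))
    assert len(doc.components) == 1
    assert doc.components[0].annotations == []


@pytest.mark.parametrize(
    "ftype,accession",
    [
        ("promoter", "SO:0000167"),
        ("RBS", "SO:0000139"),
        ("CDS", "SO:0000316"),
        ("terminator", "SO:0000141"),
        ("rep_origin", "SO:0000296"),
        ("never_heard_of_it", "SO:0000110"),
    ],
)
def test_role_mapping(ftype, accession):
    assert role_for_feature(ftype).endswith(accession)


def test_role_map_and_reverse_compose_to_identity_on_mapped_keys():
    for key, uri in ROLE_BY_FEATURE.items():
        if FEATURE_BY_ROLE[uri] == key:  # first-listed key per accession
            assert feature_for_role(role_for_feature(key)) == key


def test_unknown_role_reverse_maps_to_misc_feature():
    assert feature_for_role("http://identifiers.org/so/SO:9999999") == "misc_feature"


def test_span_emits_one_based_inclusive_range():
    rec = GeneticRecord(id="r", sequence="A" * 30, features=[Feature("CDS", Span(9, 20))])
    ann = record_to_sbol(rec).components[0].annotations[0]
    assert (ann.start, ann.end) == (10, 20)


def test_reverse_complement_orientation_round_trips_to_minus_strand():
    rec = GeneticRecord(
        id="r", sequence="A" * 30, features=[Feature("CDS", Span(0, 9), strand=-1)]
    )
    back = sbol_to_record(record_to_sbol(rec))
    assert back.features[0].strand == -1


def test_duplicate_display_ids_get_deterministic_suffixes():
    rec = GeneticRecord(
        id="r",
        sequence="A" * 30,
        features=[Feature("CDS", Span(0, 5)), Feature("CDS", Span(10, 15)), Feature("CDS", Span(20, 25))],
    )
    ids = [a.display_id for a in record_to_sbol(rec).components[0].annotations]
    assert ids == ["CDS", "CDS_2", "CDS_3"]


def test_empty_sequence_is_rejected():
    with pytest.raises(SynbioValidationError):
        record_to_sbol(GeneticRecord(id="r", sequence=""))


def test_sanitize_display_id():
    assert sanitize_display_id("p15A ori (v2)") == "p15A_ori__v2_"
    assert sanitize_display_id("3xFLAG") == "_3xFLAG"


def test_round_trip_preserves_feature_table(and_gate_record):
    back = sbol_to_record(record_to_sbol(and_gate_record))
    assert [(f.type, f.location, f.strand) for f in back.features] == [
        (f.type, f.location, f.strand) for f in and_gate_record.features
    ]
    assert back.sequence == and_gate_record.sequence


def test_xml_round_trip_is_identity(and_gate_record):
    doc = record_to_sbol(and_gate_record)
    doc2 = read_sbol_xml(write_sbol_xml(doc))
    assert doc2.components == doc.components
    assert doc2.sequences == doc.sequences


def test_empty_document_serializes_to_bare_rdf_root():
    xml = write_sbol_xml(SbolDocument())
    assert "RDF" in xml
    assert "ComponentDefinition" not in xml


def test_hand_written_minimal_sbol_parses_to_one_component():
    doc = read_sbol_xml(fx.make_minimal_sbol())
    assert len(doc.components) == 1
    assert doc.components[0].display_id == "minimal"
    assert doc.sequences[0].elements == "ACGTACGT"


def test_component_without_sequence_is_rejected():
    doc = read_sbol_xml(fx.make_minimal_sbol())
    doc.components[0].sequence_ref = None
    with pytest.raises(SynbioValidationError, match="minimal"):
        sbol_to_record(doc)


def test_emitted_uris_are_namespace_prefixed_and_valid(and_gate_record):
    doc = record_to_sbol(and_gate_record, namespace="http://example.org/designs")
    uri = re.compile(r"^https?://\S+$")
    for comp in doc.components:
        assert comp.identity.startswith("http://example.org/designs/")
        assert uri.match(comp.identity)
        for ann in comp.annotations:
            assert uri.match(ann.role)
    for seq in doc.sequences:
        assert seq.identity.startswith("http://example.org/designs/")


@settings(max_examples=100, deadline=None, derandomize=True)
@given(rec=genetic_records())
def test_sbol_round_trip_property(rec):
    """genbank<->sbol edges preserve feature count, spans and strands."""
    back = sbol_to_record(read_sbol_xml(write_sbol_xml(record_to_sbol(rec))))
    assert back.sequence == rec.sequence
    got = sorted((f.location.start, f.location.end, f.strand) for f in back.features)
    want = sorted((f.location.start, f.location.end, f.strand) for f in rec.features)
    assert got == want


# ---------------------------------------------------------------------------
# any-to-any conversion


def test_sniffing(and_gate_genbank, and_gate_record):
    from synbiokit.records import write_record

    assert sniff_format(and_gate_genbank) == "genbank"
    assert sniff_format(">x\nACGT\n") == "fasta"
    assert sniff_format(write_record(and_gate_record, "gff3")) == "gff3"
    assert sniff_format(write_sbol_xml(record_to_sbol(and_gate_record))) == "sbol"
    with pytest.raises(Exception, match="detect"):
        sniff_format("garbage with no format sigils whatsoever")


def test_genbank_to_sbol_to_genbank_preserves_feature_count(and_gate_genbank):
    sbol_xml = convert(and_gate_genbank, "sbol")
    gb_again = convert(sbol_xml, "genbank")
    from synbiokit.records import read_record

    (rec,) = read_record(gb_again, "genbank")
    assert len(rec.features) == 5


def test_genbank_to_fasta_is_lossy_with_warning(and_gate_genbank, and_gate_record):
    with pytest.warns(UserWarning, match="drops"):
        fasta = convert(and_gate_genbank, "fasta")
    assert "".join(fasta.strip().splitlines()[1:]) == and_gate_record.sequence


def test_gff3_with_fasta_companion_converts_to_five_annotations(and_gate_record):
    from synbiokit.records import write_record

    gff = write_record(and_gate_record, "gff3")
    doc = read_sbol_xml(convert(gff, "sbol"))
    assert len(doc.components[0].annotations) == 5
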