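"""Deterministic generators for every demo and test input.

Nothing here is downloaded or read from disk: each generator is a pure
function of its seed, so the whole test suite (and the worked examples in
the documentation) run with no network and no external data.

The AND-gate artifacts emulate a two-input genetic logic gate: a
blue-light-inducible system plus a chemical inducer jointly driving
expression of a red fluorescent reporter.  The *sequence content* is
synthetic (random bases under a fixed seed) — only the part structure
(promoter, RBS, CDS, terminator, replication origin on a circular
plasmid) mirrors the real design; likewise the kinetic parameters of the
ODE fixture are illustrative, chosen to give crisp AND behaviour, not
measured values.
"""

from __future__ import annotations

import random
from pathlib import Path

from synbiokit.automation import (
    PickList,
    Plate,
    Transfer,
    add_transfer,
    create_plate,
    fill_well,
)
from synbiokit.codon import CODONS_BY_AA
from synbiokit.models import (
    FORMAT_SBML,
    FORMAT_SEDML,
    OdeModel,
    Parameter,
    TimeCourseSpec,
    export_sbml,
    export_sedml,
    pack_omex,
)
from synbiokit.records import Feature, GeneticRecord, Span, write_record

AND_GATE_LENGTH = 3000

#: part structure of the AND-gate plasmid: (feature key, internal span,
#: strand, label).  Coordinates are fixed by construction.
AND_GATE_PARTS = [
    ("promoter", Span(99, 135), 1, "pBLind"),
    ("RBS", Span(149, 171), 1, "rbs34"),
    ("CDS", Span(179, 857), 1, "RFP"),
    ("terminator", Span(869, 950), 1, "L3S2P21"),
    ("rep_origin", Span(1999, 2600), 1, "pUC_ori"),
]


def make_and_gate_record(seed: int = 0) -> GeneticRecord:
    """The AND-gate plasmid as a record: 3000 bp, circular, 5 parts."""
    rng = random.Random(seed)
    seq = "".join(rng.choice("ACGT") for _ in range(AND_GATE_LENGTH))
    features = [
        Feature(ftype, span, strand, {"label": [label]})
        for ftype, span, strand, label in AND_GATE_PARTS
    ]
    return GeneticRecord(
        id="pANDgate",
        sequence=seq,
        description="synthetic AND logic gate plasmid (blue light AND inducer -> RFP)",
        topology="circular",
        features=features,
    )


def make_and_gate_genbank(seed: int = 0) -> str:
    """GenBank flat-file text of the AND-gate plasmid (byte-deterministic)."""
    return write_record(make_and_gate_record(seed), "genbank")


#: circuit-string form of the same design for the diagram renderer: two
#: sensor cassettes driving a reporter cassette, plus the origin
AND_GATE_CIRCUIT = "p.blue.pBLind r c.gray.EL222 t p r c.orange.AraC t p r c.red.RFP t o"
AND_GATE_REGULATION = "2->8.activation 6->8.activation"


def make_demo_picklist() -> tuple[Plate, Plate, PickList]:
    """The liquid-handling demo: a 96-well source plate with two filled
    wells, a 384-well destination plate, and a picklist of two transfers."""
    source = create_plate("Source", 96)
    fill_well(source, "A1", "dna_backbone", 50.0)
    fill_well(source, "A2", "dna_insert", 50.0)
    dest = create_plate("Destination", 384)
    picklist = PickList()
    add_transfer(picklist, Transfer("Source", "A1", "Destination", "A1", 10.0))
    add_transfer(picklist, Transfer("Source", "A2", "Destination", "A1", 10.0))
    return source, dest, picklist


def make_kazusa_fixture() -> str:
    """A complete 64-codon table in Kazusa text format with hand-chosen
    counts.

    Within each amino acid the lexicographically sorted codons get counts
    10, 20, 30, ... — except leucine, which carries the documented 60/40
    split (CTG 60, CTT 40, the other four codons 0).
    """
    counts: dict[str, int] = {}
    for aa, codons in sorted(CODONS_BY_AA.items()):
        if aa == "L":
            for c in codons:
                counts[c] = 0
            counts["CTG"] = 60
            counts["CTT"] = 40
        else:
            for i, c in enumerate(sorted(codons)):
                counts[c] = 10 * (i + 1)
    total = sum(counts.values())
    lines = ["# synthetic codon-usage fixture (Kazusa layout: CODON per-1000 (count))"]
    row = []
    for codon in sorted(counts):
        rna = codon.replace("T", "U")
        per1000 = 1000.0 * counts[codon] / total
        row.append(f"{rna} {per1000:4.1f}({counts[codon]:6d})")
        if len(row) == 4:
            lines.append("  ".join(row))
            row = []
    if row:
        lines.append("  ".join(row))
    return "\n".join(lines) + "\n"


def make_and_gate_model(u1: float = 1.0, u2: float = 1.0) -> OdeModel:
    """Kinetic AND-gate fixture: two inducer inputs with first-order
    sensor dynamics, a product-of-Hills AND term driving reporter mRNA,
    and first-order dilution throughout.

    ``u1``/``u2`` are the input levels (1.0 = on; the off state is a leaky
    0.05 so off-state output is small but nonzero).  Time is in minutes;
    concentrations are in arbitrary units (dimensionless in the SBML).
    """
    return OdeModel(
        variables=["x1", "x2", "m", "R"],
        odes=[
            "a1*u1 - d1*x1",
            "a2*u2 - d2*x2",
            "b*hill(x1, K1, n1)*hill(x2, K2, n2) - deg_m*m",
            "k_R*m - deg_R*R",
        ],
        init={"x1": 0.0, "x2": 0.0, "m": 0.0, "R": 0.0},
        params=[
            Parameter("u1", u1),
            Parameter("u2", u2),
            Parameter("a1", 10.0),
            Parameter("a2", 10.0),
            Parameter("d1", 0.1),
            Parameter("d2", 0.1),
            Parameter("b", 5.0),
            Parameter("K1", 50.0),
            Parameter("K2", 50.0),
            Parameter("n1", 2.0),
            Parameter("n2", 2.0),
            Parameter("deg_m", 0.2),
            Parameter("k_R", 2.0),
            Parameter("deg_R", 0.05),
        ],
        name="ANDgate",
    )


INPUT_OFF = 0.05  # leaky off-state input level
INPUT_STATES = ("00", "01", "10", "11")

AND_GATE_TIMECOURSE = TimeCourseSpec(start=0.0, end=500.0, points=201, outputs=["m", "R"])


def make_and_gate_omex() -> bytes:
    """COMBINE archive with the four AND-gate input states (00/01/10/11):
    one SBML model and one SED-ML time course per state."""
    entries = []
    for state in INPUT_STATES:
        u1 = 1.0 if state[0] == "1" else INPUT_OFF
        u2 = 1.0 if state[1] == "1" else INPUT_OFF
        model = make_and_gate_model(u1, u2)
        model.name = f"ANDgate_{state}"
        sbml_name = f"ANDgate_{state}.xml"
        entries.append((sbml_name, export_sbml(model), FORMAT_SBML))
        entries.append(
            (
                f"ANDgate_{state}.sedml",
                export_sedml(sbml_name, AND_GATE_TIMECOURSE, task_id=f"task_{state}"),
                FORMAT_SEDML,
            )
        )
    return pack_omex(entries)


def make_decay_model() -> tuple[OdeModel, TimeCourseSpec]:
    """Analytic benchmark: dX/dt = -k X, X(0)=10, k=0.1, so
    X(t) = 10 exp(-0.1 t) exactly."""
    model = OdeModel(
        variables=["X"],
        odes=["-k*X"],
        init={"X": 10.0},
        params=[Parameter("k", 0.1, "dimensionless")],
        init_units={"X": "molL"},
        name="decay",
    )
    return model, TimeCourseSpec(start=0.0, end=10.0, points=101, outputs=["X"])


MINIMAL_SBOL = """<?xml version="1.0" encoding="utf-8"?>
<rdf:RDF xmlns:rdf="http://www.w3.org/1999/02/22-rdf-syntax-ns#"
         xmlns:sbol="http://sbols.org/v2#">
  <sbol:ComponentDefinition rdf:about="http://example.org/minimal/1">
    <sbol:displayId>minimal</sbol:displayId>
    <sbol:persistentIdentity rdf:resource="http://example.org/minimal"/>
    <sbol:sequence rdf:resource="http://example.org/minimal_seq/1"/>
  </sbol:ComponentDefinition>
  <sbol:Sequence rdf:about="http://example.org/minimal_seq/1">
    <sbol:displayId>minimal_seq</sbol:displayId>
    <sbol:elements>ACGTACGT</sbol:elements>
    <sbol:encoding rdf:resource="http://www.chem.qmul.ac.uk/iubmb/misc/naseq.html"/>
  </sbol:Sequence>
</rdf:RDF>
"""


def make_minimal_sbol() -> str:
    """A hand-written minimal SBOL 2 document: one component, one sequence."""
    return MINIMAL_SBOL


def write_fixtures(outdir: str | Path, seed: int = 0) -> list[Path]:
    """Write every fixture file into ``outdir``; returns the paths."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    from synbiokit.automation import scenario_to_json

    source, dest, picklist = make_demo_picklist()
    written = {
        "and_gate.gb": make_and_gate_genbank(seed),
        "and_gate.omex": make_and_gate_omex(),
        "codon_usage.txt": make_kazusa_fixture(),
        "minimal.sbol": make_minimal_sbol(),
        "picklist_demo.json": scenario_to_json([source, dest], picklist),
    }
    paths = []
    for name, content in written.items():
        p = out / name
        if isinstance(content, bytes):
            p.write_bytes(content)
        else:
            p.write_text(content)
        paths.append(p)
    return paths
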