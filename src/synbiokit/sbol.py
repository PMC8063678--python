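"""Native SBOL 2.x interop: GenBank/FASTA/GFF3 <-> SBOL with RDF/XML I/O.

The data model is ComponentDefinition-centric (SBOL 2.x): a converted
record becomes one root ComponentDefinition carrying SequenceAnnotations
(each with a 1-based inclusive Range and a Sequence Ontology role URI) and
one attached Sequence with IUPAC-DNA encoding.  Feature keys map to SO
roles through a bundled, editable table (``data/so_roles.tsv``); unknown
keys fall back to ``SO:0000110`` (sequence_feature) and unknown roles
reverse-map to ``misc_feature``, so conversion is total.

Serialization uses rdflib; validation is structural only (resolvable
references, URI syntax) — no network service is contacted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from rdflib import RDF, Graph, Literal, Namespace, URIRef

from synbiokit.errors import SynbioParseError, SynbioValidationError
from synbiokit.records import FORMATS, Feature, GeneticRecord, Span, read_record, write_record

SBOL2 = Namespace("http://sbols.org/v2#")
SO_BASE = "http://identifiers.org/so/"
DNA_ENCODING = "http://www.chem.qmul.ac.uk/iubmb/misc/naseq.html"
DEFAULT_NAMESPACE = "http://synbiokit.org"

INLINE = "inline"
REVERSE = "reverseComplement"
_ORIENT_URI = {
    INLINE: str(SBOL2["inline"]),
    REVERSE: str(SBOL2["reverseComplement"]),
}

_SO_PATTERN = re.compile(r"SO:\d{7}$")


def _load_role_table() -> tuple[dict[str, str], dict[str, str]]:
    fwd: dict[str, str] = {}
    rev: dict[str, str] = {}
    path = resources.files("synbiokit") / "data" / "so_roles.tsv"
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, acc = line.split("\t")
        fwd[key] = SO_BASE + acc
        rev.setdefault(SO_BASE + acc, key)
    return fwd, rev


ROLE_BY_FEATURE, FEATURE_BY_ROLE = _load_role_table()
UNKNOWN_ROLE = SO_BASE + "SO:0000110"
UNKNOWN_FEATURE = "misc_feature"


def role_for_feature(feature_type: str) -> str:
    """SO role URI for a GenBank feature key (``SO:0000110`` fallback)."""
    return ROLE_BY_FEATURE.get(feature_type, UNKNOWN_ROLE)


def feature_for_role(role_uri: str) -> str:
    """GenBank feature key for an SO role URI (``misc_feature`` fallback)."""
    return FEATURE_BY_ROLE.get(role_uri, UNKNOWN_FEATURE)


# ---------------------------------------------------------------------------
# data model


@dataclass
class SbolAnnotation:
    """A SequenceAnnotation: a named, oriented 1-based inclusive Range."""

    display_id: str
    start: int  # 1-based inclusive
    end: int  # inclusive
    orientation: str = INLINE
    role: str = UNKNOWN_ROLE
    name: str = ""

    def __post_init__(self):
        if self.start < 1 or self.end < self.start:
            raise SynbioValidationError(
                f"Range must satisfy 1 <= start <= end, got ({self.start}, {self.end})"
            )
        if self.orientation not in (INLINE, REVERSE):
            raise SynbioValidationError(f"unknown orientation {self.orientation!r}")
        if not _SO_PATTERN.search(self.role):
            raise SynbioValidationError(f"role URI {self.role!r} does not end in SO:NNNNNNN")


@dataclass
class SbolComponent:
    identity: str
    display_id: str
    roles: list[str] = field(default_factory=list)
    annotations: list[SbolAnnotation] = field(default_factory=list)
    sequence_ref: str | None = None
    name: str = ""
    description: str = ""


@dataclass
class SbolSequence:
    identity: str
    display_id: str
    elements: str
    encoding: str = DNA_ENCODING


@dataclass
class SbolDocument:
    namespace: str = DEFAULT_NAMESPACE
    components: list[SbolComponent] = field(default_factory=list)
    sequences: list[SbolSequence] = field(default_factory=list)

    def validate(self) -> None:
        idents = [c.identity for c in self.components] + [s.identity for s in self.sequences]
        if len(set(idents)) != len(idents):
            raise SynbioValidationError("duplicate identities in document")
        seq_ids = {s.identity for s in self.sequences}
        for c in self.components:
            if c.sequence_ref is not None and c.sequence_ref not in seq_ids:
                raise SynbioValidationError(
                    f"component {c.identity} references missing sequence {c.sequence_ref}"
                )


# ---------------------------------------------------------------------------
# record <-> document


def sanitize_display_id(raw: str) -> str:
    """Make an SBOL-safe display id: non-alphanumerics -> ``_``, leading digit prefixed."""
    out = re.sub(r"[^0-9A-Za-z_]", "_", raw) or "component"
    if out[0].isdigit():
        out = "_" + out
    return out


def record_to_sbol(record: GeneticRecord, namespace: str = DEFAULT_NAMESPACE) -> SbolDocument:
    """Convert a genetic record to an SBOL document.

    One root ComponentDefinition plus one Sequence; every feature becomes a
    SequenceAnnotation whose Range is 1-based inclusive (internal
    ``Span(9, 20)`` emits ``Range(10, 20)``) and whose role comes from the
    bundled SO mapping.
    """
    if not record.sequence:
        raise SynbioValidationError("cannot convert a record with an empty sequence")
    namespace = namespace.rstrip("/")
    root_id = sanitize_display_id(record.id)
    seen: dict[str, int] = {}
    annotations = []
    for f in record.features:
        base = sanitize_display_id(
            f.qualifiers.get("label", [f.type])[0] if f.qualifiers.get("label") else f.type
        )
        seen[base] = seen.get(base, 0) + 1
        disp = base if seen[base] == 1 else f"{base}_{seen[base]}"
        start1, end1 = f.location.start + 1, f.location.end
        if f.origin_spanning:
            # flatten wrap-around to the full-record extent; lossy, flagged by name
            start1, end1 = 1, len(record.sequence)
        annotations.append(
            SbolAnnotation(
                display_id=disp,
                start=start1,
                end=end1,
                orientation=INLINE if f.strand == 1 else REVERSE,
                role=role_for_feature(f.type),
                name=f.qualifiers.get("label", [""])[0] if f.qualifiers.get("label") else "",
            )
        )
    seq_identity = f"{namespace}/{root_id}_sequence/1"
    comp = SbolComponent(
        identity=f"{namespace}/{root_id}/1",
        display_id=root_id,
        roles=[SO_BASE + "SO:0000804"],  # engineered_region
        annotations=annotations,
        sequence_ref=seq_identity,
        description=record.description,
    )
    seq = SbolSequence(identity=seq_identity, display_id=f"{root_id}_sequence", elements=record.sequence)
    doc = SbolDocument(namespace=namespace, components=[comp], sequences=[seq])
    doc.validate()
    return doc


def sbol_to_record(doc: SbolDocument) -> GeneticRecord:
    """Inverse of :func:`record_to_sbol` on its image.

    Recovers feature spans, strands and (via the reverse role map) GenBank
    feature keys from the first component that has an attached sequence.
    """
    doc.validate()
    comp = next((c for c in doc.components if c.sequence_ref is not None), None)
    if comp is None:
        if doc.components:
            raise SynbioValidationError(
                f"component {doc.components[0].identity} has no attached sequence"
            )
        raise SynbioValidationError("document has no components")
    seq = next(s for s in doc.sequences if s.identity == comp.sequence_ref)
    features = []
    for ann in sorted(comp.annotations, key=lambda a: (a.start, a.end)):
        quals: dict[str, list[str]] = {}
        if ann.name:
            quals["label"] = [ann.name]
        features.append(
            Feature(
                type=feature_for_role(ann.role),
                location=Span(ann.start - 1, ann.end),
                strand=1 if ann.orientation == INLINE else -1,
                qualifiers=quals,
            )
        )
    return GeneticRecord(
        id=comp.display_id,
        sequence=seq.elements,
        description=comp.description,
        topology="linear",
        features=features,
    )


# ---------------------------------------------------------------------------
# RDF/XML serialization


def write_sbol_xml(doc: SbolDocument) -> str:
    """Serialize to SBOL2 RDF/XML (ComponentDefinition / SequenceAnnotation /
    Range / Sequence vocabulary)."""
    doc.validate()
    g = Graph()
    g.bind("sbol", SBOL2)
    for comp in doc.components:
        c = URIRef(comp.identity)
        g.add((c, RDF.type, SBOL2.ComponentDefinition))
        g.add((c, SBOL2.displayId, Literal(comp.display_id)))
        g.add((c, SBOL2.persistentIdentity, URIRef(comp.identity.rsplit("/", 1)[0])))
        g.add((c, SBOL2.type, URIRef("http://www.biopax.org/release/biopax-level3.owl#DnaRegion")))
        for role in comp.roles:
            g.add((c, SBOL2.role, URIRef(role)))
        if comp.description:
            g.add((c, URIRef("http://purl.org/dc/terms/description"), Literal(comp.description)))
        if comp.sequence_ref:
            g.add((c, SBOL2.sequence, URIRef(comp.sequence_ref)))
        for ann in comp.annotations:
            a = URIRef(f"{comp.identity.rsplit('/', 1)[0]}/{ann.display_id}/1")
            g.add((c, SBOL2.sequenceAnnotation, a))
            g.add((a, RDF.type, SBOL2.SequenceAnnotation))
            g.add((a, SBOL2.displayId, Literal(ann.display_id)))
            g.add((a, SBOL2.role, URIRef(ann.role)))
            if ann.name:
                g.add((a, URIRef("http://purl.org/dc/terms/title"), Literal(ann.name)))
            r = URIRef(f"{a}/range")
            g.add((a, SBOL2.location, r))
            g.add((r, RDF.type, SBOL2.Range))
            g.add((r, SBOL2.start, Literal(ann.start)))
            g.add((r, SBOL2.end, Literal(ann.end)))
            g.add((r, SBOL2.orientation, URIRef(_ORIENT_URI[ann.orientation])))
    for seq in doc.sequences:
        s = URIRef(seq.identity)
        g.add((s, RDF.type, SBOL2.Sequence))
        g.add((s, SBOL2.displayId, Literal(seq.display_id)))
        g.add((s, SBOL2.elements, Literal(seq.elements)))
        g.add((s, SBOL2.encoding, URIRef(seq.encoding)))
    return g.serialize(format="xml")


def _one(g: Graph, subj, pred, what: str):
    val = g.value(subj, pred)
    if val is None:
        raise SynbioValidationError(f"{subj} is missing required property {what}")
    return val


def read_sbol_xml(text: str) -> SbolDocument:
    """Parse SBOL2 RDF/XML produced by :func:`write_sbol_xml` (or compatible)."""
    g = Graph()
    try:
        g.parse(data=text, format="xml")
    except Exception as e:  # rdflib raises several SAX/xml error types
        raise SynbioParseError(f"not valid RDF/XML: {e}") from None
    components = []
    namespace = DEFAULT_NAMESPACE
    for c in sorted(g.subjects(RDF.type, SBOL2.ComponentDefinition)):
        display_id = str(_one(g, c, SBOL2.displayId, "sbol:displayId"))
        namespace = str(c).rsplit("/", 2)[0]
        roles = sorted(str(r) for r in g.objects(c, SBOL2.role))
        seq_ref = g.value(c, SBOL2.sequence)
        desc = g.value(c, URIRef("http://purl.org/dc/terms/description"))
        annotations = []
        for a in g.objects(c, SBOL2.sequenceAnnotation):
            loc = _one(g, a, SBOL2.location, "sbol:location")
            start = _one(g, loc, SBOL2.start, "sbol:start")
            end = _one(g, loc, SBOL2.end, "sbol:end")
            orient = g.value(loc, SBOL2.orientation)
            role = g.value(a, SBOL2.role)
            name = g.value(a, URIRef("http://purl.org/dc/terms/title"))
            annotations.append(
                SbolAnnotation(
                    display_id=str(_one(g, a, SBOL2.displayId, "sbol:displayId")),
                    start=int(start),
                    end=int(end),
                    orientation=REVERSE if orient is not None and str(orient).endswith("reverseComplement") else INLINE,
                    role=str(role) if role is not None else UNKNOWN_ROLE,
                    name=str(name) if name is not None else "",
                )
            )
        annotations.sort(key=lambda x: (x.start, x.end, x.display_id))
        components.append(
            SbolComponent(
                identity=str(c),
                display_id=display_id,
                roles=roles,
                annotations=annotations,
                sequence_ref=str(seq_ref) if seq_ref is not None else None,
                description=str(desc) if desc is not None else "",
            )
        )
    sequences = []
    for s in sorted(g.subjects(RDF.type, SBOL2.Sequence)):
        sequences.append(
            SbolSequence(
                identity=str(s),
                display_id=str(_one(g, s, SBOL2.displayId, "sbol:displayId")),
                elements=str(_one(g, s, SBOL2.elements, "sbol:elements")),
                encoding=str(g.value(s, SBOL2.encoding) or DNA_ENCODING),
            )
        )
    doc = SbolDocument(namespace=namespace, components=components, sequences=sequences)
    doc.validate()
    return doc


# ---------------------------------------------------------------------------
# any-to-any conversion


_EXT_FORMAT = {
    ".gb": "genbank",
    ".gbk": "genbank",
    ".genbank": "genbank",
    ".fa": "fasta",
    ".fasta": "fasta",
    ".fna": "fasta",
    ".gff": "gff3",
    ".gff3": "gff3",
    ".xml": "sbol",
    ".sbol": "sbol",
    ".rdf": "sbol",
}


def sniff_format(path_or_text: str) -> str:
    """Detect genbank / fasta / gff3 / sbol from an extension, then content."""
    p = Path(path_or_text) if "\n" not in path_or_text else None
    if p is not None and p.suffix.lower() in _EXT_FORMAT and p.exists():
        return _EXT_FORMAT[p.suffix.lower()]
    text = path_or_text
    if p is not None and p.exists():
        text = p.read_text()
    head = text.lstrip()[:4096]
    if head.startswith("LOCUS"):
        return "genbank"
    if head.startswith("##gff-version"):
        return "gff3"
    if head.startswith(">"):
        return "fasta"
    if head.startswith("<?xml") or head.startswith("<rdf:RDF") or "sbols.org/v2" in head:
        return "sbol"
    raise SynbioParseError(
        "cannot detect input format; tried genbank (LOCUS), gff3 (##gff-version), "
        "fasta (>), sbol (RDF/XML)"
    )


def convert(path_or_text: str, target: str, namespace: str = DEFAULT_NAMESPACE) -> str:
    """Convert between any two of genbank / fasta / gff3 / sbol.

    The conversion matrix is total; edges into FASTA are lossy (features
    dropped, a warning is emitted).
    """
    if target not in FORMATS + ("sbol",):
        raise SynbioValidationError(f"unknown target format {target!r}")
    source = sniff_format(path_or_text)
    if source == "sbol":
        text = _maybe_read(path_or_text)
        records = [sbol_to_record(read_sbol_xml(text))]
    else:
        records = read_record(path_or_text, source)
    if target == "sbol":
        if not records:
            raise SynbioValidationError("no records to convert")
        return write_sbol_xml(record_to_sbol(records[0], namespace))
    if target == "fasta" and any(r.features for r in records):
        import warnings

        warnings.warn("FASTA output drops all feature annotations", stacklevel=2)
    return write_record(records, target)


def _maybe_read(path_or_text: str) -> str:
    p = Path(path_or_text) if "\n" not in path_or_text else None
    if p is not None and p.exists():
        return p.read_text()
    return path_or_text
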