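"""Genetic sequence records and GenBank / FASTA / GFF3 readers and writers.

The in-memory model is deliberately small: a :class:`GeneticRecord` holds a
DNA sequence, linear/circular topology and an ordered list of
:class:`Feature` objects whose :class:`Span` coordinates are 0-based,
half-open.  Dialect conventions (GenBank and GFF3 are 1-based inclusive)
are converted at the I/O boundary only, so all internal arithmetic is
offset-free.

Origin-spanning features on circular records (GenBank ``join(a..N,1..b)``)
are kept as a single feature flagged ``origin_spanning`` whose span carries
the raw wrap-around coordinates; writers re-emit the ``join``.

GenBank and FASTA parsing/writing are delegated to Biopython's ``SeqIO``;
GFF3 is read and written directly (9 tab-separated columns, attribute
percent-escaping, optional ``##FASTA`` section).
"""

from __future__ import annotations

import io
import re
import urllib.parse
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from synbiokit.errors import SynbioParseError, SynbioValidationError

FORMATS = ("genbank", "fasta", "gff3")

_SEQ_ALPHABET = set("ACGTNacgtnRYSWKMBDHVryswkmbdhvUu")


@dataclass(frozen=True)
class Span:
    """Half-open 0-based interval ``[start, end)``.

    For origin-spanning features on circular records ``start > end`` is
    permitted when the owning feature is flagged; :meth:`sub_spans` then
    returns the two linear pieces.
    """

    start: int
    end: int

    def __post_init__(self):
        if self.start < 0 or self.end < 0:
            raise SynbioValidationError(f"negative coordinate in span ({self.start}, {self.end})")

    @property
    def length(self) -> int:
        if self.end >= self.start:
            return self.end - self.start
        return -1  # wrap spans need the sequence length; see wrapped_length

    def wrapped_length(self, seq_len: int) -> int:
        if self.end >= self.start:
            return self.end - self.start
        return (seq_len - self.start) + self.end

    def sub_spans(self, seq_len: int) -> tuple["Span", ...]:
        """Normalize a wrap-around span into its linear sub-spans."""
        if self.end >= self.start:
            return (self,)
        return (Span(self.start, seq_len), Span(0, self.end))


@dataclass
class Feature:
    """One annotated region: a GenBank feature key, a span and a strand."""

    type: str
    location: Span
    strand: int = 1
    qualifiers: dict[str, list[str]] = field(default_factory=dict)
    origin_spanning: bool = False

    def __post_init__(self):
        if not self.type:
            raise SynbioValidationError("feature type must be non-empty")
        if self.strand not in (1, -1):
            raise SynbioValidationError(f"strand must be +1 or -1, got {self.strand}")
        if not self.origin_spanning and self.location.end < self.location.start:
            raise SynbioValidationError(
                f"span end < start ({self.location.start}, {self.location.end}) "
                "on a feature not flagged origin_spanning"
            )


@dataclass
class GeneticRecord:
    """An annotated DNA sequence — the lingua franca of all conversions."""

    id: str
    sequence: str
    description: str = ""
    topology: str = "linear"
    features: list[Feature] = field(default_factory=list)
    annotations: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.topology not in ("linear", "circular"):
            raise SynbioValidationError(f"unknown topology {self.topology!r}")
        bad = set(self.sequence) - _SEQ_ALPHABET
        if bad:
            raise SynbioValidationError(f"sequence contains non-nucleotide characters {sorted(bad)!r}")
        self.validate_features()

    def validate_features(self) -> None:
        n = len(self.sequence)
        for f in self.features:
            if f.origin_spanning:
                if self.topology != "circular":
                    raise SynbioValidationError(
                        f"origin-spanning feature {f.type!r} on a linear record"
                    )
                if f.location.start > n or f.location.end > n:
                    raise SynbioValidationError(
                        f"feature {f.type!r} {f.location} outside sequence of length {n}"
                    )
            elif f.location.end > n:
                raise SynbioValidationError(
                    f"feature {f.type!r} ends at {f.location.end} beyond sequence length {n}"
                )


# ---------------------------------------------------------------------------
# coordinate conversion (the only place off-by-one logic lives)

def to_internal(start_1based: int, end_inclusive: int) -> Span:
    """Dialect (1-based, inclusive) -> internal (0-based, half-open)."""
    return Span(start_1based - 1, end_inclusive)


def to_dialect(span: Span) -> tuple[int, int]:
    """Internal (0-based, half-open) -> dialect (1-based, inclusive)."""
    return span.start + 1, span.end


# ---------------------------------------------------------------------------
# Biopython bridge

def _from_seqrecord(rec: SeqRecord) -> GeneticRecord:
    n = len(rec.seq)
    features: list[Feature] = []
    for f in rec.features:
        if f.type == "source":
            continue
        strand = -1 if f.location.strand == -1 else 1
        quals = {k: [str(x) for x in v] for k, v in f.qualifiers.items()}
        parts = f.location.parts
        if len(parts) == 2 and int(parts[0].end) == n and int(parts[1].start) == 0:
            # join(a..N,1..b): wrap-around on a circular plasmid
            span = Span(int(parts[0].start), int(parts[1].end))
            features.append(Feature(f.type, span, strand, quals, origin_spanning=True))
        else:
            span = Span(int(f.location.start), int(f.location.end))
            features.append(Feature(f.type, span, strand, quals))
    topology = rec.annotations.get("topology", "linear")
    if topology not in ("linear", "circular"):
        topology = "linear"
    ann = {
        k: str(v)
        for k, v in rec.annotations.items()
        if k not in ("topology", "molecule_type") and isinstance(v, str)
    }
    return GeneticRecord(
        id=rec.id if rec.id not in (None, "<unknown id>") else rec.name,
        sequence=str(rec.seq),
        # the GenBank writer terminates DEFINITION with a period; undo it
        description=""
        if rec.description in ("<unknown description>",)
        else rec.description.rstrip("."),
        topology=topology,
        features=features,
        annotations=ann,
    )


def _to_seqrecord(record: GeneticRecord) -> SeqRecord:
    rec = SeqRecord(
        Seq(record.sequence),
        id=record.id,
        name=re.sub(r"\W", "_", record.id)[:16] or "record",
        description=record.description,
    )
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = record.topology
    for k, v in record.annotations.items():
        rec.annotations.setdefault(k, v)
    n = len(record.sequence)
    for f in record.features:
        strand = f.strand
        if f.origin_spanning:
            loc = CompoundLocation(
                [
                    SimpleLocation(f.location.start, n, strand),
                    SimpleLocation(0, f.location.end, strand),
                ]
            )
        else:
            loc = SimpleLocation(f.location.start, f.location.end, strand)
        rec.features.append(SeqFeature(loc, type=f.type, qualifiers=dict(f.qualifiers)))
    return rec


# ---------------------------------------------------------------------------
# GFF3

_GFF_ESCAPE = ";=&,%\t\n"


def _gff_escape(s: str) -> str:
    return urllib.parse.quote(s, safe=" :/()[]'\"<>@!*+.-_|?{}~^`#$")


def _gff_unescape(s: str) -> str:
    return urllib.parse.unquote(s)


def _write_gff3(records: list[GeneticRecord]) -> str:
    lines = ["##gff-version 3"]
    for rec in records:
        lines.append(f"##sequence-region {rec.id} 1 {len(rec.sequence)}")
        if rec.topology == "circular":
            lines.append(f"# topology={rec.topology}")
        for i, f in enumerate(rec.features):
            attrs = [f"ID={_gff_escape(rec.id)}_f{i}"]
            if f.origin_spanning:
                attrs.append("origin_spanning=true")
            for k, vals in f.qualifiers.items():
                attrs.append(f"{_gff_escape(k)}={','.join(_gff_escape(v) for v in vals)}")
            start1, end1 = to_dialect(f.location)
            lines.append(
                "\t".join(
                    [
                        rec.id,
                        "synbiokit",
                        f.type,
                        str(start1),
                        str(end1),
                        ".",
                        "+" if f.strand == 1 else "-",
                        ".",
                        ";".join(attrs),
                    ]
                )
            )
    lines.append("##FASTA")
    for rec in records:
        lines.append(f">{rec.id}" + (f" {rec.description}" if rec.description else ""))
        for i in range(0, len(rec.sequence), 60):
            lines.append(rec.sequence[i : i + 60])
    return "\n".join(lines) + "\n"


def _read_gff3(text: str) -> list[GeneticRecord]:
    feature_rows: dict[str, list[tuple[int, Feature]]] = {}
    topologies: dict[str, str] = {}
    order: list[str] = []
    fasta_lines: list[str] = []
    in_fasta = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if in_fasta:
            fasta_lines.append(line)
            continue
        if line.startswith("##FASTA"):
            in_fasta = True
            continue
        if line.startswith("# topology=circular"):
            if order:
                topologies[order[-1]] = "circular"
            continue
        if line.startswith("##sequence-region"):
            parts = line.split()
            if len(parts) >= 2 and parts[1] not in order:
                order.append(parts[1])
                feature_rows.setdefault(parts[1], [])
            continue
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise SynbioParseError(
                f"GFF3 line has {len(cols)} columns, expected 9", line=lineno
            )
        seqid, _source, ftype, start_s, end_s, _score, strand_s, _phase, attr_s = cols
        try:
            start1, end1 = int(start_s), int(end_s)
        except ValueError:
            raise SynbioParseError("non-integer GFF3 coordinates", line=lineno) from None
        if strand_s not in ("+", "-", "."):
            raise SynbioParseError(f"bad strand {strand_s!r}", line=lineno)
        quals: dict[str, list[str]] = {}
        origin_spanning = False
        for pair in attr_s.split(";"):
            if not pair:
                continue
            if "=" not in pair:
                raise SynbioParseError(f"malformed attribute {pair!r}", line=lineno)
            k, v = pair.split("=", 1)
            k = _gff_unescape(k)
            if k == "ID":
                continue
            if k == "origin_spanning":
                origin_spanning = v == "true"
                continue
            quals[k] = [_gff_unescape(x) for x in v.split(",")]
        if origin_spanning:
            # raw wrap coordinates were written as start..end with start > end
            span = Span(start1 - 1, end1)
        else:
            span = to_internal(start1, end1)
        feat = Feature(
            ftype, span, -1 if strand_s == "-" else 1, quals, origin_spanning=origin_spanning
        )
        if seqid not in order:
            order.append(seqid)
        feature_rows.setdefault(seqid, []).append((lineno, feat))

    sequences: dict[str, str] = {}
    descriptions: dict[str, str] = {}
    current = None
    for line in fasta_lines:
        if line.startswith(">"):
            head = line[1:].split(None, 1)
            current = head[0]
            descriptions[current] = head[1] if len(head) > 1 else ""
            sequences[current] = ""
        elif current is not None:
            sequences[current] += line.strip()

    records = []
    for seqid in order:
        seq = sequences.get(seqid, "")
        feats = [f for _, f in feature_rows.get(seqid, [])]
        topo = topologies.get(seqid, "linear")
        if any(f.origin_spanning for f in feats):
            topo = "circular"
        try:
            records.append(
                GeneticRecord(
                    id=seqid,
                    sequence=seq,
                    description=descriptions.get(seqid, ""),
                    topology=topo,
                    features=feats,
                )
            )
        except SynbioValidationError as e:
            raise SynbioValidationError(f"record {seqid!r}: {e}") from None
    return records


# ---------------------------------------------------------------------------
# public API

def read_record(path_or_text: str, format: str) -> list[GeneticRecord]:
    """Parse GenBank / FASTA / GFF3 into :class:`GeneticRecord` objects.

    ``path_or_text`` may be a filesystem path or the raw text itself
    (anything containing a newline or a format sigil is treated as text).

    Coordinates are converted from the dialect's 1-based inclusive
    convention to the internal 0-based half-open one;
    ``complement(...)`` / ``-`` strands map to ``-1``; GenBank topology is
    taken from the LOCUS line.
    """
    if format not in FORMATS:
        raise SynbioValidationError(f"unknown format {format!r}; expected one of {FORMATS}")
    text = _slurp(path_or_text)
    if format == "gff3":
        return _read_gff3(text)
    handle = io.StringIO(text)
    try:
        seq_records = list(SeqIO.parse(handle, "genbank" if format == "genbank" else "fasta"))
    except ValueError as e:
        raise SynbioParseError(f"cannot parse {format}: {e}") from None
    records = []
    for sr in seq_records:
        try:
            records.append(_from_seqrecord(sr))
        except SynbioValidationError as e:
            raise SynbioValidationError(f"record {sr.id!r}: {e}") from None
    return records


def write_record(records: list[GeneticRecord] | GeneticRecord, format: str) -> str:
    """Serialize records to GenBank / FASTA / GFF3 text.

    FASTA is lossy (features dropped).  GenBank wraps the sequence 60 per
    line in LOCUS/ORIGIN layout; GFF3 emits 9 columns with coordinates back
    in 1-based inclusive form plus a ``##FASTA`` section.
    """
    if isinstance(records, GeneticRecord):
        records = [records]
    if format not in FORMATS:
        raise SynbioValidationError(f"unknown format {format!r}; expected one of {FORMATS}")
    if format == "gff3":
        return _write_gff3(records)
    if format == "genbank":
        for r in records:
            if not r.id:
                raise SynbioValidationError("GenBank output requires a non-empty record id")
    out = io.StringIO()
    SeqIO.write(
        [_to_seqrecord(r) for r in records],
        out,
        "genbank" if format == "genbank" else "fasta",
    )
    return out.getvalue()


def _slurp(path_or_text: str) -> str:
    import os

    if "\n" not in path_or_text and len(path_or_text) < 4096 and os.path.exists(path_or_text):
        with open(path_or_text) as fh:
            return fh.read()
    return path_or_text
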