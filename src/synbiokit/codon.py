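"""Codon usage tables, Kazusa-format parsing, taxonomy mapping and codon
optimization.

A :class:`CodonUsageTable` maps each amino-acid letter (including ``*``
for stop) to its synonymous codons and their relative frequencies, which
sum to 1 per amino acid.  Tables parse from the Kazusa Codon Usage
Database text layout (``CODON  per-1000 (count)``, RNA alphabet accepted
and normalized to DNA); relative frequencies are computed from the raw
counts.

The toolkit is offline-first: a small set of tables ships with the
package (synthetic snapshots in genuine Kazusa format — see
``data/codon_tables/``), keyed by organism name or NCBI taxonomy id
through a bundled name<->taxid table.  A live fetch from the online
database is available behind an explicit ``allow_fetch`` flag.

Two back-translation methods are provided: ``optimise_max`` (always the
most frequent codon, lexicographic tie-break) and ``optimise_weighted``
(codons sampled in proportion to their usage, seeded for
reproducibility).  Both guarantee that translating the result recovers
the input protein under the standard genetic code.
"""

from __future__ import annotations

import difflib
import re
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq

from synbiokit.errors import SynbioParseError, SynbioValidationError

_STANDARD = unambiguous_dna_by_id[1]

#: amino acid (incl. '*') for each of the 64 DNA codons, standard code
AA_BY_CODON: dict[str, str] = dict(_STANDARD.forward_table)
for _stop in _STANDARD.stop_codons:
    AA_BY_CODON[_stop] = "*"
assert len(AA_BY_CODON) == 64

CODONS_BY_AA: dict[str, list[str]] = {}
for _codon, _aa in sorted(AA_BY_CODON.items()):
    CODONS_BY_AA.setdefault(_aa, []).append(_codon)

AMINO_ACIDS = frozenset(CODONS_BY_AA)  # 20 letters + '*'

_KAZUSA_ENTRY = re.compile(r"([ACGUTacgut]{3})\s+([0-9.]+)\s*\(\s*([0-9]+)\s*\)")


@dataclass
class CodonUsageTable:
    """Per-amino-acid relative codon frequencies for one organism."""

    organism: str
    taxid: int
    usage: dict[str, dict[str, float]]
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        codons = [c for aa in self.usage.values() for c in aa]
        if len(codons) != 64 or set(codons) != set(AA_BY_CODON):
            missing = sorted(set(AA_BY_CODON) - set(codons))
            raise SynbioValidationError(
                f"table must cover all 64 codons; missing {missing}"
            )
        for aa, freqs in self.usage.items():
            for codon in freqs:
                if AA_BY_CODON[codon] != aa:
                    raise SynbioValidationError(
                        f"codon {codon} listed under {aa!r} but translates to "
                        f"{AA_BY_CODON[codon]!r}"
                    )
            total = sum(freqs.values())
            if abs(total - 1.0) > 1e-9:
                raise SynbioValidationError(
                    f"frequencies for {aa!r} sum to {total!r}, expected 1"
                )

    def frequency(self, codon: str) -> float:
        return self.usage[AA_BY_CODON[codon]][codon]


def parse_kazusa(text: str, organism: str = "", taxid: int = 0) -> CodonUsageTable:
    """Parse Kazusa codon-frequency text (``CODON per-1000(count)``).

    U is normalized to T; relative frequencies are computed as
    count / sum-of-counts over each amino acid's codons.  An amino acid
    whose codons all have zero counts falls back to uniform frequencies
    with a warning.
    """
    counts: dict[str, int] = {}
    for codon_raw, _per1000, count in _KAZUSA_ENTRY.findall(text):
        codon = codon_raw.upper().replace("U", "T")
        if codon not in AA_BY_CODON:
            continue
        if codon in counts:
            raise SynbioParseError(f"codon {codon} appears more than once")
        counts[codon] = int(count)
    if len(counts) != 64:
        missing = sorted(set(AA_BY_CODON) - set(counts))
        raise SynbioParseError(
            f"expected 64 codons, parsed {len(counts)}; missing: {', '.join(missing)}"
        )
    usage: dict[str, dict[str, float]] = {}
    for aa, codons in CODONS_BY_AA.items():
        total = sum(counts[c] for c in codons)
        if total == 0:
            warnings.warn(
                f"all codons for {aa!r} have zero counts; using uniform frequencies",
                stacklevel=2,
            )
            usage[aa] = {c: 1.0 / len(codons) for c in codons}
        else:
            usage[aa] = {c: counts[c] / total for c in codons}
    return CodonUsageTable(organism=organism, taxid=taxid, usage=usage, counts=counts)


# ---------------------------------------------------------------------------
# taxonomy mapping and bundled tables


def _load_taxonomy() -> tuple[dict[str, int], dict[int, str]]:
    by_name: dict[str, int] = {}
    by_id: dict[int, str] = {}
    path = resources.files("synbiokit") / "data" / "taxonomy.tsv"
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, taxid = line.split("\t")
        by_name[name] = int(taxid)
        by_id.setdefault(int(taxid), name)
    return by_name, by_id


_TAXID_BY_NAME, _NAME_BY_TAXID = _load_taxonomy()


def name_to_taxid(name: str) -> int:
    if name not in _TAXID_BY_NAME:
        close = difflib.get_close_matches(name, _TAXID_BY_NAME, n=3, cutoff=0.4)
        hint = f"; did you mean {close}?" if close else ""
        raise SynbioValidationError(f"unknown organism {name!r}{hint}")
    return _TAXID_BY_NAME[name]


def taxid_to_name(taxid: int) -> str:
    if taxid not in _NAME_BY_TAXID:
        raise SynbioValidationError(f"unknown taxonomy id {taxid}")
    return _NAME_BY_TAXID[taxid]


KAZUSA_URL = "http://www.kazusa.or.jp/codon/cgi-bin/showcodon.cgi?species={taxid}&aa=1&style=N"


def get_table(name_or_taxid: str | int, allow_fetch: bool = False) -> CodonUsageTable:
    """Codon usage table by organism name or NCBI taxid.

    Resolution order: bundled table (offline, default) then — only with
    ``allow_fetch=True`` — the live Kazusa database.
    """
    if isinstance(name_or_taxid, int) or str(name_or_taxid).isdigit():
        taxid = int(name_or_taxid)
        organism = taxid_to_name(taxid)
    else:
        organism = str(name_or_taxid)
        taxid = name_to_taxid(organism)
    bundle = resources.files("synbiokit") / "data" / "codon_tables" / f"{taxid}.txt"
    try:
        text = bundle.read_text()
    except FileNotFoundError:
        if not allow_fetch:
            bundled = sorted(
                _NAME_BY_TAXID[t]
                for t in _NAME_BY_TAXID
                if (resources.files("synbiokit") / "data" / "codon_tables" / f"{t}.txt").is_file()
            )
            raise SynbioValidationError(
                f"no bundled codon table for {organism!r} (taxid {taxid}); "
                f"bundled organisms: {bundled}. Pass allow_fetch=True to query "
                "the Kazusa database."
            ) from None
        import urllib.request

        with urllib.request.urlopen(KAZUSA_URL.format(taxid=taxid), timeout=30) as resp:
            text = resp.read().decode()
    return parse_kazusa(text, organism=organism, taxid=taxid)


# ---------------------------------------------------------------------------
# optimization


def _check_protein(protein: str) -> None:
    for i, aa in enumerate(protein):
        if aa not in AMINO_ACIDS:
            raise SynbioValidationError(
                f"invalid amino-acid letter {aa!r} at position {i}"
            )


def optimise_max(protein: str, table: CodonUsageTable) -> str:
    """Back-translate using each amino acid's most frequent codon
    (lexicographically smallest codon on ties); deterministic."""
    _check_protein(protein)
    best = {
        aa: min(freqs, key=lambda c: (-freqs[c], c)) for aa, freqs in table.usage.items()
    }
    return "".join(best[aa] for aa in protein)


def optimise_weighted(protein: str, table: CodonUsageTable, seed: int) -> str:
    """Back-translate sampling each codon in proportion to its relative
    frequency; the same seed always reproduces the same sequence."""
    _check_protein(protein)
    rng = np.random.default_rng(seed)
    out = []
    for aa in protein:
        codons = CODONS_BY_AA[aa]
        probs = np.array([table.usage[aa][c] for c in codons])
        out.append(codons[rng.choice(len(codons), p=probs / probs.sum())])
    return "".join(out)


def translate(dna: str) -> str:
    """Standard-genetic-code translation; ``*`` marks stop codons."""
    if len(dna) % 3 != 0:
        raise SynbioValidationError(
            f"sequence length {len(dna)} is not a multiple of 3"
        )
    dna = dna.upper().replace("U", "T")
    bad = set(dna) - set("ACGT")
    if bad:
        raise SynbioValidationError(f"non-ACGT characters in DNA: {sorted(bad)}")
    return str(Seq(dna).translate())
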