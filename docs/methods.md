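# Methods and design notes

This note records the models, conventions and deliberate design choices
behind synbiokit, and what the bundled synthetic fixtures do and do not
demonstrate.

## Sequence records and coordinate conventions

All internal coordinates are 0-based, half-open (`Span(start, end)`,
length = end − start).  GenBank and GFF3 both speak 1-based inclusive;
the conversion happens exactly once, at the I/O boundary
(`to_internal` / `to_dialect`), and is an involution by construction.
Sequence case is preserved on read (some tools encode annotation in
case) and upper-cased only for comparisons.  Unknown GenBank feature
keys pass through untouched: lossless conversion is the module's
contract.

Origin-spanning features on circular records are kept as one feature
flagged `origin_spanning` whose span carries the raw wrap-around
coordinates (start > end); `Span.sub_spans(seq_len)` normalizes to the
two linear pieces and the GenBank writer re-emits `join(a..N,1..b)`.
GFF3 output marks these with an `origin_spanning=true` attribute rather
than splitting into two rows, which keeps the round trip exact at the
cost of a non-standard attribute.

GenBank and FASTA parsing/writing delegate to Biopython's SeqIO; GFF3 is
implemented directly (9 columns, percent-escaping in attributes,
`##FASTA` section for the sequence) because no installed library offers
a symmetric text-level GFF3 writer.  A test cross-checks our GFF3 output
against gffutils as an independent parser.

## SBOL interop

The data model is SBOL 2.x, ComponentDefinition-centric: one root
component with SequenceAnnotations (1-based inclusive Ranges, per the
SBOL specification) plus one Sequence with IUPAC-DNA encoding.  SBOL 3
support would be a versioning seam on top of the same internal types.

Feature-key ↔ Sequence-Ontology role mapping lives in an editable
bundled table (`data/so_roles.tsv`).  Totality is guaranteed by two
fallbacks: unknown feature keys map to `SO:0000110`
(*sequence_feature*), unknown roles reverse-map to `misc_feature`.
Display ids are sanitized (non-alphanumerics → `_`, leading digit
prefixed with `_`) and duplicates get deterministic `_2`, `_3` suffixes;
the sanitization scheme is our choice, not mandated by any format.
Validation is structural (unique identities, resolvable references, URI
syntax) — no network validator is contacted.

Documents serialize through rdflib as RDF/XML.  Equality after a
write/read round trip is semantic (parsed object graphs), not
byte-level, since RDF/XML serialization order is not significant.

## Circuit diagrams

Circuit strings are whitespace-separated tokens
`[-]code[.color][.name]` with codes p/r/c/t/o; parts are indexed 0..n−1
left to right and a leading `-` means reverse orientation.  The token
grammar detail is a design choice: the dot delimiter keeps tokens
whitespace-free, and a single extension is read as a color only when it
is an SVG named color or `#RRGGBB` (otherwise as the name).  Regulation
entries are `i->j.kind[.color]` with kind ∈ {activation, repression};
activation arcs end in an arrowhead, repression in a flat bar, per SBOL
Visual.  Self-regulation arcs are rejected.

Layout uses a fixed 30×30 unit cell per part on a horizontal backbone.
Reverse parts are rotated 180° about their cell centre, which mirrors
them below the backbone without changing their x-interval.  Arc height
tiers are assigned by greedy interval-graph coloring so arcs with
overlapping x-extents never share a tier.  All geometry uses fixed
number formatting and no timestamps, so rendering is byte-deterministic;
golden-file tests pin the output.

Circular plasmid maps place each feature as an annular arc from angle
360°·start/len, clockwise from 12 o'clock, with labels outside at the
mid-angle; a feature covering the whole plasmid is drawn as a full
circle (SVG arcs cannot express 360°).  Linear maps are a scaled track
of rectangles.

## ODE models and model exchange

Right-hand sides arrive as strings over a small grammar (`+ − * / ^`,
parentheses, `exp`, `log`, `pow`, and `hill(x,K,n) ≡ xⁿ/(Kⁿ+xⁿ)`),
parsed by a recursive-descent parser that validates every identifier
against the declared variables/parameters/`t` and reports unknown names
with their character position.  SBML export emits one species per
variable (initialAmount), one parameter per constant and one RateRule
per ODE — direct ODE semantics, no reaction network.  `hill` is expanded
to its rational form in the emitted MathML so documents stay within
standard operators; reading the SBML back therefore yields the expanded
expression, which simulates identically.

Units are free-text tokens mapped to SBML unit definitions for a small
whitelist (second, minute, molL, dimensionless); anything else is
emitted as dimensionless with a warning.

Integration uses scipy's `RK45` — the Dormand–Prince 4(5) embedded
pair — at rtol 1e−6, atol 1e−9, sampled on the uniform grid of the time
course.  An independent fixed-step RK4 integrator (`rk4_fixed_step`)
exists solely as a brute-force cross-check; tests require agreement
within 1e−5 relative on random stable 3-species linear systems (RK4 at
h=1e−4 over t∈[0,1]; sizes chosen to keep the suite fast while leaving
no room for an integrator bug to hide).

SED-ML is restricted to Level 1 uniformTimeCourse with one model per
file; `numberOfPoints` counts intervals, hence `points − 1` on export.
COMBINE archives are zip files whose `manifest.xml` lists every entry
plus the manifest itself, with identifiers.org COMBINE format URIs; zip
timestamps are pinned so archives are byte-deterministic.
`execute_omex` runs every SED-ML task it finds, loading each referenced
SBML back into an `OdeModel` — a fully self-contained round trip.

### The AND-gate fixture model

The demo kinetic model is a four-variable Hill AND gate:

    dx1/dt = a1·u1 − d1·x1
    dx2/dt = a2·u2 − d2·x2
    dm/dt  = b·hill(x1,K1,n1)·hill(x2,K2,n2) − deg_m·m
    dR/dt  = k_R·m − deg_R·R

with u ∈ {0.05, 1} (leaky off state), a=10, d=0.1, b=5, K=50, n=2,
deg_m=0.2, k_R=2, deg_R=0.05, all initial conditions 0, simulated over
0–500 minutes at 201 points.  These parameters are illustrative — chosen
to give fast equilibration and a large on/off contrast (~80×) — not
measurements of any real EL222/arabinose system.  The leaky off state
makes the ≥10× on/off comparison a finite, meaningful ratio instead of a
division by zero.

## Lab automation

Volumes are µL internally; the Echo CSV dialect converts to nL and
snaps to the instrument's 2.5 nL droplet grid (error in strict mode,
round-with-warning otherwise).  Default well capacities (96-well
200 µL, 384-well 65 µL, etc.) are working-volume conventions and
overridable.  Well naming is row-letter-then-number without zero
padding ("A1"); importers accept padded names.

Transfers move content under a proportional-mixing model: a draw carries
each component of the source well in proportion to its volume fraction.
This is the simplest physically consistent semantics for pooled wells;
it ignores real-world effects like incomplete mixing or dead volume.
Simulation deep-copies the plates, so inputs are never mutated, and
volume is conserved exactly for successful transfers.  The failure
policy (`abort` default, `skip` optional) decides whether later
transfers still run after a failure.

## Codon usage

Tables parse from the Kazusa text layout (`CODON per-1000 (count)`; RNA
accepted, normalized to DNA) and store relative frequencies computed
from raw counts, normalized per amino acid.  All 64 codons must be
present; an amino acid with all-zero counts falls back to uniform with a
warning.  The bundled tables for *Escherichia coli* (562) and
*Saccharomyces cerevisiae* (4932) are **synthetic snapshots** in genuine
Kazusa format (generated counts, labelled as such in the files): they
exercise the full pipeline offline but carry no biological signal, so
sequences optimized against them are format-correct, not
expression-optimized.  The live database is reachable with
`get_table(..., allow_fetch=True)`.

Two optimizers ship: `optimise_max` (argmax codon per residue,
lexicographically smallest on ties, fully deterministic) and
`optimise_weighted` (sampling ∝ frequency under a caller-supplied seed).
Both guarantee `translate(result) == protein` under the standard genetic
code (translation table 1 only; alternative codes are out of scope).

## Fixtures and what passing tests show

Every test input is generated by a pure function of a seed — the
3000 bp AND-gate plasmid (random bases, fixed part structure at
documented coordinates), the two-transfer picklist demo, the 64-codon
table with its 60/40 leucine split, and the four-state OMEX archive.
Passing tests therefore demonstrate correctness of the *machinery* —
parsing, conversion, rendering, integration, bookkeeping — on clean,
well-formed inputs.  They do not demonstrate robustness to the full
zoo of real-world GenBank dialect quirks (we target NCBI-canonical
layout and tolerate missing LOCUS fields), nor biological validity of
the synthetic sequences, parameters or codon counts.

## Known limitations

- SBOL: no ModuleDefinitions/interactions, no provenance, no
  combinatorial derivations.
- SED-ML: uniform time course only; no repeated tasks or parameter
  changes.
- Models: no stochastic simulation, steady-state or flux analysis; no
  events or algebraic rules in SBML.
- Automation: no instrument drivers, scheduling or labware geometry
  beyond well counts.
- Codon: no CAI scoring, restriction-site avoidance or GC constraints.
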