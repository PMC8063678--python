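"""Genetic-circuit diagrams (SBOL Visual) and plasmid maps as SVG.

A circuit is written as a compact string of whitespace-separated tokens.
Each token is ``[-]code[.color][.name]`` where the code letters mean

====  ======================
p     promoter (bent arrow)
r     ribosome binding site (half-disc)
c     coding sequence (block arrow)
t     terminator (tee)
o     origin of replication (circle on the backbone)
====  ======================

and a leading ``-`` draws the part in the reverse orientation (mirrored
through its cell centre onto the underside of the backbone).  Parts are
indexed 0..n-1 left to right.  The first dot-extension is taken as a color
if it is an SVG named color or ``#RRGGBB``, otherwise as the part name; a
second extension is always the name.

Regulatory links are written ``i->j.kind[.color]`` with kind in
{activation, repression}; they render as orthogonal arcs above the
backbone ending in an arrowhead (activation) or a flat bar (repression).
Arc heights are assigned by greedy interval coloring so overlapping arcs
never share a tier.

All output is plain SVG 1.1 text built deterministically: the same input
always yields byte-identical output (no timestamps, stable ids, fixed
number formatting).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

from synbiokit.errors import SynbioParseError, SynbioValidationError
from synbiokit.records import GeneticRecord

PART_CODES = {
    "p": "promoter",
    "r": "RBS",
    "c": "CDS",
    "t": "terminator",
    "o": "rep_origin",
}

DEFAULT_COLORS = {
    "p": "#2e8b57",
    "r": "#e69f00",
    "c": "#4169e1",
    "t": "#cc0000",
    "o": "#707070",
}

FEATURE_COLORS = {
    "promoter": "#2e8b57",
    "RBS": "#e69f00",
    "ribosome_binding_site": "#e69f00",
    "CDS": "#4169e1",
    "terminator": "#cc0000",
    "rep_origin": "#707070",
}

# subset of the SVG 1.1 named colors, enough to disambiguate color-vs-name
SVG_NAMED_COLORS = frozenset(
    """aqua black blue brown chocolate coral crimson cyan darkblue darkgreen
    darkorange darkred fuchsia gold gray green grey indigo khaki lavender lime
    magenta maroon navy olive orange orchid pink plum purple red salmon sienna
    silver teal tomato turquoise violet white yellow""".split()
)

_HEX_COLOR = re.compile(r"^#[0-9A-Fa-f]{6}$")

# glyph geometry: 30x30 unit cell, backbone through the cell's vertical centre
CELL = 30
MARGIN = 10


def _is_color(token: str) -> bool:
    return token.lower() in SVG_NAMED_COLORS or bool(_HEX_COLOR.match(token))


@dataclass
class PartSpec:
    """One glyph in the circuit: code, orientation and optional styling."""

    code: str
    orientation: str = "forward"  # or "reverse"
    color: str | None = None
    name: str | None = None
    index: int = 0

    @property
    def part_type(self) -> str:
        return PART_CODES[self.code]

    @property
    def fill(self) -> str:
        return self.color or DEFAULT_COLORS[self.code]


@dataclass
class RegulationSpec:
    """A regulatory arc between two part indices."""

    from_index: int
    to_index: int
    kind: str  # activation | repression
    color: str | None = None

    def __post_init__(self):
        if self.kind not in ("activation", "repression"):
            raise SynbioValidationError(f"unknown regulation kind {self.kind!r}")
        if self.from_index == self.to_index:
            raise SynbioValidationError("self-regulation arcs are unsupported")


def parse_circuit_string(s: str) -> list[PartSpec]:
    """Parse ``"p r c t o"``-style circuit strings into parts indexed 0..n-1."""
    parts: list[PartSpec] = []
    for pos, token in enumerate(s.split()):
        body = token
        orientation = "forward"
        if body.startswith("-"):
            orientation = "reverse"
            body = body[1:]
        if not body:
            raise SynbioParseError(f"empty part token at position {pos}", column=pos)
        fields = body.split(".")
        code = fields[0]
        if code not in PART_CODES:
            raise SynbioParseError(
                f"unknown part code {code!r} in token {token!r} at position {pos} "
                f"(expected one of {sorted(PART_CODES)})",
                column=pos,
            )
        color = None
        name = None
        ext = fields[1:]
        if len(ext) == 1:
            if _is_color(ext[0]):
                color = ext[0]
            else:
                name = ext[0]
        elif len(ext) >= 2:
            color, name = ext[0], ".".join(ext[1:])
            if not _is_color(color):
                raise SynbioParseError(
                    f"{color!r} in token {token!r} is not an SVG color or #RRGGBB",
                    column=pos,
                )
        parts.append(PartSpec(code, orientation, color, name, index=len(parts)))
    return parts


_REG_RE = re.compile(r"^(\d+)->(\d+)\.(\w+)(?:\.(\S+))?$")


def parse_regulations(s: str) -> list[RegulationSpec]:
    """Parse ``"2->0.repression 1->3.activation.red"``-style regulation strings."""
    regs: list[RegulationSpec] = []
    for pos, token in enumerate(s.split()):
        m = _REG_RE.match(token)
        if not m:
            raise SynbioParseError(
                f"cannot parse regulation {token!r} at position {pos} "
                "(expected 'i->j.kind[.color]')",
                column=pos,
            )
        frm, to, kind, color = m.groups()
        if color is not None and not _is_color(color):
            raise SynbioParseError(f"{color!r} is not an SVG color or #RRGGBB", column=pos)
        regs.append(RegulationSpec(int(frm), int(to), kind, color))
    return regs


# ---------------------------------------------------------------------------
# layout


def _part_cx(index: int) -> float:
    return MARGIN + index * CELL + CELL / 2


def assign_arc_tiers(regs: list[RegulationSpec]) -> list[int]:
    """Greedy interval-graph coloring: overlapping arcs get distinct tiers."""
    intervals = [
        (min(_part_cx(r.from_index), _part_cx(r.to_index)),
         max(_part_cx(r.from_index), _part_cx(r.to_index)))
        for r in regs
    ]
    tiers = [0] * len(regs)
    order = sorted(range(len(regs)), key=lambda i: intervals[i])
    for k, i in enumerate(order):
        used = {
            tiers[j]
            for j in order[:k]
            if intervals[j][0] < intervals[i][1] and intervals[i][0] < intervals[j][1]
        }
        t = 0
        while t in used:
            t += 1
        tiers[i] = t
    return tiers


def _fmt(v: float) -> str:
    s = f"{v:.1f}"
    return s[:-2] if s.endswith(".0") else s


# ---------------------------------------------------------------------------
# glyphs (drawn forward in a cell centred at cx on backbone y=B; reverse
# parts are rotated 180 degrees about the cell centre, which mirrors them
# below the backbone without changing their x-interval)


def _glyph(part: PartSpec, cx: float, B: float) -> str:
    fill = part.fill
    c = part.code
    el: list[str] = []
    if c == "p":
        el.append(
            f'<path d="M {_fmt(cx - 8)} {_fmt(B)} V {_fmt(B - 18)} H {_fmt(cx + 4)}" '
            f'fill="none" stroke="{fill}" stroke-width="2"/>'
        )
        el.append(
            f'<polygon points="{_fmt(cx + 4)},{_fmt(B - 22)} {_fmt(cx + 11)},{_fmt(B - 18)} '
            f'{_fmt(cx + 4)},{_fmt(B - 14)}" fill="{fill}"/>'
        )
    elif c == "r":
        el.append(
            f'<path d="M {_fmt(cx - 8)} {_fmt(B)} A 8 8 0 0 1 {_fmt(cx + 8)} {_fmt(B)} Z" '
            f'fill="{fill}" stroke="black" stroke-width="1"/>'
        )
    elif c == "c":
        x0 = cx - CELL / 2
        el.append(
            f'<polygon points="{_fmt(x0 + 3)},{_fmt(B - 8)} {_fmt(x0 + 19)},{_fmt(B - 8)} '
            f'{_fmt(x0 + 27)},{_fmt(B)} {_fmt(x0 + 19)},{_fmt(B + 8)} {_fmt(x0 + 3)},{_fmt(B + 8)}" '
            f'fill="{fill}" stroke="black" stroke-width="1"/>'
        )
    elif c == "t":
        el.append(
            f'<path d="M {_fmt(cx)} {_fmt(B)} V {_fmt(B - 14)} M {_fmt(cx - 8)} {_fmt(B - 14)} '
            f'H {_fmt(cx + 8)}" fill="none" stroke="{fill}" stroke-width="2"/>'
        )
    elif c == "o":
        el.append(
            f'<circle cx="{_fmt(cx)}" cy="{_fmt(B)}" r="7" fill="white" '
            f'stroke="{fill}" stroke-width="2"/>'
        )
    return "".join(el)


def render_circuit(
    parts: list[PartSpec],
    regulations: list[RegulationSpec] | None = None,
    title: str | None = None,
) -> str:
    """Render a parsed circuit to deterministic SVG text.

    One glyph per part sits on a horizontal backbone; reverse parts are
    mirrored below it.  Repression arcs end in a flat bar, activation arcs
    in an arrowhead.
    """
    regulations = regulations or []
    for r in regulations:
        for idx in (r.from_index, r.to_index):
            if idx < 0 or idx >= len(parts):
                raise SynbioValidationError(
                    f"regulation {r.from_index}->{r.to_index} refers to part {idx}, "
                    f"but only {len(parts)} parts were given"
                )
    tiers = assign_arc_tiers(regulations)
    n_tiers = max(tiers, default=-1) + 1
    top = 30 + 12 * n_tiers + 24  # arc region above the backbone
    B = float(top)
    width = max(2 * MARGIN + CELL * len(parts), 60)
    height = top + 50
    out = [
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{width}" height="{height}" viewBox="0 0 {width} {height}">'
    ]
    if title:
        out.append(f'<title>{title}</title>')
    out.append(
        f'<line x1="0" y1="{_fmt(B)}" x2="{width}" y2="{_fmt(B)}" '
        f'stroke="black" stroke-width="2"/>'
    )
    for part in parts:
        cx = _part_cx(part.index)
        body = _glyph(part, cx, B)
        if part.orientation == "reverse":
            out.append(f'<g transform="rotate(180 {_fmt(cx)} {_fmt(B)})">{body}</g>')
        else:
            out.append(body)
        if part.name:
            out.append(
                f'<text x="{_fmt(cx)}" y="{_fmt(B + 36)}" font-size="9" '
                f'font-family="sans-serif" text-anchor="middle">{part.name}</text>'
            )
    for reg, tier in zip(regulations, tiers):
        x1 = _part_cx(reg.from_index)
        x2 = _part_cx(reg.to_index)
        y_anchor = B - 26
        y_arc = B - 30 - 12 * tier
        color = reg.color or ("#2e8b57" if reg.kind == "activation" else "#cc0000")
        out.append(
            f'<path d="M {_fmt(x1)} {_fmt(y_anchor)} V {_fmt(y_arc)} H {_fmt(x2)} '
            f'V {_fmt(y_anchor)}" fill="none" stroke="{color}" stroke-width="1.5"/>'
        )
        if reg.kind == "activation":
            out.append(
                f'<polygon points="{_fmt(x2 - 4)},{_fmt(y_anchor)} {_fmt(x2 + 4)},{_fmt(y_anchor)} '
                f'{_fmt(x2)},{_fmt(y_anchor + 6)}" fill="{color}"/>'
            )
        else:
            out.append(
                f'<line x1="{_fmt(x2 - 6)}" y1="{_fmt(y_anchor)}" x2="{_fmt(x2 + 6)}" '
                f'y2="{_fmt(y_anchor)}" stroke="{color}" stroke-width="2.5"/>'
            )
    out.append("</svg>")
    return "\n".join(out) + "\n"


def plot_circuit(circuit: str, regulation: str = "", title: str | None = None) -> str:
    """Convenience wrapper: parse both strings and render."""
    return render_circuit(parse_circuit_string(circuit), parse_regulations(regulation), title)


# ---------------------------------------------------------------------------
# plasmid maps


def _polar(cx: float, cy: float, r: float, angle_deg: float) -> tuple[float, float]:
    # clockwise from 12 o'clock
    a = math.radians(angle_deg)
    return cx + r * math.sin(a), cy - r * math.cos(a)


def feature_angles(record: GeneticRecord) -> list[tuple[float, float]]:
    """(start, end) angles in degrees, clockwise from 12 o'clock, per feature."""
    n = len(record.sequence)
    out = []
    for f in record.features:
        a0 = 360.0 * f.location.start / n
        if f.origin_spanning:
            a1 = 360.0 * (f.location.end + n) / n
        else:
            a1 = 360.0 * f.location.end / n
        out.append((a0, a1))
    return out


def render_plasmid_map(record: GeneticRecord, style: str = "circular") -> str:
    """Draw a plasmid map: features as annular arcs (circular) or a scaled
    track of rectangles (linear), colored by feature type."""
    if style not in ("circular", "linear"):
        raise SynbioValidationError(f"unknown style {style!r}")
    if len(record.sequence) == 0:
        raise SynbioValidationError("cannot draw a map of a zero-length sequence")
    if style == "linear":
        return _linear_map(record)
    W = H = 320
    cx = cy = W / 2
    r = 100.0
    out = [
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{W}" height="{H}" viewBox="0 0 {W} {H}">',
        f'<circle cx="{_fmt(cx)}" cy="{_fmt(cy)}" r="{_fmt(r)}" fill="none" '
        f'stroke="#888888" stroke-width="2"/>',
        f'<text x="{_fmt(cx)}" y="{_fmt(cy - 4)}" font-size="12" font-family="sans-serif" '
        f'text-anchor="middle">{record.id}</text>',
        f'<text x="{_fmt(cx)}" y="{_fmt(cy + 12)}" font-size="10" font-family="sans-serif" '
        f'text-anchor="middle">{len(record.sequence)} bp</text>',
    ]
    for f, (a0, a1) in zip(record.features, feature_angles(record)):
        color = FEATURE_COLORS.get(f.type, "#999999")
        label = f.qualifiers.get("label", [f.type])[0] if f.qualifiers.get("label") else f.type
        if a1 - a0 >= 360.0:
            out.append(
                f'<circle cx="{_fmt(cx)}" cy="{_fmt(cy)}" r="{_fmt(r)}" fill="none" '
                f'stroke="{color}" stroke-width="12"/>'
            )
        else:
            x0, y0 = _polar(cx, cy, r, a0)
            x1, y1 = _polar(cx, cy, r, a1)
            large = 1 if (a1 - a0) > 180.0 else 0
            out.append(
                f'<path d="M {_fmt(x0)} {_fmt(y0)} A {_fmt(r)} {_fmt(r)} 0 {large} 1 '
                f'{_fmt(x1)} {_fmt(y1)}" fill="none" stroke="{color}" stroke-width="12"/>'
            )
        mid = (a0 + a1) / 2 % 360
        lx, ly = _polar(cx, cy, r + 22, mid)
        anchor = "start" if 0 < mid < 180 else ("end" if 180 < mid < 360 else "middle")
        out.append(
            f'<text x="{_fmt(lx)}" y="{_fmt(ly)}" font-size="9" font-family="sans-serif" '
            f'text-anchor="{anchor}">{label}</text>'
        )
    out.append("</svg>")
    return "\n".join(out) + "\n"


def _linear_map(record: GeneticRecord) -> str:
    n = len(record.sequence)
    W, H = 520, 110
    x_off, track_w, y = 20.0, 480.0, 45.0
    out = [
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{W}" height="{H}" viewBox="0 0 {W} {H}">',
        f'<line x1="{_fmt(x_off)}" y1="{_fmt(y)}" x2="{_fmt(x_off + track_w)}" '
        f'y2="{_fmt(y)}" stroke="#888888" stroke-width="2"/>',
        f'<text x="{_fmt(x_off)}" y="20" font-size="11" font-family="sans-serif">'
        f"{record.id} ({n} bp)</text>",
    ]
    for f in sorted(record.features, key=lambda f: (f.location.start, f.location.end)):
        color = FEATURE_COLORS.get(f.type, "#999999")
        label = f.qualifiers.get("label", [f.type])[0] if f.qualifiers.get("label") else f.type
        x = x_off + track_w * f.location.start / n
        w = track_w * f.location.wrapped_length(n) / n
        out.append(
            f'<rect x="{_fmt(x)}" y="{_fmt(y - 7)}" width="{_fmt(max(w, 1.0))}" height="14" '
            f'fill="{color}" stroke="black" stroke-width="0.5"/>'
        )
        out.append(
            f'<text x="{_fmt(x + max(w, 1.0) / 2)}" y="{_fmt(y + 24)}" font-size="8" '
            f'font-family="sans-serif" text-anchor="middle">{label}</text>'
        )
    out.append("</svg>")
    return "\n".join(out) + "\n"
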