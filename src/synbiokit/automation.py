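"""Microplates, wells, transfers and picklists for liquid-handling robots.

A :class:`Plate` is created empty in one of the standard SBS formats
(6/24/96/384/1536 wells); each :class:`Well` tracks its contents as a
component-name -> volume (µL) mapping under a per-well capacity.  A
:class:`PickList` is an ordered programme of :class:`Transfer` steps that
can be simulated against the plates (proportional mixing: a transfer
carries each source component in proportion to its fraction of the source
well) and exported as CSV for a liquid handler — either a generic dialect
or the Labcyte Echo dialect (volumes in nanoliters at 2.5 nL resolution).

Simulation never mutates its inputs: it returns fresh end-state plates
plus a per-transfer report.  Volume is conserved exactly for every
successful transfer.
"""

from __future__ import annotations

import copy
import csv
import io
import json
import math
import warnings
from dataclasses import dataclass, field

from synbiokit.errors import SynbioValidationError

# format -> (rows, cols)
PLATE_FORMATS = {6: (2, 3), 24: (4, 6), 96: (8, 12), 384: (16, 24), 1536: (32, 48)}

# working-volume defaults in µL, overridable per plate
DEFAULT_CAPACITY = {6: 5000.0, 24: 2000.0, 96: 200.0, 384: 65.0, 1536: 12.0}

ECHO_RESOLUTION_NL = 2.5


def _row_letters(rows: int) -> list[str]:
    out = []
    for i in range(rows):
        out.append(chr(ord("A") + i) if i < 26 else "A" + chr(ord("A") + i - 26))
    return out


def well_names(fmt: int) -> list[str]:
    rows, cols = PLATE_FORMATS[fmt]
    return [f"{r}{c}" for r in _row_letters(rows) for c in range(1, cols + 1)]


def normalize_well_name(name: str) -> str:
    """Accept zero-padded names ('A01') but store unpadded ('A1')."""
    i = 0
    while i < len(name) and name[i].isalpha():
        i += 1
    row, col = name[:i].upper(), name[i:]
    if not row or not col or not col.isdigit():
        raise SynbioValidationError(f"malformed well name {name!r}")
    return f"{row}{int(col)}"


@dataclass
class Well:
    name: str
    capacity: float
    contents: dict[str, float] = field(default_factory=dict)

    @property
    def volume(self) -> float:
        return sum(self.contents.values())

    @property
    def is_empty(self) -> bool:
        return self.volume == 0.0


@dataclass
class Plate:
    name: str
    format: int
    wells: dict[str, Well] = field(default_factory=dict)

    def __post_init__(self):
        if self.format not in PLATE_FORMATS:
            raise SynbioValidationError(
                f"unsupported plate format {self.format}; "
                f"supported: {sorted(PLATE_FORMATS)}"
            )
        if not self.wells:
            cap = DEFAULT_CAPACITY[self.format]
            self.wells = {w: Well(w, cap) for w in well_names(self.format)}

    def well(self, name: str) -> Well:
        key = normalize_well_name(name)
        if key not in self.wells:
            raise SynbioValidationError(f"no well {name!r} on plate {self.name!r}")
        return self.wells[key]

    @property
    def total_volume(self) -> float:
        return sum(w.volume for w in self.wells.values())


def create_plate(name: str, format: int, capacity: float | None = None) -> Plate:
    """A named plate of the given format with every well present and empty."""
    plate = Plate(name=name, format=format)
    if capacity is not None:
        for w in plate.wells.values():
            w.capacity = capacity
    return plate


def fill_well(plate: Plate, well: str, component: str, volume: float) -> Plate:
    """Add ``volume`` µL of ``component`` to a well (in place)."""
    if volume <= 0:
        raise SynbioValidationError(f"fill volume must be positive, got {volume}")
    w = plate.well(well)
    if w.volume + volume > w.capacity + 1e-9:
        raise SynbioValidationError(
            f"well {w.name} on {plate.name!r} would hold {w.volume + volume:g} µL, "
            f"over its {w.capacity:g} µL capacity"
        )
    w.contents[component] = w.contents.get(component, 0.0) + volume
    return plate


@dataclass(frozen=True)
class Transfer:
    source_plate: str
    source_well: str
    dest_plate: str
    dest_well: str
    volume: float  # µL

    def __post_init__(self):
        if self.volume <= 0:
            raise SynbioValidationError(f"transfer volume must be positive, got {self.volume}")


@dataclass
class PickList:
    transfers: list[Transfer] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.transfers)


def add_transfer(picklist: PickList, transfer: Transfer) -> PickList:
    """Append a transfer; execution order is append order."""
    picklist.transfers.append(transfer)
    return picklist


# ---------------------------------------------------------------------------
# simulation


@dataclass
class TransferReport:
    index: int
    ok: bool
    message: str = ""


def simulate_picklist(
    picklist: PickList, plates: list[Plate], on_error: str = "abort"
) -> tuple[dict[str, Plate], list[TransferReport]]:
    """Apply the transfers in order against copies of the plates.

    Components move in proportion to their fraction of the source well.
    A transfer fails (insufficient source volume, destination overflow,
    unknown plate/well) without corrupting state; ``on_error`` decides
    whether the remaining transfers still run ("skip") or not ("abort").
    Inputs are never mutated.
    """
    if on_error not in ("abort", "skip"):
        raise SynbioValidationError(f"on_error must be 'abort' or 'skip', got {on_error!r}")
    state = {p.name: copy.deepcopy(p) for p in plates}
    if len(state) != len(plates):
        raise SynbioValidationError("duplicate plate names supplied")
    report: list[TransferReport] = []
    for i, tr in enumerate(picklist.transfers):
        try:
            if tr.source_plate not in state:
                raise SynbioValidationError(f"unknown source plate {tr.source_plate!r}")
            if tr.dest_plate not in state:
                raise SynbioValidationError(f"unknown destination plate {tr.dest_plate!r}")
            src = state[tr.source_plate].well(tr.source_well)
            dst = state[tr.dest_plate].well(tr.dest_well)
            if src.volume < tr.volume - 1e-9:
                raise SynbioValidationError(
                    f"transfer {i}: source {tr.source_plate}/{src.name} holds "
                    f"{src.volume:g} µL, cannot draw {tr.volume:g} µL"
                )
            if dst.volume + tr.volume > dst.capacity + 1e-9:
                raise SynbioValidationError(
                    f"transfer {i}: destination {tr.dest_plate}/{dst.name} would exceed "
                    f"its {dst.capacity:g} µL capacity"
                )
            fraction = tr.volume / src.volume
            moved = {comp: vol * fraction for comp, vol in src.contents.items()}
            for comp, vol in moved.items():
                src.contents[comp] -= vol
                if src.contents[comp] <= 1e-12:
                    del src.contents[comp]
                dst.contents[comp] = dst.contents.get(comp, 0.0) + vol
            report.append(TransferReport(i, True))
        except SynbioValidationError as e:
            report.append(TransferReport(i, False, str(e)))
            if on_error == "abort":
                break
    return state, report


# ---------------------------------------------------------------------------
# CSV export / import

ECHO_HEADER = [
    "Source Plate Name",
    "Source Well",
    "Destination Plate Name",
    "Destination Well",
    "Transfer Volume",
]
GENERIC_HEADER = ["source_plate", "source_well", "dest_plate", "dest_well", "volume_ul"]


def export_picklist(picklist: PickList, dialect: str = "generic_csv", strict: bool = False) -> str:
    """CSV in execution order.

    echo_csv writes volumes in nanoliters; volumes that are not a multiple
    of the Echo's 2.5 nL droplet either raise (``strict``) or are rounded
    to the nearest droplet with a warning.
    """
    if dialect not in ("echo_csv", "generic_csv"):
        raise SynbioValidationError(f"unknown picklist dialect {dialect!r}")
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    if dialect == "generic_csv":
        writer.writerow(GENERIC_HEADER)
        for tr in picklist.transfers:
            writer.writerow(
                [tr.source_plate, tr.source_well, tr.dest_plate, tr.dest_well, repr(tr.volume)]
            )
        return buf.getvalue()
    writer.writerow(ECHO_HEADER)
    for i, tr in enumerate(picklist.transfers):
        nl = tr.volume * 1000.0
        droplets = nl / ECHO_RESOLUTION_NL
        if abs(droplets - round(droplets)) > 1e-9:
            if strict:
                raise SynbioValidationError(
                    f"transfer {i}: {nl:g} nL is not a multiple of "
                    f"{ECHO_RESOLUTION_NL} nL (Echo droplet size)"
                )
            nl = round(droplets) * ECHO_RESOLUTION_NL
            warnings.warn(
                f"transfer {i}: volume rounded to {nl:g} nL (2.5 nL resolution)",
                stacklevel=2,
            )
        writer.writerow(
            [tr.source_plate, tr.source_well, tr.dest_plate, tr.dest_well,
             f"{nl:g}" if nl != int(nl) else str(int(nl))]
        )
    return buf.getvalue()


def import_picklist(text: str) -> PickList:
    """Read a generic_csv picklist back (inverse of the generic export)."""
    reader = csv.reader(io.StringIO(text))
    header = next(reader, None)
    if header != GENERIC_HEADER:
        raise SynbioValidationError(
            f"expected generic_csv header {GENERIC_HEADER}, got {header}"
        )
    pl = PickList()
    for row in reader:
        if not row:
            continue
        sp, sw, dp, dw, vol = row
        add_transfer(pl, Transfer(sp, normalize_well_name(sw), dp, normalize_well_name(dw), float(vol)))
    return pl


# ---------------------------------------------------------------------------
# JSON scenario (plates + picklist) for the CLI


def scenario_to_json(plates: list[Plate], picklist: PickList) -> str:
    return json.dumps(
        {
            "plates": [
                {
                    "name": p.name,
                    "format": p.format,
                    "wells": {
                        w.name: {"capacity": w.capacity, "contents": w.contents}
                        for w in p.wells.values()
                        if not w.is_empty or w.capacity != DEFAULT_CAPACITY[p.format]
                    },
                }
                for p in plates
            ],
            "transfers": [
                {
                    "source_plate": t.source_plate,
                    "source_well": t.source_well,
                    "dest_plate": t.dest_plate,
                    "dest_well": t.dest_well,
                    "volume_ul": t.volume,
                }
                for t in picklist.transfers
            ],
        },
        indent=2,
    )


def scenario_from_json(text: str) -> tuple[list[Plate], PickList]:
    data = json.loads(text)
    plates = []
    for pd in data.get("plates", []):
        plate = create_plate(pd["name"], int(pd["format"]))
        for wname, wd in pd.get("wells", {}).items():
            well = plate.well(wname)
            if "capacity" in wd:
                well.capacity = float(wd["capacity"])
            for comp, vol in wd.get("contents", {}).items():
                fill_well(plate, wname, comp, float(vol))
        plates.append(plate)
    pl = PickList()
    for td in data.get("transfers", []):
        add_transfer(
            pl,
            Transfer(
                td["source_plate"],
                normalize_well_name(td["source_well"]),
                td["dest_plate"],
                normalize_well_name(td["dest_well"]),
                float(td["volume_ul"]),
            ),
        )
    if math.isnan(sum(t.volume for t in pl.transfers)):
        raise SynbioValidationError("NaN volume in picklist")
    return plates, pl
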