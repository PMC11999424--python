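"""Deck, labware, pipette and temperature-module model with placement rules.

The liquid handler exposes 11 usable deck slots plus a fixed trash chute at
slot 12, arranged as a 3-column x 4-row grid (slots 1-3 nearest the user,
then 4-6, 7-9, and 10-11 + trash at the back).  Temperature modules can only
sit on the outer-edge slots (cord routing), and a cooling module placed
edge-adjacent to a heating module fails to reach temperature — the validator
treats both as hard errors.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

from .errors import ModelError

__all__ = [
    "LabwareDef",
    "ModuleDef",
    "PipetteConfig",
    "Placement",
    "DeckLayout",
    "CapacityReport",
    "LayoutIssue",
    "standard_labware",
    "build_heatshock_layout",
    "build_conjugation_layout",
    "validate_layout",
    "capacity",
    "position_names",
    "TRASH_SLOT",
    "MODULE_SLOTS",
]

TRASH_SLOT = 12

#: Slots that can host a temperature module (outer edges, cord constraint).
MODULE_SLOTS = frozenset({1, 3, 4, 6, 7, 9, 10})

#: Liquid that cannot be reliably drawn from the bottom of a vessel, uL.
DEAD_VOLUME_UL = {
    "tuberack_6x50ml": 500.0,
    "tuberack_15x15ml": 100.0,
}


@dataclass(frozen=True)
class LabwareDef:
    """A labware definition: position count and per-position capacity (uL)."""

    name: str
    kind: str
    positions: int
    capacity_uL: float


_STANDARD = {
    "plate96_pcr": LabwareDef("96-well 200 uL PCR plate (fully skirted)", "plate96_pcr", 96, 200.0),
    "plate96_deepwell": LabwareDef("96-well 2 mL deep-well plate", "plate96_deepwell", 96, 2000.0),
    "tiprack300": LabwareDef("300 uL tip rack", "tiprack300", 96, 300.0),
    "tiprack1000": LabwareDef("1000 uL tip rack", "tiprack1000", 96, 1000.0),
    "tuberack_6x50ml": LabwareDef("6 x 50 mL tube rack", "tuberack_6x50ml", 6, 50000.0),
    "tuberack_15x15ml": LabwareDef("15 x 15 mL tube rack", "tuberack_15x15ml", 15, 15000.0),
    "alu_block": LabwareDef("96-well aluminium block", "alu_block", 96, 200.0),
    "trash": LabwareDef("trash chute", "trash", 1, math.inf),
}


def standard_labware(kind: str) -> LabwareDef:
    """Return the canonical definition for a known labware kind."""
    try:
        return _STANDARD[kind]
    except KeyError:
        raise ModelError("unknown_labware", f"unknown labware kind {kind!r}") from None


def dead_volume(kind: str) -> float:
    """Unrecoverable volume per position for a labware kind (0 for plates)."""
    return DEAD_VOLUME_UL.get(kind, 0.0)


def position_names(kind: str) -> list[str]:
    """Well/tube names of a labware kind, in column-major order (A1, B1, ...)."""
    lw = standard_labware(kind)
    if lw.kind in ("plate96_pcr", "plate96_deepwell", "tiprack300", "tiprack1000", "alu_block"):
        rows, cols = 8, 12
    elif lw.kind == "tuberack_6x50ml":
        rows, cols = 2, 3
    elif lw.kind == "tuberack_15x15ml":
        rows, cols = 3, 5
    else:  # trash
        return ["A1"]
    return [f"{chr(ord('A') + r)}{c + 1}" for c in range(cols) for r in range(rows)]


@dataclass(frozen=True)
class ModuleDef:
    """A heating/cooling module occupying a deck slot; setpoint 4-95 degC."""

    role: str  # "cooling" | "heating"
    setpoint: float

    def __post_init__(self) -> None:
        if self.role not in ("cooling", "heating"):
            raise ModelError("module", f"unknown module role {self.role!r}")
        if not (4.0 <= self.setpoint <= 95.0):
            raise ModelError("module", f"setpoint {self.setpoint} outside 4-95 degC")


@dataclass(frozen=True)
class PipetteConfig:
    """A pipetting head: channel count, volume range, and relative speed."""

    channels: int
    max_volume: float
    min_volume: float = 1.0
    speed_factor: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.speed_factor <= 1):
            raise ModelError("pipette", "speed_factor must be in (0, 1]")


#: The pipettes the two workflows use.
P300_MULTI = PipetteConfig(channels=8, max_volume=300.0, min_volume=20.0)
P300_SINGLE = PipetteConfig(channels=1, max_volume=300.0, min_volume=20.0)
P1000_SINGLE = PipetteConfig(channels=1, max_volume=1000.0, min_volume=100.0)


@dataclass(frozen=True)
class Placement:
    """Contents of one deck slot: labware, optionally on a module or adapter."""

    labware: LabwareDef
    module: ModuleDef | None = None
    adapter: str | None = None


@dataclass
class CapacityReport:
    """Maximum experiment size a layout supports."""

    max_ecoli: int
    max_strep: int
    max_reactions: int


@dataclass(frozen=True)
class LayoutIssue:
    """One validation finding; ``severity`` is ``error`` or ``warning``."""

    code: str
    severity: str
    message: str


@dataclass
class DeckLayout:
    """Assignment of labware/modules to deck slots; slot 12 is always trash."""

    slots: dict[int, Placement] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.slots.setdefault(TRASH_SLOT, Placement(standard_labware("trash")))

    def place(self, slot: int, placement: Placement) -> None:
        if slot == TRASH_SLOT:
            raise ModelError("slot", "slot 12 is the fixed trash chute")
        if not (1 <= slot <= 11):
            raise ModelError("slot", f"slot {slot} outside 1-11")
        if slot in self.slots:
            raise ModelError("occupied", f"slot {slot} already occupied")
        self.slots[slot] = placement

    def occupied_slots(self) -> set[int]:
        return set(self.slots)

    def labware_at(self, slot: int) -> LabwareDef:
        try:
            return self.slots[slot].labware
        except KeyError:
            raise ModelError("slot", f"slot {slot} is empty") from None

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        out: dict[str, dict] = {}
        for slot in sorted(self.slots):
            p = self.slots[slot]
            entry: dict = {"labware": p.labware.kind}
            if p.module is not None:
                entry["module"] = {"role": p.module.role, "setpoint": p.module.setpoint}
            if p.adapter is not None:
                entry["adapter"] = p.adapter
            out[str(slot)] = entry
        return {"slots": out}

    @classmethod
    def from_dict(cls, data: dict) -> "DeckLayout":
        slots: dict[int, Placement] = {}
        for key, entry in data["slots"].items():
            module = None
            if "module" in entry:
                module = ModuleDef(entry["module"]["role"], entry["module"]["setpoint"])
            slots[int(key)] = Placement(
                standard_labware(entry["labware"]), module, entry.get("adapter")
            )
        return cls(slots=slots)

    def to_json(self, indent: int | None = 2) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=indent)

    @classmethod
    def from_json(cls, text: str) -> "DeckLayout":
        return cls.from_dict(json.loads(text))


# ---------------------------------------------------------------------------
# layout builders

def build_heatshock_layout() -> DeckLayout:
    """The single-plate heat-shock deck.

    Slot 6: deep-well plate with recovery medium; slot 7: cooling module
    (4 degC) carrying the plasmid PCR plate; slot 8: freezer-chilled
    aluminium block with the competent-cell PCR plate; slot 9: heating module
    (42 degC) with the heat-shock PCR plate; slot 11: 300 uL tips.
    """
    layout = DeckLayout()
    layout.place(6, Placement(standard_labware("plate96_deepwell")))
    layout.place(7, Placement(standard_labware("plate96_pcr"), ModuleDef("cooling", 4.0)))
    layout.place(8, Placement(standard_labware("plate96_pcr"), adapter="alu_block"))
    layout.place(9, Placement(standard_labware("plate96_pcr"), ModuleDef("heating", 42.0)))
    layout.place(11, Placement(standard_labware("tiprack300")))
    return layout


def build_conjugation_layout(n_ecoli: int, n_strep: int, n_reactions: int) -> DeckLayout:
    """A conjugation deck scaled to the design size.

    Deep-well plates fill slot 3 then slot 2 (second plate only past 96
    reactions); 50 mL racks fill slots 4, 5, 6 as needed; 15 mL racks slot 9
    then 8; 1000 uL tips at slot 7; 300 uL tips at slot 11 then 10.
    """
    from .design import MAX_ECOLI, MAX_REACTIONS, MAX_STREP

    if not (1 <= n_ecoli <= MAX_ECOLI):
        raise ModelError("capacity", f"n_ecoli={n_ecoli} outside 1..{MAX_ECOLI}")
    if not (1 <= n_strep <= MAX_STREP):
        raise ModelError("capacity", f"n_strep={n_strep} outside 1..{MAX_STREP}")
    if not (1 <= n_reactions <= MAX_REACTIONS):
        raise ModelError("capacity", f"n_reactions={n_reactions} outside 1..{MAX_REACTIONS}")

    layout = DeckLayout()
    for i in range(math.ceil(n_reactions / 96)):
        layout.place([3, 2][i], Placement(standard_labware("plate96_deepwell")))
    for i in range(math.ceil(n_ecoli / 6)):
        layout.place([4, 5, 6][i], Placement(standard_labware("tuberack_6x50ml")))
    for i in range(math.ceil(n_strep / 15)):
        layout.place([9, 8][i], Placement(standard_labware("tuberack_15x15ml")))
    layout.place(7, Placement(standard_labware("tiprack1000")))
    for i in range(math.ceil(n_reactions / 96)):
        layout.place([11, 10][i], Placement(standard_labware("tiprack300")))
    return layout


# ---------------------------------------------------------------------------
# validation

def _grid(slot: int) -> tuple[int, int]:
    """Slot number -> (row, col) in the 3-column x 4-row deck grid."""
    return (slot - 1) // 3, (slot - 1) % 3


def _adjacent(a: int, b: int) -> bool:
    (ra, ca), (rb, cb) = _grid(a), _grid(b)
    return abs(ra - rb) + abs(ca - cb) == 1


def validate_layout(layout: DeckLayout, partial_multichannel: bool = False) -> list[LayoutIssue]:
    """Static placement checks; returns issues rather than raising.

    Rules: (a) temperature modules only on the outer-edge slots; (b) a
    cooling module sharing a grid edge with a heating module is an error
    (it fails to reach temperature); (c) with partial multi-channel tip
    pickup, any module in front-row slots 1-3 is a head-collision error;
    (d) the trash chute must be present at slot 12.
    """
    issues: list[LayoutIssue] = []
    modules = {
        slot: p.module for slot, p in layout.slots.items() if p.module is not None
    }
    for slot, mod in sorted(modules.items()):
        if slot not in MODULE_SLOTS:
            issues.append(
                LayoutIssue(
                    "module_slot",
                    "error",
                    f"{mod.role} module at slot {slot}: modules are restricted to slots "
                    f"{sorted(MODULE_SLOTS)} (cord constraint)",
                )
            )
    cooling = [s for s, m in modules.items() if m.role == "cooling"]
    heating = [s for s, m in modules.items() if m.role == "heating"]
    for c in cooling:
        for h in heating:
            if _adjacent(c, h):
                issues.append(
                    LayoutIssue(
                        "thermal_adjacency",
                        "error",
                        f"cooling module at slot {c} is edge-adjacent to heating module at "
                        f"slot {h}: the cold block fails to reach its target temperature",
                    )
                )
    if partial_multichannel:
        for slot in sorted(modules):
            if slot in (1, 2, 3):
                issues.append(
                    LayoutIssue(
                        "multichannel_collision",
                        "error",
                        f"module at front-row slot {slot}: partial multi-channel pickup "
                        "collides the pipette head with modules in slots 1-3",
                    )
                )
    trash = layout.slots.get(TRASH_SLOT)
    if trash is None or trash.labware.kind != "trash":
        issues.append(LayoutIssue("missing_trash", "error", "slot 12 must hold the trash chute"))
    return issues


def capacity(layout: DeckLayout) -> CapacityReport:
    """Maximum sources/reactions the racks and plates of a layout support."""
    max_ecoli = sum(
        p.labware.positions for p in layout.slots.values() if p.labware.kind == "tuberack_6x50ml"
    )
    max_strep = sum(
        p.labware.positions for p in layout.slots.values() if p.labware.kind == "tuberack_15x15ml"
    )
    plates = sum(1 for p in layout.slots.values() if p.labware.kind == "plate96_deepwell")
    return CapacityReport(max_ecoli=max_ecoli, max_strep=max_strep, max_reactions=96 * plates)
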