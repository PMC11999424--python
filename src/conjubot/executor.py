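"""Virtual plan execution with volume, tip and provenance accounting.

:func:`execute` replays a :class:`~conjubot.plan.StepPlan` against its deck
layout, maintaining per-well material mixtures and per-tip contents, and
enforcing the physical constraints: tips must be attached to move liquid,
tips and wells cannot overfill, and sources cannot be drawn below their
dead volume.  The result is a :class:`Ledger` of events and final states.

Air gaps are tracked as an inert compressible phase inside the tip: they
count against tip capacity but are vented at dispense and excluded from
liquid conservation.  Liquid is conserved exactly — every aspirated
microliter ends in a well, a tube, an attached tip, or the trash.

:func:`audit_contamination` scans the ledger for the cross-contamination
rule: a tip may only aspirate from a source that already contains every
non-sterile material the tip has touched (contact with sterile media is
exempt, which is what makes reusing media-transfer tips for the donor
strain legal).
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field

from .deck import DeckLayout, dead_volume, position_names
from .errors import ExecError
from .plan import Step, StepPlan, addr, split_addr

__all__ = ["WellState", "TipState", "Ledger", "execute", "audit_contamination",
           "DEFAULT_STERILE_MATERIALS", "render_audit_report"]

#: Materials whose contact never contaminates a tip.
DEFAULT_STERILE_MATERIALS = frozenset({"LB", "2xYT", "water", "TE"})

_EPS = 1e-9


@dataclass
class WellState:
    """Final state of one well/tube: total volume and per-material breakdown."""

    volume_uL: float
    materials: dict[str, float]

    @property
    def components(self) -> set[str]:
        return {m for m, v in self.materials.items() if v > _EPS}


@dataclass
class TipState:
    """One physical tip: liquid mixture, air plug, and non-sterile contact set."""

    id: int
    size: int
    liquid: dict[str, float] = field(default_factory=dict)
    air: float = 0.0
    contact: set[str] = field(default_factory=set)

    @property
    def liquid_volume(self) -> float:
        return sum(self.liquid.values())


@dataclass
class Ledger:
    """Virtual-execution record.

    ``events`` is one dict per elementary action (per channel for
    multi-channel steps); ``final_wells`` maps addresses to
    :class:`WellState`; ``tip_pickups`` counts tips by size;
    ``violations`` holds the contamination audit result;
    ``conservation_residual_uL`` is the largest per-material imbalance
    between initial and final liquid inventories.
    """

    events: list[dict] = field(default_factory=list)
    final_wells: dict[str, WellState] = field(default_factory=dict)
    trash_uL: dict[str, float] = field(default_factory=dict)
    tip_pickups: dict[int, int] = field(default_factory=dict)
    violations: list[dict] = field(default_factory=list)
    conservation_residual_uL: float = 0.0

    def to_json(self, indent: int | None = 2) -> str:
        payload = {
            "events": self.events,
            "final_wells": {
                a: {"volume_uL": w.volume_uL, "materials": w.materials}
                for a, w in sorted(self.final_wells.items())
            },
            "trash_uL": self.trash_uL,
            "tip_pickups": {str(k): v for k, v in sorted(self.tip_pickups.items())},
            "violations": self.violations,
            "conservation_residual_uL": self.conservation_residual_uL,
        }
        return json.dumps(payload, sort_keys=True, indent=indent)


class _Sim:
    def __init__(self, layout: DeckLayout, init: dict[str, tuple[float, str]], sterile: frozenset):
        self.layout = layout
        self.sterile = sterile
        self.wells: dict[str, dict[str, float]] = {}
        self.valid_wells: dict[int, set[str]] = {}
        for a, (vol, mat) in init.items():
            self._check_address(a)
            self.wells.setdefault(a, {})
            self.wells[a][mat] = self.wells[a].get(mat, 0.0) + float(vol)
        self.initial: dict[str, float] = {}
        for w in self.wells.values():
            for m, v in w.items():
                self.initial[m] = self.initial.get(m, 0.0) + v
        self.attached: list[TipState] | None = None
        self.tip_counter = 0
        self.pickups: dict[int, int] = {}
        self.trash: dict[str, float] = {}
        self.events: list[dict] = []

    # -- helpers ------------------------------------------------------------

    def _check_address(self, a: str) -> None:
        slot, well = split_addr(a)
        if slot not in self.layout.slots:
            raise ExecError("address", f"{a}: slot {slot} is empty in the layout")
        if slot not in self.valid_wells:
            self.valid_wells[slot] = set(position_names(self.layout.labware_at(slot).kind))
        if well not in self.valid_wells[slot]:
            raise ExecError("address", f"{a}: no such position on {self.layout.labware_at(slot).kind}")

    def _well(self, a: str) -> dict[str, float]:
        self._check_address(a)
        return self.wells.setdefault(a, {})

    def _channel_addresses(self, step: Step) -> list[str]:
        if step.slot is None or step.well is None:
            raise ExecError("address", f"{step.kind} step lacks a slot/well address")
        if step.channel_count == 1:
            return [addr(step.slot, step.well)]
        row, col = step.well[0], step.well[1:]
        if row != "A":
            raise ExecError("address", "multi-channel steps must address the row-A well of a column")
        return [addr(step.slot, f"{chr(ord('A') + i)}{col}") for i in range(step.channel_count)]

    def _need_tips(self, step: Step) -> list[TipState]:
        if self.attached is None:
            raise ExecError("no_tip", f"{step.kind} with no tips attached")
        if len(self.attached) < step.channel_count:
            raise ExecError("no_tip", f"{step.kind}: {step.channel_count} channels, "
                                      f"{len(self.attached)} tips attached")
        return self.attached

    def _nonsterile(self, materials) -> set[str]:
        return {m for m in materials if m not in self.sterile}

    # -- step handlers ------------------------------------------------------

    def run_step(self, i: int, step: Step) -> None:
        handler = getattr(self, f"_do_{step.kind}", None)
        if handler is None:
            raise ExecError("step", f"unknown step kind {step.kind!r}")
        handler(i, step)

    def _log(self, i: int, kind: str, **extra) -> None:
        self.events.append({"i": i, "kind": kind, **extra})

    def _do_set_temperature(self, i: int, step: Step) -> None:
        self._log(i, "set_temperature", slot=step.slot, temperature_c=step.temperature_c)

    def _do_wait(self, i: int, step: Step) -> None:
        self._log(i, "wait", duration_s=step.duration_s)

    def _do_pause_for_user(self, i: int, step: Step) -> None:
        self._log(i, "pause_for_user", note=step.note)

    def _do_manual_prompt(self, i: int, step: Step) -> None:
        self._log(i, "manual_prompt", note=step.note)

    def _do_pick_tips(self, i: int, step: Step) -> None:
        if self.attached is not None:
            raise ExecError("tip_attached", "pick_tips while tips are already attached")
        if step.tip_size not in (300, 1000):
            raise ExecError("step", f"pick_tips needs tip_size 300 or 1000, got {step.tip_size}")
        self.attached = []
        for _ in range(step.channel_count):
            self.tip_counter += 1
            self.attached.append(TipState(id=self.tip_counter, size=step.tip_size))
        self.pickups[step.tip_size] = self.pickups.get(step.tip_size, 0) + step.channel_count
        self._log(i, "pick_tips", size=step.tip_size, count=step.channel_count,
                  tips=[t.id for t in self.attached])

    def _do_drop_tips(self, i: int, step: Step) -> None:
        tips = self._need_tips(step)
        for t in tips:
            for m, v in t.liquid.items():
                if v > _EPS:
                    self.trash[m] = self.trash.get(m, 0.0) + v
        self._log(i, "drop_tips", tips=[t.id for t in tips])
        self.attached = None

    def _do_air_gap(self, i: int, step: Step) -> None:
        tips = self._need_tips(step)
        vol = float(step.volume_uL or 0.0)
        for t in tips:
            if t.liquid_volume + t.air + vol > t.size + _EPS:
                raise ExecError("tip_capacity", f"air gap overfills the {t.size} uL tip")
            t.air += vol
        self._log(i, "air_gap", volume_uL=vol, tips=[t.id for t in tips])

    def _do_aspirate(self, i: int, step: Step) -> None:
        tips = self._need_tips(step)
        vol = float(step.volume_uL or 0.0)
        if vol <= 0:
            raise ExecError("volume", "aspirate volume must be > 0")
        for t, a in zip(tips, self._channel_addresses(step)):
            well = self._well(a)
            slot, _ = split_addr(a)
            dv = dead_volume(self.layout.labware_at(slot).kind)
            total = sum(well.values())
            src_materials = sorted(m for m, v in well.items() if v > _EPS)
            self._log(
                i, "aspirate", address=a, volume_uL=vol, tip=t.id,
                source_materials=src_materials,
                tip_contact=sorted(t.contact),
            )
            if total - vol < dv - _EPS:
                raise ExecError(
                    "overdraw",
                    f"{a}: aspirating {vol:g} uL would leave {total - vol:g} uL "
                    f"(< {dv:g} uL dead volume)",
                )
            if t.liquid_volume + t.air + vol > t.size + _EPS:
                raise ExecError("tip_capacity", f"{a}: {vol:g} uL overfills the {t.size} uL tip")
            frac = vol / total
            for m in list(well):
                take = well[m] * frac
                well[m] -= take
                t.liquid[m] = t.liquid.get(m, 0.0) + take
            t.contact |= self._nonsterile(src_materials)

    def _do_dispense(self, i: int, step: Step) -> None:
        tips = self._need_tips(step)
        vol = float(step.volume_uL or 0.0)
        if vol <= 0:
            raise ExecError("volume", "dispense volume must be > 0")
        for t, a in zip(tips, self._channel_addresses(step)):
            well = self._well(a)
            slot, _ = split_addr(a)
            cap = self.layout.labware_at(slot).capacity_uL
            liquid = t.liquid_volume
            dispensed = min(vol, liquid)
            vented = vol - dispensed
            if vented > t.air + _EPS:
                raise ExecError(
                    "volume", f"{a}: dispense of {vol:g} uL exceeds tip contents "
                              f"({liquid:g} uL liquid + {t.air:g} uL air)"
                )
            dest_before = sorted(m for m, v in well.items() if v > _EPS)
            if sum(well.values()) + dispensed > cap + _EPS:
                raise ExecError("overflow", f"{a}: dispense would exceed the {cap:g} uL capacity")
            if liquid > _EPS and dispensed > _EPS:
                frac = dispensed / liquid
                for m in list(t.liquid):
                    give = t.liquid[m] * frac
                    t.liquid[m] -= give
                    well[m] = well.get(m, 0.0) + give
            t.air -= vented
            t.contact |= self._nonsterile(dest_before)
            self._log(i, "dispense", address=a, volume_uL=vol, tip=t.id,
                      dest_materials_before=dest_before)

    def _do_mix(self, i: int, step: Step) -> None:
        tips = self._need_tips(step)
        vol = float(step.volume_uL or 0.0)
        for t, a in zip(tips, self._channel_addresses(step)):
            well = self._well(a)
            if vol > t.size + _EPS:
                raise ExecError("tip_capacity", f"{a}: mix volume {vol:g} uL exceeds tip size")
            materials = sorted(m for m, v in well.items() if v > _EPS)
            t.contact |= self._nonsterile(materials)
            self._log(i, "mix", address=a, volume_uL=vol, tip=t.id,
                      source_materials=materials)

    # -- wrap-up ------------------------------------------------------------

    def finish(self) -> Ledger:
        final = {
            a: WellState(volume_uL=sum(w.values()), materials={m: v for m, v in w.items()})
            for a, w in self.wells.items()
        }
        residual = 0.0
        materials = set(self.initial)
        for w in self.wells.values():
            materials |= set(w)
        materials |= set(self.trash)
        for m in materials:
            total = sum(w.get(m, 0.0) for w in self.wells.values()) + self.trash.get(m, 0.0)
            if self.attached:
                total += sum(t.liquid.get(m, 0.0) for t in self.attached)
            residual = max(residual, abs(total - self.initial.get(m, 0.0)))
        return Ledger(
            events=self.events,
            final_wells=final,
            trash_uL=dict(self.trash),
            tip_pickups=dict(self.pickups),
            conservation_residual_uL=residual,
        )


def execute(
    plan: StepPlan,
    layout: DeckLayout | None = None,
    initial_contents: dict[str, tuple[float, str]] | None = None,
    sterile_materials: frozenset[str] = DEFAULT_STERILE_MATERIALS,
) -> Ledger:
    """Replay ``plan`` on a virtual deck and return the resulting ledger.

    ``layout`` and ``initial_contents`` default to the ones embedded in the
    plan.  The call is deterministic and leaves its inputs untouched.

    Raises
    ------
    ExecError
        ``no_tip``, ``overdraw``, ``overflow``, ``tip_capacity``,
        ``address``, ``volume`` or ``tip_attached`` on the first physical
        constraint violation.
    """
    layout = layout if layout is not None else plan.layout
    init = initial_contents if initial_contents is not None else plan.initial_contents
    sim = _Sim(layout, copy.deepcopy(dict(init)), frozenset(sterile_materials))
    for i, step in enumerate(plan.steps):
        sim.run_step(i, step)
    ledger = sim.finish()
    ledger.violations = audit_contamination(ledger)
    return ledger


def audit_contamination(ledger: Ledger) -> list[dict]:
    """Cross-contamination scan over a completed ledger.

    A violation is recorded for every aspirate whose source material set is
    not a superset of the tip's non-sterile contact set at that moment —
    i.e. the tip would carry foreign material into the source.
    """
    violations: list[dict] = []
    for e in ledger.events:
        if e["kind"] != "aspirate":
            continue
        contact = set(e["tip_contact"])
        source = set(e["source_materials"])
        if not contact <= source:
            violations.append(
                {
                    "event": e["i"],
                    "address": e["address"],
                    "tip": e["tip"],
                    "foreign": sorted(contact - source),
                    "message": (
                        f"tip {e['tip']} aspirated from {e['address']} carrying foreign "
                        f"material {sorted(contact - source)}"
                    ),
                }
            )
    return violations


def render_audit_report(ledger: Ledger) -> str:
    """Plain-text audit summary of a ledger."""
    lines = [
        "Contamination audit",
        "===================",
        f"events: {len(ledger.events)}",
        f"tip pickups: " + ", ".join(f"{v} x {k} uL" for k, v in sorted(ledger.tip_pickups.items())),
        f"liquid conservation residual: {ledger.conservation_residual_uL:.3e} uL",
        f"violations: {len(ledger.violations)}",
    ]
    for v in ledger.violations:
        lines.append(f"  - step {v['event']}: {v['message']}")
    return "\n".join(lines) + "\n"
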