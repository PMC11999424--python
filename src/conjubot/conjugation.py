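"""Conjugation planner: well assignment, step plan, media accounting.

Each reaction mixes 150 uL of washed donor *E. coli* culture with 150 uL of
*Streptomyces* spore suspension in a deep-well plate well (300 uL final —
the classical 500 uL mix shrunk so a 1000 uL tip covers six wells at once
and no centrifugation step is needed).

Donor transfers use one 1000 uL tip per E. coli source: per batch of up to
six wells the tip aspirates ``150 x batch + 50`` uL — the 50 uL overage
replaces the blow-out at the end of a repeat-dispense, which would spray
material — repeat-dispenses 150 uL per well, and returns the overage to the
same source tube (which cannot contaminate) before the next aspiration.
Recipient transfers always take a fresh 300 uL tip per reaction, the
cross-contamination-critical step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .deck import DeckLayout, build_conjugation_layout, dead_volume, position_names
from .design import ExperimentDesign, expand_pattern
from .errors import PlanError
from .plan import Step, StepPlan, addr

__all__ = [
    "WellAssignment",
    "MediaReport",
    "assign_wells",
    "plan_conjugation",
    "media_requirement",
    "check_source_volumes",
    "ecoli_tube_address",
    "strep_tube_address",
    "conjugation_initial_contents",
    "VOL_ECOLI",
    "VOL_SPORES",
    "OVERAGE",
    "BATCH_SIZE",
]

VOL_ECOLI = 150.0  #: donor culture per reaction, uL
VOL_SPORES = 150.0  #: spore suspension per reaction, uL
OVERAGE = 50.0  #: extra volume aspirated per repeat-dispense cycle, uL
BATCH_SIZE = 6  #: wells served per 1000 uL aspiration (6*150 + 50 = 950 uL)

#: LB per donor strain, mL: 5 mL preculture + 15 mL expansion + 2 x 20 mL washes.
LB_PER_ECOLI_ML = 60.0

_PLATE_SLOTS = (3, 2)  # slot 3 filled first
_RACK50_SLOTS = (4, 5, 6)
_RACK15_SLOTS = (9, 8)

_POS50 = position_names("tuberack_6x50ml")
_POS15 = position_names("tuberack_15x15ml")


def ecoli_tube_address(index: int) -> tuple[int, str]:
    """Deck position of the ``index``-th 50 mL donor tube (racks at 4, 5, 6)."""
    if index >= 18:
        raise PlanError("capacity", f"no 50 mL rack position for tube index {index}")
    return _RACK50_SLOTS[index // 6], _POS50[index % 6]


def strep_tube_address(index: int) -> tuple[int, str]:
    """Deck position of the ``index``-th 15 mL spore tube (racks at 9 then 8)."""
    if index >= 30:
        raise PlanError("capacity", f"no 15 mL rack position for tube index {index}")
    return _RACK15_SLOTS[index // 15], _POS15[index % 15]


@dataclass
class WellAssignment:
    """Reaction index -> (plate slot, well), in fill order.

    Wells fill column-major (A1, B1, ... H1, A2, ...) on the slot-3 plate
    first; the slot-2 plate is used only past 96 reactions.
    """

    entries: tuple[tuple[int, str], ...] = ()

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, i: int) -> tuple[int, str]:
        return self.entries[i]


def assign_wells(reactions: list[tuple[str, str]]) -> WellAssignment:
    """Assign each reaction a deep-well position, in reaction order."""
    n = len(reactions)
    if n == 0:
        raise PlanError("empty", "no reactions to assign")
    if n > 192:
        raise PlanError("capacity", f"{n} reactions > 192 (two plates)")
    plate_wells = position_names("plate96_deepwell")
    entries = []
    for i in range(n):
        slot = _PLATE_SLOTS[i // 96]
        entries.append((slot, plate_wells[i % 96]))
    return WellAssignment(tuple(entries))


@dataclass
class MediaReport:
    """Minimum media volumes for a conjugation run.

    ``lb_total_mL`` covers off-deck overnight culturing with washes for all
    donor strains; ``per_tube_min_uL`` gives on-deck minimum fills per tube
    (draws + transient overage + dead volume).
    """

    lb_per_ecoli_mL: float
    lb_total_mL: float
    media_2xYT_mL: float
    per_tube_min_uL: dict[str, float] = field(default_factory=dict)


def _wells_per_source(design: ExperimentDesign) -> tuple[dict[str, int], dict[str, int]]:
    reactions = expand_pattern(design)
    ec: dict[str, int] = {e.id: 0 for e in design.ecoli_sources}
    st: dict[str, int] = {s.id: 0 for s in design.strep_sources}
    for e_id, s_id in reactions:
        ec[e_id] += 1
        st[s_id] += 1
    return ec, st


def _required_ecoli_uL(wells: int) -> float:
    # peak depletion is during the final batch: all net draws plus one overage
    if wells == 0:
        return 0.0
    return VOL_ECOLI * wells + OVERAGE + dead_volume("tuberack_6x50ml")


def _required_strep_uL(wells: int) -> float:
    if wells == 0:
        return 0.0
    return VOL_SPORES * wells + dead_volume("tuberack_15x15ml")


def media_requirement(design: ExperimentDesign) -> MediaReport:
    """Minimum LB (culturing + washes) and 2xYT the design needs.

    LB: 60 mL per donor strain (5 mL preculture + 15 mL expansion + two
    washes with an equal 20 mL volume).  2xYT per spore tube: 150 uL per
    reaction it serves plus the 100 uL tube dead volume.
    """
    ec, st = (
        _wells_per_source(design)
        if design.mix_pattern.pairs
        else ({e.id: 0 for e in design.ecoli_sources}, {s.id: 0 for s in design.strep_sources})
    )
    per_tube: dict[str, float] = {}
    for e in design.ecoli_sources:
        per_tube[e.id] = _required_ecoli_uL(ec.get(e.id, 0))
    yt_total = 0.0
    for s in design.strep_sources:
        need = _required_strep_uL(st.get(s.id, 0))
        per_tube[s.id] = need
        yt_total += need
    n_ecoli = len(design.ecoli_sources)
    return MediaReport(
        lb_per_ecoli_mL=LB_PER_ECOLI_ML,
        lb_total_mL=LB_PER_ECOLI_ML * n_ecoli,
        media_2xYT_mL=yt_total / 1000.0,
        per_tube_min_uL=per_tube,
    )


def check_source_volumes(
    design: ExperimentDesign, assignment: WellAssignment | None = None
) -> list[str]:
    """Flag tubes whose stated fill cannot cover their draws.

    Only sources with a declared ``fill_uL`` are checked; usable volume is
    the fill minus the tube dead volume, and the requirement includes the
    transient 50 uL overage for donor tubes.
    """
    if not design.mix_pattern.pairs:
        return []
    ec, st = _wells_per_source(design)
    issues: list[str] = []
    for e in design.ecoli_sources:
        need = _required_ecoli_uL(ec.get(e.id, 0))
        if e.fill_uL is not None and e.fill_uL < need:
            issues.append(
                f"E. coli tube {e.id!r}: fill {e.fill_uL:g} uL < required {need:g} uL "
                f"(incl. {OVERAGE:g} uL overage + {dead_volume('tuberack_6x50ml'):g} uL dead volume)"
            )
    for s in design.strep_sources:
        need = _required_strep_uL(st.get(s.id, 0))
        if s.fill_uL is not None and s.fill_uL < need:
            issues.append(
                f"Streptomyces tube {s.id!r}: fill {s.fill_uL:g} uL < required {need:g} uL "
                f"(incl. {dead_volume('tuberack_15x15ml'):g} uL dead volume)"
            )
    return issues


def _batches(wells: list[tuple[int, str]]) -> list[list[tuple[int, str]]]:
    return [wells[i : i + BATCH_SIZE] for i in range(0, len(wells), BATCH_SIZE)]


def plan_conjugation(
    design: ExperimentDesign,
    user: str = "",
    timestamp: str = "",
    enable_media_predispense: bool = False,
) -> StepPlan:
    """Compile the conjugation workflow into a step plan.

    Phase 1 moves donor culture with one 1000 uL tip per E. coli source
    (repeat-dispense batches of six, overage returned to the tube); phase 2
    moves spores with a fresh 300 uL tip per reaction.  With
    ``enable_media_predispense`` a sterile 2xYT pre-dispense runs first per
    source, and its tip is reused for that source's donor transfers (legal:
    sterile-media contact cannot contaminate).
    """
    reactions = expand_pattern(design)
    if not reactions:
        raise PlanError("empty", "design has no reactions")
    assignment = assign_wells(reactions)

    issues = check_source_volumes(design, assignment)
    if issues:
        raise PlanError("volume", "; ".join(issues))

    n_ecoli = len(design.ecoli_sources)
    n_strep = len(design.strep_sources)
    media_tube: tuple[int, str] | None = None
    rack_positions = n_ecoli
    if enable_media_predispense:
        if n_ecoli >= 18:
            raise PlanError(
                "capacity", "media pre-dispense needs a free 50 mL rack position (max 17 sources)"
            )
        media_tube = ecoli_tube_address(n_ecoli)
        rack_positions = n_ecoli + 1
    layout = build_conjugation_layout(rack_positions, n_strep, len(reactions))

    ec_index = {e.id: i for i, e in enumerate(design.ecoli_sources)}
    st_index = {s.id: i for i, s in enumerate(design.strep_sources)}
    wells_by_source: dict[str, list[tuple[int, str]]] = {e.id: [] for e in design.ecoli_sources}
    for i, (e_id, _s_id) in enumerate(reactions):
        wells_by_source[e_id].append(assignment[i])

    steps: list[Step] = []

    def _repeat_dispense(src: tuple[int, str], wells: list[tuple[int, str]], what: str) -> None:
        for batch in _batches(wells):
            draw = VOL_ECOLI * len(batch) + OVERAGE
            steps.append(
                Step(
                    "aspirate",
                    slot=src[0],
                    well=src[1],
                    volume_uL=draw,
                    channel_count=1,
                    note=f"{what}: repeat-dispense batch of {len(batch)} + {OVERAGE:g} uL overage",
                )
            )
            for slot, well in batch:
                steps.append(
                    Step("dispense", slot=slot, well=well, volume_uL=VOL_ECOLI, channel_count=1)
                )
            steps.append(
                Step(
                    "dispense",
                    slot=src[0],
                    well=src[1],
                    volume_uL=OVERAGE,
                    channel_count=1,
                    note="return overage to source tube",
                )
            )

    # phase 1: donor E. coli (and optional sterile media pre-dispense), one
    # 1000 uL tip per source
    for e in design.ecoli_sources:
        wells = wells_by_source[e.id]
        if not wells:
            continue
        steps.append(Step("pick_tips", slot=7, channel_count=1, tip_size=1000))
        if media_tube is not None:
            _repeat_dispense(media_tube, wells, "2xYT pre-dispense")
        src = ecoli_tube_address(ec_index[e.id])
        _repeat_dispense(src, wells, f"E. coli {e.id}")
        steps.append(Step("drop_tips", channel_count=1, tip_size=1000))

    # phase 2: spores, fresh 300 uL tip per reaction
    for i, (_e_id, s_id) in enumerate(reactions):
        src = strep_tube_address(st_index[s_id])
        slot, well = assignment[i]
        steps += [
            Step("pick_tips", slot=11, channel_count=1, tip_size=300),
            Step(
                "aspirate",
                slot=src[0],
                well=src[1],
                volume_uL=VOL_SPORES,
                channel_count=1,
                note=f"spores {s_id}",
            ),
            Step("dispense", slot=slot, well=well, volume_uL=VOL_SPORES, channel_count=1),
            Step("drop_tips", channel_count=1, tip_size=300),
        ]

    steps.append(
        Step(
            "manual_prompt",
            note="streak each well on MS agar + 10 mM MgCl2, incubate at 30 degC overnight",
        )
    )

    metadata = {
        "mode": "conjugation",
        "user": user,
        "created": timestamp,
        "design": {
            "n_ecoli": n_ecoli,
            "n_strep": n_strep,
            "n_reactions": len(reactions),
            "media_predispense": enable_media_predispense,
            "pairs": [[p.ecoli_id, p.strep_id, p.replicates] for p in design.mix_pattern.pairs],
        },
    }
    return StepPlan(
        steps=steps,
        layout=layout,
        metadata=metadata,
        initial_contents=conjugation_initial_contents(
            design, enable_media_predispense=enable_media_predispense
        ),
    )


def conjugation_initial_contents(
    design: ExperimentDesign, enable_media_predispense: bool = False
) -> dict[str, tuple[float, str]]:
    """Tube loading for simulation: stated fills, or the computed minimum."""
    ec, st = _wells_per_source(design)
    contents: dict[str, tuple[float, str]] = {}
    for i, e in enumerate(design.ecoli_sources):
        need = _required_ecoli_uL(ec.get(e.id, 0))
        fill = e.fill_uL if e.fill_uL is not None else need
        if fill > 0:
            slot, well = ecoli_tube_address(i)
            contents[addr(slot, well)] = (fill, e.id)
    for j, s in enumerate(design.strep_sources):
        need = _required_strep_uL(st.get(s.id, 0))
        fill = s.fill_uL if s.fill_uL is not None else need
        if fill > 0:
            slot, well = strep_tube_address(j)
            contents[addr(slot, well)] = (fill, s.id)
    if enable_media_predispense:
        total_wells = sum(ec.values())
        n_batches = sum(math.ceil(w / BATCH_SIZE) for w in ec.values() if w)
        fill = VOL_ECOLI * total_wells + OVERAGE * min(1, n_batches) + dead_volume(
            "tuberack_6x50ml"
        )
        slot, well = ecoli_tube_address(len(design.ecoli_sources))
        contents[addr(slot, well)] = (fill, "2xYT")
    return contents
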