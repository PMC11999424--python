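"""Heat-shock transformation planner.

Compiles a heat-shock design into an explicit step plan for one 96-well
plate of transformations: chill plasmid + competent-cell mix at 4 degC,
30 s heat shock at 42 degC, then dilution into recovery medium — all with
the 8-channel 300 uL head at two-thirds pipetting speed (small volumes form
droplets and bubbles at full speed).

Per column the liquid path is: 50 uL competent cells (slot 8, chilled
aluminium block) into the plasmid plate on the cooling module (slot 7,
2 uL plasmid per well), mix, 30 min hold; then 45 uL of the 52 uL mix —
7 uL stays behind to avoid bubbles — moved with a 30 uL air gap to the
42 degC plate (slot 9); after 30 s, a composite transfer aspirates 100 uL
recovery LB from the deep-well plate (slot 6), a 30 uL air gap, then the
45 uL shocked mix, and dispenses everything back into the deep-well,
leaving each recovery well at 995 uL (950 preloaded - 100 + 145).
"""

from __future__ import annotations

import math

from .deck import DeckLayout, P300_MULTI, PipetteConfig, build_heatshock_layout
from .errors import PlanError
from .plan import Step, StepPlan, addr

__all__ = [
    "plan_heatshock",
    "airgap_composite_transfer",
    "heatshock_initial_contents",
    "VOL_CELLS",
    "VOL_PLASMID",
    "VOL_SAMPLE",
    "VOL_MEDIA",
    "AIR_GAP",
    "SPEED_FACTOR",
]

VOL_CELLS = 50.0  #: competent cells per well, uL
VOL_PLASMID = 2.0  #: plasmid DNA per well, uL
VOL_SAMPLE = 45.0  #: mix volume carried forward (of the 52 uL), uL
VOL_MEDIA = 100.0  #: recovery LB aspirated per well, uL
VOL_LB_PER_WELL = 950.0  #: LB preloaded per deep-well well, uL
AIR_GAP = 30.0  #: air plug between media and sample, uL
SPEED_FACTOR = 2.0 / 3.0  #: pipetting speed relative to default
CHILL_S = 30 * 60.0  #: pre-shock hold at 4 degC, s
SHOCK_S = 30.0  #: heat shock duration, s

_SLOT_MEDIA = 6
_SLOT_COLD = 7
_SLOT_CELLS = 8
_SLOT_HOT = 9
_SLOT_TIPS = 11


def airgap_composite_transfer(
    media_vol: float,
    air_vol: float,
    sample_vol: float,
    media_src: tuple[int, str] | None,
    sample_src: tuple[int, str],
    dest: tuple[int, str],
    pipette: PipetteConfig = P300_MULTI,
    speed_factor: float = SPEED_FACTOR,
    channel_count: int = 8,
    note: str = "",
) -> list[Step]:
    """Composite transfer: aspirate media, an air plug, then sample; dispense all.

    Zero media or air volumes elide the corresponding step.  The summed
    volume (liquid + air) must fit the pipette.
    """
    total = media_vol + air_vol + sample_vol
    if total > pipette.max_volume:
        raise PlanError(
            "volume",
            f"composite transfer of {total} uL exceeds the {pipette.max_volume} uL pipette",
        )
    steps: list[Step] = []
    if media_vol > 0:
        if media_src is None:
            raise PlanError("volume", "media volume given without a media source")
        steps.append(
            Step(
                "aspirate",
                slot=media_src[0],
                well=media_src[1],
                volume_uL=media_vol,
                speed_factor=speed_factor,
                channel_count=channel_count,
                note=note,
            )
        )
    if air_vol > 0:
        steps.append(
            Step("air_gap", volume_uL=air_vol, channel_count=channel_count, note=note)
        )
    steps.append(
        Step(
            "aspirate",
            slot=sample_src[0],
            well=sample_src[1],
            volume_uL=sample_vol,
            speed_factor=speed_factor,
            channel_count=channel_count,
            note=note,
        )
    )
    steps.append(
        Step(
            "dispense",
            slot=dest[0],
            well=dest[1],
            volume_uL=total,
            speed_factor=speed_factor,
            channel_count=channel_count,
            note=note,
        )
    )
    return steps


def _columns(n_samples: int) -> list[int]:
    return list(range(1, math.ceil(n_samples / 8) + 1))


def plan_heatshock(
    design,
    n_samples: int,
    user: str = "",
    timestamp: str = "",
    layout: DeckLayout | None = None,
) -> StepPlan:
    """Compile the heat-shock workflow for ``n_samples`` transformations.

    Samples fill whole 8-well columns (partial columns are rounded up so the
    multi-channel head always picks a full row of tips, avoiding the
    front-row collision).  The cooling module is always set before the
    heating module — activating them in the other order leaves the cold
    block unable to reach 4 degC.
    """
    if n_samples > 96:
        raise PlanError("capacity", f"{n_samples} samples > 96 (one plate per deck)")
    if n_samples < 1:
        raise PlanError("empty", "n_samples must be >= 1")
    layout = layout or build_heatshock_layout()
    cols = _columns(n_samples)

    steps: list[Step] = [
        Step("set_temperature", slot=_SLOT_COLD, temperature_c=4.0, note="cooling module first"),
        Step("set_temperature", slot=_SLOT_HOT, temperature_c=42.0),
        Step(
            "pause_for_user",
            note=(
                "load competent cells (slot 8), plasmid plate (slot 7), "
                f"deep-well plate with {VOL_LB_PER_WELL:g} uL warm LB per well (slot 6)"
            ),
        ),
    ]
    # phase 1: cells onto plasmid plate at 4 degC, mix
    for c in cols:
        col_well = f"A{c}"
        steps += [
            Step("pick_tips", slot=_SLOT_TIPS, channel_count=8, tip_size=300),
            Step(
                "aspirate",
                slot=_SLOT_CELLS,
                well=col_well,
                volume_uL=VOL_CELLS,
                speed_factor=SPEED_FACTOR,
                channel_count=8,
            ),
            Step(
                "dispense",
                slot=_SLOT_COLD,
                well=col_well,
                volume_uL=VOL_CELLS,
                speed_factor=SPEED_FACTOR,
                channel_count=8,
            ),
            Step(
                "mix",
                slot=_SLOT_COLD,
                well=col_well,
                volume_uL=30.0,
                speed_factor=SPEED_FACTOR,
                channel_count=8,
            ),
            Step("drop_tips", channel_count=8, tip_size=300),
        ]
    steps.append(Step("wait", duration_s=CHILL_S, note="chill mix at 4 degC"))
    # phase 2: mix to the 42 degC plate (air-gapped; see plan notes)
    for c in cols:
        col_well = f"A{c}"
        steps.append(Step("pick_tips", slot=_SLOT_TIPS, channel_count=8, tip_size=300))
        steps += airgap_composite_transfer(
            0.0,
            AIR_GAP,
            VOL_SAMPLE,
            None,
            (_SLOT_COLD, col_well),
            (_SLOT_HOT, col_well),
            note="air-gapped transfer to heat shock; 7 uL of the 52 uL mix left behind",
        )
        steps.append(Step("drop_tips", channel_count=8, tip_size=300))
    steps.append(Step("wait", duration_s=SHOCK_S, note="heat shock at 42 degC"))
    # phase 3: composite media + sample into the recovery deep-well
    for c in cols:
        col_well = f"A{c}"
        steps.append(Step("pick_tips", slot=_SLOT_TIPS, channel_count=8, tip_size=300))
        steps += airgap_composite_transfer(
            VOL_MEDIA,
            AIR_GAP,
            VOL_SAMPLE,
            (_SLOT_MEDIA, col_well),
            (_SLOT_HOT, col_well),
            (_SLOT_MEDIA, col_well),
            note="composite recovery transfer (media / air / shocked mix)",
        )
        steps.append(Step("drop_tips", channel_count=8, tip_size=300))
    steps.append(
        Step(
            "manual_prompt",
            note="seal the deep-well plate, incubate 60 min at 37 degC / 250 rpm, then plate",
        )
    )

    metadata = {
        "mode": "heatshock",
        "user": user,
        "created": timestamp,
        "design": {
            "n_samples": n_samples,
            "n_columns": len(cols),
            "plasmids": [p.name for p in design.plasmids] if design is not None else [],
        },
    }
    return StepPlan(
        steps=steps,
        layout=layout,
        metadata=metadata,
        initial_contents=heatshock_initial_contents(n_samples),
    )


def heatshock_initial_contents(n_samples: int) -> dict[str, tuple[float, str]]:
    """Reagent loading for simulation: every well of each processed column.

    The 8-channel head pipettes whole columns, so all 8 wells of each
    occupied column carry reagent; wells padding a partial column are blanks
    that consume reagent but hold no sample of interest.
    """
    contents: dict[str, tuple[float, str]] = {}
    for c in _columns(n_samples):
        for r in "ABCDEFGH":
            well = f"{r}{c}"
            contents[addr(_SLOT_CELLS, well)] = (VOL_CELLS, "competent-cells")
            contents[addr(_SLOT_COLD, well)] = (VOL_PLASMID, "plasmid")
            contents[addr(_SLOT_MEDIA, well)] = (VOL_LB_PER_WELL, "LB")
    return contents
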