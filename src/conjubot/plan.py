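"""Step and StepPlan: the explicit, serializable liquid-handling program.

A :class:`StepPlan` is the compiler output shared by both workflow planners,
the virtual executor and the artifact renderers.  Steps are fully explicit —
every aspirate/dispense names a slot, a well/tube position and a volume — so
a plan can be replayed, audited and rendered without re-running the compiler.

Addresses are written ``"slotN:W"`` (e.g. ``slot3:A1``) wherever a flat key
is needed (initial contents, ledger states).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

from .deck import DeckLayout

__all__ = ["Step", "StepPlan", "addr", "split_addr", "STEP_KINDS"]

STEP_KINDS = frozenset(
    {
        "set_temperature",
        "pause_for_user",
        "pick_tips",
        "drop_tips",
        "aspirate",
        "air_gap",
        "dispense",
        "mix",
        "wait",
        "manual_prompt",
    }
)


def addr(slot: int, well: str) -> str:
    """Flat address string for a (slot, well) pair."""
    return f"slot{slot}:{well}"


def split_addr(address: str) -> tuple[int, str]:
    """Inverse of :func:`addr`."""
    slot_part, well = address.split(":", 1)
    return int(slot_part.removeprefix("slot")), well


@dataclass
class Step:
    """One atomic plan step.

    ``channel_count`` > 1 means the 8-channel head: ``well`` addresses the
    row-A well of a column and the step applies to the whole column, one
    channel per row.  ``tip_size`` applies to pick/drop steps; thermal and
    timing steps use ``temperature_c`` / ``duration_s``.
    """

    kind: str
    slot: int | None = None
    well: str | None = None
    volume_uL: float | None = None
    speed_factor: float | None = None
    channel_count: int = 1
    tip_size: int | None = None
    temperature_c: float | None = None
    duration_s: float | None = None
    note: str = ""

    def to_dict(self) -> dict:
        d = asdict(self)
        return {k: v for k, v in d.items() if v is not None and v != "" or k in ("kind", "channel_count")}

    @classmethod
    def from_dict(cls, data: dict) -> "Step":
        return cls(**data)


@dataclass
class StepPlan:
    """An ordered step list plus the deck layout and starting contents.

    ``metadata`` carries mode, user, timestamp and a design summary;
    ``initial_contents`` maps flat addresses to ``(volume_uL, material)``
    and is what the virtual executor loads before replay, making a
    serialized plan self-contained for simulation and audit.
    """

    steps: list[Step]
    layout: DeckLayout
    metadata: dict = field(default_factory=dict)
    initial_contents: dict[str, tuple[float, str]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "metadata": self.metadata,
            "layout": self.layout.to_dict(),
            "initial_contents": {k: list(v) for k, v in sorted(self.initial_contents.items())},
            "steps": [s.to_dict() for s in self.steps],
        }

    def to_json(self, indent: int | None = 2) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=indent)

    @classmethod
    def from_dict(cls, data: dict) -> "StepPlan":
        return cls(
            steps=[Step.from_dict(s) for s in data["steps"]],
            layout=DeckLayout.from_dict(data["layout"]),
            metadata=data.get("metadata", {}),
            initial_contents={
                k: (float(v[0]), str(v[1])) for k, v in data.get("initial_contents", {}).items()
            },
        )

    @classmethod
    def from_json(cls, text: str) -> "StepPlan":
        return cls.from_dict(json.loads(text))
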