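"""Run-output suite: design echo, consumables BOM, plate maps, run log, robot script.

Every renderer here is a pure function of (design, plan, layout, user,
timestamp): regenerating any artifact from the same inputs is byte-identical,
which is what makes run directories diffable and auditable.  The spreadsheet
is emitted both as XLSX (for the bench) and CSV (bit-stable, used by golden
tests); plate images are deterministic SVG text mirroring the CSV grids; the
robot script follows the Opentrons Python API v2 protocol-file convention
and embeds a machine-readable copy of the plan so that parsing the script
recovers an equal plan.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass
from pathlib import Path

from openpyxl import Workbook

from .conjugation import WellAssignment, media_requirement
from .deck import DeckLayout
from .design import ExperimentDesign, TSV_COLUMNS
from .errors import ArtifactError
from .executor import Ledger, render_audit_report
from .plan import Step, StepPlan

__all__ = [
    "BOMRow",
    "ConsumablesBOM",
    "render_design_table",
    "render_bom",
    "render_plate_map",
    "parse_plate_map",
    "plate_map_svg",
    "heatshock_sample_grid",
    "assignment_grids",
    "render_runlog",
    "render_protocol_script",
    "parse_protocol_script",
    "write_run_directory",
]

_ROWS = "ABCDEFGH"
_COLS = list(range(1, 13))


# ---------------------------------------------------------------------------
# design echo (writer side of the TSV round-trip)

def _fmt(x) -> str:
    if x is None:
        return ""
    if isinstance(x, float):
        return format(x, "g")
    return str(x)


def render_design_table(design: ExperimentDesign) -> str:
    """Serialize a design back to the TSV schema accepted by the parser."""
    out = ["\t".join(TSV_COLUMNS)]

    def row(**kw) -> None:
        out.append("\t".join(_fmt(kw.get(c)) for c in TSV_COLUMNS))

    for a in design.antibiotics:
        row(kind="antibiotic", id=a.name, final_conc_ug_per_ml=a.final_conc)
    for p in design.plasmids:
        row(kind="plasmid", id=p.name, antibiotic=p.selection_antibiotic, dna_ng=p.dna_amount)
    for e in design.ecoli_sources:
        row(kind="ecoli", id=e.id, plasmid=e.plasmid, fill_uL=e.fill_uL)
    for s in design.strep_sources:
        row(kind="strep", id=s.id, spores_per_aliquot=s.spore_count, fill_uL=s.fill_uL)
    for pr in design.mix_pattern.pairs:
        row(kind="pair", ecoli=pr.ecoli_id, strep=pr.strep_id, replicates=pr.replicates)
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# consumables BOM

@dataclass(frozen=True)
class BOMRow:
    item: str
    category: str
    quantity: float
    unit: str


@dataclass
class ConsumablesBOM:
    """Bill of materials for one run; tip counts equal executor tip pickups."""

    rows: list[BOMRow]

    def quantity(self, item: str) -> float:
        for r in self.rows:
            if r.item == item:
                return r.quantity
        return 0.0

    def to_csv(self) -> str:
        buf = io.StringIO()
        w = csv.writer(buf, lineterminator="\n")
        w.writerow(["item", "category", "quantity", "unit"])
        for r in self.rows:
            w.writerow([r.item, r.category, _fmt(r.quantity), r.unit])
        return buf.getvalue()

    def to_xlsx(self, path: str | Path) -> None:
        wb = Workbook()
        ws = wb.active
        ws.title = "consumables"
        ws.append(["item", "category", "quantity", "unit"])
        for r in self.rows:
            ws.append([r.item, r.category, r.quantity, r.unit])
        wb.save(str(path))


def render_bom(
    plan: StepPlan, layout: DeckLayout | None = None, design: ExperimentDesign | None = None
) -> ConsumablesBOM:
    """Count tips, labware, tubes, seals and media for a plan.

    Tip counts are derived from the plan's pick-tip steps, so they always
    match the virtual executor's pickup tally for the same plan.
    """
    layout = layout if layout is not None else plan.layout
    tips = {300: 0, 1000: 0}
    for s in plan.steps:
        if s.kind == "pick_tips" and s.tip_size in tips:
            tips[s.tip_size] += s.channel_count

    rows: list[BOMRow] = [
        BOMRow("300 uL tips", "tips", tips[300], "tips"),
        BOMRow("1000 uL tips", "tips", tips[1000], "tips"),
    ]
    lw_counts: dict[str, int] = {}
    module_count = 0
    for slot in sorted(layout.slots):
        p = layout.slots[slot]
        if p.labware.kind == "trash":
            continue
        lw_counts[p.labware.kind] = lw_counts.get(p.labware.kind, 0) + 1
        if p.module is not None:
            module_count += 1
        if p.adapter is not None:
            lw_counts[p.adapter] = lw_counts.get(p.adapter, 0) + 1
    labware_names = {
        "plate96_deepwell": "96-well 2 mL deep-well plate",
        "plate96_pcr": "96-well 200 uL PCR plate",
        "tiprack300": "300 uL tip rack",
        "tiprack1000": "1000 uL tip rack",
        "tuberack_6x50ml": "6 x 50 mL tube rack",
        "tuberack_15x15ml": "15 x 15 mL tube rack",
        "alu_block": "96-well aluminium block",
    }
    for kind in sorted(lw_counts):
        rows.append(BOMRow(labware_names.get(kind, kind), "labware", lw_counts[kind], "pieces"))
    if module_count:
        rows.append(BOMRow("temperature module", "hardware", module_count, "modules"))

    mode = plan.metadata.get("mode", "")
    if design is not None and mode == "conjugation":
        rows.append(BOMRow("50 mL Falcon tube", "tubes", len(design.ecoli_sources), "tubes"))
        rows.append(BOMRow("15 mL Falcon tube", "tubes", len(design.strep_sources), "tubes"))
        media = media_requirement(design)
        rows.append(BOMRow("LB media (culturing + washes)", "media", media.lb_total_mL, "mL"))
        rows.append(BOMRow("2xYT media", "media", round(media.media_2xYT_mL, 3), "mL"))
        for a in design.antibiotics:
            rows.append(BOMRow(a.name, "antibiotic", a.final_conc, "ug/mL final"))
    if mode == "heatshock":
        lb_uL = sum(v for v, m in plan.initial_contents.values() if m == "LB")
        rows.append(BOMRow("LB media (recovery, on deck)", "media", round(lb_uL / 1000.0, 3), "mL"))
        deepwells = lw_counts.get("plate96_deepwell", 0)
        rows.append(BOMRow("adhesive 96-well sealing film", "consumable", deepwells, "pieces"))
        if design is not None:
            for a in design.antibiotics:
                rows.append(BOMRow(a.name, "antibiotic", a.final_conc, "ug/mL final"))
    return ConsumablesBOM(rows)


# ---------------------------------------------------------------------------
# plate maps

def assignment_grids(
    assignment: WellAssignment, labels: list[str] | None = None
) -> dict[int, list[list[str]]]:
    """8x12 label grids per plate slot, from a well assignment.

    ``labels`` runs parallel to the assignment entries (defaults to the
    1-based reaction number).
    """
    grids: dict[int, list[list[str]]] = {}
    for i, (slot, well) in enumerate(assignment.entries):
        grid = grids.setdefault(slot, [["" for _ in _COLS] for _ in _ROWS])
        r = _ROWS.index(well[0])
        c = int(well[1:]) - 1
        grid[r][c] = labels[i] if labels is not None else str(i + 1)
    return grids


def heatshock_sample_grid(n_samples: int) -> list[list[str]]:
    """Column-major sample map (S01, S02, ...) for a heat-shock plate."""
    grid = [["" for _ in _COLS] for _ in _ROWS]
    for i in range(n_samples):
        grid[i % 8][i // 8] = f"S{i + 1:02d}"
    return grid


def render_plate_map(grid: list[list[str]]) -> str:
    """CSV text of an 8x12 grid: header of column numbers, row-letter lines."""
    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow([""] + [str(c) for c in _COLS])
    for r, row in zip(_ROWS, grid):
        w.writerow([r] + row)
    return buf.getvalue()


def parse_plate_map(text: str) -> list[list[str]]:
    """Inverse of :func:`render_plate_map`."""
    rows = list(csv.reader(io.StringIO(text)))
    if len(rows) != 9 or [c for c in rows[0][1:]] != [str(c) for c in _COLS]:
        raise ArtifactError("parse", "not a plate-map CSV")
    return [row[1:] for row in rows[1:]]


def assignment_from_grids(grids: dict[int, list[list[str]]]) -> WellAssignment:
    """Recover a well assignment from plate grids via the column-major fill order."""
    entries: list[tuple[int, str]] = []
    for slot in (3, 2):
        grid = grids.get(slot)
        if grid is None:
            continue
        for c in range(12):
            for r in range(8):
                if grid[r][c] != "":
                    entries.append((slot, f"{_ROWS[r]}{c + 1}"))
    return WellAssignment(tuple(entries))


def plate_map_svg(grid: list[list[str]], title: str = "") -> str:
    """Deterministic SVG rendering of a plate grid (mirrors the CSV exactly)."""
    cell_w, cell_h, pad = 64, 34, 30
    width = pad + 12 * cell_w + 10
    height = pad + 8 * cell_h + 40
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" height="{height}">',
        f'<text x="{pad}" y="18" font-size="14" font-family="monospace">{title}</text>',
    ]
    for c in _COLS:
        x = pad + (c - 1) * cell_w + cell_w // 2
        parts.append(
            f'<text x="{x}" y="{pad - 4}" font-size="10" text-anchor="middle" '
            f'font-family="monospace">{c}</text>'
        )
    for ri, r in enumerate(_ROWS):
        y = pad + ri * cell_h + cell_h // 2 + 4
        parts.append(
            f'<text x="{pad - 12}" y="{y}" font-size="10" text-anchor="middle" '
            f'font-family="monospace">{r}</text>'
        )
        for ci in range(12):
            x = pad + ci * cell_w
            yy = pad + ri * cell_h
            label = grid[ri][ci]
            fill = "#dfeffb" if label else "#ffffff"
            parts.append(
                f'<rect x="{x}" y="{yy}" width="{cell_w}" height="{cell_h}" '
                f'fill="{fill}" stroke="#555555"/>'
            )
            if label:
                parts.append(
                    f'<text x="{x + cell_w // 2}" y="{yy + cell_h // 2 + 3}" font-size="8" '
                    f'text-anchor="middle" font-family="monospace">{label}</text>'
                )
    parts.append("</svg>")
    return "\n".join(parts) + "\n"


# ---------------------------------------------------------------------------
# run log

def _describe(step: Step) -> str:
    where = f"slot {step.slot} {step.well}" if step.well else (f"slot {step.slot}" if step.slot else "")
    head = {
        "set_temperature": f"set temperature module at {where} to {_fmt(step.temperature_c)} degC",
        "pause_for_user": "pause for user",
        "pick_tips": f"pick up {step.channel_count} x {step.tip_size} uL tip(s) from {where}",
        "drop_tips": f"drop {step.channel_count} tip(s) to trash",
        "aspirate": f"aspirate {_fmt(step.volume_uL)} uL from {where}",
        "air_gap": f"aspirate {_fmt(step.volume_uL)} uL air gap",
        "dispense": f"dispense {_fmt(step.volume_uL)} uL to {where}",
        "mix": f"mix {_fmt(step.volume_uL)} uL at {where}",
        "wait": f"wait {_fmt(step.duration_s)} s",
        "manual_prompt": "manual step",
    }.get(step.kind, step.kind)
    extras = []
    if step.channel_count > 1 and step.kind in ("aspirate", "dispense", "mix"):
        extras.append(f"{step.channel_count} channels")
    if step.speed_factor is not None and step.kind in ("aspirate", "dispense", "mix"):
        extras.append(f"speed x{step.speed_factor:.3g}")
    if step.note:
        extras.append(step.note)
    return head + (f" ({'; '.join(extras)})" if extras else "")


def render_runlog(
    design: ExperimentDesign | None, plan: StepPlan, user: str, timestamp: str
) -> str:
    """Run-log text: user identity, run time, experiment specifics, step list."""
    if not user:
        raise ArtifactError("user", "run log requires a user identity")
    meta = plan.metadata
    lines = [
        "Run log",
        "=======",
        f"user: {user}",
        f"timestamp: {timestamp}",
        f"mode: {meta.get('mode', 'unknown')}",
    ]
    d = meta.get("design", {})
    if meta.get("mode") == "conjugation":
        lines += [
            f"E. coli sources: {d.get('n_ecoli', '?')}",
            f"Streptomyces sources: {d.get('n_strep', '?')}",
            f"reactions: {d.get('n_reactions', '?')}",
        ]
    elif meta.get("mode") == "heatshock":
        lines += [
            f"samples: {d.get('n_samples', '?')}",
            f"columns: {d.get('n_columns', '?')}",
        ]
    if design is not None:
        lines.append(
            "antibiotics: "
            + ", ".join(f"{a.name} ({_fmt(a.final_conc)} ug/mL)" for a in design.antibiotics)
        )
        lines.append("plasmids: " + ", ".join(p.name for p in design.plasmids))
    lines.append(f"steps: {len(plan.steps)}")
    lines.append("")
    for i, step in enumerate(plan.steps, start=1):
        lines.append(f"{i:4d}. {_describe(step)}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# robot protocol script

_API_LABWARE = {
    "plate96_pcr": "biorad_96_wellplate_200ul_pcr",
    "plate96_deepwell": "nest_96_wellplate_2ml_deep",
    "tiprack300": "opentrons_96_tiprack_300ul",
    "tiprack1000": "opentrons_96_tiprack_1000ul",
    "tuberack_6x50ml": "opentrons_6_tuberack_falcon_50ml_conical",
    "tuberack_15x15ml": "opentrons_15_tuberack_falcon_15ml_conical",
}

_PLAN_BEGIN = "# === BEGIN PLAN JSON ==="
_PLAN_END = "# === END PLAN JSON ==="


def render_protocol_script(plan: StepPlan) -> str:
    """Emit a self-contained robot protocol script (Opentrons API v2 dialect).

    The script loads only the slots the layout occupies, and replays the
    embedded plan with a small step interpreter.  The embedded JSON copy is
    authoritative: parsing the script recovers a plan equal to the input.
    """
    meta = plan.metadata
    plan_json = plan.to_json(indent=2)
    sizes = sorted({s.tip_size for s in plan.steps if s.kind == "pick_tips" and s.tip_size})
    multi = any(s.channel_count > 1 for s in plan.steps)

    load_lines: list[str] = []
    tiprack_by_size: dict[int, list[str]] = {300: [], 1000: []}
    for slot in sorted(plan.layout.slots):
        p = plan.layout.slots[slot]
        kind = p.labware.kind
        if kind == "trash":
            continue
        if p.module is not None:
            load_lines.append(
                f'    module_{slot} = protocol.load_module("temperature module", "{slot}")'
            )
            load_lines.append(
                f'    labware[{slot}] = module_{slot}.load_labware("{_API_LABWARE[kind]}")'
            )
        else:
            load_lines.append(
                f'    labware[{slot}] = protocol.load_labware("{_API_LABWARE[kind]}", "{slot}")'
            )
        if kind == "tiprack300":
            tiprack_by_size[300].append(f"labware[{slot}]")
        elif kind == "tiprack1000":
            tiprack_by_size[1000].append(f"labware[{slot}]")

    pipette_lines: list[str] = []
    if multi:
        racks = ", ".join(tiprack_by_size[300])
        pipette_lines.append(
            f'    pipettes[300] = protocol.load_instrument("p300_multi_gen2", "left", '
            f"tip_racks=[{racks}])"
        )
    else:
        if 300 in sizes:
            racks = ", ".join(tiprack_by_size[300])
            pipette_lines.append(
                f'    pipettes[300] = protocol.load_instrument("p300_single_gen2", "left", '
                f"tip_racks=[{racks}])"
            )
        if 1000 in sizes:
            racks = ", ".join(tiprack_by_size[1000])
            pipette_lines.append(
                f'    pipettes[1000] = protocol.load_instrument("p1000_single_gen2", "right", '
                f"tip_racks=[{racks}])"
            )

    body = "\n".join(load_lines + pipette_lines)
    return f'''"""Autogenerated liquid-handling protocol ({meta.get("mode", "run")})."""
import json

from opentrons import protocol_api

metadata = {{
    "protocolName": "conjubot {meta.get("mode", "run")}",
    "author": {meta.get("user", "")!r},
    "apiLevel": "2.13",
}}

{_PLAN_BEGIN}
_PLAN_JSON = r"""
{plan_json}
"""
{_PLAN_END}


def run(protocol: protocol_api.ProtocolContext):
    plan = json.loads(_PLAN_JSON)
    labware = {{}}
    pipettes = {{}}
{body}
    current = None
    for step in plan["steps"]:
        kind = step["kind"]
        if kind == "set_temperature":
            protocol.comment(f"set slot {{step['slot']}} to {{step['temperature_c']}} C")
        elif kind == "pause_for_user" or kind == "manual_prompt":
            protocol.pause(step.get("note", ""))
        elif kind == "wait":
            protocol.delay(seconds=step["duration_s"])
        elif kind == "pick_tips":
            current = pipettes[step["tip_size"]] if step["tip_size"] in pipettes else list(pipettes.values())[0]
            current.pick_up_tip()
        elif kind == "drop_tips":
            current.drop_tip()
        elif kind == "aspirate":
            current.aspirate(step["volume_uL"], labware[step["slot"]][step["well"]])
        elif kind == "air_gap":
            current.air_gap(step["volume_uL"])
        elif kind == "dispense":
            current.dispense(step["volume_uL"], labware[step["slot"]][step["well"]])
        elif kind == "mix":
            current.mix(3, step["volume_uL"], labware[step["slot"]][step["well"]])
'''


def parse_protocol_script(text: str) -> StepPlan:
    """Recover the embedded plan from a generated protocol script."""
    m = re.search(
        re.escape(_PLAN_BEGIN) + r'\n_PLAN_JSON = r"""\n(.*?)\n"""\n' + re.escape(_PLAN_END),
        text,
        re.DOTALL,
    )
    if not m:
        raise ArtifactError("parse", "no embedded plan found in script")
    return StepPlan.from_json(m.group(1))


# ---------------------------------------------------------------------------
# run directory

def write_run_directory(
    outdir: str | Path,
    design: ExperimentDesign,
    plan: StepPlan,
    user: str,
    timestamp: str,
    ledger: Ledger | None = None,
) -> list[Path]:
    """Write the full output suite for one run into ``outdir``.

    Files: design.tsv (echo), plan.json, layout.json, bom.csv, bom.xlsx,
    per-plate plate_slotN.csv/.svg, runlog.txt, protocol.py, and — when a
    ledger is supplied — ledger.json and audit.txt.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write(name: str, text: str) -> None:
        path = outdir / name
        path.write_text(text)
        written.append(path)

    _write("design.tsv", render_design_table(design))
    _write("plan.json", plan.to_json())
    _write("layout.json", plan.layout.to_json())
    bom = render_bom(plan, plan.layout, design)
    _write("bom.csv", bom.to_csv())
    bom.to_xlsx(outdir / "bom.xlsx")
    written.append(outdir / "bom.xlsx")

    if plan.metadata.get("mode") == "conjugation":
        from .conjugation import assign_wells
        from .design import expand_pattern

        reactions = expand_pattern(design)
        assignment = assign_wells(reactions)
        labels = [f"{e}+{s}" for e, s in reactions]
        for slot, grid in sorted(assignment_grids(assignment, labels).items(), reverse=True):
            _write(f"plate_slot{slot}.csv", render_plate_map(grid))
            _write(f"plate_slot{slot}.svg", plate_map_svg(grid, title=f"deep-well plate, slot {slot}"))
    else:
        n = plan.metadata.get("design", {}).get("n_samples", 0)
        grid = heatshock_sample_grid(n)
        _write("plate_slot7.csv", render_plate_map(grid))
        _write("plate_slot7.svg", plate_map_svg(grid, title="transformation plate, slot 7"))

    _write("runlog.txt", render_runlog(design, plan, user, timestamp))
    _write("protocol.py", render_protocol_script(plan))
    if ledger is not None:
        _write("ledger.json", ledger.to_json())
        _write("audit.txt", render_audit_report(ledger))
    return written
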