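"""Artifact rendering: BOM, plate maps, run log, protocol script."""

import pytest

from conjubot import (
    ArtifactError,
    DeckLayout,
    assign_wells,
    execute,
    expand_pattern,
    generate_fixture_design,
    plan_conjugation,
    plan_heatshock,
)
from conjubot.artifacts import (
    assignment_from_grids,
    assignment_grids,
    heatshock_sample_grid,
    parse_plate_map,
    parse_protocol_script,
    render_bom,
    render_design_table,
    render_plate_map,
    render_protocol_script,
    render_runlog,
    plate_map_svg,
    write_run_directory,
)
from conjubot.design import parse_design_table
from conjubot.plan import StepPlan


class TestBOM:
    def test_counts_match_executor_pickups(self, small_design, heatshock_design):
        for plan in (
            plan_conjugation(small_design),
            plan_heatshock(heatshock_design, 24),
        ):
            ledger = execute(plan)
            bom = render_bom(plan)
            assert bom.quantity("300 uL tips") == ledger.tip_pickups.get(300, 0)
            assert bom.quantity("1000 uL tips") == ledger.tip_pickups.get(1000, 0)

    def test_96_reaction_run_with_8_sources(self):
        design = generate_fixture_design(seed=3, n_ecoli=8, n_strep=8, n_reactions=96)
        plan = plan_conjugation(design)
        bom = render_bom(plan, design=design)
        used = len({e for e, _ in expand_pattern(design)})
        assert bom.quantity("300 uL tips") == 96
        assert bom.quantity("1000 uL tips") == used
        assert bom.quantity("96-well 2 mL deep-well plate") == 1

    def test_192_reactions_need_two_deepwell_plates(self):
        design = generate_fixture_design(seed=7, n_ecoli=18, n_strep=30, n_reactions=192)
        bom = render_bom(plan_conjugation(design), design=design)
        assert bom.quantity("96-well 2 mL deep-well plate") == 2

    def test_empty_plan_has_zero_counts(self):
        plan = StepPlan(steps=[], layout=DeckLayout(), metadata={})
        bom = render_bom(plan)
        assert all(r.quantity == 0 for r in bom.rows)

    def test_csv_is_deterministic_and_xlsx_written(self, small_design, tmp_path):
        plan = plan_conjugation(small_design)
        bom = render_bom(plan, design=small_design)
        assert bom.to_csv() == render_bom(plan, design=small_design).to_csv()
        bom.to_xlsx(tmp_path / "bom.xlsx")
        assert (tmp_path / "bom.xlsx").stat().st_size > 0


class TestPlateMaps:
    def test_96_reactions_fill_one_plate_only(self):
        asg = assign_wells([("e", "s")] * 96)
        grids = assignment_grids(asg)
        assert set(grids) == {3}
        assert all(c for row in grids[3] for c in row)

    def test_97th_reaction_labels_one_cell_on_slot2(self):
        grids = assignment_grids(assign_wells([("e", "s")] * 97))
        labeled = [c for row in grids[2] for c in row if c]
        assert labeled == ["97"]

    def test_csv_round_trip_recovers_the_assignment(self, small_design):
        reactions = expand_pattern(small_design)
        asg = assign_wells(reactions)
        grids = assignment_grids(asg, [f"{e}+{s}" for e, s in reactions])
        parsed = {s: parse_plate_map(render_plate_map(g)) for s, g in grids.items()}
        assert parsed == grids
        assert assignment_from_grids(parsed) == asg

    def test_svg_mirrors_the_csv_labels(self):
        grid = heatshock_sample_grid(10)
        svg = plate_map_svg(grid, title="samples")
        for row in grid:
            for label in row:
                if label:
                    assert f">{label}<" in svg
        assert svg.count("<rect") == 96


class TestRunlog:
    def test_contains_identity_time_mode_and_all_steps(self, small_design):
        plan = plan_conjugation(small_design, user="casey", timestamp="2026-01-05T10:00:00Z")
        log = render_runlog(small_design, plan, "casey", "2026-01-05T10:00:00Z")
        assert "casey" in log and "2026-01-05T10:00:00Z" in log
        assert "mode: conjugation" in log
        assert f"steps: {len(plan.steps)}" in log
        # one numbered line per step
        assert f"{len(plan.steps):4d}. " in log

    def test_stable_golden_text(self, small_design):
        plan = plan_conjugation(small_design, user="casey", timestamp="t0")
        assert render_runlog(small_design, plan, "casey", "t0") == render_runlog(
            small_design, plan, "casey", "t0"
        )

    def test_missing_user_rejected(self, small_design):
        plan = plan_conjugation(small_design)
        with pytest.raises(ArtifactError):
            render_runlog(small_design, plan, "", "t0")


class TestProtocolScript:
    def test_embedded_plan_round_trips(self, small_design, heatshock_design):
        for plan in (
            plan_conjugation(small_design, user="u", timestamp="t"),
            plan_heatshock(heatshock_design, 8, user="u", timestamp="t"),
        ):
            script = render_protocol_script(plan)
            assert parse_protocol_script(script) == plan

    def test_script_references_only_occupied_slots(self, small_design):
        plan = plan_conjugation(small_design)
        script = render_protocol_script(plan)
        import re

        referenced = {int(m) for m in re.findall(r'load_(?:labware|module)\([^)]*"(\d+)"\)', script)}
        assert referenced <= plan.layout.occupied_slots()

    def test_identical_plans_identical_scripts(self, small_design):
        a = render_protocol_script(plan_conjugation(small_design, user="u", timestamp="t"))
        b = render_protocol_script(plan_conjugation(small_design, user="u", timestamp="t"))
        assert a == b


class TestRunDirectory:
    def test_full_suite_written_and_design_echo_parses(self, small_design, tmp_path):
        plan = plan_conjugation(small_design, user="u", timestamp="t")
        ledger = execute(plan)
        paths = write_run_directory(tmp_path, small_design, plan, "u", "t", ledger=ledger)
        names = {p.name for p in paths}
        assert {"design.tsv", "plan.json", "layout.json", "bom.csv", "bom.xlsx",
                "plate_slot3.csv", "plate_slot3.svg", "runlog.txt", "protocol.py",
                "ledger.json", "audit.txt"} <= names
        echoed = parse_design_table((tmp_path / "design.tsv").read_text())
        assert echoed == small_design


def test_design_tsv_writer_round_trips(small_design, full_design, heatshock_design):
    for d in (small_design, full_design, heatshock_design):
        assert parse_design_table(render_design_table(d)) == d
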