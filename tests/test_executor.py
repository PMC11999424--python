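"""Virtual execution: physical constraints, conservation, contamination audit."""

import copy
import random

import pytest

from conjubot import (
    ExecError,
    execute,
    expand_pattern,
    generate_fixture_design,
    plan_conjugation,
)
from conjubot.conjugation import assign_wells
from conjubot.design import (
    AntibioticSpec,
    EcoliSource,
    ExperimentDesign,
    MixPair,
    MixPattern,
    PlasmidSpec,
    StrepSource,
)
from conjubot.executor import audit_contamination
from conjubot.plan import addr


def brute_force_composition(design):
    """Independent oracle: final deep-well contents straight from the mix pattern."""
    reactions = []
    for pair in design.mix_pattern.pairs:
        reactions += [(pair.ecoli_id, pair.strep_id)] * pair.replicates
    rows = "ABCDEFGH"
    expected = {}
    for i, (e, s) in enumerate(reactions):
        slot = 3 if i < 96 else 2
        j = i % 96
        well = f"{rows[j % 8]}{j // 8 + 1}"
        expected[addr(slot, well)] = {e: 150.0, s: 150.0}
    return expected


def _two_strep_design():
    return ExperimentDesign(
        mode="conjugation",
        antibiotics=(AntibioticSpec("apramycin", 100.0),),
        plasmids=(PlasmidSpec("pA", "apramycin"),),
        ecoli_sources=(EcoliSource("E1", "pA"),),
        strep_sources=(StrepSource("S1"), StrepSource("S2")),
        mix_pattern=MixPattern((MixPair("E1", "S1", 1), MixPair("E1", "S2", 1))),
    )


class TestConstraints:
    def test_deleted_pick_tips_raises_no_tip(self, small_design):
        plan = plan_conjugation(small_design)
        plan.steps = [s for s in plan.steps if s.kind != "pick_tips"]
        with pytest.raises(ExecError) as e:
            execute(plan)
        assert e.value.reason == "no_tip"

    def test_overdraw_below_dead_volume(self, small_design):
        plan = plan_conjugation(small_design)
        first = next(a for a, (v, m) in plan.initial_contents.items() if m.startswith("EC"))
        contents = dict(plan.initial_contents)
        vol, mat = contents[first]
        contents[first] = (vol - 200.0, mat)  # 200 uL short of the requirement
        with pytest.raises(ExecError) as e:
            execute(plan, initial_contents=contents)
        assert e.value.reason == "overdraw"

    def test_overflow_above_well_capacity(self, small_design):
        plan = plan_conjugation(small_design)
        # a deep-well well already near capacity overflows on the first dispense
        dest = next(
            addr(s.slot, s.well) for s in plan.steps if s.kind == "dispense" and s.slot == 3
        )
        contents = dict(plan.initial_contents)
        contents[dest] = (1950.0, "water")
        with pytest.raises(ExecError) as e:
            execute(plan, initial_contents=contents)
        assert e.value.reason == "overflow"

    def test_tip_capacity_enforced(self, small_design):
        bad = copy.deepcopy(plan_conjugation(small_design))
        for s in bad.steps:
            if s.kind == "aspirate" and s.volume_uL == 150.0:
                s.volume_uL = 400.0  # exceeds the 300 uL spore tip
                break
        with pytest.raises(ExecError) as e:
            execute(bad)
        assert e.value.reason in ("tip_capacity", "overdraw")

    def test_execute_is_deterministic_and_pure(self, small_design):
        plan = plan_conjugation(small_design)
        snapshot = plan.to_json()
        a = execute(plan)
        b = execute(plan)
        assert a.to_json() == b.to_json()
        assert plan.to_json() == snapshot


class TestAudit:
    def test_generated_plan_is_clean(self, small_design):
        ledger = execute(plan_conjugation(small_design))
        assert audit_contamination(ledger) == []

    def test_reusing_a_spore_tip_across_sources_is_one_violation(self):
        plan = plan_conjugation(_two_strep_design())
        # find the spore-phase blocks: pick/aspirate/dispense/drop per reaction
        drops = [i for i, s in enumerate(plan.steps)
                 if s.kind == "drop_tips" and s.tip_size == 300]
        picks = [i for i, s in enumerate(plan.steps)
                 if s.kind == "pick_tips" and s.tip_size == 300]
        # remove the tip change between reaction 1 (S1) and reaction 2 (S2)
        plan.steps = [s for i, s in enumerate(plan.steps) if i not in (drops[0], picks[1])]
        ledger = execute(plan)
        assert len(ledger.violations) == 1
        assert "S2" in ledger.violations[0]["address"] or ledger.violations[0]["foreign"]

    def test_media_predispense_tips_reused_for_donor_are_clean(self):
        plan = plan_conjugation(_two_strep_design(), enable_media_predispense=True)
        ledger = execute(plan)
        assert ledger.violations == []


class TestPropertySweep:
    def test_random_designs_plan_execute_audit_clean(self):
        """Seeded sweep: planner output always executes cleanly and matches the
        brute-force recomputation of well composition from the mix pattern."""
        rng = random.Random(20260901)
        for _ in range(25):
            design = generate_fixture_design(
                rng.randrange(2**31),
                n_ecoli=rng.randint(1, 18),
                n_strep=rng.randint(1, 30),
                n_reactions=rng.randint(1, 192),
            )
            plan = plan_conjugation(design)
            ledger = execute(plan)
            assert ledger.violations == []
            assert ledger.conservation_residual_uL <= 1e-9
            expected = brute_force_composition(design)
            got = {
                a: {m: v for m, v in w.materials.items() if v > 1e-9}
                for a, w in ledger.final_wells.items()
                if (a.startswith("slot3:") or a.startswith("slot2:")) and w.volume_uL > 1e-9
            }
            assert got.keys() == expected.keys()
            for a in expected:
                assert got[a] == pytest.approx(expected[a])

    def test_unassigned_wells_never_receive_liquid(self, small_design):
        ledger = execute(plan_conjugation(small_design))
        reactions = expand_pattern(small_design)
        assigned = {addr(s, w) for s, w in assign_wells(reactions).entries}
        plate_wells = {a for a in ledger.final_wells
                       if a.startswith("slot3:") or a.startswith("slot2:")}
        for a in plate_wells - assigned:
            assert ledger.final_wells[a].volume_uL <= 1e-9
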