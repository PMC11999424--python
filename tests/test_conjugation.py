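"""Conjugation planner: well assignment, batching, media accounting."""

import pytest

from conjubot import (
    PlanError,
    assign_wells,
    check_source_volumes,
    execute,
    expand_pattern,
    generate_fixture_design,
    media_requirement,
    plan_conjugation,
)
from conjubot.conjugation import BATCH_SIZE, OVERAGE, VOL_ECOLI
from conjubot.design import (
    AntibioticSpec,
    EcoliSource,
    ExperimentDesign,
    MixPair,
    MixPattern,
    PlasmidSpec,
    StrepSource,
    with_fills,
)


def _design(n_strep=1, reps=12, fills=None):
    d = ExperimentDesign(
        mode="conjugation",
        antibiotics=(AntibioticSpec("apramycin", 100.0),),
        plasmids=(PlasmidSpec("pA", "apramycin"),),
        ecoli_sources=(EcoliSource("E1", "pA"),),
        strep_sources=tuple(StrepSource(f"S{j+1}") for j in range(n_strep)),
        mix_pattern=MixPattern(tuple(
            MixPair("E1", f"S{j+1}", reps) for j in range(n_strep)
        )),
    )
    return with_fills(d, fills) if fills else d


class TestAssignWells:
    def test_first_reaction_lands_at_slot3_A1(self):
        assert assign_wells([("e", "s")])[0] == (3, "A1")

    def test_reaction_97_starts_the_slot2_plate(self):
        asg = assign_wells([("e", "s")] * 97)
        assert asg[95] == (3, "H12")
        assert asg[96] == (2, "A1")

    def test_column_major_order(self):
        asg = assign_wells([("e", "s")] * 10)
        assert [w for _, w in asg.entries[:9]] == [
            "A1", "B1", "C1", "D1", "E1", "F1", "G1", "H1", "A2"
        ]

    def test_capacity_and_empty(self):
        with pytest.raises(PlanError) as e:
            assign_wells([("e", "s")] * 193)
        assert e.value.reason == "capacity"
        with pytest.raises(PlanError) as e:
            assign_wells([])
        assert e.value.reason == "empty"


class TestPlanConjugation:
    def test_12_wells_from_one_source_use_two_aspirations_and_one_tip(self):
        plan = plan_conjugation(_design(reps=12))
        tube_asp = [s for s in plan.steps
                    if s.kind == "aspirate" and s.slot == 4]
        assert len(tube_asp) == 2
        assert all(a.volume_uL == BATCH_SIZE * VOL_ECOLI + OVERAGE for a in tube_asp)
        picks_1000 = [s for s in plan.steps if s.kind == "pick_tips" and s.tip_size == 1000]
        assert len(picks_1000) == 1

    def test_tip_lifecycle_96_reactions_8_sources(self):
        design = generate_fixture_design(seed=3, n_ecoli=8, n_strep=8, n_reactions=96)
        ledger = execute(plan_conjugation(design))
        used_sources = len({e for e, _ in expand_pattern(design)})
        assert ledger.tip_pickups[1000] == used_sources
        assert ledger.tip_pickups[300] == 96

    def test_every_assigned_well_ends_at_300_uL(self, small_design):
        ledger = execute(plan_conjugation(small_design))
        vols = [w.volume_uL for a, w in ledger.final_wells.items()
                if a.startswith("slot3:") and w.volume_uL > 1e-9]
        assert len(vols) == len(expand_pattern(small_design))
        assert all(v == pytest.approx(300.0, abs=1e-9) for v in vols)

    def test_batches_never_exceed_six_and_last_is_remainder(self):
        plan = plan_conjugation(_design(reps=8))  # 8 wells -> 6 + 2
        tube_asp = [s.volume_uL for s in plan.steps
                    if s.kind == "aspirate" and s.slot == 4]
        assert tube_asp == [6 * VOL_ECOLI + OVERAGE, 2 * VOL_ECOLI + OVERAGE]

    def test_plan_is_deterministic(self, small_design):
        a = plan_conjugation(small_design, user="u", timestamp="t").to_json()
        b = plan_conjugation(small_design, user="u", timestamp="t").to_json()
        assert a == b

    def test_insufficient_fill_names_the_tube(self):
        with pytest.raises(PlanError) as e:
            plan_conjugation(_design(reps=12, fills={"S1": 1000.0}))
        assert e.value.reason == "volume"
        assert "S1" in str(e.value)

    def test_media_predispense_adds_sterile_phase_reusing_donor_tip(self):
        plan = plan_conjugation(_design(reps=12), enable_media_predispense=True)
        ledger = execute(plan)
        assert ledger.violations == []
        # wells now hold media + donor + spores
        vols = [w.volume_uL for a, w in ledger.final_wells.items()
                if a.startswith("slot3:") and w.volume_uL > 1e-9]
        assert all(v == pytest.approx(450.0) for v in vols)
        # still one 1000 uL tip per donor source (reused across media + donor)
        assert ledger.tip_pickups[1000] == 1


class TestMediaRequirement:
    def test_single_strain_needs_60_mL_LB(self):
        report = media_requirement(_design())
        assert report.lb_per_ecoli_mL == 60.0
        assert report.lb_total_mL == 60.0

    def test_no_strains_no_LB(self):
        design = ExperimentDesign(
            mode="conjugation",
            antibiotics=(AntibioticSpec("apramycin", 100.0),),
            strep_sources=(StrepSource("S1"),),
        )
        assert media_requirement(design).lb_total_mL == 0.0

    def test_18_strains_need_1080_mL(self, full_design):
        assert media_requirement(full_design).lb_total_mL == 1080.0

    def test_2xYT_per_tube_includes_dead_volume(self):
        report = media_requirement(_design(reps=12))
        assert report.per_tube_min_uL["S1"] == 12 * 150.0 + 100.0


class TestCheckSourceVolumes:
    def test_2_mL_covers_12_wells(self):
        assert check_source_volumes(_design(reps=12, fills={"S1": 2000.0})) == []

    def test_1_mL_cannot_cover_12_wells(self):
        issues = check_source_volumes(_design(reps=12, fills={"S1": 1000.0}))
        assert len(issues) == 1 and "S1" in issues[0]

    def test_design_without_pattern_yields_no_issues(self):
        design = ExperimentDesign(
            mode="conjugation",
            antibiotics=(AntibioticSpec("apramycin", 100.0),),
            strep_sources=(StrepSource("S1", fill_uL=1.0),),
        )
        assert check_source_volumes(design) == []
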