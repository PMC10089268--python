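"""Weekly flag assessment, mission selection with the red-history tie-break,
plan generation, validation, points and motivation."""

import itertools

import pytest

import habitcoach as hc
from habitcoach.coaching import (
    DEFAULT_AGENT_REPORT_ITEMS,
    Behaviour,
    Catalogue,
    Mission,
    MissionMode,
    OutcomeStatus,
    Validator,
)
from habitcoach.types import (
    Ability,
    Dimension,
    FlagHistory,
    FlagStatus,
    Instrument,
    QuestionnaireResponse,
)

G, Y, R = FlagStatus.green, FlagStatus.yellow, FlagStatus.red
PA = Dimension.physical_activity_sleep


def pa_rule(var):
    return hc.StratificationRule(
        variable_id=var, direction="lower_is_worse",
        green_yellow_cutoff=60, yellow_red_cutoff=30,
    )


def make_dimension(n_behaviours, example_numbering=False):
    """One dimension with behaviours P1..Pn and one mission each.

    Default numbering: mission i targets Pi. The alternative mirrors the
    worked example catalogue, where mission 1 targets P2 (the 'Increase active
    minutes' behaviour singled out there).
    """
    behaviours = [
        Behaviour(
            behaviour_id=f"P{i}", label=f"behaviour {i}", dimension=PA,
            source_variables=[f"v{i}"], rule=pa_rule(f"v{i}"),
        )
        for i in range(1, n_behaviours + 1)
    ]
    targets = [f"P{i}" for i in range(1, n_behaviours + 1)]
    if example_numbering and n_behaviours >= 2:
        targets[0], targets[1] = "P2", "P1"
    missions = [
        Mission(mission_id=i, dimension=PA, target_behaviour_id=t,
                points=10, ability=Ability.dexterity)
        for i, t in enumerate(targets, start=1)
    ]
    return Catalogue(missions=missions, behaviours=behaviours)


def history(behaviour_id, flags):
    weeks = [f"2026-W{10 + i:02d}" for i in range(len(flags))]
    return FlagHistory(behaviour_id, weeks, list(flags))


def brute_force_select(flags, histories, order):
    """Independent restatement of the selection rule: most severe current
    flag, then longest red run ending now, then configured order."""
    def red_run(b):
        if flags[b] is not R:
            return 0
        run = 1
        for f in reversed(histories.get(b, history(b, [])).flags):
            if f is not R:
                break
            run += 1
        return run

    ranked = sorted(
        order, key=lambda b: (-int(flags[b]), -red_run(b), order.index(b))
    )
    return ranked[0]


# --- mission selection --------------------------------------------------

def test_worked_example_most_recent_red_run_wins():
    """P2 red for the three most recent weeks beats behaviours whose red
    flags are older; the selected mission targets P2."""
    cat = make_dimension(4)
    flags = {"P1": Y, "P2": R, "P3": Y, "P4": G}
    hists = {
        "P1": history("P1", [R, Y, Y]),  # red exists, but older
        "P2": history("P2", [Y, R, R]),  # red in T_N-1, T_N-2 (and now)
        "P3": history("P3", [Y, Y, Y]),
    }
    mission = hc.select_mission_for_dimension(flags, hists, cat, PA)
    assert mission.target_behaviour_id == "P2"
    assert mission.mission_id == 2  # catalogue numbered mission i -> Pi
    # in the worked example's own numbering the same selection is mission 1
    alt = make_dimension(4, example_numbering=True)
    assert hc.select_mission_for_dimension(flags, hists, alt, PA).mission_id == 1


def test_red_run_tie_break_among_equal_flags():
    cat = make_dimension(3)
    flags = {"P1": R, "P2": R, "P3": Y}
    hists = {
        "P1": history("P1", [R, Y, R]),  # run of 2 ending now (incl. current)
        "P2": history("P2", [R, R, R]),  # run of 4 ending now
    }
    assert hc.select_mission_for_dimension(flags, hists, cat, PA).target_behaviour_id == "P2"


def test_single_red_behaviour_is_prioritised():
    cat = make_dimension(3)
    flags = {"P1": G, "P2": G, "P3": R}
    assert hc.select_mission_for_dimension(flags, {}, cat, PA).target_behaviour_id == "P3"


def test_all_green_selects_first_behaviour_as_maintenance():
    cat = make_dimension(3)
    flags = {"P1": G, "P2": G, "P3": G}
    assert hc.select_mission_for_dimension(flags, {}, cat, PA).target_behaviour_id == "P1"


def test_selection_matches_bruteforce_exhaustively_3x3():
    """Full enumeration: 3 behaviours, every current-flag assignment and
    every 3-week history combination, against the independent rule."""
    cat = make_dimension(3)
    order = ["P1", "P2", "P3"]
    all_hists = list(itertools.product([G, Y, R], repeat=3))
    for current in itertools.product([G, Y, R], repeat=3):
        flags = dict(zip(order, current))
        for h1, h2 in itertools.product(all_hists, repeat=2):
            hists = {"P1": history("P1", h1), "P2": history("P2", h2)}
            got = hc.select_mission_for_dimension(flags, hists, cat, PA)
            assert got.target_behaviour_id == brute_force_select(flags, hists, order)


def test_red_priority_soundness_sampled(rng):
    """Whenever some behaviour is red, the selected mission targets a red one."""
    cat = make_dimension(4)
    order = [f"P{i}" for i in range(1, 5)]
    levels = [G, Y, R]
    for _ in range(300):
        flags = {b: levels[rng.integers(3)] for b in order}
        hists = {
            b: history(b, [levels[rng.integers(3)] for _ in range(int(rng.integers(0, 5)))])
            for b in order
        }
        chosen = hc.select_mission_for_dimension(flags, hists, cat, PA)
        if R in flags.values():
            assert flags[chosen.target_behaviour_id] is R


def test_selection_requires_missions_for_dimension(catalogue):
    with pytest.raises(ValueError):
        hc.select_mission_for_dimension({"P1": G}, {}, catalogue, Dimension.diet)


# --- weekly assessment --------------------------------------------------

def ffq(child, items):
    return QuestionnaireResponse(child, "2026-W02", Instrument.ffq, tuple(items))


def test_all_green_inputs_give_all_green_flags(engine_config):
    wearable = {"steps": 11000, "active_minutes": 70, "sleep_minutes": 560}
    reports = [
        ffq("c1", [("fruit_freq", "daily"), ("vegetables_freq", "2+/day"),
                   ("sweets_freq", "never")]),
        QuestionnaireResponse("c1", "2026-W02", Instrument.paqc,
                              tuple((f"pq{i}", 4) for i in range(1, 10))),
        QuestionnaireResponse("c1", "2026-W02", Instrument.agent_report,
                              tuple((f"ar{i}", 1) for i in range(1, 7))),
    ]
    flags = hc.assess_weekly_flags(reports, wearable, engine_config.behaviours)
    assert set(flags.values()) == {G}
    assert len(flags) == len(engine_config.behaviours)


def test_red_sweets_flags_the_diet_behaviour(engine_config):
    reports = [ffq("c1", [("sweets_freq", "daily")])]
    flags = hc.assess_weekly_flags(reports, {}, engine_config.behaviours)
    assert flags["P7"] is R


def test_missing_data_policy_yellow_with_warning(engine_config, caplog):
    with caplog.at_level("WARNING"):
        flags = hc.assess_weekly_flags([], {}, engine_config.behaviours)
    assert set(flags.values()) == {Y}
    assert any("missing-data policy" in m for m in caplog.messages)


def test_missing_data_strict_policy_raises(engine_config):
    with pytest.raises(ValueError):
        hc.assess_weekly_flags([], {}, engine_config.behaviours, missing_policy="strict")


def test_multi_variable_behaviour_takes_worst_flag():
    b = Behaviour(
        behaviour_id="B", label="combo", dimension=PA,
        source_variables=["v1", "v2"], rule=pa_rule("ignored"),
    )
    flags = hc.assess_weekly_flags([], {"v1": 80.0, "v2": 10.0}, [b])
    assert flags["B"] is R


# --- plan generation ----------------------------------------------------

def test_plan_has_three_missions_one_per_dimension(catalogue):
    flags = {b.behaviour_id: Y for b in catalogue.behaviours}
    plan = hc.generate_coaching_plan("c1", "2026-W02", flags, {}, catalogue)
    assert len(plan.missions) == 3
    assert {m.dimension for m in plan.missions} == set(Dimension)
    assert plan.week_id == "2026-W03"  # applies to the following week


def test_plan_is_deterministic(catalogue):
    flags = {b.behaviour_id: R for b in catalogue.behaviours}
    p1 = hc.generate_coaching_plan("c1", "2026-W02", flags, {}, catalogue)
    p2 = hc.generate_coaching_plan("c1", "2026-W02", flags, {}, catalogue)
    assert p1 == p2


def test_all_green_child_gets_maintenance_plan(catalogue):
    flags = {b.behaviour_id: G for b in catalogue.behaviours}
    plan = hc.generate_coaching_plan("c1", "2026-W52", flags, {}, catalogue)
    first = {d: catalogue.behaviour_order(d)[0] for d in Dimension}
    for mission in plan.missions:
        assert mission.target_behaviour_id == first[mission.dimension]
    assert plan.week_id == "2026-W53"  # 2026 is a 53-week ISO year
    assert hc.next_iso_week("2026-W53") == "2027-W01"  # year rollover


def test_catalogue_rejects_cross_dimension_missions():
    b = Behaviour(behaviour_id="P1", label="x", dimension=PA,
                  source_variables=["v"], rule=pa_rule("v"))
    m = Mission(mission_id=1, dimension=Dimension.diet, target_behaviour_id="P1")
    with pytest.raises(ValueError):
        Catalogue(missions=[m], behaviours=[b])


# --- validation, points, motivation -------------------------------------

@pytest.fixture()
def plan(catalogue):
    flags = {b.behaviour_id: Y for b in catalogue.behaviours}
    return hc.generate_coaching_plan("c1", "2026-W02", flags, {}, catalogue)


def test_carer_feedback_sets_outcome(plan):
    mid = plan.missions[0].mission_id
    fb = hc.CarerFeedback(mid, "c1", plan.week_id, True, Validator.family)
    out = hc.validate_mission(fb, plan)
    assert out.status is OutcomeStatus.completed
    out2 = hc.validate_mission(
        hc.CarerFeedback(mid, "c1", plan.week_id, False, Validator.educator), plan
    )
    assert out2.status is OutcomeStatus.not_completed


def test_feedback_for_unassigned_mission_is_rejected(plan):
    fb = hc.CarerFeedback(999, "c1", plan.week_id, True, Validator.family)
    with pytest.raises(ValueError):
        hc.validate_mission(fb, plan)


def test_unreported_missions_pend_then_expire(plan):
    pending = hc.resolve_outcomes(plan, [], deadline_passed=False)
    assert all(o.status is OutcomeStatus.pending for o in pending)
    expired = hc.resolve_outcomes(plan, [], deadline_passed=True)
    assert all(o.status is OutcomeStatus.not_completed for o in expired)


def test_conflicting_reports_resolved_educator_over_family(plan, caplog):
    mid = plan.missions[0].mission_id
    fb = [
        hc.CarerFeedback(mid, "c1", plan.week_id, True, Validator.family),
        hc.CarerFeedback(mid, "c1", plan.week_id, False, Validator.educator),
    ]
    with caplog.at_level("WARNING"):
        outcomes = hc.resolve_outcomes(plan, fb)
    by_id = {o.mission_id: o for o in outcomes}
    assert by_id[mid].status is OutcomeStatus.not_completed
    assert by_id[mid].validated_by is Validator.educator


def outcome(mission_id, status=OutcomeStatus.completed):
    return hc.MissionOutcome(mission_id, "c1", "2026-W03", status, Validator.educator)


def test_points_zero_when_nothing_completed(catalogue):
    ledger = hc.award_points([outcome(1, OutcomeStatus.not_completed)], catalogue)
    assert ledger.total == 0
    assert all(v == 0.0 for v in ledger.ability_pct.values())


def test_points_single_completed_mission(catalogue):
    # mission 3 is a 10-point discipline mission in the default catalogue
    ledger = hc.award_points([outcome(3)], catalogue)
    assert ledger.total == 10
    assert ledger.ability_pct[Ability.discipline] == 100.0


def test_points_split_across_abilities():
    behaviours = [
        Behaviour(behaviour_id="P1", label="a", dimension=PA,
                  source_variables=["v"], rule=pa_rule("v")),
        Behaviour(behaviour_id="P2", label="b", dimension=Dimension.education_empowerment,
                  source_variables=["w"], rule=pa_rule("w")),
    ]
    cat = Catalogue(
        missions=[
            Mission(mission_id=1, dimension=PA, target_behaviour_id="P1",
                    points=10, ability=Ability.dexterity),
            Mission(mission_id=2, dimension=Dimension.education_empowerment,
                    target_behaviour_id="P2", points=30, ability=Ability.intelligence),
        ],
        behaviours=behaviours,
    )
    ledger = hc.award_points([outcome(1), outcome(2)], cat)
    assert ledger.total == 40
    assert ledger.ability_pct[Ability.dexterity] == pytest.approx(25.0)
    assert ledger.ability_pct[Ability.discipline] == pytest.approx(0.0)
    assert ledger.ability_pct[Ability.intelligence] == pytest.approx(75.0)
    assert sum(ledger.ability_pct.values()) == pytest.approx(100.0)


def test_points_conserve_catalogue_totals(catalogue, rng):
    outcomes = [
        outcome(m.mission_id,
                OutcomeStatus.completed if rng.random() < 0.5 else OutcomeStatus.not_completed)
        for m in catalogue.missions
    ]
    ledger = hc.award_points(outcomes, catalogue)
    expected = sum(
        m.points for m, o in zip(catalogue.missions, outcomes)
        if o.status is OutcomeStatus.completed
    )
    assert ledger.total == expected
    if expected:
        assert sum(ledger.ability_pct.values()) == pytest.approx(100.0)


def test_motivation_silent_when_all_missions_progress(plan):
    progress = {m.mission_id: True for m in plan.missions}
    assert hc.trigger_motivation(plan, progress) == []


def test_motivation_messages_for_stalled_and_risky(plan):
    progress = {m.mission_id: True for m in plan.missions}
    progress[plan.missions[0].mission_id] = False
    risk = hc.RiskDetectionResult(
        child_id="c1", variable_id="steps", segments=[], classes=[],
        verdict=hc.Verdict.unhealthy_trend_confirmed_by_forecast,
    )
    messages = hc.trigger_motivation(plan, progress, [risk])
    kinds = sorted(m.kind for m in messages)
    assert kinds == ["risk_alert", "stalled_mission"]
    assert messages[0].mission_id == plan.missions[0].mission_id
    # idempotent within the week
    assert hc.trigger_motivation(plan, progress, [risk]) == messages


# --- agent report -------------------------------------------------------

def test_agent_report_template_has_six_unique_items():
    template = hc.build_agent_report("c1", "2026-W02")
    assert len(template.items) == 6
    assert len(set(template.item_ids)) == 6
    assert template.instrument is Instrument.agent_report
    assert hc.build_agent_report("c1", "2026-W02") == template


def test_agent_report_rejects_wrong_item_count_in_strict_mode():
    items = DEFAULT_AGENT_REPORT_ITEMS[:5]
    with pytest.raises(ValueError):
        hc.build_agent_report("c1", "2026-W02", items=items)
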