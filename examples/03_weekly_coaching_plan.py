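"""Generate one child's weekly coaching plan from self-reports and wearables.

Assesses traffic-light flags for every configured behaviour, then selects
one mission per dimension (red behaviours first, ties broken by the most
recent run of red weeks), validates carer feedback and awards points.
"""

import habitcoach as hc
from habitcoach.coaching import Validator
from habitcoach.types import FlagHistory, FlagStatus, Instrument, QuestionnaireResponse

cfg = hc.load_config()
catalogue = cfg.catalogue()

wearables = {"steps": 5200, "active_minutes": 25, "sleep_minutes": 545}
reports = [
    QuestionnaireResponse("nina", "2026-W09", Instrument.ffq,
                          (("fruit_freq", "2-3/week"), ("vegetables_freq", "daily"),
                           ("sweets_freq", "daily"))),
    QuestionnaireResponse("nina", "2026-W09", Instrument.paqc,
                          tuple((f"pq{i}", v) for i, v in enumerate([2, 3, 2, 2, 3, 2, 1, 2, 3], 1))),
    QuestionnaireResponse("nina", "2026-W09", Instrument.agent_report,
                          tuple((f"ar{i}", v) for i, v in enumerate([1, 1, 0, 0, 1, 1], 1))),
]

flags = hc.assess_weekly_flags(reports, wearables, cfg.behaviours, cfg.ffq_mapping)
print("flags:", {b: str(f) for b, f in flags.items()})

# P2 (active minutes) has been red for two previous weeks as well
histories = {"P2": FlagHistory("P2", ["2026-W07", "2026-W08"],
                               [FlagStatus.red, FlagStatus.red])}
plan = hc.generate_coaching_plan("nina", "2026-W09", flags, histories, catalogue)
print(f"plan for {plan.week_id}:")
for m in plan.missions:
    print(f"  mission {m.mission_id} [{m.dimension.value}] -> {m.target_behaviour_id}: "
          f"{m.description} ({m.points} pts, {m.ability.value})")

feedback = [hc.CarerFeedback(m.mission_id, "nina", plan.week_id, True, Validator.educator)
            for m in plan.missions[:2]]
outcomes = hc.resolve_outcomes(plan, feedback, deadline_passed=True)
ledger = hc.award_points(outcomes, catalogue)
print(f"completed {sum(o.status.value == 'completed' for o in outcomes)}/3 missions, "
      f"{ledger.total} points; ability split "
      + ", ".join(f"{a.value} {p:.0f}%" for a, p in ledger.ability_pct.items()))
# One mission per dimension: the red active-minutes behaviour wins the
# physical-activity slot via the red-history tie-break.
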