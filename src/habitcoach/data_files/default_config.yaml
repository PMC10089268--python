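# Default engine configuration.
#
# Stratification cut-offs are programme-editable placeholders informed by
# common school-age guidance (60 min/day of activity, ~9 h sleep, daily
# fruit and vegetables, limited sweets); real deployments calibrate them
# against their own baseline evaluation.

seed: 0
lms_table: null        # null -> bundled synthetic reference table

policies:
  missing_data: yellow          # or "strict"
  validation_deadline_weeks: 1  # feedback window after the plan week

ffq_mapping:
  never: 0
  "<1/week": 0.5
  "1/week": 1
  "2-3/week": 2.5
  "4-6/week": 5
  daily: 7
  "2+/day": 14

behaviours:
  - behaviour_id: P1
    label: Increase daily steps
    dimension: physical_activity_sleep
    source_variables: [steps]
    rule: {variable_id: steps, direction: lower_is_worse,
           green_yellow_cutoff: 9000, yellow_red_cutoff: 6000, units: steps/day}
  - behaviour_id: P2
    label: Increase active minutes
    dimension: physical_activity_sleep
    source_variables: [active_minutes]
    rule: {variable_id: active_minutes, direction: lower_is_worse,
           green_yellow_cutoff: 60, yellow_red_cutoff: 30, units: min/day}
  - behaviour_id: P3
    label: Increase sleep duration
    dimension: physical_activity_sleep
    source_variables: [sleep_minutes]
    rule: {variable_id: sleep_minutes, direction: lower_is_worse,
           green_yellow_cutoff: 540, yellow_red_cutoff: 480, units: min/night}
  - behaviour_id: P4
    label: Increase overall physical activity (PAQ-C)
    dimension: physical_activity_sleep
    source_variables: [paqc_score]
    rule: {variable_id: paqc_score, direction: lower_is_worse,
           green_yellow_cutoff: 3.5, yellow_red_cutoff: 2.5, units: score}
  - behaviour_id: P5
    label: Increase fruit consumption
    dimension: diet
    source_variables: [fruit_freq]
    rule: {variable_id: fruit_freq, direction: lower_is_worse,
           green_yellow_cutoff: 7, yellow_red_cutoff: 2, units: servings/week}
  - behaviour_id: P6
    label: Increase vegetable consumption
    dimension: diet
    source_variables: [vegetables_freq]
    rule: {variable_id: vegetables_freq, direction: lower_is_worse,
           green_yellow_cutoff: 7, yellow_red_cutoff: 2, units: servings/week}
  - behaviour_id: P7
    label: Reduce sweets and sugary snacks
    dimension: diet
    source_variables: [sweets_freq]
    rule: {variable_id: sweets_freq, direction: higher_is_worse,
           green_yellow_cutoff: 2, yellow_red_cutoff: 5, units: servings/week}
  - behaviour_id: P8
    label: Keep up the weekly agent report habits
    dimension: education_empowerment
    source_variables: [agent_report_score]
    rule: {variable_id: agent_report_score, direction: lower_is_worse,
           green_yellow_cutoff: 5, yellow_red_cutoff: 3, units: healthy answers}

# Ability mapping default: physical activity -> dexterity, diet -> discipline,
# education & empowerment -> intelligence.
missions:
  - {mission_id: 1, dimension: physical_activity_sleep, target_behaviour_id: P1,
     description: "Walk 1000 extra steps every day this week", mode: individual,
     points: 10, ability: dexterity}
  - {mission_id: 2, dimension: physical_activity_sleep, target_behaviour_id: P2,
     description: "Play actively for one hour after school", mode: social,
     points: 10, ability: dexterity}
  - {mission_id: 3, dimension: physical_activity_sleep, target_behaviour_id: P3,
     description: "Lights out by 21:30 every school night", mode: individual,
     points: 10, ability: discipline}
  - {mission_id: 4, dimension: physical_activity_sleep, target_behaviour_id: P4,
     description: "Try a new sport or game with friends", mode: social,
     points: 20, ability: dexterity}
  - {mission_id: 5, dimension: diet, target_behaviour_id: P5,
     description: "Eat a piece of fruit with every breakfast", mode: individual,
     points: 10, ability: discipline}
  - {mission_id: 6, dimension: diet, target_behaviour_id: P6,
     description: "Help cook a vegetable dish with your family", mode: social,
     points: 20, ability: discipline}
  - {mission_id: 7, dimension: diet, target_behaviour_id: P7,
     description: "Swap the afternoon sweet for a healthy snack", mode: individual,
     points: 10, ability: discipline}
  - {mission_id: 8, dimension: education_empowerment, target_behaviour_id: P8,
     description: "Fill in your agent report and learn one new healthy fact", mode: individual,
     points: 10, ability: intelligence}

detector:
  steps:
    {period: 7, max_segments: 3, min_slope: 100, max_slope: 2000,
     harm_direction: descending_is_harmful, horizon: 7, max_gap: 2}
  active_minutes:
    {period: 7, max_segments: 3, min_slope: 2, max_slope: 60,
     harm_direction: descending_is_harmful, horizon: 7, max_gap: 2}
  sleep_minutes:
    {period: 7, max_segments: 3, min_slope: 5, max_slope: 120,
     harm_direction: descending_is_harmful, horizon: 7, max_gap: 2}

agent_report_items:
  - [ar1, "Did you eat fruit every day this week?"]
  - [ar2, "Did you eat vegetables every day this week?"]
  - [ar3, "Did you avoid sugary drinks and sweets most days?"]
  - [ar4, "Were you active for at least one hour most days?"]
  - [ar5, "Did you play outside or do sport with friends or family?"]
  - [ar6, "Did you go to bed on time most nights?"]
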