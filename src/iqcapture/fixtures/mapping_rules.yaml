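# Intelligent Quotation configuration binding the preadmission questionnaire
# to the patient-profile template.  Implements all five rule kinds; rules
# target fields in 20 sections spread over 5 of the 11 functional health
# patterns (health perception/management, nutrition/metabolism, elimination,
# activity/exercise, cognition/perception).
rules:
  # ---- health perception / health management ----
  - kind: term_map
    source: q11
    target: s_hp_alcohol.drinking_habit
    mapping:
      I drink: Drinks
      I don't drink: Does not drink
  - kind: quote
    source: q11a
    target: s_hp_alcohol.drinking_frequency
  - kind: calculate
    calc: pure_alcohol
    sources: {volume: q11c, cans: q11d}
    target: s_hp_alcohol.pure_alcohol_g
    parameters: {alcohol_fraction: 0.05}
  - kind: calculate
    calc: alcohol_units
    sources: {volume: q11c, cans: q11d}
    target: s_hp_alcohol.alcohol_units
    parameters: {alcohol_fraction: 0.05, grams_per_unit: 20}
  - kind: term_map
    source: q12
    target: s_hp_smoking.smoking_status
    mapping:
      I have never smoked: Never smoked
      I used to smoke but quit: Ex-smoker
      I currently smoke: Current smoker
  - kind: calculate
    calc: smoking_duration
    sources: {status: q12, start_age: q12a, quit_age: q12b}
    target: s_hp_smoking.smoking_duration_years
  - kind: quote
    source: q12d
    target: s_hp_smoking.cigarettes_per_day
  - kind: quote
    source: q10b
    target: s_hp_restriction_compliance.follows_restriction
  - kind: quote
    source: q03d
    target: s_hp_falls.fall_history

  # ---- nutrition / metabolism ----
  - kind: quote
    source: q10
    target: s_nu_diet_restriction.restrictions
  - kind: interview_stub
    source: q10
    stubs:
      Calorie restriction: s_nu_diet_restriction.calorie_detail
      Protein restriction: s_nu_diet_restriction.protein_detail
      Salt restriction: s_nu_diet_restriction.salt_detail
      Fat restriction: s_nu_diet_restriction.fat_detail
      Other restriction: s_nu_diet_restriction.other_detail
  - kind: term_map
    source: q09
    target: s_nu_weight_change.weight_change
    mapping:
      I gained weight: Gained
      I lost weight: Lost
      No change: No change
  - kind: quote
    source: q09a
    target: s_nu_weight_change.weight_change_kg
  - kind: quote
    source: q09b
    target: s_nu_weight_change.weight_change_months
  - kind: term_map
    source: q07
    target: s_nu_appetite.appetite
    mapping:
      Good: Good
      Somewhat poor: Slightly decreased
      Poor: Decreased
  - kind: quote
    source: q07a
    target: s_nu_appetite.intake_amount
  - kind: quote
    source: q07b
    target: s_nu_swallowing.dysphagia
  - kind: aggregate
    sources: [q13, q13a]
    target: s_nu_dentures.dentures
    combine:
      - match: {q13: "No"}
        value: None
      - match: {q13a: Partial denture}
        value: Partial denture
      - match: {q13a: Full denture}
        value: Full denture

  # ---- elimination ----
  - kind: term_map
    source: q06
    target: s_el_toileting.toileting_ability
    mapping:
      I can do it myself: Independent
      I can do it with someone's assistance: Needs help
      I cannot do it myself: Unable
  - kind: quote
    source: q06b
    target: s_el_aids.elimination_aids
  - kind: quote
    source: q06a
    target: s_el_toilet_help.help_detail

  # ---- activity / exercise ----
  - kind: aggregate
    sources: [q03, q03b]
    target: s_ac_walking.mobility
    comment_field: s_ac_walking.mobility_comment
    comment_template: "Has difficulty even with support: {q03b}"
    combine:
      - match: {q03: I can do it myself}
        value: Independent
      - match: {q03: I can do it with someone's assistance}
        value: Needs help
      - match: {q03: I cannot do it myself}
        value: Unable
  - kind: quote
    source: q03a
    target: s_ac_devices.assistive_devices
  - kind: term_map
    source: q08
    target: s_ac_leg_condition.leg_condition
    mapping:
      Have leg weakness: Lower extremity weakness
      Told by a doctor not to put weight on either leg: Weight-bearing restriction
      Spend most of my time on the bed: Activity intolerance
  - kind: quote
    source: q08a
    target: s_ac_leg_condition.affected_side
  - kind: term_map
    source: q04
    target: s_ac_dressing.dressing_ability
    mapping:
      I can do it myself: Independent
      I can do it with someone's assistance: Needs help
      I cannot do it myself: Unable
  - kind: term_map
    source: q05
    target: s_ac_bathing.bathing_ability
    mapping:
      I can do it myself: Independent
      I can do it with someone's assistance: Needs help
      I cannot do it myself: Unable
  - kind: quote
    source: q05a
    target: s_ac_bathing.bathing_help
  - kind: quote
    source: q03c
    target: s_ac_transfer.needs_attendant

  # ---- cognition / perception ----
  - kind: quote
    source: q01
    target: s_co_vision.vision_trouble
  - kind: quote
    source: q01a
    target: s_co_vision.vision_detail
  - kind: quote
    source: q01b
    target: s_co_vision.corrective_lenses
  - kind: term_map
    source: q02
    target: s_co_hearing.hearing
    mapping:
      "Yes": Hearing impairment
      "No": No impairment
  - kind: quote
    source: q02a
    target: s_co_hearing.hearing_aid
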