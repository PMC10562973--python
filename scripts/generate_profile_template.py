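"""Regenerate src/iqcapture/fixtures/profile_template.yaml (run from repo root)."""
import yaml

PATTERNS = [
    "health perception/health management",
    "nutrition/metabolism",
    "elimination",
    "activity/exercise",
    "sleep/rest",
    "cognition/perception",
    "self-perception/self-concept",
    "role/relationship",
    "sexuality/reproduction",
    "coping/stress tolerance",
    "values/beliefs",
]

YN = ["Yes", "No"]
ABILITY = ["Independent", "Needs help", "Unable"]

def f(id, kind, options=None):
    d = {"id": id, "kind": kind}
    if options:
        d["options"] = options
    return d

sections = []

def sec(id, pattern, title, fields):
    sections.append({"id": id, "pattern": pattern, "title": title, "fields": fields})

hp = PATTERNS[0]; nu = PATTERNS[1]; el = PATTERNS[2]; ac = PATTERNS[3]
sl = PATTERNS[4]; co = PATTERNS[5]; sp = PATTERNS[6]; ro = PATTERNS[7]
sx = PATTERNS[8]; cs = PATTERNS[9]; vb = PATTERNS[10]

# ---- quoted sections (20), fields aligned with the packaged ruleset ----
sec("s_hp_alcohol", hp, "Drinking habits", [
    f("drinking_habit", "single_choice", ["Drinks", "Does not drink"]),
    f("drinking_frequency", "single_choice",
      ["Every day", "5-6 days a week", "3-4 days a week", "1-2 days a week", "Occasionally"]),
    f("pure_alcohol_g", "text_entry"),
    f("alcohol_units", "text_entry"),
])
sec("s_hp_smoking", hp, "Smoking habits", [
    f("smoking_status", "single_choice", ["Never smoked", "Ex-smoker", "Current smoker"]),
    f("smoking_duration_years", "text_entry"),
    f("cigarettes_per_day", "text_entry"),
])
sec("s_hp_restriction_compliance", hp, "Adherence to instructed restrictions", [
    f("follows_restriction", "single_choice", YN),
    f("compliance_note", "text_entry"),
])
sec("s_hp_falls", hp, "Fall history", [
    f("fall_history", "single_choice", YN),
    f("fall_note", "text_entry"),
])
sec("s_nu_diet_restriction", nu, "Dietary restrictions", [
    f("restrictions", "multi_choice",
      ["Calorie restriction", "Protein restriction", "Salt restriction",
       "Fat restriction", "Other restriction", "No restrictions"]),
    f("calorie_detail", "text_entry"),
    f("protein_detail", "text_entry"),
    f("salt_detail", "text_entry"),
    f("fat_detail", "text_entry"),
    f("other_detail", "text_entry"),
])
sec("s_nu_weight_change", nu, "Weight change", [
    f("weight_change", "single_choice", ["Gained", "Lost", "No change"]),
    f("weight_change_kg", "text_entry"),
    f("weight_change_months", "text_entry"),
])
sec("s_nu_appetite", nu, "Appetite", [
    f("appetite", "single_choice", ["Good", "Slightly decreased", "Decreased"]),
    f("intake_amount", "single_choice", ["About half", "A few mouthfuls", "Almost none"]),
])
sec("s_nu_swallowing", nu, "Swallowing", [
    f("dysphagia", "single_choice", YN),
    f("dysphagia_note", "text_entry"),
])
sec("s_nu_dentures", nu, "Dentures", [
    f("dentures", "single_choice", ["None", "Partial denture", "Full denture"]),
    f("denture_trouble", "single_choice", YN),
])
sec("s_el_toileting", el, "Toileting ability", [
    f("toileting_ability", "single_choice", ABILITY),
    f("toileting_note", "text_entry"),
])
sec("s_el_aids", el, "Elimination aids", [
    f("elimination_aids", "multi_choice",
      ["Diaper", "Urinal", "Portable toilet", "Urinary catheter"]),
    f("aids_note", "text_entry"),
])
sec("s_el_toilet_help", el, "Help needed when toileting", [
    f("help_detail", "multi_choice", ["Moving to the toilet", "Clothing adjustment", "Wiping"]),
    f("help_note", "text_entry"),
])
sec("s_ac_walking", ac, "Walking and mobility", [
    f("mobility", "single_choice", ABILITY),
    f("mobility_comment", "text_entry"),
])
sec("s_ac_devices", ac, "Assistive devices", [
    f("assistive_devices", "multi_choice", ["Cane", "Walker", "Wheelchair", "Handrail"]),
    f("device_note", "text_entry"),
])
sec("s_ac_leg_condition", ac, "Lower-extremity condition", [
    f("leg_condition", "multi_choice",
      ["Lower extremity weakness", "Weight-bearing restriction", "Activity intolerance"]),
    f("affected_side", "single_choice", ["Right", "Left", "Both"]),
])
sec("s_ac_dressing", ac, "Dressing ability", [
    f("dressing_ability", "single_choice", ABILITY),
    f("dressing_note", "text_entry"),
])
sec("s_ac_bathing", ac, "Bathing ability", [
    f("bathing_ability", "single_choice", ABILITY),
    f("bathing_help", "multi_choice",
      ["Washing body", "Washing hair", "Getting in and out of the bathtub"]),
])
sec("s_ac_transfer", ac, "Transfer and supervision", [
    f("needs_attendant", "single_choice", YN),
    f("transfer_note", "text_entry"),
])
sec("s_co_vision", co, "Vision", [
    f("vision_trouble", "single_choice", YN),
    f("vision_detail", "single_choice", ["Blurred vision", "Narrow visual field", "Double vision"]),
    f("corrective_lenses", "single_choice", YN),
])
sec("s_co_hearing", co, "Hearing", [
    f("hearing", "single_choice", ["No impairment", "Hearing impairment"]),
    f("hearing_aid", "single_choice", YN),
])

# ---- skeletal sections to reach the per-pattern allocation ----
def skeleton(pattern, prefix, titles):
    for i, title in enumerate(titles, 1):
        sec(f"{prefix}{i:02d}", pattern, title, [
            f(f"{prefix}{i:02d}_status", "single_choice", ["No problem", "Needs attention"]),
            f(f"{prefix}{i:02d}_note", "text_entry"),
        ])

skeleton(hp, "s_hp_x", ["Health perception", "Medication management",
                        "Infection history", "Home medical devices"])          # hp: 4+4=8
skeleton(nu, "s_nu_x", ["Skin condition", "Pressure injury risk", "Hydration",
                        "Food allergies", "Nutrition route"])                   # nu: 5+5=10
skeleton(el, "s_el_x", ["Bowel habits", "Urinary habits", "Ostomy", "Dialysis"])# el: 3+4=7
skeleton(ac, "s_ac_x", ["Exercise habits", "Instrumental ADL", "Braces and orthoses",
                        "Respiratory function", "Cardiac function", "Rehabilitation"])  # ac: 6+6=12
skeleton(sl, "s_sl_x", ["Sleep pattern", "Sleep aids", "Rest habits",
                        "Daytime drowsiness", "Night-time awakening"])          # sl: 5
skeleton(co, "s_co_x", ["Memory", "Orientation", "Pain", "Speech",
                        "Literacy", "Decision making"])                         # co: 2+6=8
skeleton(sp, "s_sp_x", ["Body image", "Self-esteem", "Mood", "Anxiety",
                        "Sense of control"])                                    # sp: 5
skeleton(ro, "s_ro_x", ["Family structure", "Key person", "Occupation",
                        "Social roles", "Caregiving duties", "Social support"]) # ro: 6
skeleton(sx, "s_sx_x", ["Reproductive history", "Menstruation",
                        "Sexual function", "Family planning"])                  # sx: 4
skeleton(cs, "s_cs_x", ["Stressors", "Coping style", "Recent life changes",
                        "Support when stressed", "Substance coping", "Crisis history"])  # cs: 6
skeleton(vb, "s_vb_x", ["Religious practice", "Cultural needs", "Care preferences",
                        "Advance directives", "Values affecting care", "Spiritual support"])  # vb: 6

data = {"id": "patient_profile", "patterns": PATTERNS, "sections": sections}
assert len(sections) == 77, len(sections)
with open("src/iqcapture/fixtures/profile_template.yaml", "w", encoding="utf-8") as fh:
    fh.write("# Patient profile template (structurally faithful skeleton):\n"
             "# 77 sections across Gordon's 11 functional health patterns.\n"
             "# Sections bound to the packaged quotation ruleset carry the\n"
             "# fields the rules target; the rest are skeletal two-field forms.\n")
    yaml.safe_dump(data, fh, sort_keys=False, allow_unicode=True, width=100)
print("sections:", len(sections))
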