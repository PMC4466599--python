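"""Generate personalised lifestyle advice from patient-reported behaviours.

Each behaviour is compared with its recommended level (boundary inclusive);
met levels get encouragement, unmet ones become areas needing improvement.
"""
import childcheck as cc

child = cc.ChildRecord(
    age=9.0, sex="male", height_cm=138.0, weight_kg=45.0,
    lifestyle={
        "fruit_veg_portions": 2,   # below the 5/day recommendation
        "mvpa_minutes": 75,        # meets 60 min/day
        "screen_hours": 4,         # above the 2 h/day limit
        "sugary_drinks": 3,        # above the 1/day limit
        "sleep_hours": 10,         # meets the 9.5 h band for age 6-12
        "breakfast_days": 7,       # daily breakfast
    },
)
report = cc.generate_advice(child, cc.load_default_ruleset())
print(report.to_text())
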