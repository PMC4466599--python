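"""Run the full three-step consultation for one child.

Weight status, per-outcome risk stratification (High adds a referral
recommendation) and lifestyle advice, composed into one printable report.
"""
import childcheck as cc

reference = cc.ReferenceTable.load_packaged()
ruleset = cc.load_default_ruleset()

# derive and calibrate both risk models on a synthetic cohort
frame = cc.generate_cohort_frame(cc.CohortConfig(n=4000, seed=3))
cardio = cc.fit_logistic(frame, "cardio_outcome", ["adjusted_bmi_z"])
ebd = cc.fit_logistic(frame, "ebd_outcome", ["bullied", "victimised", "sedentary_hours"])
strata = {
    "cardio_outcome": cc.calibrate_strata(cardio.predict_frame(frame), frame["cardio_outcome"]),
    "ebd_outcome": cc.calibrate_strata(ebd.predict_frame(frame), frame["ebd_outcome"]),
}

child = cc.ChildRecord(
    age=12.0, sex="male", ethnicity="Black", height_cm=152.0, weight_kg=72.0,
    lifestyle={"fruit_veg_portions": 3, "mvpa_minutes": 30, "screen_hours": 5,
               "sugary_drinks": 2, "sleep_hours": 8, "breakfast_days": 4},
    bullied=True, victimised=True, sedentary_hours=6.0,
)
report = cc.run_consultation(child, reference, [cardio, ebd], strata, ruleset)
print(report.to_text(normalised=True))
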