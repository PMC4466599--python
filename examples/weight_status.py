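"""Classify one child's weight status against the packaged growth reference.

BMI is converted to an LMS z-score and centile at the child's age and sex;
centile >= 91 is overweight, >= 98 obese (UK clinical convention).
"""
import childcheck as cc

reference = cc.ReferenceTable.load_packaged()
child = cc.ChildRecord(age=10.7, sex="female", ethnicity="Asian",
                       height_cm=148.6, weight_kg=54.0)

status = cc.classify_weight_status(child, reference)
print(f"BMI:      {status.bmi:.1f} kg/m2")
print(f"z-score:  {status.z:.2f}")
print(f"centile:  {status.centile:.1f}")
print(f"category: {status.category.value}")
# The centile places this child relative to same-age, same-sex reference
# children; the category drives the consultation's first-step message.
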