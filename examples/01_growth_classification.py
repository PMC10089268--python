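"""Classify a child's nutritional status from weight and height.

Builds one anthropometric record, converts BMI to an age- and sex-specific
z-score with the LMS transform against the bundled (synthetic) reference
table, and maps the z-score to one of the five nutritional-status bands.
"""

import datetime as dt

import habitcoach as hc

profile = hc.ChildProfile("maria", hc.Sex.female, birth_date=dt.date(2016, 2, 14))
record = hc.AnthropometricRecord("maria", dt.date(2026, 3, 2),
                                 weight_kg=42.5, height_m=1.41)

bmi = hc.compute_bmi(record.weight_kg, record.height_m)
table = hc.load_default_lms()
z = table.zscore(bmi, profile.sex, profile.age_months(record.date))
status = hc.classify_nutritional_status(z)

print(f"age          : {profile.age_months(record.date)} months")
print(f"BMI          : {bmi:.2f} kg/m2")
print(f"BMI-for-age z: {z:+.2f}")
print(f"status       : {status.value}")
# The z-score says how far this BMI sits from the reference median for the
# child's age and sex, in SD-like units; bands at -3/-2/+1/+2 give the five
# statuses (severe thinness ... obesity).
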