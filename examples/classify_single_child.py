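"""Score one child by hand: BMI, z-score, percentile, percent of P95, status.

Uses the bundled synthetic reference (real analyses substitute a CDC-style
LMS file via bmiage.load_lms_reference).
"""

from bmiage import (
    Sex,
    bmi_at_percentile,
    bmi_from_hw,
    classify,
    make_reference,
    pct_of_p95,
    percentile_from_z,
    zscore_from_bmi,
)

reference = make_reference()

# a 10.5-year-old girl, 142 cm, 48 kg
sex, age_y, height_cm, weight_kg = Sex.FEMALE, 10.5, 142.0, 48.0

bmi = bmi_from_hw(height_cm, weight_kg)
L, M, S = reference.interpolate(sex, age_y * 12.0)
z = zscore_from_bmi(bmi, L, M, S)
pct = percentile_from_z(z)
p95 = bmi_at_percentile(95.0, L, M, S)
b95 = pct_of_p95(bmi, p95)
status = classify(bmi, pct, b95)

print(f"BMI          {bmi:6.2f} kg/m^2")
print(f"BMI z-score  {z:6.3f}   (0 = reference median for this sex/age)")
print(f"BMI pct      {pct:6.2f}   (rank in the reference population)")
print(f"% of P95     {b95:6.2f}   (>=120 / >=140 mark severe obesity classes 2/3)")
print(f"status       {status}")
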