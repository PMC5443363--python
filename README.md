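# bmiage

Sex-specific BMI-for-age scoring and charting for children and adolescents
(ages 2 to <20 years), with severe-obesity percentile curves.

Standard pediatric growth charts stop being informative once BMI exceeds
~35 kg/m² — exactly the range where severe obesity lives. `bmiage` scores
each child against an LMS growth reference, classifies weight status into
six mutually exclusive categories (underweight through severe obesity
class 3), and draws BMI-for-age charts whose y-axis extends to 60 kg/m²
and which include the 120%-of-P95 and 140%-of-P95 cut-point curves, for
cross-sectional cohorts (thousands of points) or longitudinal trajectories.
It is aimed at epidemiologists, school-health programs, intervention
studies and clinicians who need to *see* the weight-status distribution of
a cohort, not just tabulate it.

## The model

The LMS method describes the sex- and age-specific BMI distribution with
three parameters — Box-Cox power *L*, median *M* (kg/m²) and coefficient
of variation *S* — giving for a BMI value *X*:

```
z = ((X/M)^L − 1) / (L·S)      (L ≠ 0)
z = ln(X/M) / S                (L = 0)
```

and percentile = Φ(z)·100. The inverse, BMI at percentile *p*, is
`M·(1 + L·S·Φ⁻¹(p/100))^(1/L)`. BMI as a percent of the 95th percentile,
`BMI_95 = 100·BMI / P95(sex, age)`, is the key metric for severe obesity.

Weight status (most severe criterion wins; lower bounds inclusive):

| category | criterion |
|---|---|
| severe obesity class 3 | BMI_95 ≥ 140 **or** BMI ≥ 40.0 kg/m² |
| severe obesity class 2 | BMI_95 ≥ 120 **or** BMI ≥ 35.0 kg/m² |
| obese class 1 | percentile ≥ 95 |
| overweight | percentile ≥ 85 |
| healthy weight | percentile ≥ 5 |
| underweight | percentile < 5 |

## Worked example

```python
from bmiage import (Sex, make_reference, bmi_from_hw, zscore_from_bmi,
                    percentile_from_z, bmi_at_percentile, pct_of_p95, classify)

reference = make_reference()            # synthetic LMS reference
sex, age_y, height_cm, weight_kg = Sex.FEMALE, 10.5, 142.0, 48.0

bmi = bmi_from_hw(height_cm, weight_kg)
L, M, S = reference.interpolate(sex, age_y * 12.0)
z = zscore_from_bmi(bmi, L, M, S)
pct = percentile_from_z(z)
b95 = pct_of_p95(bmi, bmi_at_percentile(95.0, L, M, S))
print(bmi, z, pct, b95, classify(bmi, pct, b95))
```

prints (see `examples/classify_single_child.py`):

```
BMI           23.80 kg/m^2
BMI z-score   0.866   (0 = reference median for this sex/age)
BMI pct       80.69   (rank in the reference population)
% of P95      88.93   (>=120 / >=140 mark severe obesity classes 2/3)
status       healthy weight
```

The girl's BMI sits at the 80.7th percentile — inside the healthy band
(5th to <85th), and well below both severe-obesity criteria.

Batch workflows read an investigator file with columns
`ID, Sex, Age_y, Height_cm, Weight_kg[, BMI]` (BMI is used only when
height or weight is missing; replicated IDs switch the run to longitudinal
mode), write `BMI_Results.csv` with the computed columns appended, and
render one chart per sex (`BMI_Graph_females.pdf`,
`BMI_Graph_males_long.eps`, ...). From the shell:

```
bmiage synth -o fixtures --n 200 --seed 7        # synthetic ref + cohort
bmiage run -i fixtures/BMI_Data.csv -r fixtures/synthetic_ref.csv -o out
```

The `examples/` directory holds one short script per capability:
single-child scoring, cohort scoring with prevalence summary,
cross-sectional and longitudinal charting, and extra percentile curves.

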