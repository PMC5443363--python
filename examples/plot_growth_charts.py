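"""Render a cross-sectional BMI-for-age chart with severe-obesity curves.

One symbol per subject over the 5th/50th/85th/95th percentile curves plus
the 120% and 140% of P95 curves; output is a reproducible vector PDF.
"""

from pathlib import Path

from bmiage import (
    ChartSpec,
    Sex,
    build_curves,
    compute_results,
    default_output_name,
    make_cohort,
    make_reference,
    render_cross_sectional,
)
from bmiage.cohort import SubjectRecord
from bmiage.lms import parse_sex

outdir = Path("example_output")
outdir.mkdir(exist_ok=True)

reference = make_reference()
cohort_df, _ = make_cohort(500, reference, seed=11, sex_ratio=1.0)  # all female
records = [
    SubjectRecord(r.ID, parse_sex(r.Sex), r.Age_y, r.Height_cm, r.Weight_kg)
    for r in cohort_df.itertuples()
]
results = compute_results(records, reference)

curves = build_curves(reference, Sex.FEMALE)  # P5/P50/P85/P95 + severe curves
spec = ChartSpec(sex=Sex.FEMALE, mode="cross_sectional", curves=curves)
path = outdir / default_output_name(Sex.FEMALE, "cross_sectional", "pdf")
scene = render_cross_sectional(results, spec, path)

print(f"wrote {path}")
print(f"  {len(scene.points[0])} subjects plotted, {len(scene.curve_lines)} reference curves")
print(f"  y-axis 10-{spec.y_max:g} kg/m^2, ages {spec.x_range[0]:g}-{spec.x_range[1]:g} years")
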