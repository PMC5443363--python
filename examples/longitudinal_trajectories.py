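"""Render a longitudinal chart: one connected trajectory per child.

Replicated IDs in the input mark the data as longitudinal; each child's
2-5 visits (spanning at most four years) are joined by a line whose slope
relative to the percentile curves shows BMI-for-age change over time.
"""

from pathlib import Path

from bmiage import (
    ChartSpec,
    Sex,
    build_curves,
    compute_results,
    default_output_name,
    detect_mode,
    make_cohort,
    make_reference,
    render_longitudinal,
)
from bmiage.cohort import SubjectRecord
from bmiage.lms import parse_sex

outdir = Path("example_output")
outdir.mkdir(exist_ok=True)

reference = make_reference()
cohort_df, _ = make_cohort(30, reference, seed=3, sex_ratio=1.0, mode="longitudinal")
records = [
    SubjectRecord(r.ID, parse_sex(r.Sex), r.Age_y, r.Height_cm, r.Weight_kg)
    for r in cohort_df.itertuples()
]
print(f"{len(records)} visit rows for {cohort_df['ID'].nunique()} children "
      f"-> mode: {detect_mode(records)}")

results = compute_results(records, reference)
curves = build_curves(reference, Sex.FEMALE)
spec = ChartSpec(sex=Sex.FEMALE, mode="longitudinal", curves=curves)
path = outdir / default_output_name(Sex.FEMALE, "longitudinal", "pdf")
scene = render_longitudinal(results, spec, path)
print(f"wrote {path}: {len(scene.trajectories)} trajectories")
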