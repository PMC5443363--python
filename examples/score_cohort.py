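"""Batch-score a cohort file and write BMI_Results.csv.

Generates a 200-subject synthetic cohort (known ground truth), scores it
against the synthetic reference, prints the prevalence table, and writes
the results CSV next to this script's working directory.
"""

from pathlib import Path

from bmiage import (
    compute_results,
    detect_mode,
    make_cohort,
    make_reference,
    prevalence_summary,
    read_cohort,
    write_results,
)

outdir = Path("example_output")
outdir.mkdir(exist_ok=True)

reference = make_reference()
make_cohort(200, reference, seed=7, out_dir=outdir)

records = read_cohort(outdir / "BMI_Data.csv")
results = compute_results(records, reference)
print(f"{len(records)} rows read, mode: {detect_mode(records)}")

summary = prevalence_summary([r.weight_status for r in results if r.weight_status])
for cat, count in summary.counts.items():
    print(f"  {cat.value:<24} {count:4d}  ({100 * summary.proportions[cat]:5.1f}%)")
print(f"  obesity (classes 1-3):   {summary.obesity_count} ({100 * summary.obesity_proportion:.1f}%)")
print(f"  severe obesity (2-3):    {summary.severe_obesity_count} ({100 * summary.severe_obesity_proportion:.1f}%)")

out = write_results(results, outdir)
print(f"wrote {out}  (input columns + BMI_kgm2, BMI_pct, BMI_z, BMI_95, Weight_status)")
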