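"""Customize the chart: extra percentile curves and a different y ceiling.

Adds the 3rd/10th/25th/75th/90th/97th percentiles alongside the standard
four, keeps the severe-obesity curves, and raises the y-axis maximum.
"""

from bmiage import Sex, build_curves, make_reference

reference = make_reference()
curves = build_curves(
    reference,
    Sex.MALE,
    percentiles=[3, 5, 10, 25, 50, 75, 85, 90, 95, 97],
    include_severe=True,
)

print(f"{len(curves.curves)} curves over {len(curves.age_grid)} age knots:")
print("  " + ", ".join(curves.curves))
age = 120.0  # 10 years
i = list(curves.age_grid).index(age)
for label in ("P50", "P95", "120% of P95", "140% of P95"):
    print(f"  {label:<12} at age 10 y: {curves.curves[label][i]:.2f} kg/m^2")
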