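"""Six-category youth weight-status classification.

Categories (ages 2 to <20 years), evaluated most-severe-first so the
OR-shaped severe-obesity criteria stay mutually exclusive:

* severe obesity class 3 — BMI >= 140% of the 95th percentile OR BMI >= 40.0
* severe obesity class 2 — BMI >= 120% of the 95th percentile OR BMI >= 35.0
* obese class 1          — BMI-for-age percentile >= 95
* overweight             — percentile >= 85
* healthy weight         — percentile >= 5
* underweight            — percentile < 5

Lower bounds are inclusive, upper bounds exclusive.  The classifier takes
the percentile and percent-of-P95 as independent, already-computed inputs
and does not cross-check them against each other.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

__all__ = ["WeightStatus", "classify", "prevalence_summary", "PrevalenceSummary"]


class WeightStatus(enum.Enum):
    """One of the six mutually exclusive weight-status categories.

    Enum values are the exact phrases written to results files.
    """

    UNDERWEIGHT = "underweight"
    HEALTHY = "healthy weight"
    OVERWEIGHT = "overweight"
    OBESE_1 = "obese class 1"
    SEVERE_2 = "severe obesity class 2"
    SEVERE_3 = "severe obesity class 3"

    def __str__(self) -> str:  # pragma: no cover - trivial
        return self.value


#: Categories ordered least to most severe.
SEVERITY_ORDER: tuple[WeightStatus, ...] = (
    WeightStatus.UNDERWEIGHT,
    WeightStatus.HEALTHY,
    WeightStatus.OVERWEIGHT,
    WeightStatus.OBESE_1,
    WeightStatus.SEVERE_2,
    WeightStatus.SEVERE_3,
)


def classify(bmi: float, bmi_pct: float, bmi_95: float) -> WeightStatus:
    """Assign the weight-status category for one subject.

    Parameters
    ----------
    bmi : float
        BMI in kg/m^2 (> 0).
    bmi_pct : float
        BMI-for-age percentile, in (0, 100).
    bmi_95 : float
        BMI as a percent of the sex/age-specific 95th percentile (> 0).
    """
    if not bmi > 0:
        raise ValueError(f"bmi must be positive, got {bmi!r}")
    if not 0.0 < bmi_pct < 100.0:
        raise ValueError(f"bmi_pct must lie in (0, 100), got {bmi_pct!r}")
    if not bmi_95 > 0:
        raise ValueError(f"bmi_95 must be positive, got {bmi_95!r}")

    if bmi_95 >= 140.0 or bmi >= 40.0:
        return WeightStatus.SEVERE_3
    if bmi_95 >= 120.0 or bmi >= 35.0:
        return WeightStatus.SEVERE_2
    if bmi_pct >= 95.0:
        return WeightStatus.OBESE_1
    if bmi_pct >= 85.0:
        return WeightStatus.OVERWEIGHT
    if bmi_pct >= 5.0:
        return WeightStatus.HEALTHY
    return WeightStatus.UNDERWEIGHT


@dataclass(frozen=True)
class PrevalenceSummary:
    """Counts and proportions per category, plus the two standard aggregates.

    ``obesity`` pools obese class 1 with severe obesity classes 2 and 3;
    ``severe_obesity`` pools classes 2 and 3 only.  Proportions are
    fractions of the total sample and sum to 1 across categories.
    """

    counts: Mapping[WeightStatus, int]
    proportions: Mapping[WeightStatus, float]
    obesity_count: int
    obesity_proportion: float
    severe_obesity_count: int
    severe_obesity_proportion: float
    n: int


def prevalence_summary(statuses: Iterable[WeightStatus]) -> PrevalenceSummary:
    """Tabulate category counts/proportions over a cohort of statuses."""
    counts = Counter(statuses)
    n = sum(counts.values())
    if n == 0:
        raise ValueError("prevalence_summary requires a non-empty collection")
    full = {cat: counts.get(cat, 0) for cat in SEVERITY_ORDER}
    props = {cat: c / n for cat, c in full.items()}
    obesity = (
        full[WeightStatus.OBESE_1]
        + full[WeightStatus.SEVERE_2]
        + full[WeightStatus.SEVERE_3]
    )
    severe = full[WeightStatus.SEVERE_2] + full[WeightStatus.SEVERE_3]
    return PrevalenceSummary(
        counts=full,
        proportions=props,
        obesity_count=obesity,
        obesity_proportion=obesity / n,
        severe_obesity_count=severe,
        severe_obesity_proportion=severe / n,
        n=n,
    )
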