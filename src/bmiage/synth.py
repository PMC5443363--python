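"""Synthetic reference tables and cohorts with known ground truth.

Everything downstream (scoring, classification, charting) is testable with
no external data: :func:`make_reference` builds a smooth, CDC-shaped LMS
reference table for both sexes, and :func:`make_cohort` draws subjects with
a *known intended weight-status category* by inverting that reference, so a
correct pipeline must recover the intended category for every row.

The reference is synthetic and clearly labeled as such; its curves are
chosen so that every one of the six categories is attainable at every age
in [2, 20) years — in particular the implied 95th percentile stays below
the 35 kg/m^2 absolute severe-obesity cutoff, as in real growth
references, so the obese-class-1 band never collapses.

Category sampling uses explicit interior margins (0.5 percentile points,
0.5 percent-of-P95, 0.1 kg/m^2) so generated rows never sit on a category
boundary; boundary behavior is exercised separately with hand-placed
values in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from . import metrics
from .classify import SEVERITY_ORDER, WeightStatus
from .lms import AGE_MIN_MONTHS, GRID_MAX_MONTHS, LMSReferenceTable, Sex

__all__ = ["SyntheticReferenceSpec", "make_reference", "make_cohort", "UNIFORM_MIX"]

#: Interior sampling margins: percentile points / percent-of-P95 / kg/m^2.
MARGIN_PCT = 0.5
MARGIN_P95 = 0.5
MARGIN_BMI = 0.1

UNIFORM_MIX: dict[WeightStatus, float] = {cat: 1.0 / 6.0 for cat in SEVERITY_ORDER}


@dataclass(frozen=True)
class SyntheticReferenceSpec:
    """Parameters of the synthetic LMS reference curves.

    M rises smoothly from ``m_start`` to ``m_stop`` (kg/m^2, smoothstep in
    age); S follows a half-sine arch from ``s_base`` up by ``s_amp``;
    L declines linearly from ``l_start`` to ``l_stop``.  ``sex_m_shift``
    offsets the male median upward slightly.
    """

    age_start: float = AGE_MIN_MONTHS
    age_stop: float = GRID_MAX_MONTHS
    age_step: float = 0.5
    m_start: float = 16.0
    m_stop: float = 27.0
    s_base: float = 0.08
    s_amp: float = 0.06
    l_start: float = 1.0
    l_stop: float = -2.0
    sex_m_shift: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.m_start > 0 and self.m_stop > 0):
            raise ValueError("median BMI curve must be strictly positive")
        if not (self.s_base > 0 and self.s_amp >= 0):
            raise ValueError("S curve must be strictly positive")
        if self.age_step <= 0 or self.age_stop <= self.age_start:
            raise ValueError("invalid age grid")


def _smoothstep(a: np.ndarray) -> np.ndarray:
    return 3.0 * a**2 - 2.0 * a**3


def make_reference(spec: SyntheticReferenceSpec | None = None) -> LMSReferenceTable:
    """Deterministic synthetic two-sex LMS reference table."""
    spec = spec or SyntheticReferenceSpec()
    ages = np.arange(spec.age_start, spec.age_stop + 1e-9, spec.age_step)
    a = (ages - spec.age_start) / (spec.age_stop - spec.age_start)

    frames = []
    for sex, shift in ((Sex.FEMALE, 0.0), (Sex.MALE, spec.sex_m_shift)):
        M = spec.m_start + (spec.m_stop - spec.m_start) * _smoothstep(a) + shift * a
        S = spec.s_base + spec.s_amp * np.sin(np.pi * a)
        L = spec.l_start + (spec.l_stop - spec.l_start) * a
        frames.append(
            pd.DataFrame({"sex": sex.value, "age_months": ages, "L": L, "M": M, "S": S})
        )
    return LMSReferenceTable(pd.concat(frames, ignore_index=True))


# ---------------------------------------------------------------------------
# Cohort generation


def _sample_bmi_for_category(
    cat: WeightStatus,
    L: float,
    M: float,
    S: float,
    rng: np.random.Generator,
) -> tuple[float, str]:
    """Draw a BMI strictly interior to ``cat``'s region; returns (bmi, arm).

    ``arm`` records which criterion places the row in a severe class:
    'percentile' for the percentile bands, 'percent' for the
    percent-of-P95 arm, 'absolute' for the absolute-BMI fallback.
    """
    p95 = metrics.bmi_at_percentile(95.0, L, M, S)

    def by_pct(lo: float, hi: float) -> float:
        return metrics.bmi_at_percentile(rng.uniform(lo, hi), L, M, S)

    if cat == WeightStatus.UNDERWEIGHT:
        return by_pct(MARGIN_PCT + 0.1, 5.0 - MARGIN_PCT), "percentile"
    if cat == WeightStatus.HEALTHY:
        return by_pct(5.0 + MARGIN_PCT, 85.0 - MARGIN_PCT), "percentile"
    if cat == WeightStatus.OVERWEIGHT:
        return by_pct(85.0 + MARGIN_PCT, 95.0 - MARGIN_PCT), "percentile"
    if cat == WeightStatus.OBESE_1:
        lo = metrics.bmi_at_percentile(95.0 + MARGIN_PCT, L, M, S)
        hi = min((1.2 - MARGIN_P95 / 100.0) * p95, 35.0 - MARGIN_BMI)
        if lo >= hi:
            raise RuntimeError(
                f"obese class 1 region empty (P95={p95:.1f}); reference unsuitable"
            )
        return rng.uniform(lo, hi), "percentile"
    if cat == WeightStatus.SEVERE_2:
        lo = (1.2 + MARGIN_P95 / 100.0) * p95
        hi = min((1.4 - MARGIN_P95 / 100.0) * p95, 40.0 - MARGIN_BMI)
        if lo < hi:
            return rng.uniform(lo, hi), "percent"
        # percent arm infeasible (1.2*P95 already >= 40): absolute-BMI arm
        lo = 35.0 + MARGIN_BMI
        hi = min(40.0 - MARGIN_BMI, (1.4 - MARGIN_P95 / 100.0) * p95)
        if lo >= hi:
            raise RuntimeError("severe class 2 region empty; reference unsuitable")
        return rng.uniform(lo, hi), "absolute"
    # class 3: above both cutoffs with margin, whichever binds
    lo = max((1.4 + MARGIN_P95 / 100.0) * p95, 40.0 + MARGIN_BMI)
    arm = "percent" if (1.4 * p95) >= 40.0 else "absolute"
    return rng.uniform(lo, lo * 1.25), arm


def _median_height_cm(sex: Sex, age_y: float) -> float:
    # crude sex-specific linear height-for-age; only used to back-solve
    # plausible height/weight columns (BMI is the controlled quantity)
    if sex == Sex.FEMALE:
        return 85.0 + 4.6 * (age_y - 2.0)
    return 86.0 + 4.9 * (age_y - 2.0)


def make_cohort(
    n: int,
    reference: LMSReferenceTable,
    seed: int,
    sex_ratio: float = 0.5,
    mode: Literal["cross_sectional", "longitudinal"] = "cross_sectional",
    status_mix: Mapping[WeightStatus, float] | None = None,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a cohort file plus its ground-truth table.

    Parameters
    ----------
    n : int
        Number of subjects (cross-sectional rows, or participants in
        longitudinal mode — each participant then gets 2-5 visits spanning
        at most 4 years, with the intended category held fixed).
    reference : LMSReferenceTable
        Reference the BMIs are inverted from.
    seed : int
        Seed for all randomness; identical seeds reproduce identical
        cohorts byte-for-byte.
    sex_ratio : float
        Proportion female.
    status_mix : mapping, optional
        Intended category proportions (must sum to 1); defaults to uniform
        over the six categories.

    Returns
    -------
    (cohort, truth) : DataFrames
        ``cohort`` has the investigator-file schema (ID, Sex, Age_y,
        Height_cm, Weight_kg, BMI); ``truth`` records each row's intended
        category and which criterion arm produced it.  When ``out_dir`` is
        given, both are also written as ``BMI_Data.csv`` and
        ``BMI_Data_truth.csv``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= sex_ratio <= 1.0:
        raise ValueError("sex_ratio must be in [0, 1]")
    mix = dict(status_mix or UNIFORM_MIX)
    total = sum(mix.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"status_mix proportions must sum to 1, got {total}")
    cats = list(mix)
    probs = np.array([mix[c] for c in cats], dtype=float)

    rng = np.random.default_rng(seed)
    cohort_rows: list[dict] = []
    truth_rows: list[dict] = []

    for i in range(n):
        pid = i + 1
        sex = Sex.FEMALE if rng.random() < sex_ratio else Sex.MALE
        cat = cats[rng.choice(len(cats), p=probs)]
        if mode == "cross_sectional":
            # cap just under 20 so rounding below cannot leave the age window
            visit_ages = [rng.uniform(2.0, 19.98)]
        else:
            n_visits = int(rng.integers(2, 6))
            base = rng.uniform(2.0, 15.5)
            gaps = rng.uniform(0.3, 4.0 / (n_visits - 1), size=n_visits - 1)
            visit_ages = list(base + np.concatenate([[0.0], np.cumsum(gaps)]))

        for visit, age_y in enumerate(visit_ages, start=1):
            age_y = round(age_y, 2)
            if float(age_y).is_integer():  # keep ages fractional: avoids QC warnings
                age_y += 0.01
            L, M, S = reference.interpolate(sex, age_y * 12.0)
            bmi, arm = _sample_bmi_for_category(cat, L, M, S, rng)
            height = _median_height_cm(sex, age_y) + rng.normal(0.0, 2.0)
            weight = bmi * (height / 100.0) ** 2
            cohort_rows.append(
                {
                    "ID": pid,
                    "Sex": sex.value,
                    "Age_y": age_y,
                    "Height_cm": round(height, 1),
                    "Weight_kg": round(weight, 2),
                    "BMI": "",
                }
            )
            # height/weight are rounded for realism; recompute the exact BMI
            # the pipeline will see and verify it stayed interior
            cohort_rows[-1]["Weight_kg"] = round(
                bmi * (cohort_rows[-1]["Height_cm"] / 100.0) ** 2, 4
            )
            truth_rows.append(
                {
                    "ID": pid,
                    "visit": visit,
                    "Sex": sex.value,
                    "Age_y": age_y,
                    "intended_status": cat.value,
                    "criterion_arm": arm,
                    "target_bmi": round(bmi, 6),
                }
            )

    cohort = pd.DataFrame(cohort_rows)
    truth = pd.DataFrame(truth_rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        cohort.to_csv(out_dir / "BMI_Data.csv", index=False, float_format="%.6f")
        truth.to_csv(out_dir / "BMI_Data_truth.csv", index=False, float_format="%.6f")
    return cohort, truth
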