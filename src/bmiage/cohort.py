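"""Cohort file I/O and per-subject scoring.

Reads investigator data files (CSV or Excel) with the columns ``ID, Sex,
Age_y, Height_cm, Weight_kg`` and optional ``BMI``, computes BMI, BMI-for-age
percentile, z-score and percent-of-P95 against an LMS reference, assigns
weight status, and writes a ``BMI_Results.csv`` that preserves the input
columns and appends the computed ones.

Batch philosophy: malformed rows never abort the run.  Each row carries a
list of QC flags; rows that cannot be scored (bad sex code, missing BMI
sources, age outside 2 to <20 years) come back flagged with empty computed
fields, and the output row count always equals the input row count.

Height and weight are computed preferentially; an investigator-supplied BMI
is used only when height or weight is absent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from . import metrics
from .classify import WeightStatus, classify
from .lms import AGE_MAX_MONTHS, AGE_MIN_MONTHS, LMSReferenceTable, Sex, parse_sex

__all__ = [
    "SubjectRecord",
    "SubjectResult",
    "read_cohort",
    "convert_length_in_to_cm",
    "convert_weight_lb_to_kg",
    "effective_bmi",
    "detect_mode",
    "compute_results",
    "write_results",
    "RESULTS_FILENAME",
]

RESULTS_FILENAME = "BMI_Results.csv"

#: Input schema: canonical field -> column header (matched case-insensitively).
INPUT_COLUMNS = {
    "id": "ID",
    "sex": "Sex",
    "age_y": "Age_y",
    "height_cm": "Height_cm",
    "weight_kg": "Weight_kg",
    "bmi": "BMI",
}

OUTPUT_COLUMNS = ("BMI_kgm2", "BMI_pct", "BMI_z", "BMI_95", "Weight_status")

#: Supplied-vs-computed BMI disagreements above this (kg/m^2) are flagged.
BMI_DISCREPANCY_TOL = 0.1

LB_PER_KG = 2.20462
CM_PER_IN = 2.54


@dataclass(frozen=True)
class SubjectRecord:
    """One measurement row from an investigator's input file."""

    id: object
    sex: Sex | None
    age_y: float | None
    height_cm: float | None = None
    weight_kg: float | None = None
    bmi_supplied: float | None = None
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class SubjectResult:
    """A scored row: the input record plus computed metrics and status.

    Computed fields are NaN (and ``weight_status`` None) when a QC flag
    prevented scoring.
    """

    record: SubjectRecord
    bmi_kgm2: float = math.nan
    bmi_pct: float = math.nan
    bmi_z: float = math.nan
    bmi_95: float = math.nan
    weight_status: WeightStatus | None = None
    bmi_source: Literal["computed", "supplied", None] = None
    qc_flags: tuple[str, ...] = ()


def convert_length_in_to_cm(inches: float) -> float:
    """Inches to centimeters: cm = inches * 2.54."""
    if inches < 0:
        raise ValueError(f"length must be non-negative, got {inches!r}")
    return inches * CM_PER_IN


def convert_weight_lb_to_kg(lbs: float) -> float:
    """Pounds to kilograms: kg = lbs / 2.20462."""
    if lbs < 0:
        raise ValueError(f"weight must be non-negative, got {lbs!r}")
    return lbs / LB_PER_KG


def read_cohort(path: str | Path, sheet: str | int = 0) -> list[SubjectRecord]:
    """Read a cohort file (.csv, .xlsx or .xls) into SubjectRecords.

    Requires ID, Sex and Age_y columns plus at least one BMI source
    (Height_cm and Weight_kg, or BMI); header matching is
    case-insensitive.  Malformed rows are returned flagged, not dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"cohort file not found: {path}")
    if path.suffix.lower() in (".xlsx", ".xls"):
        raw = pd.read_excel(path, sheet_name=sheet)
    else:
        raw = pd.read_csv(path)

    lower = {str(c).strip().lower(): c for c in raw.columns}
    colmap = {
        canonical: lower.get(header.lower())
        for canonical, header in INPUT_COLUMNS.items()
    }
    for required in ("id", "sex", "age_y"):
        if colmap[required] is None:
            raise ValueError(
                f"cohort file {path.name} missing required column {INPUT_COLUMNS[required]!r}"
            )
    has_hw = colmap["height_cm"] is not None and colmap["weight_kg"] is not None
    if not has_hw and colmap["bmi"] is None:
        raise ValueError(
            f"cohort file {path.name} needs Height_cm and Weight_kg columns, or a BMI column"
        )

    records = []
    for _, row in raw.iterrows():
        records.append(_parse_row(row, colmap))
    return records


def _parse_row(row: pd.Series, colmap: dict[str, str | None]) -> SubjectRecord:
    flags: list[str] = []

    def num(canonical: str) -> float | None:
        col = colmap[canonical]
        if col is None:
            return None
        value = pd.to_numeric(row[col], errors="coerce")
        if pd.isna(value):
            if not pd.isna(row[col]) and str(row[col]).strip() != "":
                flags.append(f"non-numeric {INPUT_COLUMNS[canonical]}: {row[col]!r}")
            return None
        return float(value)

    sex: Sex | None = None
    raw_sex = row[colmap["sex"]]
    try:
        sex = parse_sex(raw_sex)
    except ValueError:
        flags.append(f"invalid sex code: {raw_sex!r}")

    age_y = num("age_y")
    if age_y is None:
        flags.append("missing age")

    height = num("height_cm")
    weight = num("weight_kg")
    bmi = num("bmi")
    if height is not None and height <= 0:
        flags.append(f"non-positive Height_cm: {height}")
        height = None
    if weight is not None and weight <= 0:
        flags.append(f"non-positive Weight_kg: {weight}")
        weight = None
    if bmi is not None and bmi <= 0:
        flags.append(f"non-positive BMI: {bmi}")
        bmi = None
    if not ((height is not None and weight is not None) or bmi is not None):
        flags.append("no BMI source (need height+weight or BMI)")

    return SubjectRecord(
        id=row[colmap["id"]],
        sex=sex,
        age_y=age_y,
        height_cm=height,
        weight_kg=weight,
        bmi_supplied=bmi,
        flags=tuple(flags),
    )


def effective_bmi(record: SubjectRecord) -> tuple[float, Literal["computed", "supplied"]]:
    """BMI to score for a record, with its provenance.

    Height and weight win whenever both are present, even if a BMI value
    was also supplied; otherwise the supplied BMI is used.
    """
    if record.height_cm is not None and record.weight_kg is not None:
        return metrics.bmi_from_hw(record.height_cm, record.weight_kg), "computed"
    if record.bmi_supplied is not None:
        return record.bmi_supplied, "supplied"
    raise ValueError(f"record {record.id!r} has neither height+weight nor BMI")


def detect_mode(
    records: Sequence[SubjectRecord],
) -> Literal["cross_sectional", "longitudinal"]:
    """Longitudinal iff any participant ID occurs more than once."""
    if len(records) == 0:
        raise ValueError("detect_mode requires a non-empty collection")
    ids = [r.id for r in records]
    return "longitudinal" if len(set(ids)) < len(ids) else "cross_sectional"


def compute_results(
    records: Sequence[SubjectRecord], reference: LMSReferenceTable
) -> list[SubjectResult]:
    """Score every record against the reference; one result per input row.

    Rows that cannot be scored (invalid sex, missing sources, age outside
    [2, 20) years, or an ID appearing with conflicting sexes) are returned
    with QC flags and empty computed fields.
    """
    conflicted = _conflicting_sex_ids(records)
    results: list[SubjectResult] = []
    for record in records:
        flags = list(record.flags)
        if record.id in conflicted:
            flags.append("conflicting sex for replicated ID")
        results.append(_score_row(record, reference, flags))
    return results


def _conflicting_sex_ids(records: Sequence[SubjectRecord]) -> set:
    seen: dict[object, set] = {}
    for r in records:
        if r.sex is not None:
            seen.setdefault(r.id, set()).add(r.sex)
    return {i for i, sexes in seen.items() if len(sexes) > 1}


def _score_row(
    record: SubjectRecord, reference: LMSReferenceTable, flags: list[str]
) -> SubjectResult:
    blocking = [f for f in flags if f != "whole-number age"]
    if (
        record.age_y is not None
        and float(record.age_y).is_integer()
        and "whole-number age" not in flags
    ):
        # whole-number (likely self-reported) age risks misclassification
        flags.append("whole-number age")
    bmi = math.nan
    source = None
    try:
        bmi, source = effective_bmi(record)
    except ValueError:
        pass  # already flagged as missing source

    if (
        source == "computed"
        and record.bmi_supplied is not None
        and abs(bmi - record.bmi_supplied) > BMI_DISCREPANCY_TOL
    ):
        flags.append(
            f"supplied BMI {record.bmi_supplied:.2f} disagrees with computed {bmi:.2f}"
        )

    age_ok = (
        record.age_y is not None
        and AGE_MIN_MONTHS <= record.age_y * 12.0 < AGE_MAX_MONTHS
    )
    if record.age_y is not None and not age_ok:
        flags.append(f"age {record.age_y} y outside supported range [2, 20)")
        blocking.append("age")

    if blocking or record.sex is None or not age_ok or math.isnan(bmi):
        return SubjectResult(record=record, bmi_source=source, qc_flags=tuple(flags))

    L, M, S = reference.interpolate(record.sex, record.age_y * 12.0)
    z = metrics.zscore_from_bmi(bmi, L, M, S)
    pct = metrics.percentile_from_z(z)
    p95 = metrics.bmi_at_percentile(95.0, L, M, S)
    b95 = metrics.pct_of_p95(bmi, p95)
    # extreme |z| saturates the normal CDF to exactly 0/100 in floating
    # point; nudge inside the open interval for the classifier only
    pct_cls = min(max(pct, np.nextafter(0.0, 1.0)), np.nextafter(100.0, 0.0))
    status = classify(bmi, pct_cls, b95)
    return SubjectResult(
        record=record,
        bmi_kgm2=bmi,
        bmi_pct=pct,
        bmi_z=z,
        bmi_95=b95,
        weight_status=status,
        bmi_source=source,
        qc_flags=tuple(flags),
    )


def results_frame(results: Iterable[SubjectResult]) -> pd.DataFrame:
    """Results as a DataFrame in the output file's column order.

    Input columns first, then BMI_kgm2, BMI_pct, BMI_z, BMI_95,
    Weight_status, then a QC_flags column.  Display rounding: BMI, BMI_pct
    and BMI_95 to 2 decimals, BMI_z to 4.
    """
    rows = []
    for res in results:
        rec = res.record
        rows.append(
            {
                "ID": rec.id,
                "Sex": rec.sex.value if rec.sex is not None else "",
                "Age_y": rec.age_y,
                "Height_cm": rec.height_cm,
                "Weight_kg": rec.weight_kg,
                "BMI": rec.bmi_supplied,
                "BMI_kgm2": round(res.bmi_kgm2, 2) if not math.isnan(res.bmi_kgm2) else None,
                "BMI_pct": round(res.bmi_pct, 2) if not math.isnan(res.bmi_pct) else None,
                "BMI_z": round(res.bmi_z, 4) if not math.isnan(res.bmi_z) else None,
                "BMI_95": round(res.bmi_95, 2) if not math.isnan(res.bmi_95) else None,
                "Weight_status": res.weight_status.value if res.weight_status else "",
                "QC_flags": "; ".join(res.qc_flags),
            }
        )
    columns = list(INPUT_COLUMNS.values()) + list(OUTPUT_COLUMNS) + ["QC_flags"]
    return pd.DataFrame(rows, columns=columns)


def write_results(results: Iterable[SubjectResult], path: str | Path) -> Path:
    """Write the results CSV; a directory path gets the default file name."""
    path = Path(path)
    if path.is_dir():
        path = path / RESULTS_FILENAME
    results_frame(results).to_csv(path, index=False)
    return path
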