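"""LMS reference tables and percentile curve construction.

A growth reference here is a per-sex table of age knots (in months) with
the three LMS parameters L (Box-Cox power), M (median BMI, kg/m^2) and
S (coefficient of variation).  This module loads and validates such tables
from CSV or spreadsheet files, interpolates the parameters at arbitrary
ages, and builds the percentile and severe-obesity curves drawn on
BMI-for-age charts.

The package deliberately ships no CDC/NCHS reference values; users supply
their own reference file, and tests run against a synthetic reference
(:mod:`bmiage.synth`).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import metrics

__all__ = [
    "Sex",
    "parse_sex",
    "LMSRecord",
    "LMSReferenceTable",
    "CurveSet",
    "load_lms_reference",
    "interpolate_lms",
    "build_curves",
    "load_percentile_curves",
    "AGE_MIN_MONTHS",
    "AGE_MAX_MONTHS",
    "GRID_MAX_MONTHS",
    "DEFAULT_PERCENTILES",
]

#: Supported subject age window, months: 2 years inclusive to 20 years exclusive.
AGE_MIN_MONTHS = 24.0
AGE_MAX_MONTHS = 240.0
#: Upper bound for reference grid knots (CDC-style grids end at 240.5).
GRID_MAX_MONTHS = 240.5

#: Standard chart percentiles: 5th, 50th, 85th and 95th.
DEFAULT_PERCENTILES: tuple[float, ...] = (5.0, 50.0, 85.0, 95.0)


class Sex(str, enum.Enum):
    FEMALE = "female"
    MALE = "male"

    def __str__(self) -> str:  # pragma: no cover - trivial
        return self.value


_SEX_ALIASES = {
    "f": Sex.FEMALE,
    "female": Sex.FEMALE,
    "m": Sex.MALE,
    "male": Sex.MALE,
}


def parse_sex(value: object) -> Sex:
    """Parse a sex code; accepts F, M, female, male (case-insensitive)."""
    if isinstance(value, Sex):
        return value
    token = str(value).strip().lower()
    try:
        return _SEX_ALIASES[token]
    except KeyError:
        raise ValueError(f"unrecognized sex code {value!r} (expected F, M, female or male)") from None


@dataclass(frozen=True)
class LMSRecord:
    """One (sex, age) row of reference parameters."""

    sex: Sex
    age_months: float
    L: float
    M: float
    S: float

    def __post_init__(self) -> None:
        if not np.isfinite([self.age_months, self.L, self.M, self.S]).all():
            raise ValueError(f"non-finite LMS parameter in {self!r}")
        if not self.M > 0:
            raise ValueError(f"M must be positive, got {self.M} at age {self.age_months}")
        if not self.S > 0:
            raise ValueError(f"S must be positive, got {self.S} at age {self.age_months}")
        if not AGE_MIN_MONTHS <= self.age_months <= GRID_MAX_MONTHS:
            raise ValueError(
                f"age_months {self.age_months} outside reference window "
                f"[{AGE_MIN_MONTHS}, {GRID_MAX_MONTHS}]"
            )


class LMSReferenceTable:
    """Validated two-sex LMS reference table, sorted by age within sex.

    Construct from a DataFrame with columns ``sex, age_months, L, M, S``
    (:meth:`from_frame`), from records, or from a file
    (:func:`load_lms_reference`).
    """

    REQUIRED_COLUMNS = ("sex", "age_months", "L", "M", "S")

    def __init__(self, frame: pd.DataFrame):
        self._frame = self._validate(frame)
        self._by_sex = {
            sex: g.reset_index(drop=True) for sex, g in self._frame.groupby("sex", sort=False)
        }

    # -- construction -------------------------------------------------

    @classmethod
    def from_records(cls, records: Iterable[LMSRecord]) -> "LMSReferenceTable":
        rows = [
            {"sex": r.sex, "age_months": r.age_months, "L": r.L, "M": r.M, "S": r.S}
            for r in records
        ]
        return cls(pd.DataFrame(rows))

    @staticmethod
    def _validate(frame: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in LMSReferenceTable.REQUIRED_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"reference table missing column(s): {', '.join(missing)}")
        df = frame.loc[:, list(LMSReferenceTable.REQUIRED_COLUMNS)].copy()
        df["sex"] = df["sex"].map(parse_sex)
        for col in ("age_months", "L", "M", "S"):
            df[col] = pd.to_numeric(df[col], errors="coerce")

        bad = df[["age_months", "L", "M", "S"]].isna().any(axis=1)
        if bad.any():
            rows = ", ".join(str(i) for i in df.index[bad][:10])
            raise ValueError(f"non-numeric LMS parameter(s) in row(s): {rows}")
        bad = ~(df["M"] > 0) | ~(df["S"] > 0)
        if bad.any():
            rows = ", ".join(str(i) for i in df.index[bad][:10])
            raise ValueError(f"M and S must be positive; violated in row(s): {rows}")
        bad = (df["age_months"] < AGE_MIN_MONTHS) | (df["age_months"] > GRID_MAX_MONTHS)
        if bad.any():
            rows = ", ".join(str(i) for i in df.index[bad][:10])
            raise ValueError(
                f"age_months outside [{AGE_MIN_MONTHS}, {GRID_MAX_MONTHS}] in row(s): {rows}"
            )

        for sex in (Sex.FEMALE, Sex.MALE):
            sub = df[df["sex"] == sex]
            if sub.empty:
                raise ValueError(f"sex stratum absent: {sex.value}")
            ages = sub["age_months"].to_numpy()
            if len(np.unique(ages)) != len(ages):
                dupes = sub["age_months"][sub["age_months"].duplicated()].unique()
                raise ValueError(f"duplicate (sex, age) pair(s) for {sex.value}: {dupes[:5]}")
            if ages.min() > AGE_MIN_MONTHS or ages.max() < AGE_MAX_MONTHS:
                raise ValueError(
                    f"{sex.value} grid spans [{ages.min()}, {ages.max()}] months; "
                    f"must cover [{AGE_MIN_MONTHS}, {AGE_MAX_MONTHS}]"
                )
        return df.sort_values(["sex", "age_months"], kind="mergesort").reset_index(drop=True)

    # -- access -------------------------------------------------------

    @property
    def frame(self) -> pd.DataFrame:
        """The validated table as a DataFrame (copy)."""
        return self._frame.copy()

    def sexes(self) -> tuple[Sex, ...]:
        return tuple(self._by_sex)

    def ages(self, sex: Sex | str) -> np.ndarray:
        return self._by_sex[parse_sex(sex)]["age_months"].to_numpy()

    def max_age(self, sex: Sex | str) -> float:
        return float(self.ages(sex)[-1])

    def interpolate(self, sex: Sex | str, age_months: float) -> tuple[float, float, float]:
        """Linearly interpolated (L, M, S) at ``age_months`` for ``sex``.

        Exact at grid knots; each parameter is interpolated independently
        and linearly in age.  Ages outside [24, grid max] raise.
        """
        sex = parse_sex(sex)
        sub = self._by_sex[sex]
        ages = sub["age_months"].to_numpy()
        if not AGE_MIN_MONTHS <= age_months <= ages[-1]:
            raise ValueError(
                f"age {age_months} months outside supported range "
                f"[{AGE_MIN_MONTHS}, {ages[-1]}] for {sex.value}"
            )
        L = float(np.interp(age_months, ages, sub["L"].to_numpy()))
        M = float(np.interp(age_months, ages, sub["M"].to_numpy()))
        S = float(np.interp(age_months, ages, sub["S"].to_numpy()))
        return L, M, S


def load_lms_reference(
    path: str | Path,
    columns: Mapping[str, str] | None = None,
    sheet: str | int = 0,
) -> LMSReferenceTable:
    """Load an LMS reference table from a CSV or spreadsheet file.

    Parameters
    ----------
    path : str or Path
        ``.csv`` files are read as delimited text; ``.xlsx``/``.xls`` via
        openpyxl/pandas.
    columns : mapping, optional
        Maps canonical names (``sex``, ``age_months``, ``L``, ``M``, ``S``)
        to the column names used in the file.  Unmapped canonical names are
        matched case-insensitively against the file header.
    sheet : str or int
        Sheet to read when the file is a spreadsheet.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"reference file not found: {path}")
    raw = _read_table(path, sheet)
    renames: dict[str, str] = {}
    lower = {str(c).strip().lower(): c for c in raw.columns}
    for canonical in LMSReferenceTable.REQUIRED_COLUMNS:
        source = (columns or {}).get(canonical)
        if source is None:
            source = lower.get(canonical.lower())
        if source is None or source not in raw.columns:
            raise ValueError(f"reference file {path.name} missing column for {canonical!r}")
        renames[source] = canonical
    return LMSReferenceTable(raw.rename(columns=renames))


def interpolate_lms(
    table: LMSReferenceTable, sex: Sex | str, age_months: float
) -> tuple[float, float, float]:
    """Module-level alias for :meth:`LMSReferenceTable.interpolate`."""
    return table.interpolate(sex, age_months)


# ---------------------------------------------------------------------------
# Percentile curves


def percentile_label(p: float) -> str:
    """Canonical curve label for a percentile ('P5', 'P97', 'P99.9')."""
    return f"P{p:g}"


SEVERE_LABELS = ("120% of P95", "140% of P95")


@dataclass
class CurveSet:
    """Per-sex percentile (and percent-of-P95) curves over an age grid.

    ``curves`` maps labels such as ``"P5"`` or ``"120% of P95"`` to BMI
    arrays aligned with ``age_grid`` (months).
    """

    sex: Sex
    age_grid: np.ndarray
    curves: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.age_grid = np.asarray(self.age_grid, dtype=float)
        self.curves = {k: np.asarray(v, dtype=float) for k, v in self.curves.items()}
        n = len(self.age_grid)
        for label, values in self.curves.items():
            if len(values) != n:
                raise ValueError(
                    f"curve {label!r} has {len(values)} values for a {n}-point age grid"
                )

    @property
    def age_grid_years(self) -> np.ndarray:
        return self.age_grid / 12.0

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"sex": self.sex.value, "age_months": self.age_grid})
        for label, values in self.curves.items():
            df[label] = values
        return df


def build_curves(
    table: LMSReferenceTable,
    sex: Sex | str,
    percentiles: Sequence[float] = DEFAULT_PERCENTILES,
    include_severe: bool = True,
    age_step: float = 0.5,
) -> CurveSet:
    """Build chart curves for one sex from an LMS reference table.

    One curve per requested percentile, evaluated with the LMS inverse at
    each grid age.  With ``include_severe``, the 120% and 140% multiples of
    the P95 curve (the class-2 and class-3 severe-obesity cut points) are
    appended, computed from P95 whether or not 95 was requested.
    """
    sex = parse_sex(sex)
    if age_step <= 0:
        raise ValueError(f"age_step must be positive, got {age_step!r}")
    for p in percentiles:
        if not 0.0 < p < 100.0:
            raise ValueError(f"percentile must lie in (0, 100), got {p!r}")

    top = min(table.max_age(sex), AGE_MAX_MONTHS)
    grid = np.arange(AGE_MIN_MONTHS, top + 1e-9, age_step)
    params = [table.interpolate(sex, a) for a in grid]

    curves: dict[str, np.ndarray] = {}
    for p in sorted(percentiles):
        curves[percentile_label(p)] = np.array(
            [metrics.bmi_at_percentile(p, L, M, S) for (L, M, S) in params]
        )
    if include_severe:
        p95 = curves.get("P95")
        if p95 is None:
            p95 = np.array([metrics.bmi_at_percentile(95.0, L, M, S) for (L, M, S) in params])
        curves[SEVERE_LABELS[0]] = 1.2 * p95
        curves[SEVERE_LABELS[1]] = 1.4 * p95
    return CurveSet(sex=sex, age_grid=grid, curves=curves)


def load_percentile_curves(
    path: str | Path, sheet: str | int = 0
) -> dict[Sex, CurveSet]:
    """Load a percentile-curve table (sex, age_months, one column per curve).

    This is the file role of a pre-tabulated reference-curve spreadsheet;
    curves built from the matching LMS table should agree with it.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"curve file not found: {path}")
    raw = _read_table(path, sheet)
    lower = {str(c).strip().lower(): c for c in raw.columns}
    for needed in ("sex", "age_months"):
        if needed not in lower:
            raise ValueError(f"curve file {path.name} missing column {needed!r}")
    raw = raw.rename(columns={lower["sex"]: "sex", lower["age_months"]: "age_months"})
    curve_cols = [c for c in raw.columns if c not in ("sex", "age_months")]
    out: dict[Sex, CurveSet] = {}
    for sex_value, g in raw.groupby("sex"):
        sex = parse_sex(sex_value)
        g = g.sort_values("age_months")
        out[sex] = CurveSet(
            sex=sex,
            age_grid=g["age_months"].to_numpy(dtype=float),
            curves={c: g[c].to_numpy(dtype=float) for c in curve_cols},
        )
    return out


def _read_table(path: Path, sheet: str | int) -> pd.DataFrame:
    suffix = path.suffix.lower()
    if suffix in (".xlsx", ".xls"):
        return pd.read_excel(path, sheet_name=sheet)
    return pd.read_csv(path)
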