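"""Core per-subject anthropometric computations.

All functions here are pure: BMI from height and weight, the LMS (Cole)
transformation between BMI and a standard-normal z-score, the percentile
attached to a z-score, the inverse map from a percentile back to BMI, and
BMI expressed as a percent of the 95th percentile.

The LMS method models the age- and sex-specific BMI distribution with three
parameters: a Box-Cox power ``L``, the median ``M`` (kg/m^2) and a
coefficient of variation ``S``.  For a measurement ``X``::

    z = ((X / M)**L - 1) / (L * S)      if L != 0
    z = ln(X / M) / S                   if L == 0

Percentiles follow from the standard normal CDF.  No truncation is applied
to extreme z-scores: the far upper tail is exactly the region of interest
when grading severe obesity.
"""

from __future__ import annotations

import math

from scipy.stats import norm

# below this the Box-Cox branch is numerically indistinguishable from the
# log branch (difference O(L)) and L*S can underflow to zero
_L_TINY = 1e-150

__all__ = [
    "bmi_from_hw",
    "zscore_from_bmi",
    "percentile_from_z",
    "bmi_at_percentile",
    "pct_of_p95",
]


def bmi_from_hw(height_cm: float, weight_kg: float) -> float:
    """Body mass index (kg/m^2) from height in cm and weight in kg.

    Computed as weight divided by height in meters squared, unrounded.
    """
    if not height_cm > 0:
        raise ValueError(f"height_cm must be positive, got {height_cm!r}")
    if not weight_kg > 0:
        raise ValueError(f"weight_kg must be positive, got {weight_kg!r}")
    return weight_kg / (height_cm / 100.0) ** 2


def zscore_from_bmi(bmi: float, L: float, M: float, S: float) -> float:
    """LMS z-score of ``bmi`` against reference parameters (L, M, S).

    Uses the log branch when ``L == 0``; the two branches agree in the
    limit L -> 0.
    """
    _check_lms(bmi, M, S)
    if abs(L) < _L_TINY:  # includes L == 0; avoids underflow in L*S
        return math.log(bmi / M) / S
    # expm1 form of ((bmi/M)**L - 1): exact limit behavior as L -> 0
    return math.expm1(L * math.log(bmi / M)) / (L * S)


def percentile_from_z(z: float) -> float:
    """Percentile (0-100 scale) corresponding to a standard-normal z."""
    if not math.isfinite(z):
        raise ValueError(f"z must be finite, got {z!r}")
    return float(norm.cdf(z)) * 100.0


def bmi_at_percentile(p: float, L: float, M: float, S: float) -> float:
    """BMI (kg/m^2) at percentile ``p`` of the LMS(L, M, S) distribution.

    Inverse of :func:`zscore_from_bmi` composed with the normal quantile:
    ``M * (1 + L*S*z)**(1/L)`` for L != 0, ``M * exp(S*z)`` for L == 0,
    where ``z`` is the standard-normal quantile of ``p/100``.

    Raises ``ValueError`` when ``1 + L*S*z <= 0`` — the Box-Cox
    distribution is undefined at that extreme.
    """
    if not 0.0 < p < 100.0:
        raise ValueError(f"percentile must lie in (0, 100), got {p!r}")
    _check_lms(M, M, S)
    z = float(norm.ppf(p / 100.0))
    if abs(L) < _L_TINY:
        return M * math.exp(S * z)
    base = 1.0 + L * S * z
    if base <= 0.0:
        raise ValueError(
            f"LMS distribution undefined at percentile {p} "
            f"(1 + L*S*z = {base:.6g} <= 0 for L={L}, S={S})"
        )
    # log1p form of (1 + L*S*z)**(1/L): stable for small |L|
    return M * math.exp(math.log1p(L * S * z) / L)


def pct_of_p95(bmi: float, p95_bmi: float) -> float:
    """BMI expressed as a percent of the 95th-percentile BMI (100 * bmi/p95)."""
    if not bmi > 0:
        raise ValueError(f"bmi must be positive, got {bmi!r}")
    if not p95_bmi > 0:
        raise ValueError(f"p95_bmi must be positive, got {p95_bmi!r}")
    return 100.0 * bmi / p95_bmi


def _check_lms(bmi: float, M: float, S: float) -> None:
    if not bmi > 0:
        raise ValueError(f"bmi must be positive, got {bmi!r}")
    if not M > 0:
        raise ValueError(f"M must be positive, got {M!r}")
    if not S > 0:
        raise ValueError(f"S must be positive, got {S!r}")
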