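"""Area-normalized impedance statistics.

Skin-electrode impedance scales inversely with contact area, so raw kOhm
readings from a 3 mm dry pillar and a 10 mm gelled cup are not comparable;
multiplying by the contact area (kOhm * cm^2) puts them on one scale.
Outliers are screened with Tukey 1.5*IQR fences per electrode type, and the
dry-vs-gelled contrast uses the two-sample Mann-Whitney rank test.
Quantiles everywhere use linear interpolation between order statistics.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

from .ioformats import ValidationError

__all__ = ["area_normalize", "tukey_outliers", "mann_whitney", "summarize"]


def area_normalize(raw_kohm, diameter_mm):
    """kOhm * contact area: raw * pi * (diameter/20)^2 with the diameter in mm.

    (diameter/20 converts the mm diameter to a cm radius.)
    """
    raw = np.asarray(raw_kohm, dtype=float)
    diam = np.asarray(diameter_mm, dtype=float)
    if np.any(raw <= 0) or np.any(diam <= 0):
        raise ValidationError("impedance and diameter must be positive")
    out = raw * np.pi * (diam / 20.0) ** 2
    return float(out) if out.ndim == 0 else out


def tukey_outliers(values, k: float = 1.5) -> np.ndarray:
    """Keep-mask for Tukey fences [Q1 - k*IQR, Q3 + k*IQR].

    With fewer than 4 values the quartiles are too unstable to flag anything;
    a warning is issued and everything is kept.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1:
        raise ValidationError("tukey_outliers expects a 1-D array")
    if len(values) < 4:
        warnings.warn("fewer than 4 values; skipping outlier detection", stacklevel=2)
        return np.ones(len(values), dtype=bool)
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    return (values >= q1 - k * iqr) & (values <= q3 + k * iqr)


def mann_whitney(group_a, group_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney test; returns (U_A, p).

    U_A = R_A - n_A(n_A+1)/2 with average ranks for ties.  The p-value is
    exact (full null distribution) when n_A*n_B <= 400 and there are no
    ties; otherwise the normal approximation with tie correction is used.
    The identity U_A + U_B = n_A*n_B always holds.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("both groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (len(a) * len(b) <= 400 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def summarize(values) -> tuple[float, float, int]:
    """(median, IQR, n) with linearly interpolated quantiles."""
    values = np.asarray(values, dtype=float)
    if len(values) < 1:
        raise ValidationError("summarize needs at least one value")
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return float(med), float(q3 - q1), int(len(values))
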