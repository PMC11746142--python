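"""ATPase-activity arithmetic, standard curves and group statistics.

Activity from a colorimetric phosphate-release (malachite-green) or ADP-Glo
assay is

    A = Δ[Pi] / ([Protein] · Δt)          (h⁻¹)

with Δ[Pi] the phosphate released in µM, [Protein] the protein concentration
in µM and Δt the incubation time in hours. Raw absorbances are converted to
µM phosphate through a linear standard curve after background correction.

Group comparisons follow the study conventions: mean ± s.e.m., 10–90th
percentile whiskers with values outside them flagged as outliers, and a
two-sided two-sample t-test (Welch by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ActivityMeasurement",
    "StandardCurve",
    "GroupSummary",
    "atpase_activity",
    "fit_standard_curve",
    "invert_standard_curve",
    "relative_activity",
    "two_sample_ttest",
    "group_summary",
]


@dataclass(frozen=True)
class ActivityMeasurement:
    """One ATPase measurement: phosphate released, protein, incubation time."""

    delta_Pi: float  # µM phosphate released
    protein: float  # µM protein
    delta_t: float  # hours

    def __post_init__(self) -> None:
        if self.protein <= 0:
            raise ValueError("protein concentration must be positive")
        if self.delta_t <= 0:
            raise ValueError("incubation time must be positive")
        if self.delta_Pi < 0:
            raise ValueError("phosphate release must be non-negative")


@dataclass(frozen=True)
class StandardCurve:
    """Linear absorbance-vs-concentration calibration."""

    slope: float  # absorbance per µM
    intercept: float  # absorbance
    r_squared: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("r_squared must lie in [0, 1]")


@dataclass(frozen=True)
class GroupSummary:
    """Boxplot-style summary: mean ± s.e.m., 10–90th percentiles, outliers."""

    n: int
    mean: float
    sem: float
    p10: float
    p90: float
    outliers: tuple[float, ...]


def atpase_activity(m: ActivityMeasurement) -> float:
    """Average ATPase activity in h⁻¹: Δ[Pi] / ([Protein]·Δt)."""
    return m.delta_Pi / (m.protein * m.delta_t)


def fit_standard_curve(
    concentrations: Sequence[float], absorbances: Sequence[float]
) -> StandardCurve:
    """Ordinary least-squares fit of absorbance against concentration (µM)."""
    c = np.asarray(concentrations, dtype=float)
    a = np.asarray(absorbances, dtype=float)
    if c.size < 3 or c.size != a.size:
        raise ValueError("need >= 3 paired calibration points")
    if np.unique(c).size < 2:
        raise ValueError("concentrations must not all be identical")
    fit = stats.linregress(c, a)
    return StandardCurve(float(fit.slope), float(fit.intercept), float(fit.rvalue**2))


def invert_standard_curve(
    curve: StandardCurve, absorbance: float, background: float = 0.0
) -> float:
    """Concentration (µM) from a background-corrected absorbance."""
    if curve.slope == 0:
        raise ValueError("standard curve has zero slope")
    return (absorbance - background - curve.intercept) / curve.slope


def relative_activity(
    group: Sequence[float], reference: Sequence[float]
) -> tuple[float, float]:
    """Activity of a group as percent of a reference, plus percent reduction.

    Returns (percent_of_reference, percent_reduction); a 210% increase over
    the reference therefore appears as (310, −210).
    """
    g = np.asarray(group, dtype=float)
    r = np.asarray(reference, dtype=float)
    if g.size == 0 or r.size == 0:
        raise ValueError("group and reference must be non-empty")
    ref_mean = float(r.mean())
    if ref_mean <= 0:
        raise ValueError("reference mean must be positive")
    percent = 100.0 * float(g.mean()) / ref_mean
    return percent, 100.0 - percent


def two_sample_ttest(
    a: Sequence[float], b: Sequence[float], equal_var: bool = False
) -> tuple[float, float]:
    """Two-sided two-sample t-test; Welch (unequal variance) by default.

    Degenerate zero-variance pairs with equal means return (0, 1) rather
    than NaN so constant replicate sets compare as "no difference".
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    if x.std() == 0 and y.std() == 0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        raise ValueError("both samples have zero variance but unequal means")
    t, p = stats.ttest_ind(x, y, equal_var=equal_var)
    return float(t), float(p)


def group_summary(values: Sequence[float]) -> GroupSummary:
    """Mean ± s.e.m. with 10–90th percentile whiskers and outliers outside them.

    s.e.m. uses the sample (n−1) standard deviation; percentiles use linear
    interpolation.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty value set")
    sem = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0
    p10, p90 = np.percentile(v, [10, 90], method="linear")
    outliers = tuple(float(x) for x in v[(v < p10) | (v > p90)])
    return GroupSummary(int(v.size), float(v.mean()), sem, float(p10), float(p90), outliers)
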