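"""Dissolution profiles, f1/f2 profile comparison, and release-rate inputs.

The f1 difference factor and f2 similarity factor are the regulatory
statistics for comparing two cumulative dissolution profiles R (reference)
and T (test) sampled at the same n timepoints::

    f1 = [ sum_t |R_t - T_t| / sum_t R_t ] * 100
    f2 = 50 * log10( [1 + (1/n) sum_t (R_t - T_t)^2]^(-1/2) * 100 )

Identical profiles give f1 = 0 and f2 = 100; the conventional decision rule
is "similar" when f2 > 50 and f1 <= 15.

This module also classifies release rapidity against the 85%-dissolved
biowaiver thresholds (15 min / 30 min) and converts a cumulative profile
into the stepwise release-rate schedule consumed by the GI simulator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import (
    AlignmentError,
    DataQualityError,
    InsufficientDataError,
    UndefinedValueError,
    ValidationError,
)

__all__ = [
    "DissolutionProfile",
    "ReleaseSchedule",
    "f1_difference",
    "f2_similarity",
    "similarity_verdict",
    "classify_release",
    "interpolate_profile",
    "release_rate_series",
]


@dataclass
class DissolutionProfile:
    """Cumulative % dissolved over time for one product in one medium."""

    product: str
    medium_ph: float
    timepoints_min: Sequence[float]
    pct_dissolved: Sequence[float]
    replicate_sd: Optional[Sequence[float]] = None

    def __post_init__(self) -> None:
        t = np.asarray(self.timepoints_min, dtype=float)
        p = np.asarray(self.pct_dissolved, dtype=float)
        if t.size == 0:
            raise ValidationError("profile must contain at least one timepoint")
        if t.size != p.size:
            raise ValidationError("timepoints and percentages differ in length")
        if t[0] <= 0:
            raise ValidationError("first timepoint must be > 0 min")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("timepoints must be strictly increasing")
        if np.any(p < 0):
            raise ValidationError("% dissolved values must be >= 0")
        if self.replicate_sd is not None and len(self.replicate_sd) != t.size:
            raise ValidationError("replicate_sd length mismatch")
        self.timepoints_min = t
        self.pct_dissolved = p

    def __len__(self) -> int:
        return len(self.timepoints_min)


def _aligned(reference: DissolutionProfile, test: DissolutionProfile) -> None:
    if len(reference) != len(test) or not np.allclose(
        reference.timepoints_min, test.timepoints_min
    ):
        raise AlignmentError(
            "profiles are sampled at different timepoints; interpolate onto "
            "a common grid before comparing"
        )


def _comparison_points(
    reference: DissolutionProfile,
    test: DissolutionProfile,
    drop_after_85: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Paired (R, T) vectors, optionally truncated one point after both
    profiles exceed 85% (the regulatory point-dropping convention)."""
    _aligned(reference, test)
    r = np.asarray(reference.pct_dissolved, dtype=float)
    t = np.asarray(test.pct_dissolved, dtype=float)
    if drop_after_85:
        both = (r >= 85.0) & (t >= 85.0)
        if both.any():
            keep = int(np.argmax(both)) + 1  # include first point past 85%
            r, t = r[:keep], t[:keep]
    return r, t


def f1_difference(
    reference: DissolutionProfile,
    test: DissolutionProfile,
    drop_after_85: bool = False,
) -> float:
    """f1 difference factor (%); 0 for identical profiles."""
    r, t = _comparison_points(reference, test, drop_after_85)
    denom = float(np.sum(r))
    if denom <= 0:
        raise UndefinedValueError("f1 undefined for an all-zero reference")
    return float(np.sum(np.abs(r - t)) / denom * 100.0)


def f2_similarity(
    reference: DissolutionProfile,
    test: DissolutionProfile,
    drop_after_85: bool = False,
) -> float:
    """f2 similarity factor; 100 for identical profiles, >50 means similar."""
    r, t = _comparison_points(reference, test, drop_after_85)
    msd = float(np.mean((r - t) ** 2))
    return 50.0 * math.log10((1.0 + msd) ** -0.5 * 100.0)


def similarity_verdict(f1: float, f2: float) -> str:
    """Combine the two criteria: ``similar`` | ``not_similar`` | ``indeterminate``.

    The profiles are similar when f2 > 50 and f1 <= 15, dissimilar when both
    criteria fail, and flagged ``indeterminate`` when the criteria disagree
    (f2 > 50 but f1 > 15) rather than silently resolved.
    """
    if f1 < 0:
        raise ValidationError("f1 must be non-negative")
    f2_ok = f2 > 50.0
    f1_ok = f1 <= 15.0
    if f2_ok and f1_ok:
        return "similar"
    if f2_ok and not f1_ok:
        return "indeterminate"
    return "not_similar"


def interpolate_profile(
    profile: DissolutionProfile, query_times_min: Iterable[float]
) -> np.ndarray:
    """Monotone piecewise-linear interpolation through (0, 0) and the
    observed points; times beyond the last observation hold the final value
    (dissolution never decreases by extrapolation)."""
    q = np.asarray(list(query_times_min), dtype=float)
    if np.any(q < 0):
        raise ValidationError("query times must be >= 0")
    knots_t = np.concatenate(([0.0], profile.timepoints_min))
    knots_p = np.concatenate(([0.0], profile.pct_dissolved))
    return np.interp(q, knots_t, knots_p)


def classify_release(profile: DissolutionProfile) -> str:
    """Release-rapidity class against the 85% biowaiver thresholds.

    ``very_rapid`` when >= 85% is dissolved by 15 min, ``rapid`` when >= 85%
    by 30 min, otherwise ``not_rapid``.  Values at 15/30 min are obtained by
    interpolation (hold-last beyond the final sample).
    """
    if profile.timepoints_min[-1] < 15.0:
        raise InsufficientDataError(
            "profile ends before 15 min; cannot classify release rapidity"
        )
    at15, at30 = interpolate_profile(profile, [15.0, 30.0])
    if at15 >= 85.0:
        return "very_rapid"
    if at30 >= 85.0:
        return "rapid"
    return "not_rapid"


@dataclass
class ReleaseSchedule:
    """Piecewise-constant release-rate representation of a profile.

    ``times_min`` are the knot times (starting at 0); ``rates_mg_min[i]`` is
    the constant release rate on ``[times_min[i], times_min[i+1])`` and the
    rate is zero beyond the last knot.  ``cum_frac`` holds the clamped
    cumulative released fraction at the knots.
    """

    times_min: np.ndarray
    rates_mg_min: np.ndarray
    cum_frac: np.ndarray
    dose_mg: float
    fast_release_per_h: float = 1000.0

    def rate_at(self, t_min: float) -> float:
        """Release rate (mg/min) at time ``t_min`` since dosing."""
        idx = int(np.searchsorted(self.times_min, t_min, side="right")) - 1
        if idx < 0 or idx >= len(self.rates_mg_min):
            return 0.0
        return float(self.rates_mg_min[idx])

    def frac_released(self, t_min: float) -> float:
        """Cumulative released fraction (0..1) at ``t_min``."""
        return float(np.interp(t_min, self.times_min, self.cum_frac))

    def fractional_rate_per_h(self, t_h: float) -> float:
        """First-order specific release rate (1/h) for the GI simulator.

        k(t) = F'(t) / (1 - F(t)) reproduces the cumulative curve when
        applied to an undepleted solid pool.  Once the profile is exhausted
        (F -> 1, or the schedule has run past its last knot with remaining
        solid) the residual solid is released at ``fast_release_per_h`` if
        the profile reached 100%, else not at all.
        """
        t_min = t_h * 60.0
        frac = self.frac_released(t_min)
        remaining = 1.0 - frac
        if remaining <= 1e-9:
            return self.fast_release_per_h
        return (self.rate_at(t_min) * 60.0) / (self.dose_mg * remaining)

    def integral_mg(self) -> float:
        """Total released mass over the schedule (mg)."""
        widths = np.diff(self.times_min)
        return float(np.sum(self.rates_mg_min * widths))


def release_rate_series(
    profile: DissolutionProfile,
    dose_mg: float,
    fast_release_per_h: float = 1000.0,
) -> ReleaseSchedule:
    """Convert a cumulative %-dissolved profile into a stepwise release-rate
    schedule whose integral equals ``dose * min(pct_last, 100)/100``.

    Percentages above 100 (assay variability) are clamped to 100 when
    converting to mass; small non-monotonic dips (<= 2 percentage points)
    are clamped to the running maximum, larger decreases raise
    :class:`DataQualityError`.
    """
    if dose_mg <= 0:
        raise ValidationError("dose must be > 0")
    pct = np.asarray(profile.pct_dissolved, dtype=float)
    if np.any(pct > 110.0):
        raise DataQualityError("% dissolved exceeds the 110% assay tolerance")
    drops = np.maximum.accumulate(pct) - pct
    if np.any(drops > 2.0):
        raise DataQualityError(
            f"cumulative dissolution decreases by {drops.max():.2f}% (> 2% tolerance)"
        )
    pct = np.minimum(np.maximum.accumulate(pct), 100.0)
    times = np.concatenate(([0.0], profile.timepoints_min))
    frac = np.concatenate(([0.0], pct)) / 100.0
    rates = dose_mg * np.diff(frac) / np.diff(times)
    return ReleaseSchedule(
        times_min=times,
        rates_mg_min=rates,
        cum_frac=frac,
        dose_mg=dose_mg,
        fast_release_per_h=fast_release_per_h,
    )
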