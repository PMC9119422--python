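"""SNP-saturation assessment over a downsampling series.

For a strain observed at an increasing schedule of subsample levels, both
the levels (read counts or depths) and the SNP counts are min–max
normalised to [0, 1] and the damped-increase ratio

    R_i = |Y_i - Y_{i-1}| / (X_i - X_{i-1})

is computed between adjacent points.  A strain is saturated when the R
sequence decreases along the series (within a small relative tolerance to
absorb sampling noise) and the final R falls below 0.1.  The SNP count at
the deepest level of a saturated series is its saturated SNP number — the
regression target of the predictor module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import InputError

logger = logging.getLogger(__name__)

DEFAULT_SCHEDULE = (
    1_000,
    10_000,
    100_000,
    1_000_000,
    10_000_000,
    20_000_000,
    30_000_000,
    40_000_000,
    50_000_000,
    60_000_000,
    80_000_000,
    100_000_000,
    200_000_000,
    300_000_000,
    400_000_000,
    500_000_000,
    1_000_000_000,
    2_000_000_000,
)

FINAL_R_THRESHOLD = 0.1
MONO_TOLERANCE = 0.05
MONO_ABS_TOLERANCE = 0.1


@dataclass
class SubsampleSchedule:
    levels: tuple[int, ...] = DEFAULT_SCHEDULE

    def __post_init__(self) -> None:
        lv = self.levels
        if any(l <= 0 for l in lv) or any(b <= a for a, b in zip(lv, lv[1:])):
            raise InputError("schedule levels must be strictly increasing positive")


@dataclass
class SaturationSeries:
    strain: str
    raw_levels: np.ndarray
    raw_counts: np.ndarray
    x: np.ndarray
    y: np.ndarray
    ratios: np.ndarray
    saturated: bool
    reasons: list[str] = field(default_factory=list)
    saturated_snp_count: Optional[int] = None


def normalize_series(
    raw_x: Sequence[float], raw_y: Sequence[float]
) -> tuple[np.ndarray, np.ndarray]:
    """Independent min–max normalisation of x and y onto [0, 1].

    A constant y series maps to all zeros (flat curve, warned); a constant
    x series is an error.
    """
    x = np.asarray(raw_x, dtype=float)
    y = np.asarray(raw_y, dtype=float)
    if len(x) != len(y):
        raise InputError("x and y lengths differ")
    if len(x) < 3:
        raise InputError("need at least 3 subsampling points")
    if np.any(np.diff(x) <= 0):
        raise InputError("raw x must be strictly increasing")
    xn = (x - x.min()) / (x.max() - x.min())
    yspan = y.max() - y.min()
    if yspan == 0:
        logger.warning("constant SNP counts; flat normalized series")
        yn = np.zeros_like(y)
    else:
        yn = (y - y.min()) / yspan
    return xn, yn


def saturation_ratios(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """R_i = |Y_i - Y_{i-1}| / (X_i - X_{i-1}) for each adjacent pair."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    dx = np.diff(x)
    if np.any(dx <= 0):
        raise InputError("duplicate or decreasing x values")
    return np.abs(np.diff(y)) / dx


def assess_saturation(
    ratios: Sequence[float],
    final_threshold: float = FINAL_R_THRESHOLD,
    mono_tolerance: float = MONO_TOLERANCE,
    mono_abs_tolerance: float = MONO_ABS_TOLERANCE,
) -> tuple[bool, list[str]]:
    """Two-condition saturation verdict.

    Saturated iff (1) the R sequence never increases by more than
    ``mono_tolerance`` relative to the previous value, and (2) the last R
    is below ``final_threshold``.  An increase that stays below
    ``mono_abs_tolerance`` does not count against (1): once the curve is
    flat, integer wiggles of a single SNP between adjacent subsamples send
    R from 0 to a tiny value, which is sampling noise rather than renewed
    discovery.  Returns (verdict, failure reasons).
    """
    r = np.asarray(ratios, dtype=float)
    if len(r) < 2:
        raise InputError("need at least 2 ratios")
    reasons: list[str] = []
    bad = np.nonzero(
        r[1:] > np.maximum(r[:-1] * (1.0 + mono_tolerance), mono_abs_tolerance)
    )[0]
    if len(bad):
        reasons.append(
            f"R increases at step {int(bad[0]) + 2} "
            f"({r[bad[0] + 1]:.4g} > {r[bad[0]]:.4g} within {mono_tolerance:.0%})"
        )
    if not r[-1] < final_threshold:
        reasons.append(f"final R {r[-1]:.4g} >= {final_threshold}")
    return (not reasons), reasons


def evaluate_series(
    strain: str,
    levels: Sequence[float],
    snp_counts: Sequence[float],
    final_threshold: float = FINAL_R_THRESHOLD,
    mono_tolerance: float = MONO_TOLERANCE,
) -> SaturationSeries:
    """Normalise, compute R, and issue the saturation verdict for one strain."""
    x, y = normalize_series(levels, snp_counts)
    r = saturation_ratios(x, y)
    sat, reasons = assess_saturation(r, final_threshold, mono_tolerance)
    return SaturationSeries(
        strain=strain,
        raw_levels=np.asarray(levels, dtype=float),
        raw_counts=np.asarray(snp_counts, dtype=float),
        x=x,
        y=y,
        ratios=r,
        saturated=sat,
        reasons=reasons,
        saturated_snp_count=int(snp_counts[-1]) if sat else None,
    )
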