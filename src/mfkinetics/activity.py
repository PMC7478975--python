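"""Swimming-activity quantification and activity-class assignment.

A worm recorded at 20 frames/s is reduced to a one-dimensional behavioral
signal by counting, for each consecutive frame pair, the pixels whose
intensity increased by more than a threshold (default 12 on the signed
-256..+256 difference scale).  A worm body images dark on a bright
background, so pixels the body vacates between frames brighten and are
counted as "active".  Long recordings are then classified into Long-, Mid-
and Short-activity decay classes from the mean activity of the early half
of the record (AA0-3) and the late/early retention ratio, and each record
is split into a high-motility and a low-motility period whose length
depends on the class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np

from .errors import InputError

# Fraction of the record treated as the high-motility period, per class.
HIGH_MOTILITY_FRACTION = {"Long": 0.5, "Mid": 0.2, "Short": 0.1}


@dataclass
class ActivityTimeSeries:
    """Active-pixel counts per frame interval.

    counts may be float-valued (synthetic traces carry Gaussian amplitude
    noise); real pixel counts are non-negative integers.
    """

    counts: np.ndarray
    dt: float = 0.05
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 1 or self.counts.size == 0:
            raise InputError("activity counts must be a non-empty 1-D sequence")
        if self.dt <= 0:
            raise InputError("frame interval dt must be positive")

    @property
    def n(self) -> int:
        return int(self.counts.size)

    @property
    def duration(self) -> float:
        """Total record duration in seconds."""
        return self.n * self.dt


@dataclass
class ActivityClassLabel:
    """Activity-decay class of one animal plus the quantities that define it."""

    activity_class: Literal["Long", "Mid", "Short"]
    aa_early: float
    aa_late: float
    ratio: float
    high_motility_fraction: float


def count_active_pixels(stack, intensity_threshold: int = 12,
                        absolute: bool = False) -> ActivityTimeSeries:
    """Count per-frame-pair active pixels in a grayscale frame stack.

    The difference frame[t+1] - frame[t] is taken signed; pixels with a
    difference strictly greater than ``intensity_threshold`` are counted.
    With ``absolute=True`` pixels with ``|difference| > threshold`` are
    counted instead (both vacated and newly covered pixels), a sensitivity
    variant only.
    """
    frames = np.asarray(stack.frames)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise InputError("frame stack must contain at least two frames of equal shape")
    diff = frames[1:].astype(np.int32) - frames[:-1].astype(np.int32)
    if absolute:
        mask = np.abs(diff) > intensity_threshold
    else:
        mask = diff > intensity_threshold
    counts = mask.sum(axis=(1, 2)).astype(float)
    return ActivityTimeSeries(counts=counts, dt=getattr(stack, "dt", 0.05),
                              meta={"source": "pixel_count",
                                    "intensity_threshold": intensity_threshold,
                                    "absolute": absolute})


def despike(series: ActivityTimeSeries, window: int = 5,
            factor: float = 10.0) -> ActivityTimeSeries:
    """Remove isolated single-frame spikes exceeding ``factor`` x local median.

    Optional artifact hook: a sample is replaced by the local median when it
    exceeds ``factor`` times the median of its surrounding window and both
    neighbours sit below that bar.  Median of an all-quiet window is treated
    as 1 count to keep the bar finite.
    """
    if window < 3 or window % 2 == 0:
        raise InputError("despike window must be an odd integer >= 3")
    x = series.counts.copy()
    n = x.size
    half = window // 2
    out = x.copy()
    for i in range(1, n - 1):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        med = float(np.median(np.concatenate([x[lo:i], x[i + 1:hi]])))
        bar = factor * max(med, 1.0)
        if x[i] > bar and x[i - 1] <= bar and x[i + 1] <= bar:
            out[i] = med
    return ActivityTimeSeries(counts=out, dt=series.dt,
                              meta={**series.meta, "despiked": True})


def classify_animal(series: ActivityTimeSeries, aa_threshold: float = 0.75,
                    ratio_threshold: float = 0.01,
                    ratio_mode: str = "late_over_early") -> ActivityClassLabel:
    """Assign a Long/Mid/Short activity-decay class.

    AA0-3 and AA3-6 are the mean activities of the early and late halves of
    the record.  With the default ``ratio_mode="late_over_early"`` the ratio
    is the retention AA3-6/AA0-3: an animal that keeps swimming into the
    late half retains a non-negligible ratio (Long), one that stops early
    retains essentially none (Mid), and one whose early activity is already
    below ``aa_threshold`` is Short.  ``ratio_mode="early_over_late"``
    exposes the reciprocal for sensitivity checks; there, a *small* ratio
    marks retention, so the comparison direction flips.
    """
    n = series.n
    if n < 2:
        raise InputError("series too short to split into early/late halves")
    half = n // 2
    aa_early = float(np.mean(series.counts[:half]))
    aa_late = float(np.mean(series.counts[half:]))

    if ratio_mode == "late_over_early":
        ratio = aa_late / aa_early if aa_early > 0 else np.inf
        retained = ratio >= ratio_threshold
    elif ratio_mode == "early_over_late":
        ratio = aa_early / aa_late if aa_late > 0 else np.inf
        retained = ratio <= ratio_threshold
    else:
        raise InputError(f"unknown ratio_mode: {ratio_mode!r}")

    if aa_early >= aa_threshold:
        cls = "Long" if retained else "Mid"
    else:
        cls = "Short"
    return ActivityClassLabel(activity_class=cls, aa_early=aa_early,
                              aa_late=aa_late, ratio=ratio,
                              high_motility_fraction=HIGH_MOTILITY_FRACTION[cls])


def split_motility_periods(series: ActivityTimeSeries,
                           label: ActivityClassLabel,
                           fraction_override: Optional[float] = None,
                           ) -> tuple[ActivityTimeSeries, ActivityTimeSeries]:
    """Split a record into (high-motility, low-motility) segments.

    The high-motility segment is the leading fraction of the record set by
    the activity class (Long 50%, Mid 20%, Short 10%); the low-motility
    segment is the remainder.  The two segments partition the input exactly.
    ``fraction_override`` replaces the class fraction (used e.g. for
    continuously swimming mutant-like cohorts analysed over the first tenth
    only).
    """
    frac = label.high_motility_fraction if fraction_override is None else fraction_override
    if not 0 < frac < 1:
        raise InputError("high-motility fraction must lie in (0, 1)")
    cut = int(round(series.n * frac))
    if cut == 0 or cut == series.n:
        raise InputError("series too short for the requested motility split")
    high = ActivityTimeSeries(counts=series.counts[:cut], dt=series.dt,
                              meta={**series.meta, "period": "high-motility"})
    low = ActivityTimeSeries(counts=series.counts[cut:], dt=series.dt,
                             meta={**series.meta, "period": "low-motility"})
    return high, low
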