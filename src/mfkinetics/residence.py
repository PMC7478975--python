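"""Two-state residence-time extraction from activity time series.

The activity amplitude distribution of an episodically swimming worm is
bimodal: a quiescent mode near zero counts and a swimming mode at tens of
counts, separated by a valley around 10-20 pixels/frame.  Thresholding the
trace at that valley (default 12, active when count >= threshold) yields
maximal runs of active and inactive frames; run length x dt is the
residence (dwell) time of one visit to that state.  Runs alternate
strictly, and under the ``keep`` boundary policy the run lengths sum
exactly to the number of frames.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .activity import ActivityTimeSeries
from .errors import InputError


@dataclass
class NormalizedProbabilityDensity:
    """Histogram-based density normalized to unit trapezoid integral."""

    bin_centers: np.ndarray
    density: np.ndarray
    binning: Literal["linear", "logarithmic"] = "linear"

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.bin_centers.shape != self.density.shape:
            raise InputError("bin_centers and density must have equal shape")

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.bin_centers))


@dataclass
class ResidenceTimeSeries:
    """Alternating active/inactive run durations.

    Run lengths are stored as integer frame counts so conservation checks
    are exact; durations in seconds are derived as ``runs * dt``.
    """

    active_runs: np.ndarray          # frame counts, ordered by round
    inactive_runs: np.ndarray
    first_state: Literal["active", "inactive"]
    dt: float
    boundary_policy: Literal["keep", "drop_edges"] = "drop_edges"
    degenerate: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.active_runs = np.asarray(self.active_runs, dtype=np.int64)
        self.inactive_runs = np.asarray(self.inactive_runs, dtype=np.int64)
        if self.dt <= 0:
            raise InputError("dt must be positive")

    @property
    def active_durations(self) -> np.ndarray:
        """Active-state residence times in seconds."""
        return self.active_runs * self.dt

    @property
    def inactive_durations(self) -> np.ndarray:
        return self.inactive_runs * self.dt

    @property
    def n_rounds(self) -> int:
        return int(min(self.active_runs.size, self.inactive_runs.size))

    def total_frames(self) -> int:
        return int(self.active_runs.sum() + self.inactive_runs.sum())

    def interleaved(self) -> np.ndarray:
        """Durations in temporal order (seconds), alternating states."""
        a, b = (self.active_runs, self.inactive_runs)
        if self.first_state == "inactive":
            a, b = b, a
        out = []
        for i in range(max(a.size, b.size)):
            if i < a.size:
                out.append(a[i])
            if i < b.size:
                out.append(b[i])
        return np.asarray(out, dtype=np.int64) * self.dt


def activity_npd(series: ActivityTimeSeries, bins=50,
                 binning: Literal["linear", "logarithmic"] = "linear",
                 ) -> NormalizedProbabilityDensity:
    """Normalized probability density of per-frame activity counts."""
    x = series.counts
    if binning == "linear":
        edges = np.histogram_bin_edges(x, bins=bins)
    elif binning == "logarithmic":
        pos = x[x > 0]
        if pos.size == 0:
            raise InputError("logarithmic binning needs positive counts")
        edges = np.geomspace(pos.min(), pos.max() * (1 + 1e-12), bins + 1)
        x = pos
    else:
        raise InputError(f"unknown binning: {binning!r}")
    return _npd_from_histogram(x, edges, binning)


def _npd_from_histogram(x, edges, binning) -> NormalizedProbabilityDensity:
    counts, edges = np.histogram(x, bins=edges)
    widths = np.diff(edges)
    centers = 0.5 * (edges[:-1] + edges[1:]) if binning == "linear" \
        else np.sqrt(edges[:-1] * edges[1:])
    density = counts / (widths * max(counts.sum(), 1))
    integral = np.trapezoid(density, centers)
    if integral > 0:
        density = density / integral
    return NormalizedProbabilityDensity(bin_centers=centers, density=density,
                                        binning=binning)


def find_activity_valley(npd: NormalizedProbabilityDensity,
                         smooth: int = 5) -> float:
    """Locate the valley between the two activity modes.

    The density is smoothed with a moving average; the valley is the
    minimum of the smoothed density strictly between the two largest local
    maxima.  Falls back to the global density minimum between the first and
    last bins when no two modes are found.
    """
    d = npd.density
    if smooth > 1:
        kernel = np.ones(smooth) / smooth
        d = np.convolve(d, kernel, mode="same")
    # local maxima of the smoothed density
    peaks = [i for i in range(1, d.size - 1) if d[i] >= d[i - 1] and d[i] >= d[i + 1]]
    if len(peaks) < 2:
        i = int(np.argmin(d[1:-1])) + 1
        return float(npd.bin_centers[i])
    top2 = sorted(sorted(peaks, key=lambda i: d[i], reverse=True)[:2])
    lo, hi = top2
    between = d[lo:hi + 1]
    # centre of the tied-minimum plateau, so an empty gap maps to its middle
    ties = np.flatnonzero(between <= between.min() + 1e-300)
    i = lo + int(ties[len(ties) // 2])
    return float(npd.bin_centers[i])


def _runs(active_mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Run-length encode a boolean mask -> (run_lengths, run_states)."""
    n = active_mask.size
    change = np.flatnonzero(np.diff(active_mask.astype(np.int8))) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [n]])
    lengths = ends - starts
    states = active_mask[starts]
    return lengths, states


def extract_residence_times(series: ActivityTimeSeries,
                            activity_threshold: float = 12.0,
                            boundary_policy: Literal["keep", "drop_edges"] = "drop_edges",
                            ) -> ResidenceTimeSeries:
    """Threshold an activity trace into alternating residence times.

    Frames with ``count >= activity_threshold`` are active.  The first and
    last runs are censored (their true durations extend beyond the record);
    ``drop_edges`` (default) excludes them, ``keep`` retains every run so
    that the run lengths sum exactly to the number of frames.
    """
    mask = series.counts >= activity_threshold
    lengths, states = _runs(mask)
    degenerate = lengths.size == 1
    if degenerate:
        warnings.warn("series is entirely one state; residence series is degenerate",
                      stacklevel=2)
    if boundary_policy == "drop_edges":
        lengths = lengths[1:-1]
        states = states[1:-1]
    elif boundary_policy != "keep":
        raise InputError(f"unknown boundary_policy: {boundary_policy!r}")
    active = lengths[states]
    inactive = lengths[~states]
    first = "active" if (states.size and states[0]) else "inactive"
    return ResidenceTimeSeries(active_runs=active, inactive_runs=inactive,
                               first_state=first, dt=series.dt,
                               boundary_policy=boundary_policy,
                               degenerate=degenerate,
                               meta={"activity_threshold": activity_threshold})
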