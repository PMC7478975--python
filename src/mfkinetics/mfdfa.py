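"""Multifractal detrended fluctuation analysis (MF-DFA).

The analysis proceeds in four stages.  (1) The series is converted to its
profile, the cumulative sum of deviations from the mean.  (2) For every
scale s the profile is cut into Ns = floor(n/s) non-overlapping segments
from the start and another Ns from the end (dual-end segmentation, so the
flanking remainder is never discarded); each of the 2Ns segments is
detrended by a least-squares polynomial (linear by default) and its mean
squared residual f^2(v, s) recorded.  (3) The order-q fluctuation function

    F(q, s) = { (1/2Ns) sum_v [f^2(v, s)]^(q/2) }^(1/q),   q != 0
    F(0, s) = exp{ (1/4Ns) sum_v ln f^2(v, s) }

is regressed in log10-log10 space against s, giving the generalized Hurst
exponent H(q).  (4) The singularity spectrum follows from the Legendre-type
transform h(q) = H(q) + q dH/dq and D(h) = q (h - H) + 1; the spectrum is
summarized by h_peak (h at the spectrum maximum, D ~ 1 — the global Hurst
exponent) and the width h(q_min) - h(q_max), an index of multifractality.

At q = 2 the pipeline reduces exactly to plain detrended fluctuation
analysis.  Negative q emphasizes the weakly fluctuating segments;
zero-fluctuation segments would make F diverge there and are excluded (and
counted) for q <= 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import logsumexp

from .errors import DegenerateSeriesError, FitError, InputError

__all__ = [
    "MFDFAConfig", "ProfileSeries", "FluctuationMatrix", "MultifractalSpectrum",
    "profile", "default_scales", "default_q_grid", "fluctuation_function",
    "generalized_hurst", "singularity_spectrum", "mfdfa_spectrum",
    "analyze_residence_series",
]


@dataclass
class MFDFAConfig:
    """Tunable knobs of the analysis.

    q grid spans [q_min, q_max] with n_q points (default 41 points on
    [-10, 10]); scales are n_scales log-spaced integers from s_min up to
    n/4; detrending is linear.  ``fit_range`` optionally restricts the
    scale band used for the H(q) regression (in samples).
    """

    q_min: float = -10.0
    q_max: float = 10.0
    n_q: int = 41
    s_min: int = 16
    n_scales: int = 20
    detrend_order: int = 1
    fit_range: Optional[tuple[float, float]] = None

    def q_grid(self) -> np.ndarray:
        return default_q_grid(self.q_min, self.q_max, self.n_q)

    def scale_grid(self, n: int) -> np.ndarray:
        return default_scales(n, s_min=self.s_min, n_scales=self.n_scales)


@dataclass
class ProfileSeries:
    """Cumulative sum of mean-subtracted input."""

    values: np.ndarray

    @property
    def n(self) -> int:
        return int(self.values.size)


@dataclass
class FluctuationMatrix:
    q_values: np.ndarray
    scales: np.ndarray
    F: np.ndarray                     # shape (n_q, n_scales)
    n_segments: np.ndarray            # 2*Ns per scale
    excluded_segments: np.ndarray     # zero-fluctuation segments per scale
    detrend_order: int = 1
    degenerate: bool = False


@dataclass
class MultifractalSpectrum:
    q_values: np.ndarray
    H: np.ndarray
    h: np.ndarray
    D: np.ndarray
    h_peak: float
    width: float
    quality_flags: list = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "q": self.q_values.tolist(), "H": self.H.tolist(),
            "h": self.h.tolist(), "D": self.D.tolist(),
            "h_peak": self.h_peak, "width": self.width,
            "quality_flags": list(self.quality_flags),
            "diagnostics": self.diagnostics,
        }


def profile(series) -> ProfileSeries:
    """Cumulative sum of deviations from the mean."""
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 16:
        raise InputError("profile needs a 1-D series of length >= 16")
    if not np.all(np.isfinite(x)):
        raise InputError("series contains non-finite values")
    return ProfileSeries(values=np.cumsum(x - x.mean()))


def default_q_grid(q_min: float = -10.0, q_max: float = 10.0,
                   n_q: int = 41) -> np.ndarray:
    if n_q < 5 or q_min >= q_max:
        raise InputError("need n_q >= 5 and q_min < q_max")
    return np.linspace(q_min, q_max, n_q)


def default_scales(n: int, s_min: int = 16, n_scales: int = 20) -> np.ndarray:
    """Log-spaced unique integer scales from s_min to n // 4."""
    s_max = n // 4
    if s_max < s_min:
        raise InputError(f"series too short for scale grid (n={n}, s_min={s_min})")
    grid = np.geomspace(s_min, s_max, n_scales)
    return np.unique(np.rint(grid).astype(int))


def _segment_fluctuations(y: np.ndarray, s: int, order: int) -> np.ndarray:
    """Mean squared detrending residual in each of the 2*Ns segments."""
    n = y.size
    ns = n // s
    fwd = y[:ns * s].reshape(ns, s)
    bwd = y[n - ns * s:].reshape(ns, s)
    segs = np.concatenate([fwd, bwd], axis=0)
    t = np.arange(s, dtype=float)
    design = np.vander(t, order + 1)            # columns t^order .. 1
    pinv = np.linalg.pinv(design)
    coef = segs @ pinv.T
    resid = segs - coef @ design.T
    return np.mean(resid ** 2, axis=1)


def fluctuation_function(profile_values, scales=None, q_values=None,
                         detrend_order: int = 1) -> FluctuationMatrix:
    """Order-q fluctuation function F(q, s) of an (already profiled) series.

    ``profile_values`` is the output of :func:`profile` (or any series to
    be segmented directly).  Dual-end segmentation yields 2*Ns segments per
    scale; moments are accumulated in log space for numerical stability at
    |q| = 10.
    """
    y = profile_values.values if isinstance(profile_values, ProfileSeries) \
        else np.asarray(profile_values, dtype=float)
    n = y.size
    scales = np.asarray(default_scales(n) if scales is None else scales, dtype=int)
    if np.any(np.diff(scales) <= 0):
        raise InputError("scales must be strictly increasing")
    if scales[0] < 4 or scales[-1] > n // 4:
        raise InputError("scales must lie within [4, n/4]")
    q = np.asarray(default_q_grid() if q_values is None else q_values, dtype=float)

    F = np.empty((q.size, scales.size))
    n_segments = np.empty(scales.size, dtype=int)
    excluded = np.zeros(scales.size, dtype=int)
    qz = np.isclose(q, 0.0)
    # residuals below float precision of the profile magnitude count as zero
    f2_floor = (1e-10 * max(1.0, float(np.max(np.abs(y), initial=0.0)))) ** 2
    any_signal = False
    for j, s in enumerate(scales):
        f2 = _segment_fluctuations(y, int(s), detrend_order)
        m = f2.size
        n_segments[j] = m
        nonzero = f2 > f2_floor
        excluded[j] = int(m - nonzero.sum())
        if excluded[j] == m:
            F[:, j] = 0.0
            continue
        any_signal = True
        logf2 = np.log(f2[nonzero])
        mz = logf2.size
        # q != 0: F = ((1/denom) sum f2^(q/2))^(1/q); zero segments drop out
        # for q > 0 (they contribute nothing) and are excluded for q < 0.
        qa = q[~qz]
        denom = np.where(qa > 0, m, mz)
        lse = logsumexp(np.outer(qa / 2.0, logf2), axis=1)
        F[~qz, j] = np.exp((lse - np.log(denom)) / qa)
        if qz.any():
            F[qz, j] = np.exp(0.5 * logf2.mean())
    if not any_signal:
        warnings.warn("all segments have zero fluctuation; series is degenerate",
                      stacklevel=2)
    return FluctuationMatrix(q_values=q, scales=scales, F=F,
                             n_segments=n_segments, excluded_segments=excluded,
                             detrend_order=detrend_order,
                             degenerate=not any_signal)


def generalized_hurst(fmat: FluctuationMatrix,
                      fit_range: Optional[tuple[float, float]] = None) -> np.ndarray:
    """Per-q slope of log10 F(q, s) against log10 s."""
    if fmat.degenerate:
        raise DegenerateSeriesError("fluctuation matrix is degenerate (all-zero)")
    s = fmat.scales.astype(float)
    in_range = np.ones(s.size, dtype=bool)
    if fit_range is not None:
        in_range = (s >= fit_range[0]) & (s <= fit_range[1])
    if in_range.sum() < 4:
        raise FitError("need >= 4 scales inside fit_range")
    H = np.empty(fmat.q_values.size)
    logs = np.log10(s)
    for i in range(fmat.q_values.size):
        Fi = fmat.F[i]
        ok = in_range & (Fi > 0) & np.isfinite(Fi)
        if ok.sum() < in_range.sum():
            warnings.warn("non-positive F values excluded from H(q) fit",
                          stacklevel=2)
        if ok.sum() < 4:
            raise FitError("fewer than 4 usable scales for H(q) fit")
        H[i] = np.polyfit(logs[ok], np.log10(Fi[ok]), 1)[0]
    return H


def singularity_spectrum(H: np.ndarray, q_values: np.ndarray,
                         derivative: str = "central") -> MultifractalSpectrum:
    """Singularity spectrum from H(q).

    h = H + q dH/dq with dH/dq by central finite differences (one-sided at
    the grid ends); D = q (h - H) + 1.  h_peak is h at the q maximizing D
    (ties resolved toward q = 0); width = h(q_min) - h(q_max).
    """
    H = np.asarray(H, dtype=float)
    q = np.asarray(q_values, dtype=float)
    if H.size != q.size or H.size < 5:
        raise InputError("H must match q_values and hold >= 5 points")
    if derivative == "central":
        dH = np.gradient(H, q)
    elif derivative == "spline":
        from scipy.interpolate import UnivariateSpline
        dH = UnivariateSpline(q, H, k=3, s=len(q)).derivative()(q)
    else:
        raise InputError(f"unknown derivative scheme: {derivative!r}")
    h = H + q * dH
    D = q * (h - H) + 1.0

    flags = []
    best = D.max()
    candidates = np.flatnonzero(D >= best - 1e-12)
    peak_idx = candidates[np.argmin(np.abs(q[candidates]))]
    h_peak = float(h[peak_idx])
    width = float(h[0] - h[-1])
    if best > 1.0 + 1e-6:
        flags.append("D_exceeds_1")
    if np.any(np.diff(h) > 1e-12):
        flags.append("non_monotone_h")
    if width < 0:
        flags.append("negative_width")
    return MultifractalSpectrum(q_values=q, H=H, h=h, D=D, h_peak=h_peak,
                                width=width, quality_flags=flags)


def mfdfa_spectrum(series, config: Optional[MFDFAConfig] = None,
                   ) -> MultifractalSpectrum:
    """Full MF-DFA chain on a raw series: profile -> F(q, s) -> H(q) -> spectrum."""
    config = config or MFDFAConfig()
    x = np.asarray(series, dtype=float)
    prof = profile(x)
    fmat = fluctuation_function(prof, scales=config.scale_grid(x.size),
                                q_values=config.q_grid(),
                                detrend_order=config.detrend_order)
    H = generalized_hurst(fmat, fit_range=config.fit_range)
    spec = singularity_spectrum(H, fmat.q_values)
    spec.diagnostics = {
        "n": int(x.size),
        "scales": fmat.scales.tolist(),
        "excluded_segments": fmat.excluded_segments.tolist(),
        "detrend_order": fmat.detrend_order,
    }
    return spec


def analyze_residence_series(durations: Sequence[float],
                             config: Optional[MFDFAConfig] = None,
                             ) -> MultifractalSpectrum:
    """MF-DFA of a residence-time series (one duration per round).

    Series shorter than 100 rounds are rejected; shorter than 500 rounds a
    warning is issued — the scale grid then spans too narrow a band for the
    H(q) regression to be reliable.
    """
    d = np.asarray(durations, dtype=float)
    if d.size < 100:
        raise InputError("need >= 100 residence times for MF-DFA")
    if d.size < 500:
        warnings.warn("fewer than 500 residence times; spectrum estimates are noisy",
                      stacklevel=2)
    return mfdfa_spectrum(d, config=config)
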