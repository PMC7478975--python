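"""Synthetic inputs with the statistical structure the analysis assumes.

Four families of generators:

* reference noises (white, pink/1-over-f, Brown) used to calibrate the
  multifractal estimator — their spectrum peaks sit at Hurst exponents of
  about 0.5, 1.0 and 1.5;
* log-normal multiplicative cascades, the canonical multifractal series,
  whose spectrum width grows with the weight variability ``sigma``;
* two-state activity traces: alternating active/inactive bouts whose
  durations follow truncated power laws, ordered by rank-matching against
  fractional Gaussian noise so the residence-time series carries long-range
  correlation, and emitted as a bimodal activity trace;
* moving-blob grayscale frame stacks for exercising the pixel counter.

Every generator takes an explicit integer seed and is deterministic for a
fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .activity import ActivityTimeSeries
from .errors import ConfigurationError, InputError
from .residence import ResidenceTimeSeries

__all__ = [
    "RawSeries", "TwoStateParams", "FrameStack",
    "generate_noise", "generate_cascade", "generate_two_state_activity",
    "generate_frame_stack", "sample_truncated_power_law",
    "truncated_power_law_cdf", "fractional_gaussian_noise",
]


@dataclass(frozen=True)
class RawSeries:
    """A plain numeric series tagged with its generating recipe."""

    values: np.ndarray
    seed: int
    kind_label: str

    @property
    def n(self) -> int:
        return int(self.values.size)


@dataclass
class TwoStateParams:
    """Settings of the two-state bout generator.

    Exponents ``a_*`` are the power-law exponents of the truncated
    residence-time densities (p(t) ~ t^-a on [t_min, t_max], seconds);
    ``level_*`` are mean activity amplitudes in pixels/frame;
    ``correlation_hurst`` sets the Hurst exponent of the fractional
    Gaussian noise used to order the bout durations in time.
    """

    a_active: float = 1.89
    a_inactive: float = 1.62
    t_min_active: float = 0.1
    t_max_active: float = 50.0
    t_min_inactive: float = 0.1
    t_max_inactive: float = 200.0
    level_active: float = 30.0
    level_inactive: float = 0.0
    amplitude_noise_sd: float = 2.0
    n_rounds: int = 1000
    dt: float = 0.05
    correlation_hurst: float = 0.5

    def validate(self) -> None:
        if self.a_active <= 1 or self.a_inactive <= 1:
            raise InputError("power-law exponents must exceed 1")
        for lo, hi in ((self.t_min_active, self.t_max_active),
                       (self.t_min_inactive, self.t_max_inactive)):
            if not 0 < lo < hi:
                raise InputError("duration bounds must satisfy 0 < t_min < t_max")
        if self.level_inactive >= self.level_active:
            raise InputError("level_inactive must be below level_active")
        if self.n_rounds < 1:
            raise InputError("n_rounds must be >= 1")
        if self.dt <= 0:
            raise InputError("dt must be positive")
        if not 0 < self.correlation_hurst < 1:
            raise InputError("correlation_hurst must lie in (0, 1)")


@dataclass
class FrameStack:
    """A stack of equally sized 8-bit grayscale frames."""

    frames: np.ndarray            # (n_frames, height, width) uint8
    dt: float = 0.05

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise InputError("a frame stack needs >= 2 frames of equal shape")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def height(self) -> int:
        return int(self.frames.shape[1])

    @property
    def width(self) -> int:
        return int(self.frames.shape[2])


# ---------------------------------------------------------------------------
# reference noises

def generate_noise(kind: str, n: int, seed: int) -> RawSeries:
    """Generate white, pink (1/f) or Brown noise of length ``n``.

    white: iid standard Gaussian.  brown: cumulative sum of the white
    series drawn from the same seed.  pink: frequency-domain synthesis —
    complex Gaussian spectral amplitudes scaled by f^(-1/2) so the power
    spectral density falls as 1/f, inverse-transformed to a real series.
    """
    if n < 64:
        raise InputError("n must be >= 64")
    if kind not in ("white", "pink", "brown"):
        raise ConfigurationError(f"unknown noise kind: {kind!r}")
    rng = np.random.default_rng(seed)
    if kind == "white":
        values = rng.standard_normal(n)
    elif kind == "brown":
        values = np.cumsum(rng.standard_normal(n))
    else:
        values = _spectral_noise(rng, n, beta=1.0)
    return RawSeries(values=values, seed=seed, kind_label=kind)


def _spectral_noise(rng: np.random.Generator, n: int, beta: float) -> np.ndarray:
    """Real series with power spectral density ~ f^(-beta)."""
    freqs = np.fft.rfftfreq(n)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-beta / 2.0)
    re = rng.standard_normal(freqs.size)
    im = rng.standard_normal(freqs.size)
    spectrum = amp * (re + 1j * im)
    spectrum[0] = 0.0
    if n % 2 == 0:
        spectrum[-1] = spectrum[-1].real
    x = np.fft.irfft(spectrum, n=n)
    return x / x.std()


# ---------------------------------------------------------------------------
# multiplicative cascade

def generate_cascade(levels: int, sigma: float, seed: int,
                     return_weights: bool = False):
    """Log-normal multiplicative cascade of length 2**levels.

    Starting from an all-ones series, level k splits the series into 2**k
    equal segments and multiplies each by an independent log-normal weight
    exp(eps), eps ~ Normal(0, sigma_seg^2), where the per-segment standard
    deviation sigma_seg = |Normal(0, sigma^2)| is itself random.  The
    two-layer randomness makes segments heterogeneous in volatility, and
    the spectrum width grows with ``sigma``.

    With ``return_weights=True`` also returns the list of per-level weight
    arrays (level k holds 2**k weights) for structural verification.
    """
    if not 1 <= levels <= 24:
        raise InputError("levels must lie in [1, 24]")
    if sigma < 0:
        raise InputError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    n = 2 ** levels
    values = np.ones(n)
    weight_tree = []
    for k in range(1, levels + 1):
        m = 2 ** k
        seg_sd = np.abs(rng.normal(0.0, sigma, size=m))
        weights = np.exp(rng.normal(0.0, 1.0, size=m) * seg_sd)
        values *= np.repeat(weights, n // m)
        weight_tree.append(weights)
    series = RawSeries(values=values, seed=seed, kind_label="cascade")
    if return_weights:
        return series, weight_tree
    return series


# ---------------------------------------------------------------------------
# truncated power-law sampling and fGn ordering

def truncated_power_law_cdf(t, a: float, t_min: float, t_max: float):
    """CDF of the density p(t) ~ t^-a truncated to [t_min, t_max], a > 1."""
    t = np.asarray(t, dtype=float)
    e = 1.0 - a
    num = t ** e - t_min ** e
    den = t_max ** e - t_min ** e
    return np.clip(num / den, 0.0, 1.0)


def sample_truncated_power_law(a: float, t_min: float, t_max: float,
                               size: int, rng: np.random.Generator):
    """Inverse-CDF samples from the truncated power law p(t) ~ t^-a."""
    if a <= 1:
        raise InputError("exponent a must exceed 1")
    if not 0 < t_min < t_max:
        raise InputError("need 0 < t_min < t_max")
    u = rng.uniform(size=size)
    e = 1.0 - a
    return (t_min ** e + u * (t_max ** e - t_min ** e)) ** (1.0 / e)


def fractional_gaussian_noise(hurst: float, n: int,
                              rng: np.random.Generator) -> np.ndarray:
    """Exact fractional Gaussian noise via circulant (Davies-Harte) embedding.

    Returns n increments of fractional Brownian motion with the given Hurst
    exponent; hurst = 0.5 reduces to iid Gaussian noise.
    """
    if not 0 < hurst < 1:
        raise InputError("hurst must lie in (0, 1)")
    if hurst == 0.5:
        return rng.standard_normal(n)
    k = np.arange(n + 1, dtype=float)
    h2 = 2.0 * hurst
    gamma = 0.5 * ((k + 1) ** h2 - 2 * k ** h2 + np.abs(k - 1) ** h2)
    row = np.concatenate([gamma, gamma[n - 1:0:-1]])
    lam = np.fft.fft(row).real
    lam = np.clip(lam, 0.0, None)       # clip tiny negative eigenvalues
    m = row.size
    z = rng.standard_normal(m) + 1j * rng.standard_normal(m)
    y = np.fft.ifft(np.sqrt(lam) * z) * np.sqrt(m)
    return y.real[:n]


def _rank_match(values: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Reorder ``values`` so their ranks follow the ranks of ``reference``."""
    order = np.argsort(np.argsort(reference))
    return np.sort(values)[order]


# ---------------------------------------------------------------------------
# two-state activity generator

def generate_two_state_activity(params: TwoStateParams, seed: int,
                                ) -> tuple[ActivityTimeSeries, ResidenceTimeSeries]:
    """Emit a bimodal activity trace plus its ground-truth residence series.

    Durations are drawn from truncated power laws, temporally ordered by
    rank-matching against fractional Gaussian noise with Hurst
    ``params.correlation_hurst``, rounded to whole frames (minimum one
    frame), and concatenated as alternating active/inactive bouts starting
    in the active state.  The activity amplitude is the state level plus
    Gaussian noise, clipped at zero.  The returned ground truth uses the
    ``keep`` boundary policy, so its run lengths sum exactly to the trace
    length.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    nr = params.n_rounds

    act = sample_truncated_power_law(params.a_active, params.t_min_active,
                                     params.t_max_active, nr, rng)
    ina = sample_truncated_power_law(params.a_inactive, params.t_min_inactive,
                                     params.t_max_inactive, nr, rng)
    act = _rank_match(act, fractional_gaussian_noise(params.correlation_hurst, nr, rng))
    ina = _rank_match(ina, fractional_gaussian_noise(params.correlation_hurst, nr, rng))

    act_frames = np.maximum(1, np.rint(act / params.dt).astype(np.int64))
    ina_frames = np.maximum(1, np.rint(ina / params.dt).astype(np.int64))

    total = int(act_frames.sum() + ina_frames.sum())
    counts = np.empty(total)
    pos = 0
    for i in range(nr):
        for frames, level in ((act_frames[i], params.level_active),
                              (ina_frames[i], params.level_inactive)):
            block = level + rng.normal(0.0, params.amplitude_noise_sd, size=frames)
            counts[pos:pos + frames] = np.maximum(block, 0.0)
            pos += frames
    series = ActivityTimeSeries(counts=counts, dt=params.dt,
                                meta={"source": "two_state_generator", "seed": seed})
    truth = ResidenceTimeSeries(active_runs=act_frames, inactive_runs=ina_frames,
                                first_state="active", dt=params.dt,
                                boundary_policy="keep",
                                meta={"ground_truth": True, "seed": seed})
    return series, truth


# ---------------------------------------------------------------------------
# moving-blob frame stacks

def generate_frame_stack(n_frames: int, blob_radius: float, step: float,
                         height: int = 120, width: int = 240, seed: int = 0,
                         noise_sd: float = 0.0, dt: float = 0.05,
                         background: int = 200, blob_intensity: int = 40,
                         axis_ratio: float = 0.6,
                         start: Optional[tuple[float, float]] = None) -> FrameStack:
    """Dark elliptical blob translating ``step`` pixels/frame on a bright field.

    The blob (semi-axes ``blob_radius`` horizontally, ``axis_ratio *
    blob_radius`` vertically) moves horizontally from ``start`` (default:
    left margin, vertical centre).  Optional Gaussian sensor noise of
    ``noise_sd`` intensity units is added per pixel.  The trajectory must
    stay inside the frame.
    """
    if n_frames < 2:
        raise InputError("need at least 2 frames")
    ry = axis_ratio * blob_radius
    if start is None:
        start = (blob_radius + 1.0, height / 2.0)
    x0, y0 = start
    x_end = x0 + step * (n_frames - 1)
    if (x0 - blob_radius < 0 or x_end + blob_radius >= width
            or y0 - ry < 0 or y0 + ry >= height):
        raise InputError("blob trajectory leaves the frame")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:height, 0:width]
    frames = np.empty((n_frames, height, width), dtype=np.uint8)
    for t in range(n_frames):
        cx = x0 + step * t
        mask = ((xx - cx) / blob_radius) ** 2 + ((yy - y0) / ry) ** 2 <= 1.0
        img = np.full((height, width), float(background))
        img[mask] = blob_intensity
        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd, size=img.shape)
        frames[t] = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return FrameStack(frames=frames, dt=dt)


def blob_mask(cx: float, cy: float, blob_radius: float, height: int, width: int,
              axis_ratio: float = 0.6) -> np.ndarray:
    """Boolean footprint of the elliptical blob at centre (cx, cy)."""
    yy, xx = np.mgrid[0:height, 0:width]
    ry = axis_ratio * blob_radius
    return ((xx - cx) / blob_radius) ** 2 + ((yy - cy) / ry) ** 2 <= 1.0
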