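# Methods

## Activity quantification

Movement is quantified from grayscale frame stacks as the number of pixels
whose intensity *rises* by more than a threshold between consecutive
frames (signed difference on the −256..+256 scale, default threshold 12).
A dark body on a bright background brightens the pixels it vacates, so the
count measures the area swept per frame interval (default dt = 0.05 s,
i.e. 20 frames/s).  A flag switches to |difference| > threshold, which
additionally counts newly covered pixels (roughly doubling counts for
disjoint footprints); the signed form is the default and the one all
downstream defaults assume.  An optional despiking hook replaces isolated
single-frame counts exceeding a configurable multiple (default 10×) of the
local median — a light-weight stand-in for camera/illumination artifact
compensation, not a general denoiser.

## Activity classes and motility periods

Long recordings of starving animals decay from a high-motility to a
low-motility regime.  Animals are classified from two statistics: AA0-3,
the mean activity of the early half of the record, and a retention ratio.
Defaults: AA0-3 ≥ 0.75 counts/frame marks a "high early activity" animal
(the low bar reflects how sparse bursty swimming signals are), and
retention = AA3-6/AA0-3 ≥ 0.01 marks an animal still measurably active in
the late half.  High early activity with retention → Long class; high
early activity without retention → Mid; low early activity → Short.  The
ratio direction is exposed (`ratio_mode`) because the literature states it
in the reciprocal form; with the reciprocal convention the comparison
direction flips and the threshold must be chosen accordingly.  Both
thresholds are setup-dependent and configurable.  The high-motility period
is the leading 50% / 20% / 10% of the record for Long / Mid / Short
animals; the split partitions the record exactly, and a per-cohort
override exists for continuously swimming (mutant-like) cohorts analysed
over, say, the first tenth only.

## Residence times

Frames with activity ≥ 12 counts/frame (the valley of the bimodal activity
amplitude distribution; an automatic valley finder is provided for
non-default data) are active; maximal runs of constant state give the
residence times.  Run lengths are stored as integers, so under the `keep`
boundary policy Σ durations = n_frames × dt holds exactly.  The first and
last runs are censored (their true lengths are unknown); the default
`drop_edges` policy removes them.  No minimum-duration filter is applied:
single-frame crossings count as bouts.

## Power-law fits

Residence-time NPDs use logarithmic binning by default (40 bins; linear
binning behind a flag) with densities renormalized to a unit trapezoid
integral; the log-log fit y = −a·x − b is an unweighted least-squares
regression of log10(density) on log10(duration) restricted to a fixed
band — 0.3–5.0 s for active, 1–50 s for inactive states.  Unweighted
log-space regression minimizes relative error, so the rare long durations
do not dominate the fit.  Zero-density bins in the band are excluded with
a warning; fewer than three usable bins is an error.  A Hill-type
maximum-likelihood exponent is available as a cross-check only; the
regression defines the reported a and b.

## MF-DFA

Profile: cumulative sum of mean-subtracted input.  Segmentation: at each
scale s, Ns = ⌊n/s⌋ segments from the start *and* Ns from the end, so the
flanking remainder is covered (2Ns segments total).  Detrending: linear by
default (higher orders available, unused by default).  Moments are
accumulated in log space (logsumexp), which keeps q = ±10 stable over the
~300-decade dynamic range f² can span.  q = 0 uses the logarithmic-mean
limit.  Zero-fluctuation segments (mean squared residual below the square
of 1e-10 × the profile magnitude) would make F diverge for q < 0; they are
excluded for q ≤ 0 and counted in the diagnostics.  A series whose every
segment detrends to zero (e.g. a pure linear profile) is flagged
degenerate.

Defaults: 41 q-values evenly spaced on [−10, 10]; 20 log-spaced integer
scales from 16 to n/4; H(q) fit over all scales (a sub-band is
configurable).  dH/dq uses central finite differences on the q-grid
(one-sided at the ends); a smoothing-spline derivative is available behind
a flag.  h_peak is h at the q maximizing D, ties resolved toward q = 0
(D(0) = 1 identically, since h − H vanishes there); width is
h(q_min) − h(q_max).  A folded (non-monotone) spectrum is returned with a
quality flag rather than raised.

Calibration: at n = 2^16, averaged over five seeds, h_peak is ≈ 0.50 /
1.00 / 1.49 for white / pink / Brown noise (theory 0.5 / 1.0 / 1.5), and
the deterministic binomial p-model reproduces its closed-form spectrum
width within ~5% at 2^12 samples.

Residence series shorter than 100 rounds are rejected and shorter than 500
produce a warning: the scale band 16..n/4 then spans under a decade and
H(q) fits become unstable.

## Synthetic data

The generators emulate the statistical structure the analysis assumes, not
worm biology (no posture, no chamber geometry).

* **Noises.**  White: iid standard Gaussian.  Brown: cumulative sum of the
  white series of the same seed.  Pink: spectral synthesis — complex
  Gaussian amplitudes scaled by f^(−1/2), inverse-transformed; adequate
  for the ±0.1 calibration tolerance, and swappable for an exact
  circulant-embedding generator behind the same contract (one is already
  used internally for fGn).
* **Cascades.**  Binary multiplicative cascade on 2^levels points;
  at level k each of the 2^k segments is multiplied by exp(ε),
  ε ~ N(0, σ_seg²), with σ_seg = |N(0, sigma²)| drawn per segment.  The
  two-layer randomness gives volatility heterogeneity with a single knob.
  Spectrum width grows markedly with sigma (≈ 0.43 → 0.96 → 1.58 for
  sigma = 0.1 → 0.3 → 0.5 at levels = 14) while h_peak drifts far less
  (≈ 1.00 → 1.19); the drift is a finite-size heavy-tail effect of this
  recipe, monotone in sigma and small between adjacent sigma values.
* **Two-state traces.**  Active/inactive durations are inverse-CDF samples
  from truncated power laws p(t) ∝ t^(−a) on [t_min, t_max]; default
  exponents 1.89 (active) and 1.62 (inactive) with t_max = 50 s and 200 s
  reproduce the wild-type Long-class high-motility setting.  Temporal
  ordering is imposed by rank-matching each duration sequence against
  exact (Davies–Harte) fractional Gaussian noise with Hurst
  `correlation_hurst`, a Schreiber-style amplitude adjustment that endows
  the residence-time *series* with long-range correlation without claiming
  a generative mechanism.  Durations are rounded to whole frames (min. one
  frame), so the ground truth conserves trace length exactly.  Note that
  for strongly heavy-tailed durations (a ≈ 1.9, t_max ≳ 50 s) the
  *apparent* h_peak of even an iid-ordered series exceeds 0.5 at finite n
  — heavy tails mimic persistence — so Hurst self-consistency checks use
  milder tails (t_max = 10 s).
* **Frame stacks.**  A dark ellipse (intensity 40, semi-axes r and 0.6 r)
  on a bright field (intensity 200) translating at a constant step, with
  optional Gaussian sensor noise.  Footprint geometry is exposed so tests
  can compute exact set-difference pixel counts.

What passing tests show — and don't.  The generators reproduce
bimodality, truncated power-law dwell times, long-range correlation and
multifractal clustering, but real recordings additionally contain
illumination drift, camera noise correlated across pixels, posture-driven
amplitude structure, and slow non-stationary activity decay within
periods.  Passing the synthetic suite validates the estimators and the
plumbing, not any biological claim about a particular dataset.

## Pipeline

`run_pipeline` applies classify → split → extract → fit + MF-DFA per
animal, isolating per-animal failures (a single-state trace, an unreadable
file) as recorded errors/notes so one degenerate animal cannot abort a
cohort.  Cohort tables report mean ± sd of (a, b) and (h_peak, width) per
class/period/state with pairwise Student-t p-values.  The configuration is
a single declarative object, echoed (with a content hash) into the output
manifest, because every threshold in the chain (12, 12, 0.75, 0.01, fit
bands) is imaging-setup-specific and must be auditable.  MF-DFA is skipped
(with a note) for groups under 100 durations.

## Known limitations

* The H(q) scale band and fit range are conventional defaults; exponents
  from short series depend on them more than the ±0.1 calibration
  tolerance suggests.
* No wavelet-leader or Chhabra–Jensen estimator, no surrogate-based
  significance test for multifractality, and no bootstrap CIs on power-law
  exponents; across-animal mean ± sd is the only dispersion reported.
* The pixel counter assumes a single animal per field (one ROI); chamber
  grids must be split upstream.
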