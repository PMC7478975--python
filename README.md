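# mfkinetics

Multifractal kinetics of episodic animal behavior.

*C. elegans* in liquid alternates between bouts of vigorous swimming and
quiescence on time scales from sub-seconds to hours.  `mfkinetics` turns
long behavioral recordings of such episodic motion into quantitative
kinetics: it reduces frame stacks to an activity signal by pixel counting,
segments the signal into alternating active/inactive residence (dwell)
times by thresholding, characterizes the residence-time distributions by
power-law fits, and measures long-range temporal correlation and
clusterization of the residence-time series with multifractal detrended
fluctuation analysis (MF-DFA).  The package targets researchers analyzing
two-state behavioral time series (worm swimming, roaming/dwelling, fly
activity bouts) who need the whole chain — or any single stage — as tested,
reusable library code.

## The statistics at the core

**Residence-time power laws.** Durations t of uninterrupted visits to one
behavioral state follow heavy-tailed densities.  On log-log axes the
normalized probability density (NPD) is fit with a line

    log10 p(t) = -a · log10 t - b

by unweighted least squares, which minimizes relative error; the exponent
`a` and intercept `b` characterize the scale-free transition kinetics.
Default fit bands are 0.3–5 s (active) and 1–50 s (inactive).

**MF-DFA.** For a series x(i), the profile Y(k) = Σ(x(i) − ⟨x⟩) is cut, at
each scale s, into Ns = ⌊n/s⌋ segments from the start and Ns from the end;
each segment v is detrended by a least-squares line and yields a mean
squared residual f²(v, s).  The order-q fluctuation function is

    F(q, s) = { (1/2Ns) Σ_v [f²(v, s)]^(q/2) }^(1/q),  q ≠ 0
    F(0, s) = exp{ (1/4Ns) Σ_v ln f²(v, s) }

The generalized Hurst exponent H(q) is the slope of log F(q, s) vs log s;
the singularity spectrum follows from h(q) = H(q) + q·dH/dq and
D(h) = q·(h − H) + 1.  Two summaries matter: **h_peak**, the local Hurst
exponent at the spectrum peak (D ≈ 1), an index of long-range memory
(white/pink/Brown noise give ≈ 0.5/1.0/1.5), and the **width**
h(q=−10) − h(q=+10), an index of multifractality, i.e. of the variety of
local temporal clusters.  At q = 2 the chain reduces exactly to classic
DFA.

Synthetic generators (reference noises, log-normal multiplicative
cascades, two-state bout traces with truncated-power-law durations, moving
blob frame stacks) make every stage testable end to end without recorded
data.

## Worked example

From a synthetic two-state trace to recovered kinetics
(`examples/two_state_residence_powerlaw.py`):

```python
from mfkinetics import (TwoStateParams, generate_two_state_activity,
                        extract_residence_times, residence_npd, fit_powerlaw,
                        ACTIVE_FIT_RANGE, INACTIVE_FIT_RANGE)

params = TwoStateParams(a_active=1.89, a_inactive=1.62, n_rounds=20_000, dt=0.01)
series, truth = generate_two_state_activity(params, seed=3)
res = extract_residence_times(series, activity_threshold=12.0)
fit = fit_powerlaw(residence_npd(res.active_durations), fit_range=ACTIVE_FIT_RANGE)
```

Output:

```
trace: 7195347 frames at dt = 0.01 s (20.0 h), 20000 bout rounds
  active: a = 1.92 (generator 1.89), b = 0.92, r^2 = 0.998 over (0.3, 5.0) s
inactive: a = 1.63 (generator 1.62), b = 0.78, r^2 = 0.998 over (1.0, 50.0) s
```

The fitted slope magnitudes recover the generator exponents: the shallower
inactive-state slope (1.63 < 1.92) means long rests are relatively more
frequent than long swims — the signature contrast between the two
transition kinetics.  Each `examples/*.py` script demonstrates one
capability (noise calibration, cascade width, pixel counting, cohort
pipeline) and prints what the numbers mean.

A thin CLI mirrors the stages:

```bash
mfkinetics simulate twostate --n-rounds 2000 --seed 1 --out act.csv
mfkinetics residence --activity act.csv --out res.csv
mfkinetics powerlaw --residence res.csv --state active
mfkinetics run --inputs act.csv --out results/
```

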