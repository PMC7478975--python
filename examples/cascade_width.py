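"""Spectrum width as an index of multifractality.

Log-normal multiplicative cascades are genuinely multifractal: their
fluctuation scaling depends on the moment order q, so the singularity
spectrum is wide, and it widens as the weight variability sigma grows,
while the global Hurst exponent h_peak moves comparatively little.
"""

import numpy as np

from mfkinetics import generate_cascade, mfdfa_spectrum

for sigma in (0.1, 0.3, 0.5):
    widths, peaks = [], []
    for seed in range(5):
        spec = mfdfa_spectrum(generate_cascade(14, sigma, seed).values)
        widths.append(spec.width)
        peaks.append(spec.h_peak)
    print(f"sigma = {sigma}: width = {np.mean(widths):.2f}, "
          f"h_peak = {np.mean(peaks):.2f}")

print("\nwidth grows with sigma: richer local clustering, i.e. greater "
      "behavioral complexity when read from residence-time series.")
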