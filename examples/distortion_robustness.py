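"""Why uncalibrated web imagery is still usable for spectral statistics.

Applies random per-channel gain and gamma distortions -- the kind of
maltreatment images suffer before reaching the Internet -- to realistic
correlated RGB samples and measures how well the distorted values still
correlate with the truth.
"""

import numpy as np

from gamutkit.gamut_gen import DistortionParams, distortion_experiment
from gamutkit.gamut_stats import REFERENCE_PHYSICAL_COV

cov = REFERENCE_PHYSICAL_COV / 100.0  # unit peak variance
dp = DistortionParams(
    gamma_range=(0.5, 1.5), gain_range=(0.5, 1.5),
    n_draws=1000, n_samples=10_000, seed=1,
)
result = distortion_experiment(cov, np.zeros(3), dp)
print(f"median per-channel correlation: {result.median:.3f}")
print(f"interquartile range: ({result.q1:.3f}, {result.q3:.3f})")
print()
print("Even gamma errors of +-50% and channel gains off by +-50% leave the")
print("distorted values correlated ~0.99 with the truth: monotone")
print("distortions barely touch the covariance structure being mined.")
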