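"""A toy spectral world that reproduces natural color statistics.

Random reflectance spectra with an inverse-square articulation power
spectrum, binned into three bands, already show the opponent structure of
natural images; in the near-binary (telegraph-wave) limit the binned colors
collapse onto the six boundary-color cube edges.
"""

import numpy as np

from gamutkit import spectral_sim as ss
from gamutkit.gamut_stats import OPPONENT_AXES

params = ss.SpectralModelParams()  # correlation length = one bin width
rgb, summary = ss.model_ensemble(params, 10_000, seed=3)
corr = summary.correlation
print("binned-channel correlations (adjacent vs far):")
print(f"  corr(1,2) = {corr[0, 1]:.3f}, corr(2,3) = {corr[1, 2]:.3f}, "
      f"corr(1,3) = {corr[0, 2]:.3f}")
print(f"dominance statistic Z = {summary.z:.2f}")
for j, name in ((1, "red-blue"), (2, "green-purple")):
    cosine = abs(float(summary.eigenvectors[:, j] @ OPPONENT_AXES[:, j]))
    angle = np.degrees(np.arccos(min(1.0, cosine)))
    print(f"minor eigenvector {j} is {angle:.1f} degrees from the {name} axis")
print()

telegraph = ss.telegraph_limit_check(ss.telegraph_params(), 10_000, seed=8)
print(f"telegraph limit: {100 * telegraph.fraction_goethe:.1f}% of samples "
      f"within 0.05 of the six single-transition (edge color) cube edges")
print("occupancy of the six green/magenta edges:",
      sum(telegraph.other_counts.values()), "of", telegraph.n)
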