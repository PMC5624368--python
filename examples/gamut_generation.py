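"""Generate color gamuts from six-parameter signatures.

Draws opponent-channel deviates in the physical domain, maps them back
through the inverse opponent transform and the logistic squashing, and
renders swatch images for a natural ("sublunar") and an "alien" preset.
"""

import numpy as np

from gamutkit import gamut_gen as gg
from gamutkit import gamut_stats as gs
from gamutkit.images import write_image

for name, preset in (("sublunar", gg.sublunar_preset()),
                     ("alien", gg.alien_preset())):
    samples = gg.sample_gamut(preset, 1024, seed=7)
    corr = np.corrcoef(samples, rowvar=False)
    sig = gs.gamut_signature(samples)
    write_image(f"swatch_{name}.png", gg.render_swatch(samples, 32, 32, cell=8))
    print(f"{name} preset: sigmas {np.round(preset.sigmas, 3)}")
    print(f"  channel correlations R-G {corr[0, 1]:.2f}, "
          f"G-B {corr[1, 2]:.2f}, R-B {corr[0, 2]:.2f}")
    print(f"  recovered signature sigmas {np.round(sig.sigmas, 2)}")
    print(f"  wrote swatch_{name}.png")
print()
print("Natural gamuts are gray-dominated with highly correlated channels;")
print("the alien preset flattens the histograms and removes most of the")
print("correlation, which never happens in terrestrial scenes.")
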