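"""Derive the optimal three-band RGB basis from daylight.

Splits the visible spectrum by two cuts so that the parallelepiped spanned
by the three band tristimulus vectors claims the largest volume fraction of
the object-color solid (the zonotope of all attenuated-daylight colors).
"""

from gamutkit import colorimetry as cm

illuminant = cm.load_d65()
observer = cm.load_cmf_1964()

partition, det = cm.optimize_cuts(illuminant, observer)
fraction = cm.volume_fraction(illuminant, observer, partition, coarsen=5)

print(f"optimal cuts: {partition.cut_low:.2f} nm, {partition.cut_high:.2f} nm")
print(f"inscribed parallelepiped |det|: {det:.4g}")
print(f"volume fraction of the color solid: {fraction:.4f}")
print()
print("The two cuts divide daylight into blue, green and red 'parts of")
print("daylight'; the volume fraction says how much of all possible object")
print("colors the resulting RGB cube covers (invariant under any linear")
print("recoding of color space).")
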