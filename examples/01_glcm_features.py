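"""Quantize a slice and read off its four Haralick features.

Builds a small textured field, rescales it to 64 gray levels, and computes
Energy, Contrast, Homogeneity and Correlation from the direction-averaged
GLCM — once for a smooth field and once for a rough one.
"""

import numpy as np

from mritexture import features_over_directions, generate_textured_field, quantize

for name, ell in [("smooth (corr. length 4 px)", 4.0), ("rough (corr. length 1 px)", 1.0)]:
    field = generate_textured_field((64, 64), ell, mean=100.0, sd=20.0, seed=0)
    q = quantize(field, n_levels=64)
    feats, ndir = features_over_directions(q)
    print(f"{name}: averaged over {ndir} directions")
    print(f"  energy      = {feats.energy:.4f}")
    print(f"  contrast    = {feats.contrast:.2f}")
    print(f"  homogeneity = {feats.homogeneity:.4f}")
    print(f"  correlation = {feats.correlation:+.4f}")

print(
    "\nSmoother texture concentrates the GLCM near its diagonal: Energy and\n"
    "Homogeneity rise, Contrast falls, and neighbouring pixels correlate more."
)
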