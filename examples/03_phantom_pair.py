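"""Generate one phantom case and propagate its ROIs across fields.

Shows the paired-acquisition design: a high-field slice with annotated
lesion/control ROIs, the low-field slice rendered through a known rigid
offset with stronger noise, and the ROI propagation that carries the
annotations into the low-field frame.
"""

import numpy as np

from mritexture import generate_phantom_pair, propagate_roi
from mritexture.phantom import default_config

cfg = default_config(seed=42)
pair = generate_phantom_pair(cfg)

print(f"high-field slice: {pair.highfield.shape}, "
      f"mean {pair.highfield.mean():.1f}, sd {pair.highfield.std():.1f}")
print(f"low-field slice : {pair.lowfield.shape}, "
      f"mean {pair.lowfield.mean():.1f}, sd {pair.lowfield.std():.1f} "
      f"(noise sigma {cfg.noise_sigma_low} vs {cfg.noise_sigma_high})")
R = pair.true_transform.rotation
angle = np.degrees(np.arctan2(R[1, 0], R[0, 0]))
print(f"true rigid offset: rotation {angle:+.1f} deg, "
      f"translation {pair.true_transform.translation} mm")

for roi in pair.rois:
    moved = propagate_roi(roi, pair.true_transform,
                          pair.geometry_high, pair.geometry_low)
    print(f"  {roi.label:15s} center {tuple(round(c, 1) for c in roi.center)} "
          f"-> low-field {tuple(round(c, 1) for c in moved.center)}, "
          f"radius {moved.radius:.1f} px")

print("\nMatched ROIs keep identical radius after propagation; the low-field\n"
      "slice is the same scene seen through the rigid offset plus heavier noise.")
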