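"""Run a complete synthetic study: 28 matched ROI pairs, both methods.

Generates 28 phantom cases, extracts Method 1 (within-ROI GLCM) and
Method 2 (texture-map average) features on both field strengths, and
prints the Welch comparison and power tables.
"""

import pandas as pd

from mritexture.pipeline import simulate_study

pd.set_option("display.width", 120)

result = simulate_study(n_pairs=28, seed=7)

cols = ["feature", "field_strength", "method", "mean_diff", "p", "d", "required_n"]
print("Cancerous vs non-suspicious, Welch two-sided test:")
print(result.comparison[cols].to_string(index=False,
                                        float_format=lambda v: f"{v:.4g}"))

print("\nLow-field power analysis (alpha 0.05, power 0.80):")
print(result.power_table.to_string(index=False,
                                   float_format=lambda v: f"{v:.3g}"))

print(
    "\nmean_diff > 0 for Energy/Homogeneity and < 0 for Contrast/Correlation\n"
    "is the reported cancer signature; required_n is the per-group sample\n"
    "size a future study would need at the observed effect size."
)
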