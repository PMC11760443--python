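# mritexture

GLCM/Haralick texture analysis for paired high-field and low-field
T2-weighted MR slices — with a synthetic phantom generator for validating
the whole pipeline when the clinical images themselves cannot be shared.

## The problem

Low-field (< 0.1 T) MRI is attractive for in-office, MRI-guided prostate
biopsy, but its images are noisier than diagnostic 3 T images and its value
for quantitative tissue characterization is an open question. A standard
quantitative approach on high-field T2-weighted images is second-order
texture analysis: rescale the slice to N = 64 gray levels, accumulate the
Gray Level Co-occurrence Matrix (GLCM) — the normalized, symmetrized
histogram P of gray-level pairs at a pixel offset — inside a region of
interest, and summarize it with the Haralick features

    Energy      = Σᵢⱼ P²ᵢⱼ
    Contrast    = Σᵢⱼ Pᵢⱼ (i−j)²
    Homogeneity = Σᵢⱼ Pᵢⱼ / (1+(i−j)²)
    Correlation = Σᵢⱼ Pᵢⱼ (i−μ)(j−μ) / σ²

computed over four in-plane offsets and averaged. Cancerous prostate tissue
characteristically shows **higher Energy and Homogeneity** and **lower
Contrast and Correlation** than normal tissue. `mritexture` implements the
full comparison pipeline for co-registered slice pairs:

* per-slice quantization to N gray levels (robust percentile scaling by
  default; the features are affine-intensity invariant);
* rigid-transform geometry: composing `T(x) = Rx + t`, resampling between
  frames, and propagating circle/mask ROIs from the high-field to the
  low-field frame with radii preserved in millimetres;
* **Method 1** — masked within-ROI GLCM features (both pair endpoints must
  lie inside the ROI), and **Method 2** — per-pixel sliding-window texture
  maps averaged over the ROI;
* statistics — unpaired two-sided Welch t-test per (feature, field, method)
  stratum, Cohen's d (pooled SD), and the noncentral-t per-group sample
  size required for power 0.80 at α = 0.05;
* a phantom generator producing paired slices with known rigid offset,
  field-dependent Rician noise, and lesions whose spatial texture (not mean
  intensity) differs from background in the direction above.

It is a library first (`import mritexture`, see `examples/`), with a thin
`mritexture` CLI (`simulate`, `run`, `report`, `init-config`) for running
file-based studies (NIfTI images, JSON ROIs/transforms, CSV reports).

## Worked example

```python
from mritexture.pipeline import simulate_study

result = simulate_study(n_pairs=28, seed=7)   # 28 matched ROI pairs
print(result.comparison[["feature", "field_strength", "method",
                         "mean_diff", "p", "d", "required_n"]])
```

The low-field rows of the comparison table (from `examples/04_full_study.py`,
which prints exactly this run):

```
    feature field_strength  method  mean_diff         p      d  required_n
     energy       lowfield method1   0.002226 3.866e-12  2.701           4
   contrast       lowfield method1      -16.1 5.971e-16 -3.615           3
homogeneity       lowfield method1    0.05145 1.651e-17   3.33           3
correlation       lowfield method1    -0.0987 5.591e-05 -1.206          12
     energy       lowfield method2   0.001896 2.268e-13  2.779           4
   contrast       lowfield method2     -11.51 7.398e-14 -2.917           4
homogeneity       lowfield method2    0.03743 4.508e-16  3.062           4
correlation       lowfield method2   -0.08769 3.177e-08 -1.762           7
```

`mean_diff` is cancerous − non-suspicious: positive for Energy and
Homogeneity, negative for Contrast and Correlation — the cancer texture
signature — with Welch `p` far below 0.05 for both extraction methods on
the noisy low-field channel. `d` is the standardized effect size and
`required_n` the per-group sample size a study would need to detect it with
power 0.80.

The file-based route produces the same tables from data on disk:

```bash
mritexture simulate --out-dir study --n-pairs 28 --seed 7
mritexture run --manifest study/manifest.json --out-dir results
```

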