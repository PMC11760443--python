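"""Sliding-window texture maps (Method 2).

For each pixel, the four Haralick features are computed from a GLCM built
over a square window centered on that pixel (clipped to the image bounds at
the border — padding would fabricate co-occurrences) and assigned to the
pixel position.  Levels come from the slice-level quantization; windows are
not re-quantized, so maps stay comparable across the image.

Pixels whose clipped window yields no co-occurrence pair in any direction
are invalid and carry NaN.  Constant windows have an undefined Correlation
and are invalid in the Correlation map only.

The interior of the image (full, unclipped windows, per-direction feature
averaging) is computed by a vectorized batch routine; border pixels fall
back to an explicit window crop.  Both paths produce identical values for
identical windows, which the test suite checks against an independent
per-window oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence, Union

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .geometry import RoiSpec
from .glcm import (
    DEFAULT_DIRECTIONS,
    FEATURE_NAMES,
    EmptyGlcmError,
    features_over_directions,
)
from .preprocess import QuantizedSlice

__all__ = ["TextureMap", "RoiSummary", "texture_map", "summarize_map_over_roi"]

_VAR_TOL = 1e-12


@dataclass(frozen=True)
class TextureMap:
    """One per-pixel feature map; invalid pixels are NaN, never 0."""

    values: np.ndarray
    feature_name: str
    window_size: int
    validity: np.ndarray

    def __post_init__(self) -> None:
        if self.window_size < 3 or self.window_size % 2 == 0:
            raise ValueError("window_size must be odd and >= 3")
        v = np.asarray(self.values, dtype=float)
        ok = np.asarray(self.validity, dtype=bool)
        if v.shape != ok.shape:
            raise ValueError("values/validity shape mismatch")
        if np.isfinite(v[~ok]).any():
            raise ValueError("invalid pixels must be NaN")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "validity", ok)


class RoiSummary(NamedTuple):
    mean: float
    n_pixels: int


def _batch_direction_features(levels, N, sel_rows, sel_cols, window_size, offset):
    """Features of full (unclipped) windows at the selected interior centers,
    for a single co-occurrence offset.  Returns four (n_pixels,) arrays."""
    dr, dc = offset
    H, W = levels.shape
    r0, r1 = max(0, -dr), H - max(0, dr)
    c0, c1 = max(0, -dc), W - max(0, dc)
    A = levels[r0:r1, c0:c1]
    B = levels[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    wh, ww = window_size - abs(dr), window_size - abs(dc)
    m = wh * ww
    hw = window_size // 2

    # center (r, c) -> window of pair-start positions at index (r - hw, c - hw)
    swA = sliding_window_view(A, (wh, ww))[sel_rows - hw, sel_cols - hw]
    swB = sliding_window_view(B, (wh, ww))[sel_rows - hw, sel_cols - hw]
    ai = swA.reshape(-1, m)
    bi = swB.reshape(-1, m)
    a = ai.astype(float)
    b = bi.astype(float)

    d2 = (a - b) ** 2
    contrast = d2.mean(axis=1)
    homogeneity = (1.0 / (1.0 + d2)).mean(axis=1)

    mu = (a.sum(axis=1) + b.sum(axis=1)) / (2.0 * m)
    ac = a - mu[:, None]
    bc = b - mu[:, None]
    var = (ac**2 + bc**2).sum(axis=1) / (2.0 * m)
    cov = (ac * bc).mean(axis=1)
    correlation = np.where(var >= _VAR_TOL, cov / np.where(var > 0, var, 1.0), np.nan)

    # Energy = sum of squared symmetrized-count probabilities.  With c_u the
    # ordered-pair count of the unordered level pair u, sum S^2 equals
    # 2*sum(c_u^2) + 2*sum_diag(c_u^2); and sum(c^2) over runs of a sorted
    # code row is sum_j (2*rank_j - 1) with rank_j the within-run position.
    codes = np.sort(np.minimum(ai, bi) * N + np.maximum(ai, bi), axis=1)
    starts = np.ones(codes.shape, dtype=bool)
    starts[:, 1:] = codes[:, 1:] != codes[:, :-1]
    idx = np.arange(m)
    last_start = np.maximum.accumulate(np.where(starts, idx[None, :], -1), axis=1)
    wgt = 2 * (idx[None, :] - last_start + 1) - 1
    diag = codes % (N + 1) == 0
    energy = (wgt.sum(axis=1) + (wgt * diag).sum(axis=1)) / (2.0 * m * m)

    return energy, contrast, homogeneity, correlation


def _pixel_features(levels, N, r, c, window_size, directions, combine):
    """Clipped-window fallback: crop and delegate to the ROI-mode machinery."""
    hw = window_size // 2
    crop = levels[max(0, r - hw) : r + hw + 1, max(0, c - hw) : c + hw + 1]
    try:
        feats, _ = features_over_directions(
            crop, directions=directions, combine=combine, n_levels=N
        )
    except EmptyGlcmError:
        return None
    return feats


def texture_map(
    q: Union[QuantizedSlice, np.ndarray],
    window_size: int = 9,
    features: Sequence[str] = FEATURE_NAMES,
    directions: Sequence[tuple] = DEFAULT_DIRECTIONS,
    combine: str = "mean_features",
    pixels: Optional[np.ndarray] = None,
    n_levels: Optional[int] = None,
) -> dict:
    """Per-pixel sliding-window Haralick maps.

    Parameters
    ----------
    q : quantized slice (or integer level grid with ``n_levels``)
    window_size : odd window edge length in pixels (default 9)
    features : which of the four maps to return
    directions, combine : as in :func:`features_over_directions`
    pixels : optional boolean grid; compute only these centers (others are
        marked invalid).  Used to restrict expensive maps to ROI pixels.

    Returns
    -------
    dict mapping feature name -> :class:`TextureMap`
    """
    if window_size < 3 or window_size % 2 == 0:
        raise ValueError("window_size must be odd and >= 3")
    if isinstance(q, QuantizedSlice):
        levels, N = q.levels, q.n_levels
    else:
        levels = np.asarray(q, dtype=np.int64)
        N = int(n_levels) if n_levels is not None else int(levels.max()) + 1
    H, W = levels.shape
    if window_size > H and window_size > W:
        raise ValueError("window larger than image in both dimensions")
    unknown = set(features) - set(FEATURE_NAMES)
    if unknown:
        raise ValueError(f"unknown features: {sorted(unknown)}")

    sel = np.ones((H, W), dtype=bool) if pixels is None else np.asarray(pixels, bool)
    if sel.shape != (H, W):
        raise ValueError("pixels mask shape does not match image")

    out = {name: np.full((H, W), np.nan) for name in FEATURE_NAMES}

    hw = window_size // 2
    interior = np.zeros((H, W), dtype=bool)
    if H >= window_size and W >= window_size:
        interior[hw : H - hw, hw : W - hw] = True

    batch = sel & interior
    if combine != "mean_features":
        batch[:] = False  # mean_glcm needs explicit per-window GLCMs
    if batch.any():
        rows, cols = np.nonzero(batch)
        acc = {name: [] for name in FEATURE_NAMES}
        for off in directions:
            e, ct, hm, cr = _batch_direction_features(
                levels, N, rows, cols, window_size, off
            )
            acc["energy"].append(e)
            acc["contrast"].append(ct)
            acc["homogeneity"].append(hm)
            acc["correlation"].append(cr)
        for name in ("energy", "contrast", "homogeneity"):
            out[name][rows, cols] = np.mean(acc[name], axis=0)
        stacked = np.array(acc["correlation"])
        defined = ~np.isnan(stacked)
        n_def = defined.sum(axis=0)
        corr_sum = np.where(defined, stacked, 0.0).sum(axis=0)
        corr = np.where(n_def > 0, corr_sum / np.maximum(n_def, 1), np.nan)
        out["correlation"][rows, cols] = corr

    rest = sel & ~batch
    for r, c in zip(*np.nonzero(rest)):
        feats = _pixel_features(levels, N, r, c, window_size, directions, combine)
        if feats is None:
            continue
        out["energy"][r, c] = feats.energy
        out["contrast"][r, c] = feats.contrast
        out["homogeneity"][r, c] = feats.homogeneity
        out["correlation"][r, c] = feats.correlation

    maps = {}
    for name in features:
        vals = out[name]
        maps[name] = TextureMap(vals, name, window_size, np.isfinite(vals))
    return maps


def summarize_map_over_roi(
    tmap: TextureMap, roi: Union[RoiSpec, np.ndarray]
) -> RoiSummary:
    """Arithmetic mean of the map over the valid pixels of an ROI.

    Raises ``ValueError`` when the ROI contains no valid map pixel.
    """
    mask = roi.rasterize(tmap.values.shape) if isinstance(roi, RoiSpec) else np.asarray(roi, bool)
    if mask.shape != tmap.values.shape:
        raise ValueError("ROI mask shape does not match map")
    use = mask & tmap.validity
    n = int(use.sum())
    if n == 0:
        raise ValueError("ROI contains no valid map pixel")
    return RoiSummary(float(tmap.values[use].mean()), n)
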