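"""Intensity normalization and gray-level quantization.

All texture computation runs on slices rescaled to a small number of gray
levels (default N = 64).  Quantization uses the floor rule

    level = floor((v - min) / (max - min) * N), clipped to [0, N - 1]

so that values at or below ``min`` map to level 0 and values at or above
``max`` map to level N - 1.  Under per-slice min/max scaling the mapping is
invariant to any positive affine change of the intensities, which makes the
downstream GLCM features affine-intensity invariant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

__all__ = ["QuantizedSlice", "quantize", "DegenerateRangeWarning"]


class DegenerateRangeWarning(UserWarning):
    """Emitted when the scaling range collapses (constant slice)."""


@dataclass(frozen=True)
class QuantizedSlice:
    """2-D integer grid of gray levels in [0, n_levels - 1]."""

    levels: np.ndarray
    n_levels: int
    source_range: tuple

    def __post_init__(self) -> None:
        lv = np.asarray(self.levels)
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")
        if lv.size and (lv.min() < 0 or lv.max() >= self.n_levels):
            raise ValueError("levels out of [0, n_levels - 1]")
        object.__setattr__(self, "levels", lv.astype(np.int64))

    @property
    def shape(self) -> tuple:
        return self.levels.shape


def _resolve_range(
    img: np.ndarray,
    range_mode: Union[str, tuple],
    mask: Optional[np.ndarray],
) -> tuple:
    vals = img[mask] if mask is not None else img
    if isinstance(range_mode, tuple):
        tag = range_mode[0]
        if tag == "percentile":
            lo, hi = np.percentile(vals, [range_mode[1], range_mode[2]])
        elif tag == "explicit":
            lo, hi = float(range_mode[1]), float(range_mode[2])
        else:
            raise ValueError(f"unknown range_mode {range_mode!r}")
        return float(lo), float(hi)
    if range_mode == "global_minmax":
        return float(vals.min()), float(vals.max())
    raise ValueError(f"unknown range_mode {range_mode!r}")


def quantize(
    image: np.ndarray,
    n_levels: int = 64,
    range_mode: Union[str, tuple] = "global_minmax",
    mask: Optional[np.ndarray] = None,
) -> QuantizedSlice:
    """Rescale a real-valued slice to ``n_levels`` gray levels.

    Parameters
    ----------
    image : 2-D real array
    n_levels : number of output gray levels N (>= 2)
    range_mode : "global_minmax", ("percentile", p_lo, p_hi) or
        ("explicit", min, max); the scaling range.
    mask : optional boolean grid restricting the range estimation (the whole
        slice is still quantized).

    A constant slice (max == min) maps everything to level 0 and raises a
    :class:`DegenerateRangeWarning`.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("image must be a non-empty 2-D array")
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    if mask is not None and np.asarray(mask).shape != img.shape:
        raise ValueError("mask shape does not match image")

    lo, hi = _resolve_range(img, range_mode, mask)
    if hi <= lo:
        warnings.warn(
            "degenerate intensity range; all levels set to 0", DegenerateRangeWarning
        )
        return QuantizedSlice(np.zeros(img.shape, dtype=np.int64), n_levels, (lo, hi))
    levels = np.floor((img - lo) / (hi - lo) * n_levels).astype(np.int64)
    np.clip(levels, 0, n_levels - 1, out=levels)
    return QuantizedSlice(levels, n_levels, (lo, hi))
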