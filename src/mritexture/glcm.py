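"""Gray Level Co-occurrence Matrices and the four Haralick features.

A GLCM counts how often pairs of gray levels occur at a fixed pixel offset.
We accumulate every ordered pair (p, p + offset) whose endpoints are both
inside the grid and — when a region of interest is supplied — both inside
the ROI, then symmetrize by adding the transpose and normalize to a
probability matrix P.

The four features kept here (the ones repeatedly found informative for
tumour-versus-normal discrimination on T2-weighted MRI) are

    Energy      = sum_ij P_ij^2
    Contrast    = sum_ij P_ij (i - j)^2
    Homogeneity = sum_ij P_ij / (1 + (i - j)^2)
    Correlation = sum_ij P_ij (i - mu)(j - mu) / sigma^2

where mu and sigma^2 are the mean and variance of the (row == column)
marginal of the symmetric P.  Correlation is undefined on a zero-variance
GLCM and is returned as NaN, never silently 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence, Union

import numpy as np

from .preprocess import QuantizedSlice

__all__ = [
    "DEFAULT_DIRECTIONS",
    "FEATURE_NAMES",
    "Glcm",
    "HaralickFeatures",
    "FeatureRecord",
    "EmptyGlcmError",
    "compute_glcm",
    "haralick_features",
    "features_over_directions",
]

#: Distance-1 offsets at 0, 45, 90 and 135 degrees, in (drow, dcol).
DEFAULT_DIRECTIONS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))

FEATURE_NAMES = ("energy", "contrast", "homogeneity", "correlation")

_VAR_TOL = 1e-12


class EmptyGlcmError(ValueError):
    """No valid co-occurrence pair exists (e.g. the ROI is too small)."""


@dataclass(frozen=True)
class Glcm:
    """Normalized symmetric co-occurrence probability matrix.

    ``pair_count`` is the symmetrized total (twice the number of ordered
    pairs accumulated).
    """

    P: np.ndarray
    n_levels: int
    offset: tuple
    pair_count: int

    def __post_init__(self) -> None:
        P = np.asarray(self.P, dtype=float)
        if P.shape != (self.n_levels, self.n_levels):
            raise ValueError("P must be n_levels x n_levels")
        if (P < 0).any() or not np.isclose(P.sum(), 1.0, atol=1e-12):
            raise ValueError("P must be non-negative and sum to 1")
        if not np.array_equal(P, P.T):
            raise ValueError("P must be exactly symmetric")
        object.__setattr__(self, "P", P)


class HaralickFeatures(NamedTuple):
    energy: float
    contrast: float
    homogeneity: float
    correlation: float  # NaN when undefined (zero-variance GLCM)


@dataclass(frozen=True)
class FeatureRecord:
    """Per-ROI feature values with full provenance."""

    energy: float
    contrast: float
    homogeneity: float
    correlation: float
    method: str  # "method1" | "method2"
    field: str  # "highfield" | "lowfield"
    label: str  # "cancerous" | "non_suspicious"
    lesion_id: str
    case_id: str = ""
    n_directions_used: int = 0

    def value(self, feature: str) -> float:
        return getattr(self, feature)


def _levels_of(q: Union[QuantizedSlice, np.ndarray], n_levels: Optional[int] = None):
    if isinstance(q, QuantizedSlice):
        return q.levels, q.n_levels
    arr = np.asarray(q)
    if n_levels is None:
        n_levels = int(arr.max()) + 1 if arr.size else 2
    return arr.astype(np.int64), int(n_levels)


def compute_glcm(
    q: Union[QuantizedSlice, np.ndarray],
    offset: tuple,
    mask: Optional[np.ndarray] = None,
    n_levels: Optional[int] = None,
) -> Glcm:
    """Accumulate the symmetric normalized GLCM for one offset.

    Every ordered pair (p, p + offset) with both endpoints inside the grid
    (and, if ``mask`` is given, both inside the mask) is counted; the count
    matrix is symmetrized by adding its transpose and normalized to sum 1.

    Raises
    ------
    EmptyGlcmError
        If no valid pair exists.
    """
    levels, N = _levels_of(q, n_levels)
    dr, dc = int(offset[0]), int(offset[1])
    if (dr, dc) == (0, 0):
        raise ValueError("offset must be non-zero")
    H, W = levels.shape
    if abs(dr) >= H or abs(dc) >= W:
        raise EmptyGlcmError("offset larger than image")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != levels.shape:
            raise ValueError("mask shape does not match image")

    # source window such that p and p+offset are both in bounds
    r0, r1 = max(0, -dr), H - max(0, dr)
    c0, c1 = max(0, -dc), W - max(0, dc)
    a = levels[r0:r1, c0:c1]
    b = levels[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    if mask is not None:
        ok = mask[r0:r1, c0:c1] & mask[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        a, b = a[ok], b[ok]
    else:
        a, b = a.ravel(), b.ravel()
    if a.size == 0:
        raise EmptyGlcmError("no valid co-occurrence pairs")

    counts = np.bincount(a * N + b, minlength=N * N).reshape(N, N)
    S = counts + counts.T
    total = int(S.sum())
    return Glcm(S / total, N, (dr, dc), total)


def haralick_features(glcm: Glcm) -> HaralickFeatures:
    """Energy, Contrast, Homogeneity and Correlation of a symmetric GLCM.

    Uses the symmetric simplification mu_i == mu_j, sigma_i == sigma_j.
    Correlation is NaN when the marginal variance is below 1e-12.
    """
    P = glcm.P
    N = glcm.n_levels
    i = np.arange(N, dtype=float)
    diff2 = (i[:, None] - i[None, :]) ** 2
    energy = float((P * P).sum())
    contrast = float((P * diff2).sum())
    homogeneity = float((P / (1.0 + diff2)).sum())

    marg = P.sum(axis=1)
    mu = float((i * marg).sum())
    var = float(((i - mu) ** 2 * marg).sum())
    if var < _VAR_TOL:
        correlation = float("nan")
    else:
        correlation = float((P * (i[:, None] - mu) * (i[None, :] - mu)).sum() / var)
    return HaralickFeatures(energy, contrast, homogeneity, correlation)


def features_over_directions(
    q: Union[QuantizedSlice, np.ndarray],
    mask: Optional[np.ndarray] = None,
    directions: Sequence[tuple] = DEFAULT_DIRECTIONS,
    combine: str = "mean_features",
    n_levels: Optional[int] = None,
) -> tuple:
    """Combine GLCM features over several offsets (default: the four
    distance-1 directions on the slice).

    combine = "mean_features" averages each feature over the directions with
    a non-empty GLCM (a direction whose Correlation is undefined is skipped
    for Correlation only); "mean_glcm" averages the normalized GLCMs first
    and computes the features once.

    Returns
    -------
    (HaralickFeatures, n_directions_used)
    """
    if combine not in ("mean_features", "mean_glcm"):
        raise ValueError(f"unknown combine mode {combine!r}")
    glcms = []
    for off in directions:
        try:
            glcms.append(compute_glcm(q, off, mask=mask, n_levels=n_levels))
        except EmptyGlcmError:
            continue
    if not glcms:
        raise EmptyGlcmError("all directions produced empty GLCMs")

    if combine == "mean_glcm":
        Pbar = np.mean([g.P for g in glcms], axis=0)
        mean_glcm = Glcm(
            Pbar, glcms[0].n_levels, (0, 0) if len(glcms) > 1 else glcms[0].offset,
            sum(g.pair_count for g in glcms),
        )
        return haralick_features(mean_glcm), len(glcms)

    per_dir = np.array([haralick_features(g) for g in glcms], dtype=float)
    with np.errstate(invalid="ignore"):
        combined = [
            float(np.nanmean(col)) if not np.all(np.isnan(col)) else float("nan")
            for col in per_dir.T
        ]
    return HaralickFeatures(*combined), len(glcms)
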