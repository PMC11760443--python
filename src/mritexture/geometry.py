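"""Rigid transforms, image resampling and ROI propagation.

The analysis operates on slice pairs acquired at two field strengths that
were aligned by a rigid transform ``T(x) = R x + t`` acting on physical
(millimetre) coordinates.  This module only *applies* transforms supplied
from outside (e.g. a manual registration exported as JSON); it never
estimates them from image content.

Conventions
-----------
* Coordinates are row-major, 0-based ``(row, col)`` (or ``(slice, row,
  col)`` in 3-D), with pixel centers at integer indices.
* Physical coordinates are millimetres: ``x = origin + spacing * index``.
* A transform stored with a case maps *high-field* physical coordinates to
  *low-field* physical coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "RigidTransform",
    "ImageGeometry",
    "RoiSpec",
    "RoiPropagationError",
    "compose",
    "apply_transform",
    "resample_to_frame",
    "propagate_roi",
    "rasterize_circle",
]

_ORTHO_TOL = 1e-9


class RoiPropagationError(ValueError):
    """Raised when an ROI maps entirely outside the target grid."""


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform ``x -> R x + t`` in physical coordinates.

    ``rotation`` is a 2x2 (slice mode) or 3x3 (volume mode) rotation matrix;
    ``translation`` is in millimetres.
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).ravel()
        if R.ndim != 2 or R.shape[0] != R.shape[1] or R.shape[0] not in (2, 3):
            raise ValueError(f"rotation must be 2x2 or 3x3, got {R.shape}")
        if t.shape != (R.shape[0],):
            raise ValueError("translation dimensionality does not match rotation")
        if not np.allclose(R.T @ R, np.eye(R.shape[0]), atol=_ORTHO_TOL):
            raise ValueError("rotation matrix is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=_ORTHO_TOL):
            raise ValueError("rotation matrix must have determinant +1")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @property
    def dim(self) -> int:
        return self.rotation.shape[0]

    @classmethod
    def identity(cls, dim: int = 2) -> "RigidTransform":
        return cls(np.eye(dim), np.zeros(dim))

    @classmethod
    def from_angle_2d(
        cls, angle_rad: float, translation: Sequence[float] = (0.0, 0.0)
    ) -> "RigidTransform":
        """In-plane rotation by ``angle_rad`` (row/col axes) plus translation."""
        c, s = np.cos(angle_rad), np.sin(angle_rad)
        return cls(np.array([[c, -s], [s, c]]), np.asarray(translation, float))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply ``R x + t`` to one point or an (n, dim) array of points."""
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        Rinv = self.rotation.T
        return RigidTransform(Rinv, -Rinv @ self.translation)

    def to_dict(self) -> dict:
        return {
            "dim": self.dim,
            "rotation": self.rotation.ravel().tolist(),
            "translation_mm": self.translation.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        dim = int(d["dim"])
        R = np.asarray(d["rotation"], float).reshape(dim, dim)
        return cls(R, np.asarray(d["translation_mm"], float))

    def to_homogeneous(self) -> np.ndarray:
        """Return the (dim+1)x(dim+1) homogeneous matrix."""
        H = np.eye(self.dim + 1)
        H[: self.dim, : self.dim] = self.rotation
        H[: self.dim, self.dim] = self.translation
        return H

    @classmethod
    def from_homogeneous(cls, H: np.ndarray) -> "RigidTransform":
        H = np.asarray(H, dtype=float)
        d = H.shape[0] - 1
        if H.shape != (d + 1, d + 1) or not np.allclose(
            H[d], np.eye(d + 1)[d], atol=1e-9
        ):
            raise ValueError("not a homogeneous transform matrix")
        return cls(H[:d, :d], H[:d, d])

    def as_inplane(self) -> "RigidTransform":
        """Reduce a 3-D transform to its in-plane (row, col) 2-D part.

        Valid only when the out-of-plane row/column of the rotation is
        (close to) identity, i.e. the transform does not tilt the slice.
        """
        if self.dim == 2:
            return self
        R = self.rotation
        if not (np.allclose(R[0], [1, 0, 0], atol=1e-6) and np.allclose(R[:, 0], [1, 0, 0], atol=1e-6)):
            raise ValueError("transform mixes the slice axis; no in-plane reduction")
        return RigidTransform(R[1:, 1:], self.translation[1:])


def compose(transforms: Iterable[RigidTransform]) -> RigidTransform:
    """Collapse a sequence of rigid transforms applied in list order.

    ``compose([T0, T1])`` maps ``x`` to ``T1(T0(x))``.
    """
    transforms = list(transforms)
    if not transforms:
        raise ValueError("compose requires at least one transform")
    dims = {T.dim for T in transforms}
    if len(dims) != 1:
        raise ValueError("cannot compose transforms of mixed dimensionality")
    R = np.eye(transforms[0].dim)
    t = np.zeros(transforms[0].dim)
    for T in transforms:
        R = T.rotation @ R
        t = T.rotation @ t + T.translation
    return RigidTransform(R, t)


def apply_transform(point: Sequence[float], T: RigidTransform) -> np.ndarray:
    """Map a physical coordinate through ``T``: returns ``R x + t``."""
    return T.apply(np.asarray(point, dtype=float))


@dataclass(frozen=True)
class ImageGeometry:
    """Axis-aligned grid geometry: shape, spacing (mm/px) and origin (mm)."""

    shape: tuple
    spacing: tuple = None
    origin: tuple = None

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        d = len(shape)
        spacing = tuple(float(s) for s in (self.spacing or (1.0,) * d))
        origin = tuple(float(o) for o in (self.origin or (0.0,) * d))
        if any(s <= 0 for s in shape) or any(s <= 0 for s in spacing):
            raise ValueError("shape and spacing must be positive")
        if len(spacing) != d or len(origin) != d:
            raise ValueError("spacing/origin dimensionality mismatch")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def dim(self) -> int:
        return len(self.shape)

    def pixel_to_physical(self, idx: np.ndarray) -> np.ndarray:
        return np.asarray(idx, float) * np.array(self.spacing) + np.array(self.origin)

    def physical_to_pixel(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, float) - np.array(self.origin)) / np.array(self.spacing)


def resample_to_frame(
    moving: np.ndarray,
    moving_geometry: ImageGeometry,
    T: RigidTransform,
    target_geometry: ImageGeometry,
    interpolation: Literal["linear", "nearest"] = "linear",
) -> tuple:
    """Resample ``moving`` onto the target frame through rigid transform ``T``.

    ``T`` maps moving-frame physical coordinates to target-frame physical
    coordinates; each target pixel center is pulled back through ``T⁻¹``.
    Out-of-bounds samples are filled with 0 and marked False in the returned
    validity mask.

    Returns
    -------
    (resampled, validity) : (float ndarray, bool ndarray)
    """
    if interpolation not in ("linear", "nearest"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    moving = np.asarray(moving, dtype=float)
    if moving.ndim != moving_geometry.dim or moving_geometry.dim != target_geometry.dim:
        raise ValueError("image/geometry dimensionality mismatch")
    d = target_geometry.dim
    grids = np.meshgrid(
        *[np.arange(n, dtype=float) for n in target_geometry.shape], indexing="ij"
    )
    idx = np.stack([g.ravel() for g in grids], axis=1)
    phys_target = target_geometry.pixel_to_physical(idx)
    phys_moving = T.inverse().apply(phys_target)
    pix_moving = moving_geometry.physical_to_pixel(phys_moving)

    coords = pix_moving.T  # (d, n) for map_coordinates
    order = 1 if interpolation == "linear" else 0
    values = ndimage.map_coordinates(
        moving, coords, order=order, mode="constant", cval=0.0
    )
    valid = np.ones(coords.shape[1], dtype=bool)
    for ax in range(d):
        lim = moving.shape[ax] - 1
        # nearest rounds; linear needs the full support inside the grid
        lo, hi = (-0.5, lim + 0.5) if order == 0 else (0.0, float(lim))
        valid &= (coords[ax] >= lo) & (coords[ax] <= hi)
    out = values.reshape(target_geometry.shape)
    validity = valid.reshape(target_geometry.shape)
    out[~validity] = 0.0
    return out, validity


@dataclass(frozen=True)
class RoiSpec:
    """Region of interest: a circle (center/radius in pixels) or a mask.

    ``label`` distinguishes biopsy-proven cancerous regions from matched
    non-suspicious regions of identical size on the same slice.
    """

    kind: Literal["circle", "mask"]
    label: Literal["cancerous", "non_suspicious"]
    lesion_id: str
    frame: Literal["highfield", "lowfield"] = "highfield"
    slice_index: int = 0
    center: tuple = None  # (row, col) pixels, circle only
    radius: float = None  # pixels, circle only
    mask: np.ndarray = None  # bool grid, mask only

    def __post_init__(self) -> None:
        if self.kind == "circle":
            if self.center is None or self.radius is None or self.radius <= 0:
                raise ValueError("circle ROI requires center and radius > 0")
            object.__setattr__(self, "center", tuple(float(c) for c in self.center))
            object.__setattr__(self, "radius", float(self.radius))
        elif self.kind == "mask":
            if self.mask is None or not np.asarray(self.mask).any():
                raise ValueError("mask ROI requires at least one true pixel")
            object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))
        else:
            raise ValueError(f"unknown ROI kind {self.kind!r}")

    def rasterize(self, shape: tuple) -> np.ndarray:
        """Binary mask on a grid of ``shape``; circle uses center-inclusion
        (pixel in iff its center lies at distance <= radius)."""
        if self.kind == "mask":
            if self.mask.shape != tuple(shape):
                raise ValueError("mask ROI shape does not match image shape")
            return self.mask
        return rasterize_circle(shape, self.center, self.radius)

    def to_dict(self) -> dict:
        d = {"label": self.label, "lesion_id": self.lesion_id, "slice": int(self.slice_index)}
        if self.kind == "circle":
            d["center_px"] = list(self.center)
            d["radius_px"] = self.radius
        else:
            d["mask"] = np.asarray(self.mask, dtype=int).tolist()
        return d


def rasterize_circle(shape: tuple, center: Sequence[float], radius: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def propagate_roi(
    roi: RoiSpec,
    T: RigidTransform,
    source_geometry: ImageGeometry,
    target_geometry: ImageGeometry,
) -> RoiSpec:
    """Carry a high-field-frame ROI into the low-field frame through ``T``.

    Circle centers are mapped through ``T`` in physical space; the radius is
    preserved in millimetres and re-expressed in target pixels (requires
    isotropic in-plane spacing).  Mask ROIs are resampled nearest-neighbour.
    """
    if roi.frame != "highfield":
        raise ValueError("propagate_roi expects an ROI in the highfield frame")
    T2 = T.as_inplane()
    if roi.kind == "circle":
        phys = source_geometry.pixel_to_physical(np.asarray(roi.center))
        new_center = target_geometry.physical_to_pixel(T2.apply(phys))
        sp_src = source_geometry.spacing
        sp_tgt = target_geometry.spacing
        if not np.isclose(sp_src[0], sp_src[1]) or not np.isclose(sp_tgt[0], sp_tgt[1]):
            raise ValueError("circle propagation requires isotropic in-plane spacing")
        new_radius = roi.radius * sp_src[0] / sp_tgt[0]
        new = replace(roi, center=tuple(new_center), radius=new_radius, frame="lowfield")
        if not rasterize_circle(target_geometry.shape, new.center, new.radius).any():
            raise RoiPropagationError("ROI maps entirely outside the target grid")
        return new
    resampled, _ = resample_to_frame(
        roi.mask.astype(float), source_geometry, T2, target_geometry, "nearest"
    )
    new_mask = resampled > 0.5
    if not new_mask.any():
        raise RoiPropagationError("ROI maps entirely outside the target grid")
    return replace(roi, mask=new_mask, frame="lowfield")
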