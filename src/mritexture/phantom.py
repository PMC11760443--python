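"""Synthetic paired high-field/low-field phantom slices.

The generator emulates the statistical structure the texture analysis
relies on, not MR physics: a prostate disc filled with a stationary
correlated Gaussian random field, circular lesions whose *spatial texture*
(correlation length and local SD) differs from background while the mean
intensity does not, a known rigid offset between the two frames, and
field-strength-dependent acquisition noise (hardware-dominated, hence
stronger, on the low-field channel).

Texture mechanism
-----------------
A correlated field is white noise convolved with an isotropic Gaussian
kernel whose width is the correlation length, rescaled to a target
mean/SD.  Within one phantom, background and lesion textures are different
smoothings of the *same* white-noise substrate: lesion discs carry no
statistical seam (identical lesion/background parameters reproduce the
background field exactly, making the two ROI classes perfectly
exchangeable in null studies), and only the texture parameters — not an
independent realization — distinguish lesion from background.

Lesions default to a *longer* correlation length and a *lower* texture SD
than background.  On the quantized slice this raises Energy and
Homogeneity and lowers Contrast inside lesions; because acquisition noise
is spatially white, the lower signal SD also lowers the neighbour
correlation of the noisy field, so GLCM Correlation drops — the four
directions reported for cancerous tissue.

Every draw is deterministic given ``PhantomConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage

from .geometry import (
    ImageGeometry,
    RigidTransform,
    RoiSpec,
    rasterize_circle,
    resample_to_frame,
)

__all__ = [
    "TextureParams",
    "LesionSpec",
    "PhantomConfig",
    "PhantomPair",
    "generate_textured_field",
    "generate_phantom_pair",
    "make_study_configs",
    "default_config",
    "null_config",
]


@dataclass(frozen=True)
class TextureParams:
    """Stationary-field parameters: correlation length (px), mean and SD
    (arbitrary intensity units)."""

    correlation_length: float
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.correlation_length <= 0:
            raise ValueError("correlation_length must be > 0")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


#: Background texture of the study conditions.
BACKGROUND_TEXTURE = TextureParams(correlation_length=1.5, mean=100.0, sd=20.0)
#: Lesion texture of the study conditions: smoother (longer correlation
#: length) and more ordered (lower SD) than background, equal mean.
LESION_TEXTURE = TextureParams(correlation_length=2.0, mean=100.0, sd=12.0)


@dataclass(frozen=True)
class LesionSpec:
    center: Tuple[float, float]  # (row, col) px, high-field frame
    radius: float  # px
    texture: TextureParams = LESION_TEXTURE

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("lesion radius must be > 0")


def _default_offset() -> RigidTransform:
    return RigidTransform.from_angle_2d(np.deg2rad(3.0), (2.0, -1.5))


@dataclass(frozen=True)
class PhantomConfig:
    """Study conditions for one phantom slice pair."""

    image_shape: Tuple[int, int] = (80, 80)
    prostate_center: Tuple[float, float] = (40.0, 40.0)
    prostate_radius: float = 28.0
    lesion_specs: Tuple[LesionSpec, ...] = ()
    background_texture: TextureParams = BACKGROUND_TEXTURE
    noise_model: str = "rician"  # "rician" | "gaussian"
    noise_sigma_high: float = 2.0
    noise_sigma_low: float = 6.0
    lesion_mean_shift: float = 0.0  # optional gross-intensity knob, off by default
    rigid_offset: RigidTransform = field(default_factory=_default_offset)
    spacing_high: Tuple[float, float] = (1.0, 1.0)
    spacing_low: Tuple[float, float] = (1.0, 1.0)
    roi_radius: Optional[float] = None  # defaults to each lesion's radius
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_model not in ("rician", "gaussian"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if min(self.noise_sigma_high, self.noise_sigma_low) < 0:
            raise ValueError("noise sigma must be >= 0")
        if self.prostate_radius <= 0:
            raise ValueError("prostate_radius must be > 0")
        pc = np.asarray(self.prostate_center, float)
        for les in self.lesion_specs:
            dist = np.hypot(*(np.asarray(les.center, float) - pc))
            if dist + les.radius > self.prostate_radius:
                raise ValueError(
                    f"lesion at {les.center} (r={les.radius}) lies outside the prostate disc"
                )

    @property
    def geometry_high(self) -> ImageGeometry:
        return ImageGeometry(self.image_shape, self.spacing_high)

    @property
    def geometry_low(self) -> ImageGeometry:
        return ImageGeometry(self.image_shape, self.spacing_low)


@dataclass(frozen=True)
class PhantomPair:
    """One simulated case: co-registered slices plus ground truth."""

    highfield: np.ndarray
    lowfield: np.ndarray
    true_transform: RigidTransform  # high-field physical -> low-field physical
    rois: Tuple[RoiSpec, ...]  # high-field frame, matched pairs
    geometry_high: ImageGeometry
    geometry_low: ImageGeometry
    lowfield_validity: np.ndarray
    config: PhantomConfig


def generate_textured_field(
    shape: Tuple[int, int],
    correlation_length: float,
    mean: float,
    sd: float,
    seed,
) -> np.ndarray:
    """Stationary correlated Gaussian random field.

    White noise is convolved with an isotropic Gaussian kernel of width
    ``correlation_length`` (pixels) and rescaled to the target mean and SD.
    ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    if len(shape) != 2 or min(shape) <= 0:
        raise ValueError("shape must be positive 2-D")
    if correlation_length <= 0:
        raise ValueError("correlation_length must be > 0")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    white = rng.standard_normal(shape)
    if sd == 0:
        return np.full(shape, float(mean))
    smooth = ndimage.gaussian_filter(white, sigma=correlation_length, mode="wrap")
    smooth = (smooth - smooth.mean()) / smooth.std()
    return smooth * sd + mean


def _add_noise(img: np.ndarray, model: str, sigma: float, rng) -> np.ndarray:
    if sigma == 0:
        return img
    if model == "gaussian":
        return img + rng.standard_normal(img.shape) * sigma
    # Rician: magnitude of the complex signal with iid Gaussian channel noise
    re = img + rng.standard_normal(img.shape) * sigma
    im = rng.standard_normal(img.shape) * sigma
    return np.hypot(re, im)


def generate_phantom_pair(config: PhantomConfig) -> PhantomPair:
    """Render one high-field/low-field slice pair with ground truth.

    The low-field slice is the noiseless high-field scene resampled through
    the true rigid offset, then degraded with the configured noise model at
    the (higher) low-field sigma; acquisition noise is added after
    resampling, as it arises in the acquiring frame.
    """
    rng = np.random.default_rng(config.seed)
    shape = tuple(config.image_shape)

    white = rng.standard_normal(shape)

    def field_from_substrate(params: TextureParams) -> np.ndarray:
        if params.sd == 0:
            return np.full(shape, float(params.mean))
        s = ndimage.gaussian_filter(white, sigma=params.correlation_length, mode="wrap")
        s = (s - s.mean()) / s.std()
        return s * params.sd + params.mean

    scene = field_from_substrate(config.background_texture)
    for les in config.lesion_specs:
        lf = field_from_substrate(les.texture)
        m = rasterize_circle(shape, les.center, les.radius)
        scene[m] = lf[m] + config.lesion_mean_shift

    high = _add_noise(scene, config.noise_model, config.noise_sigma_high, rng)
    low_scene, validity = resample_to_frame(
        scene, config.geometry_high, config.rigid_offset, config.geometry_low, "linear"
    )
    low = _add_noise(low_scene, config.noise_model, config.noise_sigma_low, rng)
    low[~validity] = 0.0

    rois = _place_rois(config, rng)
    return PhantomPair(
        high, low, config.rigid_offset, tuple(rois),
        config.geometry_high, config.geometry_low, validity, config,
    )


def _place_rois(config: PhantomConfig, rng) -> List[RoiSpec]:
    """Cancerous ROI on each lesion; a matched non-suspicious ROI of
    identical radius on the same slice, inside the prostate and clear of
    every lesion."""
    rois: List[RoiSpec] = []
    pc = np.asarray(config.prostate_center, float)
    taken = [(np.asarray(l.center, float), l.radius) for l in config.lesion_specs]
    for k, les in enumerate(config.lesion_specs):
        r = float(config.roi_radius or les.radius)
        lesion_id = f"lesion{k:02d}"
        rois.append(
            RoiSpec("circle", "cancerous", lesion_id, "highfield",
                    0, tuple(les.center), r)
        )
        max_off = config.prostate_radius - r
        for attempt in range(10_000):
            ang = rng.uniform(0, 2 * np.pi)
            rad = max_off * np.sqrt(rng.uniform())
            cand = pc + rad * np.array([np.cos(ang), np.sin(ang)])
            clear = all(
                np.hypot(*(cand - c)) >= cr + r + 2.0 for c, cr in taken
            )
            if clear:
                break
        else:
            raise ValueError("could not place a matched non-suspicious ROI")
        taken.append((cand, r))
        rois.append(
            RoiSpec("circle", "non_suspicious", lesion_id, "highfield",
                    0, tuple(cand), r)
        )
    return rois


def default_config(seed: int = 0, rng=None, **overrides) -> PhantomConfig:
    """Paper-trend study conditions: one lesion pair per slice, lesion
    texture smoother/more ordered than background, equal means.

    The lesion center is drawn uniformly inside the prostate (with margin)
    from ``rng`` (or a generator seeded by ``seed``).
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    lesion_radius = overrides.pop("lesion_radius", 8.0)
    lesion_texture = overrides.pop("lesion_texture", LESION_TEXTURE)
    shape = overrides.pop("image_shape", (80, 80))
    pc = overrides.pop("prostate_center", (shape[0] / 2.0, shape[1] / 2.0))
    pr = overrides.pop("prostate_radius", 28.0)
    max_off = pr - lesion_radius - 1.0
    ang = rng.uniform(0, 2 * np.pi)
    rad = max_off * np.sqrt(rng.uniform())
    center = (pc[0] + rad * np.cos(ang), pc[1] + rad * np.sin(ang))
    return PhantomConfig(
        image_shape=shape,
        prostate_center=pc,
        prostate_radius=pr,
        lesion_specs=(LesionSpec(center, lesion_radius, lesion_texture),),
        seed=seed,
        **overrides,
    )


def null_config(seed: int = 0, rng=None, **overrides) -> PhantomConfig:
    """Null study conditions: lesion texture identical to background, so
    cancerous and non-suspicious ROIs are statistically exchangeable."""
    overrides.setdefault("lesion_texture", BACKGROUND_TEXTURE)
    return default_config(seed=seed, rng=rng, **overrides)


def make_study_configs(
    n_pairs: int = 28, seed: int = 0, null: bool = False, **overrides
) -> List[PhantomConfig]:
    """One config per case (slice with one lesion pair), mirroring a study
    of ``n_pairs`` annotated slices.  Case seeds are derived from ``seed``."""
    rng = np.random.default_rng(seed)
    factory = null_config if null else default_config
    configs = []
    for _ in range(n_pairs):
        case_seed = int(rng.integers(0, 2**31 - 1))
        configs.append(factory(seed=case_seed, rng=rng, **overrides))
    return configs
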