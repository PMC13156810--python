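"""Resampling, normalization, label inflation and augmentation.

The localization stage is trained not on the thin lumen label itself but on
an inflated region-of-interest target: per axial slice, the labeled pixels
are replaced by (the union with) a disk centered on their centroid whose
radius is ``(1 + eps)`` times the equivalent-circle radius of the labeled
area,

    r = (1 + eps) * sqrt(l * w * N / pi),

where ``l`` and ``w`` are the in-plane pixel dimensions (mm), ``N`` the
number of labeled pixels on the slice, and ``eps`` in [0, 1] an adjustable
inflation factor.  This guarantees the ROI covers the artery with a
controllable margin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .image import LumenLabel, VolumeImage

__all__ = [
    "DEFAULT_TARGET_SPACING",
    "InflationSpec",
    "SliceLabel",
    "AugmentSpec",
    "resample",
    "resample_label",
    "znorm",
    "slice_center",
    "inflation_radius",
    "inflate_labels",
    "augment",
]

#: Common voxel spacing (slice, row, col) in mm that all volumes are
#: resampled to before localization.
DEFAULT_TARGET_SPACING = (0.59, 0.46, 0.46)


@dataclass(frozen=True)
class InflationSpec:
    """Parameters of the ROI inflation rule."""

    epsilon: float = 0.5  # adjustable inflation factor, in [0, 1]
    pixel_length: float = DEFAULT_TARGET_SPACING[1]  # l, mm
    pixel_width: float = DEFAULT_TARGET_SPACING[2]  # w, mm

    def __post_init__(self) -> None:
        if not (0.0 <= self.epsilon <= 1.0):
            raise ValueError("epsilon must lie in [0, 1]")
        if self.pixel_length <= 0 or self.pixel_width <= 0:
            raise ValueError("pixel dimensions must be positive")


@dataclass
class SliceLabel:
    """Labeled pixel coordinates of one axial slice."""

    slice_index: int
    coords: np.ndarray  # (N, 2) array of (row, col) pixel indices

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 2)

    @property
    def n(self) -> int:
        return len(self.coords)

    @classmethod
    def from_mask_slice(cls, slice_index: int, mask2d: np.ndarray) -> "SliceLabel":
        return cls(slice_index, np.argwhere(np.asarray(mask2d) > 0))


def resample(vol: VolumeImage, target_spacing=DEFAULT_TARGET_SPACING, mode: str = "linear") -> VolumeImage:
    """Resample a volume to ``target_spacing``.

    The output shape is ``round(shape * spacing / target)`` per axis (at
    least 1), which preserves the world extent to within one voxel.  Labels
    must use ``mode="nearest"`` (see :func:`resample_label`).
    """
    target = tuple(float(s) for s in target_spacing)
    if any(s <= 0 for s in target):
        raise ValueError("target spacing must be positive")
    in_shape = np.asarray(vol.shape)
    in_sp = np.asarray(vol.spacing)
    out_shape = np.maximum(np.round(in_shape * in_sp / np.asarray(target)).astype(int), 1)
    if tuple(out_shape) == vol.shape and np.allclose(in_sp, target):
        return VolumeImage(vol.values.copy(), target, vol.origin)
    order = {"linear": 1, "nearest": 0}[mode]
    zoom = out_shape / in_shape
    out = ndimage.zoom(np.asarray(vol.values, dtype=np.float32), zoom, order=order,
                       mode="nearest", grid_mode=True)
    out = np.ascontiguousarray(out[: out_shape[0], : out_shape[1], : out_shape[2]])
    return VolumeImage(out, target, vol.origin)


def resample_label(label: LumenLabel, target_spacing=DEFAULT_TARGET_SPACING) -> LumenLabel:
    """Resample a binary mask: linear interpolation, thresholded at 0.5.

    Interpolating the indicator and taking its 0.5 level set keeps the
    output binary while tracking the surface with sub-voxel accuracy; plain
    nearest-neighbor resampling systematically inflates tubes that are only
    a few voxels thick.
    """
    vol = VolumeImage(label.mask.astype(np.float32), label.spacing, label.origin)
    res = resample(vol, target_spacing, mode="linear")
    return LumenLabel((res.values >= 0.5).astype(np.uint8), res.spacing, res.origin)


def znorm(vol: VolumeImage) -> VolumeImage:
    """Z-score normalize: subtract the mean, divide by the population sd.

    A constant volume maps to all zeros.
    """
    x = np.asarray(vol.values, dtype=np.float64)
    mu = x.mean()
    sd = x.std()
    if sd == 0:
        return vol.with_values(np.zeros_like(x, dtype=np.float32))
    return vol.with_values(((x - mu) / sd).astype(np.float32))


def slice_center(s: SliceLabel) -> tuple[float, float]:
    """Centroid (mean row, mean col) of the labeled pixels of one slice."""
    if s.n == 0:
        raise ValueError(f"slice {s.slice_index} has no labeled pixels (no center)")
    c = s.coords.mean(axis=0)
    return float(c[0]), float(c[1])


def inflation_radius(s: SliceLabel, spec: InflationSpec) -> float:
    """ROI radius (mm): ``(1 + eps) * sqrt(l * w * N / pi)``; 0 if empty."""
    if s.n == 0:
        return 0.0
    return (1.0 + spec.epsilon) * float(
        np.sqrt(spec.pixel_length * spec.pixel_width * s.n / np.pi)
    )


def inflate_labels(label: LumenLabel, spec: InflationSpec | None = None) -> LumenLabel:
    """Build the localization target: per-slice union of the label with the
    inflated disk about the slice centroid.

    The disk is rasterized with the pixel-center-in-circle rule using the
    label's own in-plane spacing; slices without labeled pixels stay empty.
    The output is always a superset of the input.
    """
    if spec is None:
        spec = InflationSpec(pixel_length=label.spacing[1], pixel_width=label.spacing[2])
    mask = np.asarray(label.mask) > 0
    out = mask.copy()
    ly, lx = label.spacing[1], label.spacing[2]
    rows = np.arange(mask.shape[1], dtype=float)
    cols = np.arange(mask.shape[2], dtype=float)
    for i in range(mask.shape[0]):
        sl = SliceLabel.from_mask_slice(i, mask[i])
        if sl.n == 0:
            continue
        cy, cx = slice_center(sl)
        r = inflation_radius(sl, spec)
        dy2 = ((rows - cy) * ly) ** 2
        dx2 = ((cols - cx) * lx) ** 2
        out[i] |= dy2[:, None] + dx2[None, :] <= r * r
    return label.with_mask(out.astype(np.uint8))


# ---------------------------------------------------------------------------
# Augmentation


@dataclass(frozen=True)
class AugmentSpec:
    """Stochastic augmentation for (volume, label) training pairs.

    The transform families are in-plane rotation, isotropic scaling, axis
    flips, additive Gaussian noise, Gaussian smoothing, intensity scaling
    and gamma contrast adjustment.  Spatial transforms are applied
    identically to image and label (label nearest-neighbor); intensity
    transforms touch the image only.  Ranges follow common volumetric
    segmentation practice and are all configurable.
    """

    rotation_deg: float = 30.0
    scale_range: tuple[float, float] = (0.7, 1.4)
    flip_prob: float = 0.5
    noise_sd_range: tuple[float, float] = (0.0, 0.1)
    smooth_sigma_range: tuple[float, float] = (0.5, 1.0)
    intensity_scale_range: tuple[float, float] = (0.75, 1.25)
    gamma_range: tuple[float, float] = (0.7, 1.5)
    p_rotation: float = 0.2
    p_scaling: float = 0.2
    p_noise: float = 0.15
    p_smoothing: float = 0.15
    p_intensity: float = 0.15
    p_contrast: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_rotation, self.p_scaling, self.flip_prob, self.p_noise,
                  self.p_smoothing, self.p_intensity, self.p_contrast):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        for lo, hi in (self.scale_range, self.noise_sd_range, self.smooth_sigma_range,
                       self.intensity_scale_range, self.gamma_range):
            if lo > hi:
                raise ValueError("range lower bound exceeds upper bound")


def augment(
    vol: VolumeImage,
    label: LumenLabel,
    spec: AugmentSpec,
    rng: np.random.Generator | None = None,
) -> tuple[VolumeImage, LumenLabel]:
    """Apply one random draw of the augmentation pipeline to an aligned pair."""
    label.check_aligned(vol)
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    img = np.asarray(vol.values, dtype=np.float32).copy()
    msk = np.asarray(label.mask, dtype=np.float32)
    did_spatial = False

    if rng.random() < spec.p_rotation:
        ang = rng.uniform(-spec.rotation_deg, spec.rotation_deg)
        img = ndimage.rotate(img, ang, axes=(1, 2), reshape=False, order=1, mode="nearest")
        msk = ndimage.rotate(msk, ang, axes=(1, 2), reshape=False, order=0, mode="nearest")
        did_spatial = True
    if rng.random() < spec.p_scaling:
        f = rng.uniform(*spec.scale_range)
        # zoom about the center, keeping the array shape fixed
        img = _center_zoom(img, f, order=1)
        msk = _center_zoom(msk, f, order=0)
        did_spatial = True
    for ax in range(3):
        if rng.random() < spec.flip_prob:
            img = np.flip(img, axis=ax)
            msk = np.flip(msk, axis=ax)
            did_spatial = True
    if rng.random() < spec.p_noise:
        sd = rng.uniform(*spec.noise_sd_range)
        img = img + rng.normal(0, sd, img.shape).astype(np.float32) * max(img.std(), 1e-8)
    if rng.random() < spec.p_smoothing:
        sigma = rng.uniform(*spec.smooth_sigma_range)
        img = ndimage.gaussian_filter(img, sigma)
    if rng.random() < spec.p_intensity:
        img = img * rng.uniform(*spec.intensity_scale_range)
    if rng.random() < spec.p_contrast:
        gamma = rng.uniform(*spec.gamma_range)
        lo, hi = img.min(), img.max()
        if hi > lo:
            img = ((img - lo) / (hi - lo)) ** gamma * (hi - lo) + lo

    out_msk = (np.ascontiguousarray(msk) > 0.5).astype(np.uint8)
    if not did_spatial:
        out_msk = label.mask.copy()
    return (
        vol.with_values(np.ascontiguousarray(img, dtype=np.float32)),
        label.with_mask(out_msk),
    )


def _center_zoom(arr: np.ndarray, factor: float, order: int) -> np.ndarray:
    """Zoom about the array center while keeping the shape fixed."""
    center = (np.asarray(arr.shape) - 1) / 2.0
    matrix = np.eye(3) / factor
    offset = center - matrix @ center
    return ndimage.affine_transform(arr, matrix, offset=offset, order=order, mode="nearest")
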