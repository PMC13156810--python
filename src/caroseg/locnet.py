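"""2D carotid localization stage and ROI crop/reconstruct bookkeeping.

A slice-wise 2D U-Net (8 encoder / 7 decoder stages at full scale) predicts
the inflated region of interest around the artery on every axial slice of
the preprocessed volume.  The union bounding box of the per-slice
predictions, expanded by a safety margin, defines the crop handed to the 3D
segmentation stage; the placement record suffices to re-embed any result
exactly into the original grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .image import LumenLabel, VolumeImage
from .nn import UNet, UNetSpec
from .training import TrainSchedule, train_network

__all__ = [
    "UNet2DConfig",
    "RoiPlacement",
    "NoRoiFoundError",
    "build_locnet",
    "train_locnet",
    "predict_roi",
    "placement_from_mask",
    "crop_to_roi",
    "embed_from_roi",
    "slice_dataset",
]


class NoRoiFoundError(RuntimeError):
    """Raised when no slice's ROI probability exceeds the threshold."""


@dataclass(frozen=True)
class UNet2DConfig:
    """Architecture of the slice-wise localization network.

    The full-scale network has 8 encoder and 7 decoder stages with two
    convolution(+norm+activation) blocks per stage and skip connections;
    base channels double per stage up to a cap.  Smaller stage counts are
    used by the desk profile.
    """

    encoder_stages: int = 8
    base_channels: int = 32
    max_channels: int = 320
    deep_supervision: bool = True
    seed: int = 0

    @property
    def decoder_stages(self) -> int:
        return self.encoder_stages - 1

    def to_unet_spec(self) -> UNetSpec:
        return UNetSpec(
            ndim=2,
            encoder_stages=self.encoder_stages,
            base_channels=self.base_channels,
            max_channels=self.max_channels,
            residual=False,
            deep_supervision=self.deep_supervision,
            seed=self.seed,
        )


def build_locnet(cfg: UNet2DConfig) -> UNet:
    """Instantiate the 2D localization U-Net (seeded, deterministic init)."""
    return UNet(cfg.to_unet_spec())


def slice_dataset(
    vols: list[VolumeImage], targets: list[LumenLabel], nonempty_ratio: float = 1.0,
    rng: np.random.Generator | None = None,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Flatten volumes into (slice, target-slice) training pairs.

    Keeps every slice whose target is non-empty plus a seeded fraction
    ``nonempty_ratio`` (empty:non-empty) of empty slices, so the slice-level
    class balance is controlled.
    """
    rng = rng or np.random.default_rng(0)
    pos, neg = [], []
    for vol, lab in zip(vols, targets):
        lab.check_aligned(vol)
        for i in range(vol.shape[0]):
            pair = (np.asarray(vol.values[i], dtype=np.float32), lab.mask[i].astype(np.float32))
            (pos if pair[1].any() else neg).append(pair)
    n_keep = min(len(neg), int(round(nonempty_ratio * len(pos))))
    keep = rng.permutation(len(neg))[:n_keep]
    return pos + [neg[i] for i in keep]


def train_locnet(
    model: UNet, dataset, schedule: TrainSchedule | None = None
) -> list[dict]:
    """Train the localization net on (slice, inflated-ROI-slice) pairs."""
    schedule = schedule or TrainSchedule.for_2d()
    if schedule.total_epochs > 0 and not dataset:
        raise ValueError("empty training dataset")
    padded = []
    for x, t in dataset:
        xp, _ = _pad2d(model, x)
        tp, _ = _pad2d(model, t)
        padded.append((xp, tp))
    return train_network(model, padded, schedule)


def _pad2d(model: UNet, arr: np.ndarray) -> tuple[np.ndarray, list]:
    out, pads = model.pad_input(arr[None, None])
    return out[0, 0], pads


@dataclass
class RoiPlacement:
    """Where the ROI crop sits inside the preprocessed volume."""

    lo: tuple[int, int, int]  # inclusive start per axis
    hi: tuple[int, int, int]  # exclusive stop per axis
    original_shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    slice_boxes: dict = field(default_factory=dict)  # slice -> (r0, c0, r1, c1)

    def __post_init__(self) -> None:
        for a in range(3):
            if not (0 <= self.lo[a] < self.hi[a] <= self.original_shape[a]):
                raise ValueError(
                    f"crop box [{self.lo}, {self.hi}) outside volume {self.original_shape}"
                )

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(l, h) for l, h in zip(self.lo, self.hi))  # type: ignore

    @property
    def crop_shape(self) -> tuple[int, int, int]:
        return tuple(h - l for l, h in zip(self.lo, self.hi))  # type: ignore


def predict_roi(
    model: UNet,
    vol: VolumeImage,
    threshold: float = 0.5,
    margin: int = 8,
    chunk: int = 8,
) -> tuple[np.ndarray, RoiPlacement]:
    """Slice-wise ROI prediction and the union crop box.

    Returns the stack of per-slice binary ROI masks and the
    :class:`RoiPlacement` whose box is the union bounding box over all
    positive slices, expanded by ``margin`` voxels per axis and clipped to
    the volume bounds.  Raises :class:`NoRoiFoundError` when no voxel
    reaches the threshold.
    """
    vals = np.asarray(vol.values, dtype=np.float32)
    masks = np.zeros(vals.shape, dtype=np.uint8)
    for start in range(0, vals.shape[0], chunk):
        block = vals[start : start + chunk][:, None]
        probs = model.predict_proba(block)[:, 0]
        masks[start : start + chunk] = probs >= threshold
    return masks, placement_from_mask_array(masks, vol.shape, vol.spacing, vol.origin, margin)


def placement_from_mask_array(
    masks: np.ndarray, shape, spacing, origin=(0.0, 0.0, 0.0), margin: int = 8
) -> RoiPlacement:
    if not masks.any():
        raise NoRoiFoundError("no ROI found: no slice exceeds the probability threshold")
    nz = np.nonzero(masks)
    lo = tuple(max(0, int(a.min()) - margin) for a in nz)
    hi = tuple(min(s, int(a.max()) + 1 + margin) for a, s in zip(nz, shape))
    boxes = {}
    for i in np.unique(nz[0]):
        rr, cc = np.nonzero(masks[i])
        boxes[int(i)] = (int(rr.min()), int(cc.min()), int(rr.max()) + 1, int(cc.max()) + 1)
    return RoiPlacement(lo, hi, tuple(shape), tuple(spacing), tuple(origin), boxes)


def placement_from_mask(label: LumenLabel, margin: int = 8) -> RoiPlacement:
    """Oracle placement from a ground-truth mask (testing / upper bound)."""
    return placement_from_mask_array(
        np.asarray(label.mask), label.shape, label.spacing, label.origin, margin
    )


def crop_to_roi(
    vol: VolumeImage | None, label: LumenLabel | None, placement: RoiPlacement
):
    """Crop volume and/or label to the placement box (origin updated)."""
    sl = placement.slices
    new_origin = tuple(
        o + l * s for o, l, s in zip(placement.origin, placement.lo, placement.spacing)
    )
    out_vol = out_lab = None
    if vol is not None:
        if vol.shape != placement.original_shape:
            raise ValueError("placement does not match volume shape")
        out_vol = VolumeImage(np.ascontiguousarray(vol.values[sl]), vol.spacing, new_origin)
    if label is not None:
        if label.shape != placement.original_shape:
            raise ValueError("placement does not match label shape")
        out_lab = LumenLabel(np.ascontiguousarray(label.mask[sl]), label.spacing, new_origin)
    return out_vol, out_lab, placement


def embed_from_roi(sub_mask: np.ndarray, placement: RoiPlacement) -> LumenLabel:
    """Re-embed a crop-sized mask into the full grid (zeros outside)."""
    sub = np.asarray(sub_mask)
    if sub.shape != placement.crop_shape:
        raise ValueError(f"sub-mask shape {sub.shape} != crop {placement.crop_shape}")
    full = np.zeros(placement.original_shape, dtype=np.uint8)
    full[placement.slices] = (sub > 0).astype(np.uint8)
    return LumenLabel(full, placement.spacing, placement.origin)
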