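"""3D residual-encoder U-Net stage: patching, loss, folds, training, ensembling.

The fine stage segments the lumen inside the ROI crop with a 3D U-Net whose
encoder uses residual blocks (6 encoder / 5 decoder stages at full scale;
average pooling replaces strided convolution in designated early stages).
Training follows the shared schedule (SGD-Nesterov, poly decay, BCE+Dice,
deep supervision) over five stratified cross-validation folds; inference
averages the fold models' probabilities and thresholds at 0.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .image import LumenLabel, VolumeImage
from .locnet import RoiPlacement, crop_to_roi, embed_from_roi
from .nn import UNet, UNetSpec, poly_lr, sigmoid
from .training import TrainSchedule, train_network

__all__ = [
    "UNet3DConfig",
    "PatchSpec",
    "FoldSplit",
    "build_segnet",
    "lr_schedule",
    "crop_patches",
    "combined_loss",
    "make_folds",
    "train_segnet",
    "ensemble_predict",
]


@dataclass(frozen=True)
class UNet3DConfig:
    """Architecture of the 3D segmentation network.

    ``avgpool_stages`` lists the (0-based) encoder stages whose first block
    downsamples by average pooling instead of a strided convolution.
    """

    encoder_stages: int = 6
    base_channels: int = 32
    max_channels: int = 320
    avgpool_stages: tuple[int, ...] = (1, 2)
    deep_supervision: bool = True
    seed: int = 0

    @property
    def decoder_stages(self) -> int:
        return self.encoder_stages - 1

    def to_unet_spec(self) -> UNetSpec:
        return UNetSpec(
            ndim=3,
            encoder_stages=self.encoder_stages,
            base_channels=self.base_channels,
            max_channels=self.max_channels,
            residual=True,
            avgpool_stages=tuple(self.avgpool_stages),
            deep_supervision=self.deep_supervision,
            seed=self.seed,
        )


def build_segnet(cfg: UNet3DConfig) -> UNet:
    return UNet(cfg.to_unet_spec())


def lr_schedule(epoch: int, sched: TrainSchedule) -> float:
    """Polynomial decay ``initial_lr * (1 - epoch/total)**0.9``."""
    return poly_lr(epoch, sched.total_epochs, sched.initial_lr, sched.poly_exponent)


@dataclass(frozen=True)
class PatchSpec:
    """Random patch sampling from an ROI crop."""

    n_patches: int = 4
    patch_size: tuple[int, int, int] = (128, 192, 192)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patches < 1:
            raise ValueError("n_patches must be >= 1")
        if any(s < 1 for s in self.patch_size):
            raise ValueError("patch_size must be positive")


def crop_patches(
    vol: np.ndarray,
    label: np.ndarray,
    spec: PatchSpec,
    rng: np.random.Generator | None = None,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Sample ``n_patches`` uniformly random patches of ``patch_size``.

    Inputs smaller than the patch are zero-padded symmetrically first, so a
    placement always exists; identical seeds give identical corners.
    """
    vol = np.asarray(vol)
    label = np.asarray(label)
    if vol.shape != label.shape:
        raise ValueError("volume/label shape mismatch")
    rng = rng or np.random.default_rng(spec.seed)
    ps = spec.patch_size
    pads = []
    for s, p in zip(vol.shape, ps):
        extra = max(0, p - s)
        pads.append((extra // 2, extra - extra // 2))
    if any(a or b for a, b in pads):
        vol = np.pad(vol, pads)
        label = np.pad(label, pads)
    max_corner = [s - p for s, p in zip(vol.shape, ps)]
    out = []
    for _ in range(spec.n_patches):
        corner = [int(rng.integers(0, m + 1)) for m in max_corner]
        sl = tuple(slice(c, c + p) for c, p in zip(corner, ps))
        out.append((vol[sl].copy(), label[sl].copy()))
    return out


def combined_loss(
    pred: np.ndarray, target: np.ndarray, w_bce: float = 1.0, w_dice: float = 1.0
) -> float:
    """BCE + (1 - soft Dice) on *probabilities*, at the given weighting."""
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    if w_bce < 0 or w_dice < 0:
        raise ValueError("weights must be positive")
    eps = 1e-7
    p = np.clip(pred, eps, 1 - eps)
    bce = float(-(target * np.log(p) + (1 - target) * np.log(1 - p)).mean())
    dice_eps = 1e-5
    dice = (2 * (pred * target).sum() + dice_eps) / (pred.sum() + target.sum() + dice_eps)
    return w_bce * bce + w_dice * (1.0 - float(dice))


@dataclass
class FoldSplit:
    """K-fold partition of lesion ids with disjoint validation sets."""

    k: int
    folds: list[tuple[list[str], list[str]]]  # (train_ids, val_ids) per fold
    stratify_keys: tuple[str, ...] = ("grade",)

    def __post_init__(self) -> None:
        all_val = [i for _, v in self.folds for i in v]
        if len(all_val) != len(set(all_val)):
            raise ValueError("validation sets overlap")


def make_folds(manifest, k: int = 5, seed: int = 0,
               stratify=("grade", "scanner_tag")) -> FoldSplit:
    """Stratified k-fold split of a cohort manifest.

    Stratifies on grade (and scanner tag when present); classes with fewer
    than ``k`` members trigger a degraded-stratification warning and a
    fallback to grade-only, then to an unstratified split.
    """
    from sklearn.model_selection import KFold, StratifiedKFold

    ids = manifest["lesion_id"].tolist()
    if len(ids) < k:
        raise ValueError(f"need at least k={k} lesions, got {len(ids)}")
    keys = [key for key in stratify if key in manifest.columns]

    def key_series(cols):
        return manifest[list(cols)].astype(str).agg("|".join, axis=1)

    chosen = None
    for cols in (keys, ["grade"] if "grade" in manifest.columns else []):
        if not cols:
            continue
        y = key_series(cols)
        if y.value_counts().min() >= k:
            chosen = (cols, y)
            break
        if list(cols) == keys and len(keys) > 1:
            warnings.warn(
                "some grade x scanner classes have fewer members than k; "
                "falling back to grade-only stratification", stacklevel=2,
            )
    folds = []
    if chosen is not None:
        cols, y = chosen
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        for tr, va in skf.split(np.zeros(len(ids)), y):
            folds.append(([ids[i] for i in tr], [ids[i] for i in va]))
        keys_used = tuple(cols)
    else:
        warnings.warn("stratification degraded: some class has < k members; "
                      "using an unstratified split", stacklevel=2)
        kf = KFold(n_splits=k, shuffle=True, random_state=seed)
        for tr, va in kf.split(np.zeros(len(ids))):
            folds.append(([ids[i] for i in tr], [ids[i] for i in va]))
        keys_used = ()
    return FoldSplit(k=k, folds=folds, stratify_keys=keys_used)


def train_segnet(
    cfg: UNet3DConfig,
    dataset: dict,
    folds: FoldSplit,
    schedule: TrainSchedule | None = None,
    patch_spec: PatchSpec | None = None,
) -> tuple[list[UNet], list[list[dict]]]:
    """Train one 3D network per fold on random ROI patches.

    ``dataset`` maps lesion_id to an (image array, label array) pair already
    preprocessed and cropped to the ROI.  Fresh patches are drawn each epoch
    from every training lesion.  Returns the fold models and their training
    histories.
    """
    schedule = schedule or TrainSchedule.for_3d()
    patch_spec = patch_spec or PatchSpec()
    models, histories = [], []
    for fold_idx, (train_ids, _val_ids) in enumerate(folds.folds):
        if not train_ids:
            raise ValueError(f"fold {fold_idx} has an empty training set")
        model = build_segnet(
            UNet3DConfig(**{**cfg.__dict__, "seed": cfg.seed + fold_idx})
        )
        div = model.spec.divisor
        patch = tuple(-(-p // div) * div for p in patch_spec.patch_size)
        ps = PatchSpec(patch_spec.n_patches, patch, patch_spec.seed)

        def epoch_data(epoch, rng, _ids=train_ids):
            out = []
            for lid in _ids:
                img, lab = dataset[lid]
                out.extend(crop_patches(img, lab, ps, rng=rng))
            return out

        rng = np.random.default_rng(schedule.seed * 9973 + fold_idx)
        hist = train_network(model, None, schedule, rng=rng, epoch_data_fn=epoch_data)
        models.append(model)
        histories.append(hist)
    return models, histories


def ensemble_predict(
    models: list[UNet],
    vol: VolumeImage,
    placement: RoiPlacement | None = None,
    threshold: float = 0.5,
    largest_component: bool = False,
) -> LumenLabel:
    """Fold-ensemble inference: mean of fold probabilities, thresholded.

    When ``placement`` is given, inference runs on the ROI crop and the
    result is re-embedded into the full grid (zeros outside the box).
    """
    if not models:
        raise ValueError("need at least one model")
    if placement is not None:
        crop, _, _ = crop_to_roi(vol, None, placement)
        x = crop.values
    else:
        x = vol.values
    x = np.asarray(x, dtype=np.float32)[None, None]
    prob = np.zeros(x.shape[2:], dtype=np.float64)
    for m in models:
        prob += m.predict_proba(x)[0, 0]
    prob /= len(models)
    mask = (prob >= threshold).astype(np.uint8)
    if largest_component and mask.any():
        from scipy import ndimage

        lab, n = ndimage.label(mask)
        if n > 1:
            sizes = ndimage.sum_labels(mask, lab, index=np.arange(1, n + 1))
            mask = (lab == (1 + int(np.argmax(sizes)))).astype(np.uint8)
    if placement is not None:
        return embed_from_roi(mask, placement)
    return LumenLabel(mask, vol.spacing, vol.origin)
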