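"""End-to-end orchestration of the three-stage cascade.

``run_cohort_experiment`` drives the full study design on a (synthetic)
cohort: per-fold training of the 2D localizer on inflated-ROI targets,
ROI cropping, per-fold training of the 3D segmenter on random patches,
held-out prediction per fold, and fold-ensemble prediction per lesion.
Setting ``with_localization=False`` removes the localization stage (the
segmenter then sees whole volumes), which is the ablation the cascade is
compared against.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .config import PipelineConfig
from .image import LumenLabel, VolumeImage
from .locnet import (NoRoiFoundError, RoiPlacement, UNet2DConfig, build_locnet,
                     crop_to_roi, placement_from_mask_array, predict_roi,
                     slice_dataset, train_locnet)
from .metrics import seg_metrics
from .phantom import generate_cohort
from .preprocess import InflationSpec, inflate_labels, znorm
from .segnet import (PatchSpec, UNet3DConfig, build_segnet, ensemble_predict,
                     make_folds, train_segnet)
from .training import TrainSchedule

logger = logging.getLogger("caroseg")

__all__ = ["CohortRun", "run_cohort_experiment", "prepare_cohort", "quantify_prediction"]


@dataclass
class CohortRun:
    """Results of one cohort training/evaluation run."""

    fold_val_dice: list[float]  # mean validation Dice per fold (fold model)
    ensemble_dice: dict[str, float]  # per-lesion Dice of the fold ensemble
    histories: list[list[dict]]
    with_localization: bool
    lost_label_voxels: int = 0  # labeled voxels outside ROI crops (cascade containment)

    @property
    def mean_ensemble_dice(self) -> float:
        return float(np.mean(list(self.ensemble_dice.values())))


def prepare_cohort(cfg: PipelineConfig, n_lesions: int, seed: int | None = None):
    """Generate and preprocess a phantom cohort per the config's profile.

    Returns (manifest, dict lesion_id -> (z-scored VolumeImage, LumenLabel,
    GroundTruthRecord)).  Phantoms are generated at the profile's grid; no
    resampling is needed since generation and the pipeline share a spacing.
    """
    from .phantom import PhantomSpec

    seed = cfg.stage_seed("cohort") if seed is None else seed
    template = PhantomSpec(
        grid_shape=tuple(cfg.phantom.grid_shape),
        spacing=tuple(cfg.phantom.spacing),
        segment_length=cfg.phantom.segment_length,
        noise_sd=cfg.phantom.noise_sd,
    )
    manifest, phantoms = generate_cohort(n_lesions, seed=seed, spec_template=template)
    data = {}
    for row, (vol, lab, truth) in zip(manifest.itertuples(), phantoms):
        data[row.lesion_id] = (znorm(vol), lab, truth)
    return manifest, data


def _full_placement(shape, spacing, origin) -> RoiPlacement:
    return RoiPlacement((0, 0, 0), tuple(shape), tuple(shape), tuple(spacing), tuple(origin))


def run_cohort_experiment(
    cfg: PipelineConfig,
    manifest,
    data: dict,
    with_localization: bool = True,
    ensemble: bool = True,
) -> CohortRun:
    """Five-fold train/validate/ensemble over a prepared cohort."""
    folds = make_folds(manifest, k=cfg.train.k_folds, seed=cfg.stage_seed("segnet"))
    infl = InflationSpec(
        cfg.preprocess.epsilon, cfg.phantom.spacing[1], cfg.phantom.spacing[2]
    )
    loc_sched = TrainSchedule.for_2d(
        batch_size=cfg.locnet.batch_size, total_epochs=cfg.locnet.epochs,
        initial_lr=cfg.train.initial_lr, poly_exponent=cfg.train.poly_exponent,
        momentum=cfg.train.momentum, deep_supervision=cfg.train.deep_supervision,
        grad_clip=cfg.train.grad_clip, seed=cfg.stage_seed("locnet"),
    )
    seg_sched = TrainSchedule.for_3d(
        batch_size=cfg.segnet.batch_size, total_epochs=cfg.segnet.epochs,
        initial_lr=cfg.train.initial_lr, poly_exponent=cfg.train.poly_exponent,
        momentum=cfg.train.momentum, deep_supervision=cfg.train.deep_supervision,
        grad_clip=cfg.train.grad_clip, seed=cfg.stage_seed("segnet"),
    )
    patch_spec = PatchSpec(cfg.segnet.n_patches, tuple(cfg.segnet.patch_size),
                           cfg.stage_seed("segnet"))

    placements: dict[str, RoiPlacement] = {}
    lost = 0
    fold_models = []
    fold_val_dice = []
    histories = []
    for fold_idx, (train_ids, val_ids) in enumerate(folds.folds):
        logger.info("fold %d: %d train / %d val", fold_idx, len(train_ids), len(val_ids))
        if with_localization:
            locnet = build_locnet(UNet2DConfig(
                encoder_stages=cfg.locnet.encoder_stages,
                base_channels=cfg.locnet.base_channels,
                max_channels=cfg.locnet.max_channels,
                deep_supervision=cfg.train.deep_supervision,
                seed=cfg.stage_seed("locnet") + fold_idx,
            ))
            vols, targets = [], []
            stride = max(1, cfg.locnet.slice_stride)
            for lid in train_ids:
                vol, lab, _ = data[lid]
                target = inflate_labels(lab, infl)
                vols.append(VolumeImage(vol.values[::stride], vol.spacing, vol.origin))
                targets.append(LumenLabel(target.mask[::stride], lab.spacing, lab.origin))
            ds = slice_dataset(vols, targets,
                               rng=np.random.default_rng(loc_sched.seed + fold_idx))
            train_locnet(locnet, ds, loc_sched)

            def _locate(lid):
                vol, _, _ = data[lid]
                try:
                    _, pl = predict_roi(locnet, vol, threshold=cfg.locnet.threshold,
                                        margin=cfg.locnet.margin)
                except NoRoiFoundError:
                    logger.warning("no ROI found for %s; using the full volume", lid)
                    pl = _full_placement(vol.shape, vol.spacing, vol.origin)
                return pl

            fold_placements = {lid: _locate(lid) for lid in train_ids}
            # a lesion's held-out placement comes from the fold that never saw it
            for lid in val_ids:
                placements[lid] = _locate(lid)
        else:
            fold_placements = {}
            for lid in train_ids + val_ids:
                vol, _, _ = data[lid]
                fold_placements[lid] = _full_placement(vol.shape, vol.spacing, vol.origin)
                placements.setdefault(lid, fold_placements[lid])

        crops = {}
        for lid in train_ids:
            vol, lab, _ = data[lid]
            pl_train = fold_placements[lid] if lid in fold_placements else placements[lid]
            cvol, clab, _ = crop_to_roi(vol, lab, pl_train)
            lost += int(lab.mask.sum()) - int(clab.mask.sum())
            crops[lid] = (cvol.values, clab.mask)
        one_fold = type(folds)(k=1, folds=[(train_ids, val_ids)],
                               stratify_keys=folds.stratify_keys)
        seg_cfg = UNet3DConfig(
            encoder_stages=cfg.segnet.encoder_stages,
            base_channels=cfg.segnet.base_channels,
            max_channels=cfg.segnet.max_channels,
            avgpool_stages=tuple(cfg.segnet.avgpool_stages),
            deep_supervision=cfg.train.deep_supervision,
            seed=cfg.stage_seed("segnet") + fold_idx,
        )
        models, hists = train_segnet(seg_cfg, crops, one_fold, seg_sched, patch_spec)
        fold_models.append(models[0])
        histories.append(hists[0])

        dices = []
        for lid in val_ids:
            vol, lab, _ = data[lid]
            pred = ensemble_predict([models[0]], vol, placements[lid])
            dices.append(seg_metrics(pred, lab).dsc)
        fold_val_dice.append(float(np.mean(dices)))
        logger.info("fold %d val Dice %.3f", fold_idx, fold_val_dice[-1])

    ensemble_dice = {}
    if ensemble:
        for lid in manifest["lesion_id"]:
            vol, lab, _ = data[lid]
            pred = ensemble_predict(fold_models, vol, placements[lid])
            ensemble_dice[lid] = seg_metrics(pred, lab).dsc
    return CohortRun(fold_val_dice, ensemble_dice, histories, with_localization, lost)


def quantify_prediction(mask: LumenLabel, cfg: PipelineConfig):
    """Stenosis quantification of a predicted (or reference) mask."""
    from .stenosis import quantify

    st = cfg.stenosis
    return quantify(
        mask, step=st.step, plane_size=st.plane_size, plane_spacing=st.plane_spacing,
        smooth_window=st.smooth_window, guard_mm=st.guard_mm,
        end_guard_mm=st.end_guard_mm, rvd_strategy=st.rvd_strategy,
    )
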