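"""3D segmentation stage: schedule, patches, loss, folds, ensembling."""

import numpy as np
import pytest

from caroseg.image import LumenLabel, VolumeImage
from caroseg.locnet import placement_from_mask, crop_to_roi
from caroseg.nn import soft_dice
from caroseg.preprocess import znorm
from caroseg.segnet import (
    FoldSplit,
    PatchSpec,
    UNet3DConfig,
    build_segnet,
    combined_loss,
    crop_patches,
    ensemble_predict,
    lr_schedule,
    make_folds,
    train_segnet,
)
from caroseg.training import TrainSchedule


class TestLrSchedule:
    def test_initial_value(self):
        assert lr_schedule(0, TrainSchedule()) == 0.01

    def test_final_epoch_zero(self):
        assert lr_schedule(1000, TrainSchedule()) == 0.0

    def test_midpoint_value(self):
        assert lr_schedule(500, TrainSchedule()) == pytest.approx(0.0053589, abs=1e-6)

    def test_matches_closed_form_at_random_epochs(self, rng):
        sched = TrainSchedule()
        for _ in range(100):
            e = int(rng.integers(0, 1001))
            assert lr_schedule(e, sched) == pytest.approx(0.01 * (1 - e / 1000) ** 0.9)


class TestCropPatches:
    def test_input_exactly_patch_size_gives_identical_patches(self, rng):
        vol = rng.normal(size=(8, 12, 12)).astype(np.float32)
        lab = (rng.random((8, 12, 12)) < 0.2).astype(np.uint8)
        out = crop_patches(vol, lab, PatchSpec(4, (8, 12, 12), seed=0))
        assert len(out) == 4
        for p, q in out:
            assert np.array_equal(p, vol)
            assert np.array_equal(q, lab)

    def test_seeded_corners_reproducible_and_seed_sensitive(self, rng):
        vol = rng.normal(size=(16, 20, 20)).astype(np.float32)
        lab = np.zeros_like(vol, dtype=np.uint8)
        a = crop_patches(vol, lab, PatchSpec(4, (8, 8, 8), seed=5))
        b = crop_patches(vol, lab, PatchSpec(4, (8, 8, 8), seed=5))
        c = crop_patches(vol, lab, PatchSpec(4, (8, 8, 8), seed=6))
        assert all(np.array_equal(x[0], y[0]) for x, y in zip(a, b))
        assert any(not np.array_equal(x[0], y[0]) for x, y in zip(a, c))

    def test_small_input_padded_to_fit(self, rng):
        vol = rng.normal(size=(4, 6, 6)).astype(np.float32)
        lab = np.zeros_like(vol, dtype=np.uint8)
        out = crop_patches(vol, lab, PatchSpec(2, (8, 8, 8), seed=0))
        assert all(p.shape == (8, 8, 8) for p, _ in out)


class TestCombinedLoss:
    def test_perfect_prediction_near_zero(self):
        t = np.zeros((4, 4, 4)); t[:2] = 1
        pred = np.clip(t, 1e-7, 1 - 1e-7)
        assert combined_loss(pred, t) <= 1e-5

    def test_total_miss_dice_term_one(self):
        t = np.zeros((4, 4)); t[:2] = 1
        pred = 1.0 - t
        loss = combined_loss(pred, t)
        # BCE explodes at clamped certainty; the Dice part contributes ~1
        p = np.clip(pred, 1e-7, 1 - 1e-7)
        bce = float(-(t * np.log(p) + (1 - t) * np.log(1 - p)).mean())
        assert loss - bce == pytest.approx(1.0, abs=1e-3)

    def test_hand_computed_two_by_two(self):
        pred = np.array([0.9, 0.1, 0.8, 0.2]).reshape(2, 2)
        t = np.array([1.0, 0.0, 1.0, 0.0]).reshape(2, 2)
        # independent scalar evaluation of BCE + (1 - soft Dice)
        bce = -(np.log(0.9) + np.log(0.9) + np.log(0.8) + np.log(0.8)) / 4
        dice = (2 * (0.9 + 0.8) + 1e-5) / ((0.9 + 0.1 + 0.8 + 0.2) + 2 + 1e-5)
        assert combined_loss(pred, t) == pytest.approx(bce + (1 - dice), abs=1e-9)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            combined_loss(np.zeros((2, 2)), np.zeros((2, 3)))


class TestMakeFolds:
    @staticmethod
    def _manifest(grades, scanners=None):
        import pandas as pd

        n = len(grades)
        d = {"lesion_id": [f"l{i:02d}" for i in range(n)], "grade": grades}
        if scanners is not None:
            d["scanner_tag"] = scanners
        return pd.DataFrame(d)

    def test_ten_lesions_five_folds_two_validation_each(self):
        man = self._manifest(["severe"] * 5 + ["moderate"] * 5)
        split = make_folds(man, k=5, seed=0)
        assert split.k == 5
        assert all(len(v) == 2 for _, v in split.folds)

    def test_stratification_balances_grades_across_folds(self):
        man = self._manifest(["severe"] * 5 + ["moderate"] * 5)
        split = make_folds(man, k=5, seed=0)
        sev = set(man.loc[man.grade == "severe", "lesion_id"])
        for _, val in split.folds:
            assert sum(v in sev for v in val) == 1

    def test_validation_sets_partition_the_cohort(self):
        man = self._manifest(["severe"] * 6 + ["moderate"] * 6 + ["mild"] * 5)
        split = make_folds(man, k=5, seed=1)
        all_val = sorted(v for _, val in split.folds for v in val)
        assert all_val == sorted(man["lesion_id"])

    def test_small_class_degrades_with_warning(self):
        man = self._manifest(["severe"] * 8 + ["mild"] * 2)
        with pytest.warns(UserWarning, match="stratification"):
            split = make_folds(man, k=5, seed=0)
        assert split.k == 5

    def test_fewer_lesions_than_folds_rejected(self):
        man = self._manifest(["severe"] * 3)
        with pytest.raises(ValueError):
            make_folds(man, k=5)

    def test_overlapping_validation_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            FoldSplit(k=2, folds=[(["a"], ["b"]), (["b"], ["b"])])


class _StubModel:
    """Constant-probability model for ensembling arithmetic tests."""

    def __init__(self, p):
        self.p = p

    def predict_proba(self, x):
        return np.full_like(np.asarray(x, dtype=np.float32), self.p)


class TestEnsemblePredict:
    def _vol(self):
        return VolumeImage(np.zeros((4, 4, 4), np.float32), (1, 1, 1))

    def test_single_model_equals_thresholded_output(self):
        out = ensemble_predict([_StubModel(0.7)], self._vol())
        assert out.mask.all()
        out = ensemble_predict([_StubModel(0.3)], self._vol())
        assert not out.mask.any()

    def test_five_copies_equal_single_model(self):
        single = ensemble_predict([_StubModel(0.7)], self._vol())
        five = ensemble_predict([_StubModel(0.7)] * 5, self._vol())
        assert np.array_equal(single.mask, five.mask)

    def test_mean_of_point_eight_and_point_four_is_foreground(self):
        out = ensemble_predict([_StubModel(0.8), _StubModel(0.4)], self._vol())
        assert out.mask.all()  # mean 0.6 >= 0.5

    def test_no_models_rejected(self):
        with pytest.raises(ValueError):
            ensemble_predict([], self._vol())


class TestTrainSegnet:
    def test_epochs_zero_leaves_weights_unchanged(self):
        cfg = UNet3DConfig(encoder_stages=3, base_channels=4, max_channels=16, seed=0)
        model = build_segnet(cfg)
        before = model.state_dict()
        dataset = {"a": (np.zeros((8, 8, 8), np.float32), np.zeros((8, 8, 8), np.uint8))}
        folds = FoldSplit(k=1, folds=[(["a"], [])])
        models, hist = train_segnet(cfg, dataset, folds,
                                    TrainSchedule.for_3d(total_epochs=0),
                                    PatchSpec(1, (8, 8, 8), 0))
        after = models[0].state_dict()
        assert all(np.array_equal(before[k], after[k]) for k in before)
        assert hist[0] == []

    def test_empty_fold_rejected(self):
        cfg = UNet3DConfig(encoder_stages=3, base_channels=4, seed=0)
        with pytest.raises(ValueError, match="empty"):
            train_segnet(cfg, {}, FoldSplit(k=1, folds=[([], [])]),
                         TrainSchedule.for_3d(total_epochs=1), PatchSpec(1, (8, 8, 8), 0))

    def test_overfit_single_phantom_reaches_dice(self, small_phantom):
        vol, label, _ = small_phantom
        pl = placement_from_mask(label, margin=6)
        cvol, clab, _ = crop_to_roi(znorm(vol), label, pl)
        cfg = UNet3DConfig(encoder_stages=4, base_channels=8, max_channels=64,
                           avgpool_stages=(1, 2), seed=0)
        dataset = {"a": (cvol.values, clab.mask)}
        folds = FoldSplit(k=1, folds=[(["a"], [])])
        # 25 epochs x 2 patches / batch 1 = 50 gradient steps
        sched = TrainSchedule.for_3d(batch_size=1, total_epochs=25)
        models, hist = train_segnet(cfg, dataset, folds, sched,
                                    PatchSpec(2, (16, 24, 24), 0))
        assert hist[0][-1]["loss"] < 0.5 * hist[0][0]["loss"]
        prob = models[0].predict_proba(cvol.values[None, None])[0, 0]
        dice = soft_dice((prob >= 0.5).astype(np.float32), clab.mask.astype(np.float32))
        assert dice >= 0.8
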