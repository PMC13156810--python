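"""Agreement statistics against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import cdist

from caroseg.metrics import (
    boundary_voxels,
    ccc,
    diag_metrics,
    icc_agreement,
    seg_metrics,
    subgroup_report,
    wilcoxon_signed_rank,
)


def brute_force_surface_distances(pred, truth, spacing=(1, 1, 1)):
    """All-pairs boundary distance oracle (no KD-tree)."""
    sp = np.asarray(spacing, float)
    bp = boundary_voxels(pred) * sp
    bt = boundary_voxels(truth) * sp
    d = cdist(bp, bt)
    d_pt = d.min(axis=1)
    d_tp = d.min(axis=0)
    pooled = np.concatenate([d_pt, d_tp])
    return pooled.mean(), np.percentile(pooled, 95)


class TestSegMetrics:
    def test_identity(self):
        m = np.zeros((6, 6, 6), np.uint8)
        m[2:5, 2:5, 2:5] = 1
        r = seg_metrics(m, m)
        assert (r.dsc, r.iou, r.rve, r.assd, r.hd95) == (1.0, 1.0, 0.0, 0.0, 0.0)
        assert r.sens == 1.0

    def test_disjoint(self):
        a = np.zeros((8, 8, 8), np.uint8); a[:2] = 1
        b = np.zeros((8, 8, 8), np.uint8); b[6:] = 1
        r = seg_metrics(a, b)
        assert r.dsc == 0.0 and r.iou == 0.0 and r.sens == 0.0

    def test_hand_counted_overlap(self):
        # |P|=4, |T|=6, |P cap T|=3 -> dsc 0.6, iou 3/7
        p = np.zeros((4, 4, 4), np.uint8)
        t = np.zeros((4, 4, 4), np.uint8)
        t[0, 0, :3] = 1; t[1, 0, :3] = 1
        p[0, 0, :3] = 1; p[3, 3, 3] = 1
        r = seg_metrics(p, t)
        assert r.dsc == pytest.approx(0.6)
        assert r.iou == pytest.approx(3 / 7)
        assert r.rve == pytest.approx(2 / 6)
        assert r.sens == pytest.approx(0.5)

    def test_shifted_cube_matches_brute_force_exactly(self):
        a = np.zeros((8, 8, 8), np.uint8); a[2:5, 2:5, 2:5] = 1
        b = np.roll(a, 1, axis=0)
        r = seg_metrics(a, b)
        assd, hd95 = brute_force_surface_distances(b, a)
        assert r.assd == pytest.approx(assd, abs=0)
        assert r.hd95 == pytest.approx(hd95, abs=0)

    def test_random_masks_match_brute_force(self, rng):
        for _ in range(25):
            a = (rng.random((10, 10, 10)) < 0.25).astype(np.uint8)
            b = (rng.random((10, 10, 10)) < 0.25).astype(np.uint8)
            if not a.any() or not b.any():
                continue
            r = seg_metrics(a, b)
            assd, hd95 = brute_force_surface_distances(a, b)
            assert r.assd == pytest.approx(assd, rel=1e-12)
            assert r.hd95 == pytest.approx(hd95, rel=1e-12)
            assert r.dsc == pytest.approx(2 * r.iou / (1 + r.iou))

    def test_spacing_scales_surface_distances(self):
        a = np.zeros((8, 8, 8), np.uint8); a[2:5, 2:5, 2:5] = 1
        b = np.roll(a, 1, axis=0)
        from caroseg.image import LumenLabel

        r1 = seg_metrics(LumenLabel(a, (1, 1, 1)), LumenLabel(b, (1, 1, 1)))
        r2 = seg_metrics(LumenLabel(a, (2, 2, 2)), LumenLabel(b, (2, 2, 2)))
        assert r2.assd == pytest.approx(2 * r1.assd)

    def test_empty_reference_rejected(self):
        a = np.zeros((4, 4, 4), np.uint8); a[0] = 1
        with pytest.raises(ValueError):
            seg_metrics(a, np.zeros((4, 4, 4), np.uint8))


class TestDiagMetrics:
    def test_perfect_predictions(self):
        r = diag_metrics([1, 1, 0, 0], [1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1])
        assert (r.acc, r.f1, r.sens, r.precision, r.spec, r.auc) == (1, 1, 1, 1, 1, 1)

    def test_all_positive_on_balanced_truth(self):
        r = diag_metrics([1, 1, 0, 0], [1, 1, 1, 1])
        assert r.sens == 1.0 and r.spec == 0.0 and r.acc == 0.5

    def test_auc_matches_mann_whitney_enumeration(self):
        r = diag_metrics([1, 1, 0, 0], [1, 0, 1, 0], [0.9, 0.4, 0.6, 0.1])
        assert r.auc == pytest.approx(0.75)  # 3 of 4 positive-negative pairs ordered

    def test_subject_permutation_invariance(self, rng):
        y = rng.integers(0, 2, 30); y[0], y[1] = 0, 1
        yhat = rng.integers(0, 2, 30)
        s = rng.random(30)
        perm = rng.permutation(30)
        r1 = diag_metrics(y, yhat, s)
        r2 = diag_metrics(y[perm], yhat[perm], s[perm])
        for k in ("acc", "f1", "sens", "precision", "spec", "auc"):
            assert getattr(r1, k) == pytest.approx(getattr(r2, k))

    def test_single_class_truth_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            diag_metrics([1, 1, 1], [1, 0, 1], [0.9, 0.2, 0.8])

    def test_confusion_counts_sum_to_n(self):
        r = diag_metrics([1, 0, 1, 0, 1], [1, 1, 0, 0, 1])
        assert r.confusion.sum() == 5


class TestCCC:
    def test_perfect_agreement(self):
        x = np.arange(10.0)
        assert ccc(x, x).estimate == pytest.approx(1.0)

    def test_perfect_disagreement_zero_mean(self):
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        assert ccc(x, -x).estimate == pytest.approx(-1.0)

    def test_hand_algebra_example(self):
        r = ccc([1, 2, 3], [2, 3, 4])
        assert r.estimate == pytest.approx(4 / 7)

    def test_ci_brackets_estimate(self, rng):
        x = rng.normal(size=50)
        y = x + rng.normal(0, 0.5, 50)
        r = ccc(x, y)
        assert r.ci_low <= r.estimate <= r.ci_high

    def test_ccc_never_exceeds_pearson(self, rng):
        for _ in range(20):
            x = rng.normal(size=30)
            y = 0.5 * x + rng.normal(0, 1, 30) + rng.normal()
            c = ccc(x, y).estimate
            p = stats.pearsonr(x, y)[0]
            assert abs(c) <= abs(p) + 1e-12

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError):
            ccc([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])


class TestICC:
    def test_identical_raters_give_one(self, rng):
        r = np.tile(rng.normal(size=10)[:, None], (1, 3))
        assert icc_agreement(r).estimate == pytest.approx(1.0, abs=1e-9)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(77)
        r = rng.normal(size=(200, 2))
        est = icc_agreement(r).estimate
        assert abs(est) <= 0.15

    def test_four_by_two_hand_table_matches_anova_arithmetic(self):
        r = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0], [7.0, 9.0]])
        n, k = r.shape
        # independent mean-squares computation
        grand = r.mean()
        msr = k * ((r.mean(1) - grand) ** 2).sum() / (n - 1)
        msc = n * ((r.mean(0) - grand) ** 2).sum() / (k - 1)
        mse = (((r - grand) ** 2).sum() - (n - 1) * msr - (k - 1) * msc) / ((n - 1) * (k - 1))
        expect = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        assert icc_agreement(r).estimate == pytest.approx(expect)

    def test_matches_pingouin_two_way_random_absolute(self, rng):
        pg = pytest.importorskip("pingouin")
        subj = rng.normal(0, 2, 15)
        r = subj[:, None] + rng.normal(0, 1, (15, 3)) + np.array([0, 0.4, -0.2])
        mine = icc_agreement(r)
        df = pd.DataFrame({
            "s": np.repeat(np.arange(15), 3),
            "r": np.tile(np.arange(3), 15),
            "y": r.ravel(),
        })
        ref = pg.intraclass_corr(df, targets="s", raters="r", ratings="y")
        row = ref[ref["Type"] == "ICC(A,1)"].iloc[0]
        assert mine.estimate == pytest.approx(row["ICC"], abs=1e-9)
        assert (round(mine.ci_low, 2), round(mine.ci_high, 2)) == tuple(row["CI95"])


class TestWilcoxon:
    def test_all_zero_differences_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])

    def test_five_pairs_match_sign_enumeration(self):
        x = np.array([1.2, -0.5, 2.0, 0.7, -0.1])
        y = np.zeros(5)
        _, p = wilcoxon_signed_rank(x, y)
        from itertools import product

        ranks = stats.rankdata(np.abs(x))
        obs = ranks[x > 0].sum()
        ge = sum(sum(r for s, r in zip(signs, ranks) if s) >= obs
                 for signs in product([0, 1], repeat=5))
        le = sum(sum(r for s, r in zip(signs, ranks) if s) <= obs
                 for signs in product([0, 1], repeat=5))
        assert p == pytest.approx(min(1.0, 2 * min(ge, le) / 32))

    def test_matches_scipy_exact_without_ties(self, rng):
        x = rng.normal(0.4, 1, 14)
        y = rng.normal(0, 1, 14)
        _, p = wilcoxon_signed_rank(x, y)
        assert p == pytest.approx(stats.wilcoxon(x, y, method="exact").pvalue)

    def test_matches_scipy_normal_approximation_for_large_n(self, rng):
        x = rng.normal(0.2, 1, 60)
        y = rng.normal(0, 1, 60)
        _, p = wilcoxon_signed_rank(x, y)
        ref = stats.wilcoxon(x, y, method="approx", correction=False).pvalue
        assert p == pytest.approx(ref, rel=1e-9)

    def test_one_sided_alternatives_are_complementary(self, rng):
        x = rng.normal(0.5, 1, 10)
        y = rng.normal(0, 1, 10)
        _, pg = wilcoxon_signed_rank(x, y, "greater")
        _, pl = wilcoxon_signed_rank(x, y, "less")
        assert pg + pl > 1.0  # both include the observed point mass


class TestSubgroupReport:
    def _table(self):
        return pd.DataFrame({
            "lesion_id": [f"l{i}" for i in range(8)],
            "grade": ["severe"] * 4 + ["moderate"] * 4,
            "dsc": [0.9, 0.92, 0.88, 0.9, 0.8, 0.82, 0.78, 0.8],
            "vol_pred": [10, 12, 11, 10, 20, 22, 21, 20],
            "vol_true": [10, 12, 11, 10.5, 20, 21.5, 21, 20],
        })

    def test_single_subgroup_equals_global_summary(self):
        t = self._table().assign(grade="severe")
        rep = subgroup_report(t, keys=("grade",), metric_cols=["dsc"])
        assert len(rep) == 1
        assert rep["dsc_mean"][0] == pytest.approx(t["dsc"].mean())

    def test_disjoint_subgroups_partition_lesions(self):
        rep = subgroup_report(self._table(), keys=("grade",), metric_cols=["dsc"])
        assert sorted(rep["grade"]) == ["moderate", "severe"]
        assert rep["n"].sum() == 8

    def test_group_means_match_direct_computation(self):
        t = self._table()
        rep = subgroup_report(t, keys=("grade",), metric_cols=["dsc"],
                              pair_cols=("vol_pred", "vol_true"))
        row = rep[rep["grade"] == "severe"].iloc[0]
        sub = t[t["grade"] == "severe"]
        assert row["dsc_mean"] == pytest.approx(sub["dsc"].mean())
        assert row["dsc_sd"] == pytest.approx(sub["dsc"].std(ddof=1))
        assert row["ccc"] == pytest.approx(ccc(sub["vol_pred"], sub["vol_true"]).estimate)

    def test_missing_keys_rejected(self):
        with pytest.raises(ValueError):
            subgroup_report(self._table(), keys=("scanner_tag",))
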