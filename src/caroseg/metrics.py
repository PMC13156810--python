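"""Segmentation, diagnostic and agreement statistics.

Overlap metrics (Dice, IoU, relative volume error, voxel sensitivity and
specificity) and surface distances (average symmetric surface distance,
95th-percentile Hausdorff) evaluate masks against references; diagnostic
metrics treat each artery as a subject of the two-class severe / non-severe
task; agreement between paired continuous measurements uses Lin's
concordance correlation coefficient and the two-way random, absolute
agreement, single-measure intraclass correlation; paired performance
differences use the Wilcoxon signed-rank test.

Surface extraction uses 6-connectivity face exposure; distances are
computed between boundary voxel centers in mm.  Specificity for
segmentation is meaningful only on ROI-sized crops (on a whole volume the
overwhelming background pins it at 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
from scipy import ndimage, stats
from scipy.spatial import cKDTree

__all__ = [
    "SegMetrics",
    "DiagMetrics",
    "AgreementStats",
    "seg_metrics",
    "diag_metrics",
    "ccc",
    "icc_agreement",
    "wilcoxon_signed_rank",
    "subgroup_report",
    "boundary_voxels",
]


# ---------------------------------------------------------------------------
# Segmentation metrics


@dataclass
class SegMetrics:
    dsc: float
    iou: float
    rve: float
    sens: float
    spec: float
    assd: float  # mm
    hd95: float  # mm

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def boundary_voxels(mask: np.ndarray) -> np.ndarray:
    """Indices (K, 3) of foreground voxels with an exposed face (6-conn)."""
    m = np.asarray(mask).astype(bool)
    eroded = ndimage.binary_erosion(
        m, structure=ndimage.generate_binary_structure(3, 1), border_value=0
    )
    return np.argwhere(m & ~eroded)


def _surface_distances(pred: np.ndarray, truth: np.ndarray, spacing) -> tuple[np.ndarray, np.ndarray]:
    sp = np.asarray(spacing, dtype=float)
    bp = boundary_voxels(pred) * sp
    bt = boundary_voxels(truth) * sp
    d_pt = cKDTree(bt).query(bp, workers=-1)[0]
    d_tp = cKDTree(bp).query(bt, workers=-1)[0]
    return d_pt, d_tp


def seg_metrics(pred, truth) -> SegMetrics:
    """Overlap and surface metrics of a predicted mask against a reference.

    Accepts :class:`~caroseg.image.LumenLabel` pairs or plain arrays (then
    unit spacing is assumed).  Raises when both masks are empty (metrics
    undefined) or the reference is empty (relative volume error undefined).
    """
    if hasattr(pred, "mask"):
        spacing = pred.spacing
        if hasattr(truth, "check_aligned") and pred.mask.shape != truth.mask.shape:
            raise ValueError("mask shapes differ")
        p = np.asarray(pred.mask).astype(bool)
        t = np.asarray(truth.mask).astype(bool)
    else:
        p = np.asarray(pred).astype(bool)
        t = np.asarray(truth).astype(bool)
        spacing = (1.0, 1.0, 1.0)
    if p.shape != t.shape:
        raise ValueError("mask shapes differ")
    np_, nt = int(p.sum()), int(t.sum())
    if nt == 0:
        raise ValueError("reference mask is empty; overlap metrics undefined")
    inter = int((p & t).sum())
    union = int((p | t).sum())
    dsc = 2.0 * inter / (np_ + nt)
    iou = inter / union
    rve = abs(np_ - nt) / nt
    sens = inter / nt
    tn = int((~p & ~t).sum())
    fp = np_ - inter
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    if np_ == 0:
        assd = hd95 = float("inf")
    else:
        d_pt, d_tp = _surface_distances(p, t, spacing)
        pooled = np.concatenate([d_pt, d_tp])
        assd = float(pooled.mean())
        hd95 = float(np.percentile(pooled, 95))
    return SegMetrics(dsc=float(dsc), iou=float(iou), rve=float(rve),
                      sens=float(sens), spec=float(spec), assd=assd, hd95=hd95)


# ---------------------------------------------------------------------------
# Diagnostic metrics


@dataclass
class DiagMetrics:
    acc: float
    f1: float
    sens: float
    precision: float
    spec: float
    auc: float
    confusion: np.ndarray  # 2x2 [[tn, fp], [fn, tp]]

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "confusion"}
        d["confusion"] = self.confusion.tolist()
        return d


def diag_metrics(true_labels, pred_labels, scores=None) -> DiagMetrics:
    """Per-artery two-class diagnostic performance.

    ``scores`` (e.g. the continuous NASCET percent) feed the rank-based
    AUC; AUC is undefined (raises) when the truth has a single class.
    """
    from sklearn import metrics as skm

    y = np.asarray(true_labels).astype(int)
    yhat = np.asarray(pred_labels).astype(int)
    if y.shape != yhat.shape:
        raise ValueError("label lists must have equal length")
    cm = skm.confusion_matrix(y, yhat, labels=[0, 1])
    tn, fp, fn, tp = cm.ravel()
    acc = (tp + tn) / cm.sum()
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    precision = tp / (tp + fp) if (tp + fp) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    f1 = (2 * precision * sens / (precision + sens)
          if (precision + sens) and np.isfinite(precision + sens) else 0.0)
    if scores is None:
        scores = yhat
    if len(np.unique(y)) < 2:
        raise ValueError("AUC undefined: truth contains a single class")
    auc = float(skm.roc_auc_score(y, np.asarray(scores, dtype=float)))
    return DiagMetrics(acc=float(acc), f1=float(f1), sens=float(sens),
                       precision=float(precision), spec=float(spec), auc=auc,
                       confusion=cm)


# ---------------------------------------------------------------------------
# Agreement statistics


@dataclass
class AgreementStats:
    estimate: float
    ci_low: float
    ci_high: float

    def to_tuple(self):
        return self.estimate, (self.ci_low, self.ci_high)


def ccc(x, y, alpha: float = 0.05) -> AgreementStats:
    """Lin's concordance correlation coefficient with a Fisher-z CI.

    ``ccc = 2 cov(x, y) / (var x + var y + (mean x - mean y)^2)`` with
    population (1/n) variances.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1D sequences")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    vx, vy = x.var(), y.var()
    if vx == 0 and vy == 0:
        raise ValueError("zero variance in both sequences; CCC undefined")
    sxy = ((x - x.mean()) * (y - y.mean())).mean()
    est = 2 * sxy / (vx + vy + (x.mean() - y.mean()) ** 2)
    est = float(np.clip(est, -1.0, 1.0))
    if abs(est) >= 1.0:
        return AgreementStats(est, est, est)
    z = np.arctanh(est)
    se = 1.0 / np.sqrt(n - 2)
    zc = stats.norm.ppf(1 - alpha / 2)
    return AgreementStats(est, float(np.tanh(z - zc * se)), float(np.tanh(z + zc * se)))


def icc_agreement(ratings, alpha: float = 0.05) -> AgreementStats:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    ``ratings`` is an (n subjects x k raters) table.  The CI follows the
    McGraw & Wong F-distribution construction.
    """
    r = np.asarray(ratings, dtype=float)
    if r.ndim != 2 or r.shape[0] < 3 or r.shape[1] < 2:
        raise ValueError("ratings must be (n>=3 subjects) x (k>=2 raters)")
    n, k = r.shape
    grand = r.mean()
    row_m = r.mean(axis=1)
    col_m = r.mean(axis=0)
    ss_rows = k * ((row_m - grand) ** 2).sum()
    ss_cols = n * ((col_m - grand) ** 2).sum()
    ss_tot = ((r - grand) ** 2).sum()
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0:
        raise ValueError("degenerate variance decomposition; ICC undefined")
    est = (msr - mse) / denom

    # Shrout-Fleiss / McGraw-Wong confidence bounds for ICC(2,1)
    if mse == 0:
        return AgreementStats(float(est), float(est), float(est))
    fj = msc / mse
    df_e = (n - 1) * (k - 1)
    vn = df_e * (k * est * fj + n * (1 + (k - 1) * est) - k * est) ** 2
    vd = (n - 1) * k**2 * est**2 * fj**2 + (n * (1 + (k - 1) * est) - k * est) ** 2
    v = vn / vd
    f_u = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_l = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f_u * mse) / (f_u * (k * msc + (k * n - k - n) * mse) + n * msr)
    upper = n * (f_l * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_l * msr)
    lower, upper = float(min(lower, est)), float(max(upper, est))
    return AgreementStats(float(est), max(-1.0, lower), min(1.0, upper))


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank


def _exact_sf(w_obs: float, ranks: np.ndarray) -> float:
    """P(W+ >= w_obs) by subset-sum DP over (possibly midrank) ranks."""
    scaled = np.round(ranks * 2).astype(int)  # midranks are multiples of 0.5
    total = scaled.sum()
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in scaled:
        dist[r:] = dist[r:] + dist[:-r]  # fresh RHS: no aliased in-place update
    dist /= 2 ** len(scaled)
    w_scaled = int(np.ceil(w_obs * 2 - 1e-9))
    return float(dist[w_scaled:].sum())


def wilcoxon_signed_rank(x, y, alternative: str = "two-sided") -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test: (statistic W+, p-value).

    Zero differences are dropped; ties receive midranks.  The null
    distribution is enumerated exactly (subset-sum over midranks) for
    n <= 25 retained pairs and approximated by the tie-corrected normal
    otherwise.  Raises when every difference is zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired equal-length sequences")
    d = x - y
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all paired differences are zero; test undefined")
    ranks = stats.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    mean_w = n * (n + 1) / 4.0
    if n <= 25:
        sf = _exact_sf(w_pos, ranks)
        cdf = 1.0 - _exact_sf(w_pos + 0.5, ranks)  # P(W+ <= w)
        if alternative == "greater":
            p = sf
        elif alternative == "less":
            p = cdf
        else:
            p = min(1.0, 2.0 * min(sf, cdf))
    else:
        _, counts = np.unique(ranks, return_counts=True)
        tie_term = ((counts**3 - counts).sum()) / 48.0
        var_w = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        z = (w_pos - mean_w) / np.sqrt(var_w)
        if alternative == "greater":
            p = float(stats.norm.sf(z))
        elif alternative == "less":
            p = float(stats.norm.cdf(z))
        else:
            p = float(2 * stats.norm.sf(abs(z)))
    return w_pos, float(min(p, 1.0))


# ---------------------------------------------------------------------------
# Subgroup reporting


def subgroup_report(results, keys=("grade",), metric_cols=None, pair_cols=None):
    """Per-subgroup mean +/- sd of metric columns, plus CCC of a value pair.

    ``results`` is a DataFrame with one row per lesion; ``keys`` are the
    grouping columns (e.g. grade, scanner_tag); ``pair_cols`` names two
    columns (e.g. predicted and true volume) whose agreement is summarized
    per subgroup.  Empty subgroups are omitted.
    """
    import pandas as pd

    keys = [k for k in keys if k in results.columns]
    if not keys:
        raise ValueError("no grouping keys present in the results table")
    if metric_cols is None:
        metric_cols = [c for c in results.columns
                       if results[c].dtype.kind in "fc" and c not in (pair_cols or ())]
    rows = []
    for gvals, sub in results.groupby(list(keys), observed=True):
        if not isinstance(gvals, tuple):
            gvals = (gvals,)
        row = dict(zip(keys, gvals))
        row["n"] = len(sub)
        for c in metric_cols:
            row[f"{c}_mean"] = float(sub[c].mean())
            row[f"{c}_sd"] = float(sub[c].std(ddof=1)) if len(sub) > 1 else 0.0
        if pair_cols is not None and len(sub) >= 3:
            try:
                st = ccc(sub[pair_cols[0]], sub[pair_cols[1]])
                row["ccc"] = st.estimate
                row["ccc_low"], row["ccc_high"] = st.ci_low, st.ci_high
            except ValueError:
                row["ccc"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
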