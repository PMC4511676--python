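"""Threshold-sweep evaluation of saliency maps against binary masks.

A saliency map is treated as a binary classifier: at threshold ``t`` every
pixel with a value ``>= t`` is predicted foreground.  Sweeping ``t`` over
the map's value range yields confusion counts per threshold, from which
five summary measures are derived: maximum F1, maximum F_beta (beta = 0.3
weights precision over recall), area under the interpolated
precision-recall curve, area under the ROC curve, and the hit-rate (how
often the globally most salient pixel falls inside the object).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import minmax_normalize

__all__ = [
    "SweepCurve",
    "EvalScores",
    "SignificanceResult",
    "threshold_sweep",
    "f_beta",
    "max_f_score",
    "pr_auc",
    "roc_auc",
    "hit_rate",
    "evaluate_dataset",
    "evaluate_images",
    "significance_tests",
]

DEFAULT_BETA = 0.3
DEFAULT_N_LEVELS = 256


@dataclass
class SweepCurve:
    """Confusion counts over an ascending threshold grid."""

    thresholds: np.ndarray
    tp: np.ndarray = field(repr=False)
    fp: np.ndarray = field(repr=False)
    n_pos: int = 0
    n_neg: int = 0

    @property
    def fn(self) -> np.ndarray:
        return self.n_pos - self.tp

    @property
    def tn(self) -> np.ndarray:
        return self.n_neg - self.fp

    @property
    def recall(self) -> np.ndarray:
        return self.tp / self.n_pos

    @property
    def precision(self) -> np.ndarray:
        """TP / (TP + FP); the empty-prediction point is assigned precision 1."""
        pred = self.tp + self.fp
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(pred > 0, self.tp / np.maximum(pred, 1), 1.0)
        return p

    @property
    def fpr(self) -> np.ndarray:
        if self.n_neg == 0:
            return np.zeros_like(self.fp, dtype=float)
        return self.fp / self.n_neg


def threshold_sweep(smap, mask, n_levels: int | str = DEFAULT_N_LEVELS) -> SweepCurve:
    """Sweep binarization thresholds over a map's value range.

    ``n_levels`` may be an integer (evenly spaced thresholds spanning
    ``[min(S), max(S)]`` inclusive) or ``"exact"`` (every distinct map
    value, making downstream metrics exact).
    """
    s = np.asarray(smap, dtype=float)
    m = np.asarray(mask).astype(bool)
    if s.shape != m.shape:
        raise ValueError("map and mask shapes differ")
    n_pos = int(m.sum())
    if n_pos == 0:
        raise ValueError("mask has no foreground pixels")
    if n_levels == "exact":
        thresholds = np.unique(s)
    else:
        if int(n_levels) < 2:
            raise ValueError("need at least 2 threshold levels")
        thresholds = np.linspace(s.min(), s.max(), int(n_levels))
    fg = np.sort(s[m])
    bg = np.sort(s[~m])
    tp = n_pos - np.searchsorted(fg, thresholds, side="left")
    fp = bg.size - np.searchsorted(bg, thresholds, side="left")
    return SweepCurve(thresholds, tp.astype(int), fp.astype(int),
                      n_pos=n_pos, n_neg=int(bg.size))


def f_beta(precision, recall, beta: float = DEFAULT_BETA):
    """``(1 + b^2) P R / (b^2 P + R)``, defined as 0 where both are 0."""
    p = np.asarray(precision, dtype=float)
    r = np.asarray(recall, dtype=float)
    b2 = beta * beta
    denom = b2 * p + r
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(denom > 0, (1 + b2) * p * r / np.where(denom > 0, denom, 1), 0.0)
    return f if f.ndim else float(f)


def max_f_score(curve: SweepCurve, beta: float = 1.0) -> float:
    """Maximum F_beta over the threshold sweep."""
    return float(np.max(f_beta(curve.precision, curve.recall, beta)))


def pr_auc(curve_or_pr, interpolation: str = "envelope") -> float:
    """Area under the precision-recall curve.

    ``"envelope"`` integrates the interpolated precision
    ``p~(r) = max{precision_i : recall_i >= r}`` over recall in [0, 1];
    ``"trapezoid"`` integrates the raw operating points.
    """
    if isinstance(curve_or_pr, SweepCurve):
        prec, rec = curve_or_pr.precision, curve_or_pr.recall
    else:
        prec, rec = (np.asarray(a, dtype=float) for a in curve_or_pr)
    if rec.size < 2:
        raise ValueError("need at least 2 operating points")
    order = np.argsort(rec, kind="stable")
    rec = rec[order]
    prec = prec[order]
    if interpolation == "envelope":
        env = np.maximum.accumulate(prec[::-1])[::-1]
        edges = np.concatenate([[0.0], rec])
        return float(np.sum(np.diff(edges) * env))
    if interpolation == "trapezoid":
        return float(np.trapezoid(prec, rec))
    raise ValueError(f"unknown interpolation {interpolation!r}")


def roc_auc(curve_or_points) -> float:
    """Trapezoidal area under (FPR, TPR) with (0,0) and (1,1) appended."""
    if isinstance(curve_or_points, SweepCurve):
        fpr, tpr = curve_or_points.fpr, curve_or_points.recall
    else:
        fpr, tpr = (np.asarray(a, dtype=float) for a in curve_or_points)
    fpr = np.concatenate([[0.0], fpr, [1.0]])
    tpr = np.concatenate([[0.0], tpr, [1.0]])
    order = np.lexsort((tpr, fpr))
    return float(np.trapezoid(tpr[order], fpr[order]))


def hit_rate(maps: Sequence, masks: Sequence) -> float:
    """Fraction of images whose maximal-saliency pixel lies in the object.

    Optimistic tie rule: if several pixels attain the maximum, a hit is
    scored when any of them is foreground; fully constant maps therefore
    always hit and are flagged with a warning.
    """
    if len(maps) != len(masks):
        raise ValueError("need one mask per map")
    hits = 0
    for s, m in zip(maps, masks):
        s = np.asarray(s, dtype=float)
        m = np.asarray(m).astype(bool)
        if not m.any():
            raise ValueError("mask has no foreground pixels")
        argmax = s == s.max()
        if argmax.all():
            warnings.warn("constant map: hit-rate uses the optimistic tie rule")
        hits += bool(m[argmax].any())
    return hits / len(maps)


@dataclass
class EvalScores:
    """Aggregate benchmark measures for a map/mask collection."""

    f1: float
    fbeta: float
    beta: float
    pr_auc: float
    roc_auc: float
    hit_rate: float
    n_images: int
    aggregation: str = "per_image"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def _aggregate_curves(curves: list[SweepCurve], aggregation: str):
    """Pointwise precision/recall/FPR over a shared threshold grid."""
    if aggregation == "per_image":
        prec = np.mean([c.precision for c in curves], axis=0)
        rec = np.mean([c.recall for c in curves], axis=0)
        fpr = np.mean([c.fpr for c in curves], axis=0)
    elif aggregation == "pooled":
        tp = np.sum([c.tp for c in curves], axis=0)
        fp = np.sum([c.fp for c in curves], axis=0)
        n_pos = sum(c.n_pos for c in curves)
        n_neg = sum(c.n_neg for c in curves)
        pooled = SweepCurve(curves[0].thresholds, tp, fp, n_pos, n_neg)
        prec, rec, fpr = pooled.precision, pooled.recall, pooled.fpr
    else:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    return prec, rec, fpr


def _prepare(maps, masks):
    """Normalize maps, drop empty-mask pairs with a warning."""
    keep_maps, keep_masks = [], []
    for s, m in zip(maps, masks):
        m = np.asarray(m).astype(bool)
        if not m.any():
            warnings.warn("skipping image with empty ground-truth mask")
            continue
        keep_maps.append(minmax_normalize(s, warn_constant=False))
        keep_masks.append(m)
    if not keep_maps:
        raise ValueError("no images with non-empty masks")
    return keep_maps, keep_masks


def evaluate_dataset(maps: Sequence, masks: Sequence,
                     n_levels: int = DEFAULT_N_LEVELS, beta: float = DEFAULT_BETA,
                     aggregation: str = "per_image") -> EvalScores:
    """Benchmark measures for paired saliency maps and ground-truth masks.

    Maps are min-max normalized to [0, 1] and swept over a shared
    threshold grid.  ``aggregation="per_image"`` averages precision,
    recall and FPR across images at each threshold before deriving the
    measures (the benchmark convention); ``"pooled"`` sums the confusion
    counts over all pixels of all images first.
    """
    if len(maps) != len(masks):
        raise ValueError("need one mask per map")
    maps, masks = _prepare(maps, masks)
    thresholds = np.linspace(0.0, 1.0, n_levels)
    curves = []
    for s, m in zip(maps, masks):
        fg = np.sort(s[m])
        bg = np.sort(s[~m])
        tp = fg.size - np.searchsorted(fg, thresholds, side="left")
        fp = bg.size - np.searchsorted(bg, thresholds, side="left")
        curves.append(SweepCurve(thresholds, tp, fp, fg.size, bg.size))
    prec, rec, fpr = _aggregate_curves(curves, aggregation)
    return EvalScores(
        f1=float(np.max(f_beta(prec, rec, 1.0))),
        fbeta=float(np.max(f_beta(prec, rec, beta))),
        beta=beta,
        pr_auc=pr_auc((prec, rec)),
        roc_auc=roc_auc((fpr, rec)),
        hit_rate=hit_rate(maps, masks),
        n_images=len(maps),
        aggregation=aggregation,
    )


def evaluate_images(maps: Sequence, masks: Sequence,
                    n_levels: int = DEFAULT_N_LEVELS,
                    beta: float = DEFAULT_BETA) -> pd.DataFrame:
    """Per-image measures (one row per image), for significance testing."""
    maps, masks = _prepare(maps, masks)
    rows = []
    for s, m in zip(maps, masks):
        c = threshold_sweep(s, m, n_levels)
        rows.append(
            {
                "f1": max_f_score(c, 1.0),
                "fbeta": max_f_score(c, beta),
                "pr_auc": pr_auc(c),
                "roc_auc": roc_auc(c),
                "hit": hit_rate([s], [m]),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class SignificanceResult:
    """Two-sample comparison of per-image metric distributions."""

    p_equal_means: float
    p_not_worse: float
    alpha: float
    reject_equal_means: bool
    reject_worse: bool
    mean_baseline: float
    mean_variant: float


def significance_tests(scores_baseline, scores_variant,
                       alpha: float = 0.05) -> SignificanceResult:
    """Paired two-sample t-tests between two algorithm variants.

    Tests (1) the two-tailed hypothesis that the per-image metric means
    are equal and (2) the one-tailed hypothesis that the variant is worse
    than the baseline.  Rejecting both at level ``alpha`` indicates a
    significant improvement.
    """
    a = np.asarray(scores_baseline, dtype=float)
    b = np.asarray(scores_variant, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per group")
    p_eq = float(stats.ttest_ind(b, a).pvalue)
    p_nw = float(stats.ttest_ind(b, a, alternative="greater").pvalue)
    return SignificanceResult(
        p_equal_means=p_eq,
        p_not_worse=p_nw,
        alpha=alpha,
        reject_equal_means=bool(p_eq < alpha),
        reject_worse=bool(p_nw < alpha),
        mean_baseline=float(a.mean()),
        mean_variant=float(b.mean()),
    )
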