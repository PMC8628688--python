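"""Instance-segmentation evaluation: AJI, IoU matching, average precision.

Operates on integer label masks (0 = background, positive integers = instance
ids, ids need not be consecutive). The Aggregated Jaccard Index (AJI) pairs
each ground-truth instance with the predicted instance of maximal IoU and
reports aggregated intersection over aggregated union, adding the pixels of
unmatched predictions to the denominator. Average precision uses the unscored
instance-segmentation convention AP(t) = TP / (TP + FP + FN), averaged over
IoU thresholds 0.50, 0.55, ..., 0.95 to give mAP (masks here carry no
confidence scores, so score-ranked COCO AP does not apply).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_THRESHOLDS = tuple(np.round(np.arange(0.50, 0.951, 0.05), 2))


def _as_mask(m) -> np.ndarray:
    m = np.asarray(m)
    if m.ndim != 2:
        raise ValueError("label masks must be 2-D")
    return m.astype(np.int64)


def _intersection_table(gt: np.ndarray, pred: np.ndarray):
    """Instance ids, per-instance areas and the pairwise intersection matrix."""
    gt_ids = np.unique(gt[gt > 0])
    pr_ids = np.unique(pred[pred > 0])
    gt_index = {g: i for i, g in enumerate(gt_ids)}
    pr_index = {p: i for i, p in enumerate(pr_ids)}
    inter = np.zeros((len(gt_ids), len(pr_ids)), dtype=np.int64)
    both = (gt > 0) & (pred > 0)
    if both.any():
        pairs, counts = np.unique(
            np.stack([gt[both], pred[both]]), axis=1, return_counts=True)
        for (g, p), c in zip(pairs.T, counts):
            inter[gt_index[g], pr_index[p]] = c
    gt_areas = np.array([(gt == g).sum() for g in gt_ids], dtype=np.int64)
    pr_areas = np.array([(pred == p).sum() for p in pr_ids], dtype=np.int64)
    return gt_ids, pr_ids, gt_areas, pr_areas, inter


def iou_matrix(gt, pred) -> np.ndarray:
    """IoU of every (ground-truth, predicted) instance pair."""
    gt, pred = _as_mask(gt), _as_mask(pred)
    if gt.shape != pred.shape:
        raise ValueError("masks differ in extent")
    _, _, ga, pa, inter = _intersection_table(gt, pred)
    union = ga[:, None] + pa[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        iou = np.where(union > 0, inter / union, 0.0)
    return iou


def aji(gt, pred) -> float:
    """Aggregated Jaccard Index in [0, 1].

    Ground-truth instances are visited in ascending id order; each is paired
    greedily with the available predicted instance of maximal IoU (ties broken
    by larger intersection, then smaller predicted id). Unused predicted
    pixels inflate the denominator.
    """
    gt, pred = _as_mask(gt), _as_mask(pred)
    if gt.shape != pred.shape:
        raise ValueError("masks differ in extent")
    gt_ids, pr_ids, ga, pa, inter = _intersection_table(gt, pred)
    if len(gt_ids) == 0:
        raise ValueError("AJI undefined for an empty ground truth")
    union = ga[:, None] + pa[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        iou = np.where(union > 0, inter / union, 0.0)
    used = np.zeros(len(pr_ids), dtype=bool)
    num = 0
    den = 0
    for i in range(len(gt_ids)):
        free = np.flatnonzero(~used)
        if free.size == 0 or (inter[i, free].max(initial=0) == 0):
            den += ga[i]
            continue
        order = sorted(free, key=lambda j: (-iou[i, j], -inter[i, j], pr_ids[j]))
        j = order[0]
        used[j] = True
        num += inter[i, j]
        den += union[i, j]
    den += pa[~used].sum()
    return float(num / den) if den else 0.0


@dataclass
class MatchResult:
    iou: np.ndarray
    pairs: list[tuple[int, int]]  # (gt id, pred id) of matched pairs
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0


def match_instances(gt, pred, iou_threshold: float = 0.5) -> MatchResult:
    """Greedy one-to-one matching in descending IoU at a threshold."""
    if not 0.0 < iou_threshold <= 1.0:
        raise ValueError("iou_threshold must lie in (0, 1]")
    gt, pred = _as_mask(gt), _as_mask(pred)
    if gt.shape != pred.shape:
        raise ValueError("masks differ in extent")
    gt_ids, pr_ids, _, _, inter = _intersection_table(gt, pred)
    iou = iou_matrix(gt, pred)
    cands = [(iou[i, j], i, j)
             for i in range(len(gt_ids)) for j in range(len(pr_ids))
             if iou[i, j] >= iou_threshold]
    cands.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_g = np.zeros(len(gt_ids), bool)
    used_p = np.zeros(len(pr_ids), bool)
    pairs = []
    for _, i, j in cands:
        if used_g[i] or used_p[j]:
            continue
        used_g[i] = used_p[j] = True
        pairs.append((int(gt_ids[i]), int(pr_ids[j])))
    tp = len(pairs)
    return MatchResult(iou, pairs, tp, len(pr_ids) - tp, len(gt_ids) - tp)


def average_precision(gt, pred, thresholds=DEFAULT_THRESHOLDS) -> pd.Series:
    """AP(t) = TP / (TP + FP + FN) per threshold, plus the mean ('mAP')."""
    out = {}
    for t in thresholds:
        m = match_instances(gt, pred, float(t))
        denom = m.tp + m.fp + m.fn
        out[float(t)] = m.tp / denom if denom else 1.0
    s = pd.Series(out, name="AP")
    s.loc["mAP"] = float(np.mean(list(out.values())))
    return s


def segmentation_report(gt, pred) -> dict:
    """AJI, per-threshold AP/mAP, and P/R/F1 at IoU 0.5 and 0.7."""
    ap = average_precision(gt, pred)
    rep = {"aji": aji(gt, pred), "mAP": float(ap.loc["mAP"]),
           "ap_per_threshold": {str(k): float(v) for k, v in ap.items()
                                if k != "mAP"}}
    for t in (0.5, 0.7):
        m = match_instances(gt, pred, t)
        rep[f"precision@{t}"] = m.precision
        rep[f"recall@{t}"] = m.recall
        rep[f"f1@{t}"] = m.f1
    return rep
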