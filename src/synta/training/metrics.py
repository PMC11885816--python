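"""Semantic and instance segmentation metrics.

``evaluate_semantic`` scores the fiber class pixelwise (accuracy, precision,
recall, F1).  ``evaluate_instances`` computes average precision,
AP = TP / (TP + FP + FN), after one-to-one greedy IoU matching between
predicted and ground-truth instances, over a sweep of IoU thresholds
(default 0.5 to 1.0 in steps of 0.05).
"""

from __future__ import annotations

import numpy as np

__all__ = ["evaluate_semantic", "evaluate_instances", "DEFAULT_IOU_THRESHOLDS"]

DEFAULT_IOU_THRESHOLDS = tuple(np.round(np.arange(0.5, 1.0001, 0.05), 2))


def _to_labels(pred: np.ndarray) -> np.ndarray:
    """Accept a label mask (H, W) or class probabilities (H, W, C)/(C, H, W)."""
    if pred.ndim == 2:
        return pred
    if pred.ndim == 3:
        axis = 2 if pred.shape[2] <= 8 else 0
        return np.argmax(pred, axis=axis)
    raise ValueError("prediction must be a 2-D label mask or 3-D probability stack")


def evaluate_semantic(pred, gt_semantic: np.ndarray, fiber_class: int = 1) -> dict:
    """Pixelwise binary metrics on the fiber class (fiber vs rest).

    Degenerate convention: with an empty ground truth and an empty
    prediction, precision/recall/F1 are defined as 1.0.
    """
    labels = _to_labels(np.asarray(pred))
    gt = np.asarray(gt_semantic)
    if labels.shape != gt.shape:
        raise ValueError("prediction and ground truth shapes differ")
    p = labels == fiber_class
    g = gt == fiber_class
    tp = int(np.sum(p & g))
    fp = int(np.sum(p & ~g))
    fn = int(np.sum(~p & g))
    tn = int(np.sum(~p & ~g))
    precision = tp / (tp + fp) if (tp + fp) else (1.0 if fn == 0 else 0.0)
    recall = tp / (tp + fn) if (tp + fn) else (1.0 if fp == 0 else 0.0)
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    if tp == 0 and fp == 0 and fn == 0:
        precision = recall = f1 = 1.0
    return {
        "accuracy": (tp + tn) / labels.size,
        "precision": precision,
        "recall": recall,
        "f1": f1,
    }


def _pair_ious(pred: np.ndarray, gt: np.ndarray):
    """IoU of every overlapping (pred id, gt id) pair, via joint histogram."""
    pred = np.asarray(pred).ravel()
    gt = np.asarray(gt).ravel()
    pred_areas = np.bincount(pred)
    gt_areas = np.bincount(gt)
    both = (pred > 0) & (gt > 0)
    if not both.any():
        return np.empty(0, np.int64), np.empty(0, np.int64), np.empty(0)
    key = pred[both].astype(np.int64) * (gt.max() + 1) + gt[both]
    pairs, inter = np.unique(key, return_counts=True)
    pid = pairs // (gt.max() + 1)
    gid = pairs % (gt.max() + 1)
    union = pred_areas[pid] + gt_areas[gid] - inter
    return pid, gid, inter / union


def evaluate_instances(
    pred_instances: np.ndarray,
    gt_instances: np.ndarray,
    iou_thresholds=DEFAULT_IOU_THRESHOLDS,
) -> dict[float, float]:
    """AP per IoU threshold with greedy one-to-one matching by descending IoU."""
    if pred_instances.shape != gt_instances.shape:
        raise ValueError("prediction and ground truth shapes differ")
    n_pred = int(np.unique(pred_instances[pred_instances > 0]).size)
    n_gt = int(np.unique(gt_instances[gt_instances > 0]).size)
    pid, gid, iou = _pair_ious(pred_instances, gt_instances)
    order = np.argsort(-iou, kind="stable")
    pid, gid, iou = pid[order], gid[order], iou[order]

    out: dict[float, float] = {}
    for thr in iou_thresholds:
        used_p: set[int] = set()
        used_g: set[int] = set()
        tp = 0
        for p_, g_, v in zip(pid, gid, iou):
            if v < thr:
                break
            if p_ in used_p or g_ in used_g:
                continue
            used_p.add(int(p_))
            used_g.add(int(g_))
            tp += 1
        fp = n_pred - tp
        fn = n_gt - tp
        denom = tp + fp + fn
        out[float(thr)] = tp / denom if denom else 1.0
    return out
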