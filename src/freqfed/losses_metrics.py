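"""Fused Dice + cross-entropy training loss and DSC / ASSD evaluation metrics.

The training loss on a soft prediction O (probabilities, class axis first)
against a one-hot ground truth G over n pixels and class set C is

    L(G, O) = -(1/n) sum_i sum_j G_ij log O_ij
              - (2/|C|) sum_j [ sum_i O_ij G_ij / (sum_i O_ij + sum_i G_ij) ]

i.e. pixel-averaged cross-entropy plus a soft-Dice reward; the minimum is -1,
attained exactly at the one-hot ground truth (all classes present).  A
smoothing constant of 1e-6 in the Dice denominator avoids 0/0 on absent
classes, and probabilities are clamped to [1e-7, 1] before the log.

Evaluation metrics operate on integer label maps:

* DSC (Dice similarity coefficient) per class: 2TP / (2TP + FP + FN).
* ASSD (average symmetric surface distance, mm): the mean over both boundary
  point sets of the distance to the nearest point of the other boundary,
  with pixel spacing applied.  Boundaries are mask pixels with at least one
  4-neighbor outside the mask; the image border counts as outside.

A class absent from both maps yields the *undefined* sentinel (NaN) and is
excluded from averages rather than counted as 0 or 1; a class present in
exactly one map scores DSC 0 (and undefined ASSD when either boundary is
empty).
"""

from __future__ import annotations

import math
from typing import Iterable, Tuple

import numpy as np
from scipy import ndimage

PROB_CLAMP = 1e-7
DICE_SMOOTH = 1e-6

#: sentinel for metrics that are undefined on a given mask pair
UNDEFINED = float("nan")

_FOUR_CONN = ndimage.generate_binary_structure(2, 1)  # 4-connectivity cross


def is_defined(value: float) -> bool:
    return not math.isnan(value)


def _check_same_shape(pred: np.ndarray, gt: np.ndarray) -> None:
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs gt {gt.shape}")


def dsc(pred: np.ndarray, gt: np.ndarray, cls: int) -> float:
    """Dice similarity coefficient of class ``cls`` between two label maps."""
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    _check_same_shape(pred, gt)
    p = pred == cls
    g = gt == cls
    np_, ng = int(p.sum()), int(g.sum())
    if np_ == 0 and ng == 0:
        return UNDEFINED
    tp = int((p & g).sum())
    return 2.0 * tp / (np_ + ng)  # 2TP + FP + FN == |P| + |G|


def boundary(mask: np.ndarray) -> np.ndarray:
    """Mask pixels with >= 1 four-neighbor outside the mask (border = outside)."""
    mask = np.asarray(mask, dtype=bool)
    eroded = ndimage.binary_erosion(mask, structure=_FOUR_CONN, border_value=0)
    return mask & ~eroded


def assd(pred: np.ndarray, gt: np.ndarray, cls: int,
         spacing: Tuple[float, float] = (1.0, 1.0)) -> float:
    """Average symmetric surface distance (mm) of class ``cls``.

    Euclidean distances between boundary pixel centers, scaled by ``spacing``
    (sx, sy) per axis; symmetric in (pred, gt).  Undefined (NaN) when either
    boundary set is empty.
    """
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    _check_same_shape(pred, gt)
    if spacing[0] <= 0 or spacing[1] <= 0:
        raise ValueError("pixel spacing must be positive")
    s_pred = boundary(pred == cls)
    s_gt = boundary(gt == cls)
    n_pred, n_gt = int(s_pred.sum()), int(s_gt.sum())
    if n_pred == 0 or n_gt == 0:
        return UNDEFINED
    # distance_transform_edt(~S) gives each pixel's distance to the nearest
    # boundary pixel of S, already spacing-scaled
    dt_gt = ndimage.distance_transform_edt(~s_gt, sampling=spacing)
    dt_pred = ndimage.distance_transform_edt(~s_pred, sampling=spacing)
    total = dt_gt[s_pred].sum() + dt_pred[s_gt].sum()
    return float(total / (n_pred + n_gt))


def softmax(logits: np.ndarray, axis: int = 0) -> np.ndarray:
    shifted = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=axis, keepdims=True)


def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    """Integer label map (...) -> one-hot (n_classes, ...)."""
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() >= n_classes:
        raise ValueError("label values outside [0, n_classes)")
    return (np.arange(n_classes).reshape((n_classes,) + (1,) * labels.ndim) == labels[None]).astype(
        np.float64
    )


def fused_loss(probs: np.ndarray, gt_onehot: np.ndarray, class_axis: int = 0) -> float:
    """Cross-entropy minus the class-averaged soft-Dice reward (see module doc)."""
    probs = np.asarray(probs, dtype=np.float64)
    gt_onehot = np.asarray(gt_onehot, dtype=np.float64)
    if probs.shape != gt_onehot.shape:
        raise ValueError(f"shape mismatch: probs {probs.shape} vs gt {gt_onehot.shape}")
    o = np.moveaxis(probs, class_axis, 0)
    g = np.moveaxis(gt_onehot, class_axis, 0)
    c = o.shape[0]
    o2 = o.reshape(c, -1)
    g2 = g.reshape(c, -1)
    n = o2.shape[1]
    ce = -(g2 * np.log(np.clip(o2, PROB_CLAMP, 1.0))).sum() / n
    num = (o2 * g2).sum(axis=1)
    den = o2.sum(axis=1) + g2.sum(axis=1) + DICE_SMOOTH
    dice = (num / den).sum() * 2.0 / c
    return float(ce - dice)


def fused_loss_and_grad(logits: np.ndarray, gt_onehot: np.ndarray,
                        class_axis: int = 1) -> Tuple[float, np.ndarray]:
    """Loss value and its gradient w.r.t. logits (softmax applied internally).

    Default layout is a batch (N, C, H, W); any layout works as long as
    ``class_axis`` names the class axis.
    """
    logits = np.asarray(logits, dtype=np.float64)
    gt_onehot = np.asarray(gt_onehot, dtype=np.float64)
    o = softmax(logits, axis=class_axis)
    loss = fused_loss(o, gt_onehot, class_axis=class_axis)

    om = np.moveaxis(o, class_axis, 0)
    gm = np.moveaxis(gt_onehot, class_axis, 0)
    c = om.shape[0]
    shape = om.shape
    o2 = om.reshape(c, -1)
    g2 = gm.reshape(c, -1)
    n = o2.shape[1]
    # dL/dO: cross-entropy part (on clamped probs) + soft-Dice part
    g_ce = -g2 / (np.clip(o2, PROB_CLAMP, 1.0) * n)
    num = (o2 * g2).sum(axis=1, keepdims=True)
    den = o2.sum(axis=1, keepdims=True) + g2.sum(axis=1, keepdims=True) + DICE_SMOOTH
    g_dice = -(2.0 / c) * (g2 * den - num) / den ** 2
    g_total = g_ce + g_dice
    # chain through per-pixel softmax: dL/dz_c = O_c (g_c - sum_j g_j O_j)
    dot = (g_total * o2).sum(axis=0, keepdims=True)
    dlogits = o2 * (g_total - dot)
    dlogits = np.moveaxis(dlogits.reshape(shape), 0, class_axis)
    return loss, dlogits


def class_average(values: Iterable[float]) -> Tuple[float, int]:
    """Mean over defined (non-NaN) entries and the count of excluded ones."""
    arr = np.asarray(list(values), dtype=np.float64)
    if arr.size == 0:
        raise ValueError("class_average of an empty collection")
    defined = arr[~np.isnan(arr)]
    excluded = int(arr.size - defined.size)
    if defined.size == 0:
        raise ValueError("class_average: every entry is undefined")
    return float(defined.mean()), excluded
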