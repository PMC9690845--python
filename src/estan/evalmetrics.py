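"""Dice loss and the seven segmentation metrics (area + boundary).

The false positive rate follows the breast-ultrasound convention of
normalizing by the number of ground-truth tumor pixels rather than by the
(huge) background: FPR = FP / |GT|, so it exceeds 1 whenever the spurious
region outgrows the tumor itself. The area error rate AER = (FP+FN)/|GT|
decomposes as FPR + (1 - TPR). Boundary metrics are computed between the
4-connected boundary pixel sets of the two masks: HD is the exact
bidirectional Hausdorff distance, MAE the average symmetric boundary
distance, both in pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import distance_transform_edt

from ._autodiff import Tensor, dice_loss_t

METRIC_NAMES = ("tpr", "fpr", "ji", "dsc", "aer", "hd", "mae")


@dataclass
class MetricReport:
    """Per-image metric record; hd/mae are NaN when flagged undefined."""

    id: str
    tpr: float
    fpr: float
    ji: float
    dsc: float
    aer: float
    hd: float
    mae: float
    group: str = ""
    is_small: bool = False
    axis_px: float = 0.0
    flags: str = ""

    def as_dict(self) -> dict:
        return {"id": self.id, "group": self.group, "is_small": self.is_small,
                "axis_px": self.axis_px, "tpr": self.tpr, "fpr": self.fpr,
                "ji": self.ji, "dsc": self.dsc, "aer": self.aer,
                "hd": self.hd, "mae": self.mae, "flags": self.flags}


def dice_loss(pred, target, eps: float = 1.0):
    """Soft Dice loss 1 - (2*sum(p*t)+eps)/(sum p + sum t + eps).

    Accepts either an autodiff Tensor (returns a differentiable scalar
    Tensor) or a plain array (returns a float).
    """
    if isinstance(pred, Tensor):
        return dice_loss_t(pred, np.asarray(target), eps=eps)
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape}, target {target.shape}")
    inter = float((pred * target).sum())
    return 1.0 - (2.0 * inter + eps) / (pred.sum() + target.sum() + eps)


def area_metrics(pred_mask, gt_mask):
    """(tpr, fpr, ji, dsc, aer) from pixel confusion counts; needs |GT| > 0."""
    pred = np.asarray(pred_mask).astype(bool)
    gt = np.asarray(gt_mask).astype(bool)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    n_gt = int(gt.sum())
    if n_gt == 0:
        raise ValueError("empty ground-truth mask: area metrics undefined")
    tp = int((pred & gt).sum())
    fp = int((pred & ~gt).sum())
    fn = n_gt - tp
    tpr = tp / n_gt
    fpr = fp / n_gt                      # denominator = actual positives
    union = tp + fp + fn
    ji = tp / union if union else 1.0
    dsc = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 1.0
    aer = (fp + fn) / n_gt
    return tpr, fpr, ji, dsc, aer


def boundary_pixels(mask) -> np.ndarray:
    """Boolean map of foreground pixels with a 4-neighbour outside the
    foreground (the image border counts as outside)."""
    m = np.asarray(mask).astype(bool)
    if not m.any():
        raise ValueError("empty mask has no boundary")
    padded = np.pad(m, 1, constant_values=False)
    interior = (padded[:-2, 1:-1] & padded[2:, 1:-1]
                & padded[1:-1, :-2] & padded[1:-1, 2:])
    return m & ~interior


def boundary_distances(pred_mask, gt_mask) -> tuple[float, float]:
    """(hd, mae): exact Hausdorff and average symmetric boundary distance.

    Nearest distances are read off exact Euclidean distance transforms of
    each boundary set, so the cost is linear in the image size.
    """
    a = boundary_pixels(pred_mask)
    g = boundary_pixels(gt_mask)
    if a.shape != g.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {g.shape}")
    dt_g = distance_transform_edt(~g)
    dt_a = distance_transform_edt(~a)
    d_a_to_g = dt_g[a]
    d_g_to_a = dt_a[g]
    hd = float(max(d_a_to_g.max(), d_g_to_a.max()))
    mae = float((d_a_to_g.sum() + d_g_to_a.sum()) / (d_a_to_g.size + d_g_to_a.size))
    return hd, mae


def evaluate_sample(prob_map, gt_mask, sample_id: str = "",
                    threshold: float = 0.5, group: str = "",
                    is_small: bool = False, axis_px: float = 0.0) -> MetricReport:
    """Binarize a probability map and compute all seven metrics.

    An empty prediction yields (tpr 0, fpr 0, ji 0, dsc 0, aer 1) and
    flags hd/mae as undefined (NaN) — the no-detection failure mode.
    """
    prob = np.asarray(prob_map)
    gt = np.asarray(gt_mask).astype(bool)
    if prob.shape != gt.shape:
        raise ValueError(f"shape mismatch: prob {prob.shape}, gt {gt.shape}")
    if not gt.any():
        raise ValueError(f"sample {sample_id!r}: empty ground truth, skipped")
    pred = prob > threshold
    tpr, fpr, ji, dsc, aer = area_metrics(pred, gt)
    if pred.any():
        hd, mae = boundary_distances(pred, gt)
        flags = ""
    else:
        hd, mae = float("nan"), float("nan")
        flags = "empty_pred"
    return MetricReport(id=sample_id, tpr=tpr, fpr=fpr, ji=ji, dsc=dsc,
                        aer=aer, hd=hd, mae=mae, group=group,
                        is_small=is_small, axis_px=axis_px, flags=flags)
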