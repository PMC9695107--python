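"""Overlap metrics (Dice, IoU) and the vertical cup-to-disc ratio.

Disc metrics are computed on the disc REGION (classes 1 and 2 combined),
cup metrics on class 2, matching anatomical usage.  Empty-vs-empty
predictions score 1.0 by convention (stated explicitly since the choice is
otherwise silent); Dice == 2*IoU/(1+IoU) holds for every pair by algebra.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .shape_loss import CUP_CLASS, DISC_CLASSES, DegenerateRegionError

__all__ = ["dice", "iou", "vertical_cdr", "EvalResult", "evaluate_masks"]


def _counts(pred: np.ndarray, true: np.ndarray) -> tuple[int, int, int]:
    pred = np.asarray(pred, dtype=bool)
    true = np.asarray(true, dtype=bool)
    if pred.shape != true.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {true.shape}")
    tp = int(np.sum(pred & true))
    fp = int(np.sum(pred & ~true))
    fn = int(np.sum(~pred & true))
    return tp, fp, fn


def dice(pred_mask: np.ndarray, true_mask: np.ndarray) -> float:
    """2TP / (FP + 2TP + FN); both masks empty -> 1.0."""
    tp, fp, fn = _counts(pred_mask, true_mask)
    if tp + fp + fn == 0:
        return 1.0
    return 2 * tp / (fp + 2 * tp + fn)


def iou(pred_mask: np.ndarray, true_mask: np.ndarray) -> float:
    """TP / (FP + TP + FN); both masks empty -> 1.0."""
    tp, fp, fn = _counts(pred_mask, true_mask)
    if tp + fp + fn == 0:
        return 1.0
    return tp / (fp + tp + fn)


def vertical_cdr(label_map: np.ndarray) -> float:
    """Vertical cup extent / vertical disc extent of a label map."""
    label_map = np.asarray(label_map)
    disc_rows = np.flatnonzero(np.isin(label_map, DISC_CLASSES).any(axis=1))
    if disc_rows.size == 0:
        raise DegenerateRegionError("disc region is empty")
    cup_rows = np.flatnonzero((label_map == CUP_CLASS).any(axis=1))
    if cup_rows.size == 0:
        return 0.0
    disc_extent = disc_rows[-1] - disc_rows[0] + 1
    cup_extent = cup_rows[-1] - cup_rows[0] + 1
    return cup_extent / disc_extent


@dataclass
class EvalResult:
    """Per-image metric table plus its means."""

    per_image: pd.DataFrame
    iou_od: float
    iou_oc: float
    dice_od: float
    dice_oc: float

    def to_csv(self, path) -> None:
        self.per_image.to_csv(path, index=False)


def evaluate_masks(pairs: Iterable[tuple[np.ndarray, np.ndarray]],
                   names: Iterable[str] | None = None) -> EvalResult:
    """Dice/IoU for disc and cup over (predicted, true) label-map pairs."""
    rows = []
    names = list(names) if names is not None else None
    for i, (pred, true) in enumerate(pairs):
        pred, true = np.asarray(pred), np.asarray(true)
        pred_disc, true_disc = np.isin(pred, DISC_CLASSES), np.isin(true, DISC_CLASSES)
        pred_cup, true_cup = pred == CUP_CLASS, true == CUP_CLASS
        rows.append({
            "name": names[i] if names else str(i),
            "iou_od": iou(pred_disc, true_disc),
            "iou_oc": iou(pred_cup, true_cup),
            "dice_od": dice(pred_disc, true_disc),
            "dice_oc": dice(pred_cup, true_cup),
        })
    if not rows:
        raise ValueError("no image pairs to evaluate")
    table = pd.DataFrame(rows)
    return EvalResult(
        per_image=table,
        iou_od=float(table["iou_od"].mean()),
        iou_oc=float(table["iou_oc"].mean()),
        dice_od=float(table["dice_od"].mean()),
        dice_oc=float(table["dice_oc"].mean()),
    )
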