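"""Segmentation scoring against ground truth: Hungarian IoU matching."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment


@dataclass(frozen=True)
class MatchResult:
    """One-to-one truth/prediction matching at an IoU threshold."""

    pairs: list  # (truth_label, pred_label, iou) for matched pairs above threshold
    n_truth: int
    n_pred: int
    match_rate: float  # matched / n_truth
    mean_iou: float  # mean IoU over matched pairs (0 if none)


def iou_matrix(truth: np.ndarray, pred: np.ndarray) -> np.ndarray:
    """Pairwise IoU between truth labels (rows) and predicted labels (cols)."""
    t = np.asarray(truth).ravel()
    p = np.asarray(pred).ravel()
    nt, npr = int(t.max()), int(p.max())
    if nt == 0 or npr == 0:
        return np.zeros((nt, npr))
    joint = np.bincount(t * (npr + 1) + p, minlength=(nt + 1) * (npr + 1))
    joint = joint.reshape(nt + 1, npr + 1).astype(np.float64)
    inter = joint[1:, 1:]
    area_t = joint[1:, :].sum(axis=1, keepdims=True)
    area_p = joint[:, 1:].sum(axis=0, keepdims=True)
    union = area_t + area_p - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(union > 0, inter / union, 0.0)


def match_labels(
    truth: np.ndarray, pred: np.ndarray, iou_threshold: float = 0.5
) -> MatchResult:
    """Optimal one-to-one assignment maximizing total IoU (Hungarian)."""
    m = iou_matrix(truth, pred)
    nt, npr = m.shape
    pairs = []
    if nt and npr:
        rows, cols = linear_sum_assignment(-m)
        for r, c in zip(rows, cols):
            if m[r, c] > iou_threshold:
                pairs.append((int(r + 1), int(c + 1), float(m[r, c])))
    matched = len(pairs)
    return MatchResult(
        pairs=pairs,
        n_truth=nt,
        n_pred=npr,
        match_rate=matched / nt if nt else 1.0,
        mean_iou=float(np.mean([p[2] for p in pairs])) if pairs else 0.0,
    )
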