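"""Ground-truth recovery scoring: one-to-one label matching by IoU."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LabelMatch", "match_labels"]


@dataclass(frozen=True)
class LabelMatch:
    true_label: int
    pred_label: int
    iou: float


def match_labels(
    true_labels: np.ndarray, pred_labels: np.ndarray, iou_min: float = 0.7
) -> tuple[list[LabelMatch], float]:
    """Greedily match true to predicted labels one-to-one by descending IoU.

    Returns the matches with IoU ≥ ``iou_min`` and the fraction of true
    labels matched.
    """
    true_labels = np.asarray(true_labels)
    pred_labels = np.asarray(pred_labels)
    if true_labels.shape != pred_labels.shape:
        raise ValueError("label maps must share a shape")
    n_true = int(true_labels.max())
    n_pred = int(pred_labels.max())
    if n_true == 0:
        return [], 1.0
    if n_pred == 0:
        return [], 0.0

    both = (true_labels > 0) & (pred_labels > 0)
    codes = true_labels[both].astype(np.int64) * (n_pred + 1) + pred_labels[both]
    pair_codes, inter = np.unique(codes, return_counts=True)
    t_ids = (pair_codes // (n_pred + 1)).astype(int)
    p_ids = (pair_codes % (n_pred + 1)).astype(int)
    area_t = np.bincount(true_labels.ravel(), minlength=n_true + 1)
    area_p = np.bincount(pred_labels.ravel(), minlength=n_pred + 1)
    iou = inter / (area_t[t_ids] + area_p[p_ids] - inter)

    order = np.argsort(-iou, kind="stable")
    used_t: set[int] = set()
    used_p: set[int] = set()
    matches: list[LabelMatch] = []
    for k in order:
        if iou[k] < iou_min:
            break
        t, p = int(t_ids[k]), int(p_ids[k])
        if t in used_t or p in used_p:
            continue
        used_t.add(t)
        used_p.add(p)
        matches.append(LabelMatch(true_label=t, pred_label=p, iou=float(iou[k])))
    return matches, len(matches) / n_true
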