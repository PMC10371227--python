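"""Evaluation metrics: mask matching, AP, track IoU, MOTA, lineage, RMSE.

Matching currency throughout is the mask IoU.  Predicted and ground-truth
masks are paired greedily in descending IoU (one-to-one); unmatched
predictions score zero.  Track-level metrics build per-frame label maps
from matches with IoU > 0.5, compute a track IoU (frames where the
mapped labels agree over frames where either track exists, which
penalises splitting), and match tracks greedily in descending track IoU.
MOTA follows the CLEAR convention with correspondences valid at mask
IoU >= 0.5.  Growth-rate accuracy is the RMSE between GP rate estimates
on matched predicted volumes and on ground-truth volumes, with a seeded
bootstrap over 90% subsamples.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .growth import VolumeSeries, conical_volume, fit_gp_volume


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection over union of two binary masks."""
    if a.shape != b.shape:
        raise ValueError("masks must share a shape")
    union = np.count_nonzero(a | b)
    if union == 0:
        raise ValueError("IoU of two empty masks is undefined")
    return np.count_nonzero(a & b) / union


@dataclass
class MatchTable:
    """One-to-one predicted-truth pairing with IoUs."""

    pairs: List[Tuple[int, int, float]]  # (pred idx, truth idx, IoU)
    unmatched_preds: List[int]
    unmatched_truths: List[int]


def match_masks(
    preds: Sequence[np.ndarray], truths: Sequence[np.ndarray]
) -> MatchTable:
    """Greedy one-to-one matching beginning with the highest IoU."""
    ious = []
    for i, p in enumerate(preds):
        for j, t in enumerate(truths):
            if (p | t).any():
                v = mask_iou(p, t)
                if v > 0:
                    ious.append((v, i, j))
    ious.sort(key=lambda x: (-x[0], x[1], x[2]))
    used_p, used_t = set(), set()
    pairs = []
    for v, i, j in ious:
        if i not in used_p and j not in used_t:
            pairs.append((i, j, v))
            used_p.add(i)
            used_t.add(j)
    return MatchTable(
        pairs=pairs,
        unmatched_preds=[i for i in range(len(preds)) if i not in used_p],
        unmatched_truths=[j for j in range(len(truths)) if j not in used_t],
    )


def match_masks_exhaustive(
    preds: Sequence[np.ndarray], truths: Sequence[np.ndarray]
) -> float:
    """Total-IoU of the best one-to-one matching by brute force (oracle)."""
    n, m = len(preds), len(truths)
    iou = np.zeros((n, m))
    for i, j in itertools.product(range(n), range(m)):
        if (preds[i] | truths[j]).any():
            iou[i, j] = mask_iou(preds[i], truths[j])
    best = 0.0
    k = min(n, m)
    for perm in itertools.permutations(range(m), k):
        best = max(best, sum(iou[i, perm[i]] for i in range(k)))
    return best


DEFAULT_AP_THRESHOLDS = np.arange(0.50, 0.951, 0.05)


def average_precision(
    table: MatchTable, thresholds: Optional[np.ndarray] = None
) -> float:
    """Area under the PR curve swept over IoU thresholds.

    At each threshold, matched pairs with IoU >= threshold are true
    positives; other predictions are false positives and unmatched truths
    (plus pairs below threshold) false negatives.  The AP is the
    trapezoidal area under the (recall, precision) points, anchored at
    recall zero with the precision of the strictest threshold.
    """
    thresholds = DEFAULT_AP_THRESHOLDS if thresholds is None else np.asarray(thresholds)
    n_pred = len(table.pairs) + len(table.unmatched_preds)
    n_truth = len(table.pairs) + len(table.unmatched_truths)
    if n_truth == 0:
        raise ValueError("no ground-truth masks")
    if n_pred == 0:
        return 0.0
    ious = np.array([v for _, _, v in table.pairs])
    points = []
    for th in thresholds:
        tp = int((ious >= th).sum())
        precision = tp / n_pred
        recall = tp / n_truth
        points.append((recall, precision))
    points.sort()
    recalls = np.array([p[0] for p in points])
    precisions = np.array([p[1] for p in points])
    recalls = np.concatenate([[0.0], recalls])
    precisions = np.concatenate([[precisions[0]], precisions])
    return float(np.trapezoid(precisions, recalls))


def mean_average_precision(
    preds_by_frame: Sequence[Sequence[np.ndarray]],
    truths_by_frame: Sequence[Sequence[np.ndarray]],
    thresholds: Optional[np.ndarray] = None,
) -> float:
    """Mean per-image AP over a movie (images with truths only)."""
    aps = []
    for preds, truths in zip(preds_by_frame, truths_by_frame):
        if len(truths) == 0:
            continue
        aps.append(average_precision(match_masks(preds, truths), thresholds))
    return float(np.mean(aps)) if aps else 0.0


# ---------------------------------------------------------------------------
# track-level metrics


def frame_label_maps(
    pred_frames: Sequence[Tuple[Sequence[np.ndarray], Sequence[int]]],
    truth_frames: Sequence[Tuple[Sequence[np.ndarray], Sequence[int]]],
    iou_threshold: float = 0.5,
) -> List[Dict[int, int]]:
    """Per-frame pred-label -> truth-label maps from IoU > threshold matches."""
    maps: List[Dict[int, int]] = []
    for (pmasks, plabels), (tmasks, tlabels) in zip(pred_frames, truth_frames):
        table = match_masks(pmasks, tmasks)
        m = {
            plabels[i]: tlabels[j]
            for i, j, v in table.pairs
            if v > iou_threshold
        }
        maps.append(m)
    return maps


def _track_spans(
    frames: Sequence[Tuple[Sequence[np.ndarray], Sequence[int]]]
) -> Dict[int, set]:
    spans: Dict[int, set] = {}
    for t, (_, labels) in enumerate(frames):
        for lab in labels:
            spans.setdefault(lab, set()).add(t)
    return spans


def track_iou(
    pred_track: int,
    truth_track: int,
    label_maps: Sequence[Dict[int, int]],
    pred_span: set,
    truth_span: set,
) -> float:
    """Frames where the predicted label maps to the truth label, over the
    frames where either track has a mask."""
    union = pred_span | truth_span
    if not union:
        return 0.0
    agree = sum(
        1
        for t in pred_span & truth_span
        if label_maps[t].get(pred_track) == truth_track
    )
    return agree / len(union)


def match_tracks(
    pred_frames, truth_frames, iou_threshold: float = 0.5
) -> Tuple[Dict[int, int], Dict[Tuple[int, int], float]]:
    """Greedy track matching in descending track IoU.

    Returns (pred_track -> truth_track map, track-IoU lookup).
    """
    label_maps = frame_label_maps(pred_frames, truth_frames, iou_threshold)
    pred_spans = _track_spans(pred_frames)
    truth_spans = _track_spans(truth_frames)
    scores = []
    for p, ps in pred_spans.items():
        for q, ts in truth_spans.items():
            v = track_iou(p, q, label_maps, ps, ts)
            if v > 0:
                scores.append((v, p, q))
    scores.sort(key=lambda x: (-x[0], x[1], x[2]))
    used_p, used_t = set(), set()
    mapping: Dict[int, int] = {}
    lookup: Dict[Tuple[int, int], float] = {}
    for v, p, q in scores:
        lookup[(p, q)] = v
        if p not in used_p and q not in used_t:
            mapping[p] = q
            used_p.add(p)
            used_t.add(q)
    return mapping, lookup


def fraction_complete_tracks(
    pred_frames, truth_frames, missing_tolerance: int = 2, iou_threshold: float = 0.5
) -> float:
    """Fraction of truth tracks whose matched predicted track's duration
    (mask count) is within ``missing_tolerance`` frames of the truth's."""
    mapping, _ = match_tracks(pred_frames, truth_frames, iou_threshold)
    pred_spans = _track_spans(pred_frames)
    truth_spans = _track_spans(truth_frames)
    if not truth_spans:
        raise ValueError("no ground-truth tracks")
    inverse = {q: p for p, q in mapping.items()}
    n_ok = 0
    for q, ts in truth_spans.items():
        p = inverse.get(q)
        if p is not None and abs(len(pred_spans[p]) - len(ts)) <= missing_tolerance:
            n_ok += 1
    return n_ok / len(truth_spans)


def mota(pred_frames, truth_frames, iou_threshold: float = 0.5) -> float:
    """Multiple Object Tracking Accuracy (CLEAR convention).

    MOTA = 1 - (FN + FP + ID switches) / total truth objects, with
    correspondences valid at mask IoU >= ``iou_threshold``; identity
    switches are counted when a truth track's corresponding predicted
    label changes between consecutive correspondences.
    """
    total_truth = sum(len(labels) for _, labels in truth_frames)
    if total_truth == 0:
        raise ValueError("no ground-truth objects")
    fn = fp = idsw = 0
    last_pred_for_truth: Dict[int, int] = {}
    for (pmasks, plabels), (tmasks, tlabels) in zip(pred_frames, truth_frames):
        table = match_masks(pmasks, tmasks)
        valid = [(i, j) for i, j, v in table.pairs if v >= iou_threshold]
        matched_p = {i for i, _ in valid}
        matched_t = {j for _, j in valid}
        fp += len(pmasks) - len(matched_p)
        fn += len(tmasks) - len(matched_t)
        for i, j in valid:
            tl, pl = tlabels[j], plabels[i]
            if tl in last_pred_for_truth and last_pred_for_truth[tl] != pl:
                idsw += 1
            last_pred_for_truth[tl] = pl
    return 1.0 - (fn + fp + idsw) / total_truth


def lineage_precision_recall(
    pred_pairs: Dict[int, int],
    truth_pairs: Dict[int, int],
    pred_frames,
    truth_frames,
    track_iou_threshold: float = 0.5,
    restrict_mothers: Optional[set] = None,
) -> Tuple[float, float]:
    """Precision and recall of bud -> mother track assignments.

    A ground-truth pair is a true positive when the truth bud track has a
    matching predicted track and that predicted track's assigned mother
    matches the truth mother track.  ``restrict_mothers`` optionally
    limits scoring to pairs whose truth mother is in the set (e.g. the
    central trapped cell).
    """
    mapping, lookup = match_tracks(pred_frames, truth_frames, iou_threshold=0.5)
    # keep only track matches above the requested track-IoU threshold
    good = {
        p: q for p, q in mapping.items() if lookup.get((p, q), 0.0) >= track_iou_threshold
    }
    truth_of_pred = dict(good)
    pred_of_truth = {q: p for p, q in good.items()}

    truth_items = {
        (b, m)
        for b, m in truth_pairs.items()
        if restrict_mothers is None or m in restrict_mothers
    }
    tp = 0
    matched_pred_pairs = set()
    for b, m in truth_items:
        pb = pred_of_truth.get(b)
        if pb is None or pb not in pred_pairs:
            continue
        pm = pred_pairs[pb]
        if truth_of_pred.get(pm) == m:
            tp += 1
            matched_pred_pairs.add((pb, pm))
    pred_items = {
        (b, m)
        for b, m in pred_pairs.items()
        if restrict_mothers is None or truth_of_pred.get(m) in restrict_mothers
    }
    fp = len(pred_items - matched_pred_pairs)
    fn = len(truth_items) - tp
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    return precision, recall


# ---------------------------------------------------------------------------
# growth-rate accuracy


def growth_rmse(
    pred_frames: Sequence[Sequence[np.ndarray]],
    truth_frames: Sequence[Tuple[Sequence[np.ndarray], Sequence[int]]],
    pixel_size: float,
    sampling_interval: float,
    n_bootstrap: int = 1000,
    seed: int = 0,
    min_points: int = 6,
) -> Tuple[float, np.ndarray]:
    """RMSE between GP growth rates on predicted vs truth volumes.

    Predicted masks are matched to truth masks per frame by highest IoU
    (tracking ignored); per truth track, a volume series is assembled
    from the matched predictions (missing frames omitted) and both series
    are GP-fitted; the RMSE is taken over all (track, time) samples where
    both estimates exist, with a seeded bootstrap over 90% subsamples.
    """
    per_track_pred: Dict[int, Dict[float, float]] = {}
    per_track_truth: Dict[int, Dict[float, float]] = {}
    for t, (preds, (tmasks, tlabels)) in enumerate(zip(pred_frames, truth_frames)):
        table = match_masks(list(preds), list(tmasks))
        time = t * sampling_interval
        for j, lab in enumerate(tlabels):
            per_track_truth.setdefault(lab, {})[time] = conical_volume(tmasks[j], pixel_size)
        for i, j, v in table.pairs:
            if v > 0:
                per_track_pred.setdefault(tlabels[j], {})[time] = conical_volume(
                    preds[i], pixel_size
                )

    errors: List[float] = []
    for lab, truth_vols in per_track_truth.items():
        pred_vols = per_track_pred.get(lab, {})
        if len(truth_vols) < min_points or len(pred_vols) < min_points:
            continue
        ts_t = np.array(sorted(truth_vols))
        ts_p = np.array(sorted(pred_vols))
        gt = fit_gp_volume(
            VolumeSeries(lab, ts_t, np.array([truth_vols[x] for x in ts_t])), seed=seed
        )
        gp = fit_gp_volume(
            VolumeSeries(lab, ts_p, np.array([pred_vols[x] for x in ts_p])), seed=seed
        )
        common, ti, pi = np.intersect1d(gt.times, gp.times, return_indices=True)
        errors.extend((gt.rate_mean[ti] - gp.rate_mean[pi]).tolist())
    if not errors:
        raise ValueError("no matched tracks with enough points for a GP fit")
    errors_arr = np.asarray(errors)
    rmse = float(np.sqrt(np.mean(errors_arr**2)))
    rng = np.random.default_rng(seed)
    k = max(1, int(round(0.9 * len(errors_arr))))
    boot = np.array(
        [
            np.sqrt(np.mean(rng.choice(errors_arr, size=k, replace=False) ** 2))
            for _ in range(n_bootstrap)
        ]
    )
    return rmse, boot
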