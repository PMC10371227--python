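"""Seeded end-to-end benchmarks on synthetic colonies.

These functions drive the full pipeline on simulator output and measure
the quantities the package is designed to deliver: instance-recovery
rates through the oracle route, the effect of spline refinement,
tracking completeness under pivoting, lineage precision/recall with
oracle bud necks, growth-rate recovery, and the cytokinesis heuristic's
hit rate.  They are used both by the test suite and by the reproduction
script, so every reported number has exactly one implementation.
"""

from __future__ import annotations

import math
from typing import Dict, List, Tuple

import numpy as np

from .growth import VolumeSeries, estimate_cytokinesis, fit_gp_volume
from .metrics import (
    fraction_complete_tracks,
    lineage_precision_recall,
    mask_iou,
    match_masks,
    mota,
)
from .pipeline import PipelineConfig, run_pipeline
from .segment import segment_frame
from .simulate import SimParams, ellipse_mask, simulate_colony
from .targets import optimize_size_boundaries
from .tracking import Tracker
from .unet import oracle_predict


def oracle_segmentation_recall(
    n_colonies: int = 20,
    seed: int = 0,
    iou_threshold: float = 0.7,
    frame_stride: int = 3,
) -> Tuple[float, int]:
    """Fraction of synthetic cells recovered at mask IoU >= threshold via
    the oracle route, over colonies with overlap bias up to 0.5."""
    recovered = total = 0
    for k in range(n_colonies):
        bias = 0.2 + 0.3 * (k % 2)  # alternate 0.2 / 0.5
        movie = simulate_colony(
            SimParams(seed=seed * 1000 + k, n_timepoints=12, n_mothers=3,
                      overlap_bias=bias, n_z=1)
        )
        frames = [f for f in movie.frames if f.masks]
        spec = optimize_size_boundaries(frames)
        for frame in frames[::frame_stride]:
            targets = oracle_predict(frame, spec, shape=movie.params.image_shape)
            instances = segment_frame(targets, spec)
            table = match_masks([i.mask for i in instances], frame.masks)
            total += len(frame.masks)
            recovered += sum(1 for _, _, v in table.pairs if v >= iou_threshold)
    return recovered / total, total


def refinement_comparison(
    n_colonies: int = 5, seed: int = 0, sigma: float = 1.0
) -> Tuple[float, float, int]:
    """Mean truth-IoU with and without radial-spline refinement on
    sigma-blurred oracle maps.  Returns (refined, raw, n cells)."""
    ious: Dict[bool, List[float]] = {True: [], False: []}
    for k in range(n_colonies):
        movie = simulate_colony(
            SimParams(seed=seed * 777 + k, n_timepoints=12, n_mothers=3,
                      overlap_bias=0.4, n_z=1)
        )
        frames = [f for f in movie.frames if f.masks]
        spec = optimize_size_boundaries(frames)
        for frame in frames[::4]:
            targets = oracle_predict(frame, spec, sigma=sigma,
                                     shape=movie.params.image_shape)
            for refine in (True, False):
                instances = segment_frame(targets, spec, refine=refine)
                table = match_masks([i.mask for i in instances], frame.masks)
                vals = [v for _, _, v in table.pairs] + [0.0] * len(table.unmatched_truths)
                ious[refine].extend(vals)
    return float(np.mean(ious[True])), float(np.mean(ious[False])), len(ious[True])


def gp_slope_recovery(n_series: int = 50, seed: int = 0) -> Tuple[float, int]:
    """Median absolute relative error of GP-recovered linear growth slopes
    (slopes 5-40 um^3/h, 2% multiplicative noise)."""
    rng = np.random.default_rng(seed)
    errors = []
    for k in range(n_series):
        slope = rng.uniform(5, 40)
        t = np.arange(20) * 5.0
        v = 50 + slope * t / 60
        v = v + rng.normal(0, 0.02 * v)
        est = fit_gp_volume(VolumeSeries(k, t, v), seed=seed + k)
        errors.append(abs(np.median(est.rate_mean[2:18]) - slope) / slope)
    return float(np.median(errors)), n_series


def tracking_benchmark(
    classifiers, mb_classifier, n_movies: int = 5, seed: int = 0,
    pivot_prob: float = 0.2,
) -> Dict[str, float]:
    """Track completeness and MOTA on pivoting colonies (oracle route)."""
    complete_num = complete_den = 0
    motas = []
    for k in range(n_movies):
        movie = simulate_colony(
            SimParams(seed=seed * 31 + k, n_timepoints=25, n_mothers=3,
                      pivot_prob=pivot_prob, n_z=1)
        )
        res = run_pipeline(PipelineConfig(seed=seed + k, p_min=0.15), movie=movie,
                           classifiers=classifiers, mother_bud_classifier=mb_classifier)
        truth = [(f.masks, f.track_labels) for f in movie.frames]
        frac = fraction_complete_tracks(res.pred_frames, truth)
        n_truth_tracks = len({t for f in movie.frames for t in f.track_labels})
        complete_num += round(frac * n_truth_tracks)
        complete_den += n_truth_tracks
        motas.append(mota(res.pred_frames, truth))
    return {
        "fraction_complete": complete_num / complete_den,
        "mota": float(np.mean(motas)),
        "n_tracks": complete_den,
    }


def rotation_identity_switches(classifiers, angle_deg: float = 30.0) -> int:
    """Identity switches when a static colony rotates rigidly by one step."""
    shape = (128, 128)
    cells = [
        ((40.0, 40.0), 12.0, 10.0, 0.3),
        ((40.0, 80.0), 11.0, 11.0, 0.0),
        ((85.0, 60.0), 13.0, 10.5, 1.0),
        ((52.0, 40.0), 6.0, 5.5, 0.2),
        ((40.0, 92.0), 5.0, 5.0, 0.1),
        ((85.0, 74.0), 7.0, 6.0, 0.5),
    ]

    def frame(rot: float):
        cy0, cx0 = 60.0, 60.0
        out = []
        for (cy, cx), a, b, phi in cells:
            c, s = math.cos(rot), math.sin(rot)
            ny = cy0 + (cy - cy0) * c - (cx - cx0) * s
            nx = cx0 + (cy - cy0) * s + (cx - cx0) * c
            out.append(ellipse_mask(shape, (ny, nx), a, b, phi + rot))
        return out

    tracker = Tracker(classifiers, p_min=0.15)
    l1 = tracker.step(frame(0.0))
    l2 = tracker.step(frame(math.radians(angle_deg)))
    return sum(a != b for a, b in zip(l1, l2))


def corruption_label_changes(classifiers, seed: int = 11) -> Tuple[float, int]:
    """Fraction of final track labels changed by dropping 20% of one
    frame's instances (temporal-aggregation robustness)."""
    movie = simulate_colony(SimParams(seed=seed, n_timepoints=20, n_mothers=3, n_z=1))

    def run(frames):
        tracker = Tracker(classifiers, p_min=0.15)
        return [tracker.step(list(f)) for f in frames]

    frames = [list(f.masks) for f in movie.frames]
    baseline = run(frames)
    corrupted = [list(f) for f in frames]
    t_mid = len(frames) // 2
    n_drop = max(1, int(0.2 * len(corrupted[t_mid])))
    corrupted[t_mid] = corrupted[t_mid][: len(corrupted[t_mid]) - n_drop]
    altered = run(corrupted)
    diff = total = 0
    for t in range(len(frames)):
        if t == t_mid:
            continue
        for a, b in zip(baseline[t], altered[t]):
            total += 1
            diff += a != b
    return diff / total, total


def lineage_benchmark(
    classifiers, mb_classifier, n_movies: int = 4, seed: int = 0
) -> Dict[str, float]:
    """Lineage precision/recall with oracle bud-neck maps."""
    tps = fps = fns = 0
    precisions, recalls = [], []
    for k in range(n_movies):
        movie = simulate_colony(
            SimParams(seed=seed * 13 + k, n_timepoints=30, n_mothers=3,
                      overlap_bias=0.3, n_z=1)
        )
        res = run_pipeline(PipelineConfig(seed=seed + k), movie=movie,
                           classifiers=classifiers, mother_bud_classifier=mb_classifier)
        truth = [(f.masks, f.track_labels) for f in movie.frames]
        # score only assignable pairs: a bud born in the movie's last one
        # or two frames cannot satisfy the three-joint-frame rule
        joint = {b: 0 for b in movie.lineage}
        for f in movie.frames:
            present = set(f.track_labels)
            for b, m in movie.lineage.items():
                joint[b] += b in present and m in present
        truth_pairs = {b: m for b, m in movie.lineage.items() if joint[b] >= 3}
        p, r = lineage_precision_recall(res.lineage, truth_pairs,
                                        res.pred_frames, truth)
        precisions.append(p)
        recalls.append(r)
    return {"precision": float(np.mean(precisions)), "recall": float(np.mean(recalls)),
            "n_movies": n_movies}


def cytokinesis_benchmark(
    n_movies: int = 8, seed: int = 0, tolerance: int = 2
) -> Tuple[float, int]:
    """Fraction of known division events localised within ``tolerance``
    time points from the bud's GP growth-rate profile."""
    hits = total = 0
    for k in range(n_movies):
        movie = simulate_colony(
            SimParams(seed=seed * 17 + k, n_timepoints=40, n_mothers=3, n_z=1)
        )
        dt = movie.params.sampling_interval
        for bud, t_true in movie.true_cytokinesis.items():
            v = movie.true_volumes[bud]
            keep = ~np.isnan(v)
            idx = np.flatnonzero(keep)
            if keep.sum() < 8 or idx[-1] < t_true + 2:
                continue
            est = fit_gp_volume(VolumeSeries(bud, idx * dt, v[keep]), seed=seed + k)
            ci, _ = estimate_cytokinesis(est)
            t_est = est.times[ci] / dt
            total += 1
            hits += abs(t_est - t_true) <= tolerance
    return hits / total if total else 0.0, total
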