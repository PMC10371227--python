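"""End-to-end pipeline: semantic maps -> instances -> tracks -> lineage ->
volumes, growth rates, cytokinesis and the escape-fraction statistic.

The pipeline consumes a movie directory written by
:func:`budtrack.simulate.emit_ground_truth` (or an in-memory
``SimulatedMovie``).  Semantic maps come either from the idealised oracle
(ground-truth targets, optionally softened) or from a trained U-net
checkpoint; everything downstream is identical in the two modes.
Tracking and lineage classifiers are loaded from a bundle when given,
otherwise they are trained on auxiliary movies simulated from the run
seed, so a run is self-contained and reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .growth import (
    GrowthEstimate,
    VolumeSeries,
    combined_growth_rate,
    conical_volume,
    escape_fraction,
    estimate_cytokinesis,
    fit_gp_volume,
)
from .segment import SegmentedInstance, segment_frame
from .simulate import SimParams, SimulatedMovie, load_ground_truth, simulate_colony
from .targets import SizeCategorySpec, optimize_size_boundaries
from .tracking import (
    LineageLedger,
    Tracker,
    candidate_pairs_for_frame,
    build_tracking_training_set,
    features_of_instance,
    train_mother_bud_classifier,
    train_track_classifiers,
)
from .unet import UNetConfig, build_unet, oracle_predict, predict_semantic

SCHEMA_VERSION = "budtrack-results-1"


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run (YAML-serialisable)."""

    input_dir: Optional[str] = None
    out_dir: Optional[str] = None
    mode: str = "oracle"  # "oracle" | "model"
    oracle_sigma: float = 0.0
    model_checkpoint: Optional[str] = None
    pixel_size: Optional[float] = None  # default: from the movie metadata
    boundaries: Optional[Tuple[float, float]] = None  # else optimised from data
    p_interior: float = 0.5
    p_min: float = 0.5
    lost_patience: int = 2
    min_joint_frames: int = 3
    cytokinesis_alpha: float = 0.5
    escape_threshold: float = 15.0  # um^3/h
    min_gp_points: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("oracle", "model"):
            raise ValueError("mode must be 'oracle' or 'model'")
        for name, value, lo, hi in [
            ("p_interior", self.p_interior, 0, 1),
            ("p_min", self.p_min, 0, 1),
            ("cytokinesis_alpha", self.cytokinesis_alpha, 0, 1),
        ]:
            if not lo <= value <= hi:
                raise ValueError(f"{name} must lie in [{lo}, {hi}]")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "boundaries" in data and data["boundaries"] is not None:
            data["boundaries"] = tuple(data["boundaries"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))


@dataclass
class PipelineResult:
    """Everything one run produces, in memory."""

    config: PipelineConfig
    spec: SizeCategorySpec
    instances_by_frame: List[List[SegmentedInstance]]
    labels_by_frame: List[List[int]]
    lineage: Dict[int, int]  # bud track -> mother track
    growth: Dict[int, GrowthEstimate]
    cytokinesis: Dict[int, Tuple[int, bool]]
    escape_times: np.ndarray
    escape_fractions: np.ndarray

    @property
    def pred_frames(self) -> List[Tuple[List[np.ndarray], List[int]]]:
        return [
            ([inst.mask for inst in insts], labels)
            for insts, labels in zip(self.instances_by_frame, self.labels_by_frame)
        ]


def _train_default_classifiers(seed: int, pivot_probs=(0.05, 0.3, 0.6)):
    """Train tracking and lineage classifiers on auxiliary simulations.

    The training movies span calm and strongly pivoting colonies so the
    morphology-only classifier sees plenty of same-cell pairs with zero
    mask overlap (pivoted buds) and learns to link them by shape alone.
    """
    movies = [
        simulate_colony(
            SimParams(
                n_timepoints=25,
                n_mothers=3,
                seed=seed * 1000 + k,
                pivot_prob=pp,
                colony_rotation_prob=0.1,
                washout_prob=0.01,
                overlap_bias=0.3,
            )
        )
        for k, pp in enumerate(pivot_probs)
    ]
    xa, xb, y = build_tracking_training_set(movies, seed=seed)
    track_clf = train_track_classifiers(xa, xb, y, seed=seed)
    mb_clf = train_mother_bud_classifier(movies, seed=seed)
    return track_clf, mb_clf


def run_pipeline(
    config: PipelineConfig,
    movie: Optional[SimulatedMovie] = None,
    classifiers=None,
    mother_bud_classifier=None,
) -> PipelineResult:
    """Run the full analysis; see module docstring.

    ``movie`` may be passed directly (library use); otherwise it is
    loaded from ``config.input_dir``.
    """
    if movie is None:
        if config.input_dir is None:
            raise ValueError("either a movie or config.input_dir is required")
        movie = load_ground_truth(config.input_dir)
    pixel_size = config.pixel_size or movie.params.pixel_size
    dt = movie.params.sampling_interval

    nonempty = [f for f in movie.frames if len(f.masks) >= 1]
    total_cells = sum(len(f.masks) for f in nonempty)
    if config.boundaries is not None:
        spec = SizeCategorySpec(boundaries=config.boundaries)
    elif total_cells >= 2:
        spec = optimize_size_boundaries(nonempty)
    else:
        spec = SizeCategorySpec()

    if classifiers is None or mother_bud_classifier is None:
        track_clf, mb_clf = _train_default_classifiers(config.seed)
        classifiers = classifiers or track_clf
        mother_bud_classifier = mother_bud_classifier or mb_clf

    model = None
    if config.mode == "model":
        if config.model_checkpoint is None:
            raise ValueError("model mode needs a checkpoint")
        model = load_checkpoint(config.model_checkpoint)

    tracker = Tracker(classifiers, p_min=config.p_min, lost_patience=config.lost_patience)
    ledger = LineageLedger()
    instances_by_frame: List[List[SegmentedInstance]] = []
    labels_by_frame: List[List[int]] = []
    volumes: Dict[int, Dict[int, float]] = {}

    for t, frame in enumerate(movie.frames):
        if config.mode == "oracle":
            targets = oracle_predict(
                frame, spec, sigma=config.oracle_sigma, shape=movie.params.image_shape
            )
        else:
            targets = predict_semantic(model, movie.images[t])
        instances = segment_frame(targets, spec, p_interior=config.p_interior)
        masks = [inst.mask for inst in instances]
        feats = [features_of_instance(inst) for inst in instances]
        labels = tracker.step(masks, feats)
        instances_by_frame.append(instances)
        labels_by_frame.append(labels)
        for inst, lab in zip(instances, labels):
            volumes.setdefault(lab, {})[t] = conical_volume(inst.mask, pixel_size)
        if len(masks) >= 2:
            pairs = candidate_pairs_for_frame(
                masks, labels, targets[7].astype(float), mother_bud_classifier
            )
            ledger.update(pairs)

    lineage = ledger.assign_mothers(min_joint_frames=config.min_joint_frames)

    growth: Dict[int, GrowthEstimate] = {}
    for track, by_t in volumes.items():
        if len(by_t) < max(4, config.min_gp_points):
            continue
        ts = np.array(sorted(by_t))
        series = VolumeSeries(track, ts * dt, np.array([by_t[k] for k in ts]))
        growth[track] = fit_gp_volume(series, seed=config.seed)

    cytokinesis = {
        bud: estimate_cytokinesis(growth[bud], alpha=config.cytokinesis_alpha)
        for bud in lineage
        if bud in growth
    }

    buds_by_mother: Dict[int, List[Tuple[np.ndarray, np.ndarray]]] = {}
    for bud, mother in lineage.items():
        if bud in growth:
            buds_by_mother.setdefault(mother, []).append(
                (growth[bud].times, growth[bud].rate_mean)
            )
    times = np.arange(movie.n_timepoints) * dt
    if buds_by_mother:
        fracs = np.array(
            [
                escape_fraction(buds_by_mother, qt, threshold=config.escape_threshold)
                for qt in times
            ]
        )
    else:
        fracs = np.zeros_like(times, dtype=float)

    return PipelineResult(
        config=config,
        spec=spec,
        instances_by_frame=instances_by_frame,
        labels_by_frame=labels_by_frame,
        lineage=lineage,
        growth=growth,
        cytokinesis=cytokinesis,
        escape_times=times,
        escape_fractions=fracs,
    )


def load_image_series(path, n_z: Optional[int] = None) -> np.ndarray:
    """Load a time-lapse TIFF as (T, n_z, H, W).

    Accepts the layout written by :func:`budtrack.simulate.emit_ground_truth`
    (pages ordered time-major, Z within time).  A plain (T, H, W) file is
    interpreted as single-Z; a 2D file as one frame of one section.
    """
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        return arr[None, None]
    if arr.ndim == 3:
        if n_z and n_z > 1:
            if arr.shape[0] % n_z:
                raise ValueError(
                    f"page count {arr.shape[0]} not divisible by n_z={n_z}"
                )
            return arr.reshape(arr.shape[0] // n_z, n_z, *arr.shape[1:])
        return arr[:, None]
    if arr.ndim == 4:
        if n_z and arr.shape[1] != n_z:
            raise ValueError(f"expected n_z={n_z}, file has {arr.shape[1]}")
        return arr
    raise ValueError(f"cannot interpret TIFF with shape {arr.shape}")


# ---------------------------------------------------------------------------
# persistence


def save_checkpoint(model, path) -> None:
    """Persist a U-net (weights + config) as a compressed npz."""
    cfg = dataclasses.asdict(model.config)
    cfg["channel_weights"] = list(cfg["channel_weights"])
    np.savez_compressed(path, __config__=json.dumps(cfg), **model.params)


def load_checkpoint(path):
    data = np.load(path, allow_pickle=False)
    cfg = json.loads(str(data["__config__"]))
    cfg["channel_weights"] = tuple(cfg["channel_weights"])
    model = build_unet(UNetConfig(**cfg))
    for k in model.params:
        model.params[k] = data[k]
    return model


def write_results(result: PipelineResult, out_dir) -> None:
    """Write a result bundle: masks (TIFF), instances (HDF5), CSV tables,
    escape-fraction series (JSON lines) and a run log."""
    import h5py

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    track_rows = []
    for t, (insts, labels) in enumerate(
        zip(result.instances_by_frame, result.labels_by_frame)
    ):
        if insts:
            arr = np.stack([i.mask.astype(np.uint8) for i in insts])
            tifffile.imwrite(out / f"pred_masks_t{t:03d}.tif", arr,
                             photometric="minisblack")
        for page, (inst, lab) in enumerate(zip(insts, labels)):
            cy, cx = inst.spline.centre
            track_rows.append(
                {
                    "time": t,
                    "track": lab,
                    "label": lab,
                    "mask_page": page,
                    "centroid_y": cy,
                    "centroid_x": cx,
                    "area": int(inst.mask.sum()),
                    "category": inst.category,
                    "score": inst.score,
                }
            )
    cols = ["time", "track", "label", "mask_page", "centroid_y", "centroid_x",
            "area", "category", "score"]
    pd.DataFrame(track_rows, columns=cols).to_csv(out / "tracks.csv", index=False)

    with h5py.File(out / "instances.h5", "w") as f:
        f.attrs["schema"] = SCHEMA_VERSION
        for t, (insts, labels) in enumerate(
            zip(result.instances_by_frame, result.labels_by_frame)
        ):
            g = f.create_group(f"t{t:03d}")
            for inst, lab in zip(insts, labels):
                gg = g.create_group(f"track{lab}")
                gg.create_dataset("centre", data=np.array(inst.spline.centre))
                gg.create_dataset("radii", data=inst.spline.knot_radii)
                gg.attrs["category"] = inst.category
                gg.attrs["score"] = inst.score

    lin_rows = [
        {"bud_track": b, "mother_track": m,
         "cytokinesis_t": result.cytokinesis.get(b, (-1, True))[0]}
        for b, m in sorted(result.lineage.items())
    ]
    pd.DataFrame(lin_rows, columns=["bud_track", "mother_track", "cytokinesis_t"]).to_csv(
        out / "lineage.csv", index=False
    )

    g_rows = []
    for track, est in sorted(result.growth.items()):
        for i, tm in enumerate(est.times):
            g_rows.append(
                {
                    "track": track,
                    "time_min": tm,
                    "volume": est.volume_mean[i],
                    "volume_sd": est.volume_sd[i],
                    "rate": est.rate_mean[i],
                    "rate_sd": est.rate_sd[i],
                }
            )
    pd.DataFrame(
        g_rows, columns=["track", "time_min", "volume", "volume_sd", "rate", "rate_sd"]
    ).to_csv(out / "growth.csv", index=False)

    with open(out / "escape_fraction.jsonl", "w") as fh:
        for tm, fr in zip(result.escape_times, result.escape_fractions):
            fh.write(json.dumps({"time_min": float(tm), "escape_fraction": float(fr)}) + "\n")

    log = {
        "schema": SCHEMA_VERSION,
        "budtrack_version": __version__,
        "python": platform.python_version(),
        "config": dataclasses.asdict(result.config),
        "size_boundaries": list(result.spec.boundaries),
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
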