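"""Synthetic trapped-colony movies with full ground truth.

Emulates the geometry of budding cells growing in microfluidic traps:
elliptical mothers that repeatedly nucleate buds on their periphery, buds
that overlap their mothers and neighbours, occasional pivoting of buds
about their mothers, and washout of non-trapped cells by the medium flow.
Every movie carries exhaustive ground truth -- per-cell (possibly
overlapping) masks, track labels, mother-bud pairs, cytokinesis times and
true volume trajectories -- so that segmentation, tracking, lineage and
growth-rate estimation can all be benchmarked without external data.

Geometry is kept in a parametric form (ellipse centre, semi-axes,
orientation) and rasterised per frame; volumes are evolved in physical
units (um^3) and projected to 2D areas via the sphere-equivalent
cross-section, so that the conical volume estimator applied to the masks
recovers a monotone transform of the true volume.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage


@dataclass
class AnnotatedFrame:
    """One time point: per-cell binary masks with track labels and lineage.

    Masks may overlap.  ``track_labels[i]`` is the (globally unique) track
    id of ``masks[i]``; ``mother_pairs`` lists ``(bud_label, mother_label)``
    for buds still attached to their mothers at this time point.
    """

    masks: List[np.ndarray]
    track_labels: List[int]
    mother_pairs: List[Tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.masks) != len(self.track_labels):
            raise ValueError("one track label per mask required")
        if len(set(self.track_labels)) != len(self.track_labels):
            raise ValueError("track labels must be unique within a frame")
        for m in self.masks:
            if not m.any():
                raise ValueError("each mask needs at least one foreground pixel")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.masks[0].shape if self.masks else (0, 0)

    def mask_of(self, label: int) -> np.ndarray:
        return self.masks[self.track_labels.index(label)]


@dataclass
class SimParams:
    """Parameters of the synthetic colony generator.

    Rates are physical (um^3/h for the linear law, 1/h specific rate for
    the exponential law); geometry is in pixels via ``pixel_size``.
    """

    image_shape: Tuple[int, int] = (128, 128)
    pixel_size: float = 0.25  # um per pixel
    n_z: int = 5
    z_spacing: float = 0.6  # um
    n_timepoints: int = 40
    sampling_interval: float = 5.0  # minutes
    n_mothers: int = 3
    mother_radius_range: Tuple[float, float] = (9.0, 13.0)  # px
    bud_growth_rate_range: Tuple[float, float] = (20.0, 45.0)
    growth_law: str = "linear"  # or "exponential"
    overlap_bias: float = 0.3
    pivot_prob: float = 0.0
    colony_rotation_prob: float = 0.0  # whole-colony rotation (flow jolt)
    washout_prob: float = 0.0
    noise_sd: float = 0.03
    seed: int = 0
    # secondary knobs (fixed study conditions, overridable for experiments)
    bud_initial_volume_range: Tuple[float, float] = (3.5, 7.5)  # um^3 at birth
    cytokinesis_volume: float = 40.0  # um^3, bud size at division
    daughter_rate_factor: float = 0.15  # daughter growth relative to bud
    mother_rate_factor: float = 0.25  # mother growth relative to bud draw
    attach_depth_range: Tuple[float, float] = (0.4, 0.8)  # fraction of bud radius
    bud_delay_frames: Tuple[int, int] = (1, 3)

    def __post_init__(self) -> None:
        h, w = self.image_shape
        if h <= 0 or w <= 0:
            raise ValueError("image area must be positive")
        if self.n_z not in (1, 5):
            raise ValueError("n_z must be 1 or 5")
        for p in (self.overlap_bias, self.pivot_prob, self.washout_prob,
                  self.colony_rotation_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.pixel_size <= 0 or self.sampling_interval <= 0:
            raise ValueError("pixel_size and sampling_interval must be positive")
        lo, hi = self.mother_radius_range
        if lo < 0 or hi < lo:
            raise ValueError("mother_radius_range must be non-negative and ordered")
        if hi >= min(h, w) / 2:
            raise ValueError("mother radius exceeds image")
        glo, ghi = self.bud_growth_rate_range
        if glo < 0 or ghi < glo:
            raise ValueError("bud_growth_rate_range must be non-negative and ordered")
        if self.growth_law not in ("linear", "exponential"):
            raise ValueError("growth_law must be 'linear' or 'exponential'")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class SimulatedMovie:
    """A simulated movie plus its exhaustive ground truth."""

    params: SimParams
    frames: List[AnnotatedFrame]
    images: List[np.ndarray]  # (n_z, H, W) float32 per time point
    true_volumes: Dict[int, np.ndarray]  # track -> (T,) um^3, nan if absent
    true_cytokinesis: Dict[int, int]  # bud track -> frame index of division
    lineage: Dict[int, int]  # bud track -> mother track
    n_washouts: int = 0

    @property
    def n_timepoints(self) -> int:
        return len(self.frames)

    def track_presence(self, track: int) -> np.ndarray:
        return ~np.isnan(self.true_volumes[track])


# ---------------------------------------------------------------------------
# geometry helpers


def ellipse_mask(
    shape: Tuple[int, int],
    centre: Tuple[float, float],
    a: float,
    b: float,
    phi: float,
) -> np.ndarray:
    """Rasterise a filled ellipse (semi-axes ``a``, ``b``; rotation ``phi``)."""
    h, w = shape
    cy, cx = centre
    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - cy, xx - cx
    c, s = math.cos(phi), math.sin(phi)
    u = dx * c + dy * s
    v = -dx * s + dy * c
    return (u / max(a, 1e-6)) ** 2 + (v / max(b, 1e-6)) ** 2 <= 1.0


def volume_to_area(volume: float, pixel_size: float, k: float = 1.0) -> float:
    """Projected 2D mask area (px^2) of a cell of given true volume (um^3).

    Uses the sphere-equivalent cross-section pi*(3V/4pi)^(2/3) scaled by
    ``k`` (projection calibration, default 1), converted to pixels.
    """
    r_um = (3.0 * volume / (4.0 * math.pi)) ** (1.0 / 3.0)
    return k * math.pi * (r_um / pixel_size) ** 2


def area_to_volume(area_px: float, pixel_size: float, k: float = 1.0) -> float:
    """Inverse of :func:`volume_to_area`."""
    r_um = math.sqrt(area_px / (k * math.pi)) * pixel_size
    return 4.0 / 3.0 * math.pi * r_um**3


# ---------------------------------------------------------------------------
# simulation core


@dataclass
class _Cell:
    track: int
    role: str  # "mother" | "bud" | "daughter"
    volume: float
    centre: Tuple[float, float]
    axis_ratio: float  # b/a <= 1
    phi: float
    rate: float
    mother: Optional[int] = None
    attach_angle: float = 0.0
    attach_depth: float = 0.6

    def radius(self, pixel_size: float) -> float:
        area = volume_to_area(self.volume, pixel_size)
        return math.sqrt(area / (math.pi * self.axis_ratio))  # semi-major a


def _cell_axes(cell: _Cell, pixel_size: float) -> Tuple[float, float]:
    a = cell.radius(pixel_size)
    return a, a * cell.axis_ratio


def _boundary_radius(a: float, b: float, phi: float, theta: float) -> float:
    """Radius of an ellipse boundary in direction ``theta`` (image frame)."""
    t = theta - phi
    return (a * b) / math.sqrt((b * math.cos(t)) ** 2 + (a * math.sin(t)) ** 2)


def _mother_positions(
    params: SimParams, rng: np.random.Generator
) -> List[Tuple[float, float]]:
    """Spread mothers quasi-uniformly, leaving room for buds at the border."""
    h, w = params.image_shape
    n = params.n_mothers
    if n == 0:
        return []
    margin = params.mother_radius_range[1] * 2.2
    pos: List[Tuple[float, float]] = []
    if n == 1:
        base = [(h / 2, w / 2)]
    else:
        # ring layout around the image centre
        ring_r = min(h, w) / 2 - margin
        base = [
            (
                h / 2 + ring_r * 0.75 * math.sin(2 * math.pi * i / n),
                w / 2 + ring_r * 0.75 * math.cos(2 * math.pi * i / n),
            )
            for i in range(n)
        ]
    for by, bx in base:
        jy, jx = rng.uniform(-3, 3, size=2)
        pos.append((float(np.clip(by + jy, margin, h - margin)),
                    float(np.clip(bx + jx, margin, w - margin))))
    return pos


def _step_volume(v: float, rate: float, dt_h: float, law: str) -> float:
    if law == "linear":
        return v + rate * dt_h
    return v * math.exp(rate * dt_h)


def simulate_colony(params: SimParams) -> SimulatedMovie:
    """Simulate a trapped colony and render its bright-field Z-stacks.

    Mothers nucleate buds cyclically on their boundary (placement biased
    toward neighbouring cells by ``overlap_bias``); bud 2D area follows the
    true volume under ``growth_law``; at cytokinesis (bud volume reaching
    ``cytokinesis_volume``) the bud continues as an independent daughter
    track; pivots rotate bud centroids about their mothers; washouts
    terminate non-mother tracks.  Identical params (incl. seed) give
    bit-identical movies.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.image_shape
    dt_h = params.sampling_interval / 60.0
    T = params.n_timepoints

    cells: Dict[int, _Cell] = {}
    next_track = 1
    volumes: Dict[int, List[float]] = {}
    cytokinesis: Dict[int, int] = {}
    lineage: Dict[int, int] = {}
    n_washouts = 0
    # per-mother budding schedule: frame at which the next bud appears
    next_bud_at: Dict[int, int] = {}
    current_bud: Dict[int, Optional[int]] = {}

    for cy, cx in _mother_positions(params, rng):
        r = rng.uniform(*params.mother_radius_range)
        q = rng.uniform(0.8, 1.0)
        vol = area_to_volume(math.pi * r * r * q, params.pixel_size)
        rate_draw = rng.uniform(*params.bud_growth_rate_range)
        cells[next_track] = _Cell(
            track=next_track,
            role="mother",
            volume=vol,
            centre=(cy, cx),
            axis_ratio=q,
            phi=rng.uniform(0, math.pi),
            rate=rate_draw * params.mother_rate_factor,
        )
        volumes[next_track] = []
        next_bud_at[next_track] = int(rng.integers(*params.bud_delay_frames, endpoint=True))
        current_bud[next_track] = None
        next_track += 1

    frames: List[AnnotatedFrame] = []
    images: List[np.ndarray] = []

    def _nearest_other_angle(mother: _Cell) -> Optional[float]:
        others = [c for c in cells.values() if c.track != mother.track]
        if not others:
            return None
        my, mx = mother.centre
        best = min(others, key=lambda c: (c.centre[0] - my) ** 2 + (c.centre[1] - mx) ** 2)
        return math.atan2(best.centre[0] - my, best.centre[1] - mx)

    def _place_bud(bud: _Cell, mother: _Cell) -> None:
        ma, mb = _cell_axes(mother, params.pixel_size)
        ba = bud.radius(params.pixel_size)
        rb = _boundary_radius(ma, mb, mother.phi, bud.attach_angle)
        d = rb + ba * (1.0 - bud.attach_depth)
        my, mx = mother.centre
        bud.centre = (my + d * math.sin(bud.attach_angle), mx + d * math.cos(bud.attach_angle))

    for t in range(T):
        # --- advance state (skip on the first frame: initial condition) ---
        if t > 0:
            # growth
            for c in cells.values():
                c.volume = _step_volume(c.volume, c.rate, dt_h, params.growth_law)
            # cytokinesis
            for c in list(cells.values()):
                if c.role == "bud" and c.volume >= params.cytokinesis_volume:
                    c.role = "daughter"
                    c.rate = c.rate * params.daughter_rate_factor
                    cytokinesis[c.track] = t
                    m = c.mother
                    if m is not None and m in cells:
                        current_bud[m] = None
                        next_bud_at[m] = t + int(
                            rng.integers(*params.bud_delay_frames, endpoint=True)
                        )
            # whole-colony rotation (e.g. a jolt of the medium flow)
            if cells and rng.random() < params.colony_rotation_prob:
                ang = rng.choice([-1.0, 1.0]) * rng.uniform(math.pi / 18, math.pi / 4)
                cy0 = float(np.mean([c.centre[0] for c in cells.values()]))
                cx0 = float(np.mean([c.centre[1] for c in cells.values()]))
                ca, sa = math.cos(ang), math.sin(ang)
                for c in cells.values():
                    dy, dx = c.centre[0] - cy0, c.centre[1] - cx0
                    c.centre = (cy0 + dy * ca - dx * sa, cx0 + dy * sa + dx * ca)
                    c.phi += ang
                    c.attach_angle += ang
            # pivots
            for c in cells.values():
                if c.role == "bud" and rng.random() < params.pivot_prob:
                    c.attach_angle += rng.choice([-1.0, 1.0]) * rng.uniform(
                        math.pi / 6, math.pi / 2
                    )
            # washouts (non-mother cells only; traps retain mothers)
            for c in list(cells.values()):
                if c.role != "mother" and rng.random() < params.washout_prob:
                    if c.role == "bud" and c.mother in cells:
                        current_bud[c.mother] = None
                        next_bud_at[c.mother] = t + int(
                            rng.integers(*params.bud_delay_frames, endpoint=True)
                        )
                    del cells[c.track]
                    n_washouts += 1
            # daughters drift slowly away from their mothers
            for c in cells.values():
                if c.role == "daughter" and c.mother in cells:
                    my, mx = cells[c.mother].centre
                    dy, dx = c.centre[0] - my, c.centre[1] - mx
                    nrm = math.hypot(dy, dx) or 1.0
                    c.centre = (c.centre[0] + 0.4 * dy / nrm, c.centre[1] + 0.4 * dx / nrm)

        # --- nucleate buds ---
        for m_track, due in list(next_bud_at.items()):
            if m_track not in cells or current_bud[m_track] is not None:
                continue
            if t >= due:
                mother = cells[m_track]
                if rng.random() < params.overlap_bias:
                    ang = _nearest_other_angle(mother)
                    attach = (
                        ang + rng.uniform(-0.3, 0.3)
                        if ang is not None
                        else rng.uniform(0, 2 * math.pi)
                    )
                else:
                    attach = rng.uniform(0, 2 * math.pi)
                bud = _Cell(
                    track=next_track,
                    role="bud",
                    volume=rng.uniform(*params.bud_initial_volume_range),
                    centre=mother.centre,
                    axis_ratio=rng.uniform(0.85, 1.0),
                    phi=rng.uniform(0, math.pi),
                    rate=rng.uniform(*params.bud_growth_rate_range),
                    mother=m_track,
                    attach_angle=attach,
                    attach_depth=rng.uniform(*params.attach_depth_range),
                )
                cells[next_track] = bud
                volumes[next_track] = [math.nan] * t
                lineage[next_track] = m_track
                current_bud[m_track] = next_track
                next_track += 1

        # keep buds glued to their (growing) mothers
        for c in cells.values():
            if c.role == "bud" and c.mother in cells:
                _place_bud(c, cells[c.mother])

        # --- rasterise and record ---
        masks: List[np.ndarray] = []
        labels: List[int] = []
        pairs: List[Tuple[int, int]] = []
        for c in sorted(cells.values(), key=lambda c: c.track):
            a, b = _cell_axes(c, params.pixel_size)
            cy = float(np.clip(c.centre[0], 1, h - 2))
            cx = float(np.clip(c.centre[1], 1, w - 2))
            c.centre = (cy, cx)
            m = ellipse_mask((h, w), c.centre, a, b, c.phi)
            if not m.any():  # fully clipped out: treat as washed out
                del cells[c.track]
                n_washouts += 1
                continue
            masks.append(m)
            labels.append(c.track)
            if c.role == "bud" and c.mother in cells:
                pairs.append((c.track, c.mother))
        frames.append(AnnotatedFrame(masks=masks, track_labels=labels, mother_pairs=pairs))

        present = set(labels)
        for track, series in volumes.items():
            if track in present:
                series.append(cells[track].volume)
            elif len(series) == t:
                series.append(math.nan)

        images.append(render_brightfield_stack(frames[-1], params, rng=rng))

    true_volumes = {
        tr: np.asarray(v + [math.nan] * (T - len(v)), dtype=float)
        for tr, v in volumes.items()
    }
    return SimulatedMovie(
        params=params,
        frames=frames,
        images=images,
        true_volumes=true_volumes,
        true_cytokinesis=cytokinesis,
        lineage=lineage,
        n_washouts=n_washouts,
    )


# ---------------------------------------------------------------------------
# rendering


def _cell_focal_plane(label: int, params: SimParams) -> float:
    """Deterministic pseudo-random focal plane (um) per track label."""
    span = params.z_spacing * (params.n_z - 1)
    frac = (label * 0.381966) % 1.0  # golden-ratio scatter
    return (frac - 0.5) * span


def render_brightfield_stack(
    frame: AnnotatedFrame, params: SimParams, rng: Optional[np.random.Generator] = None
) -> np.ndarray:
    """Render a schematic bright-field Z-stack of one annotated frame.

    Cells appear as a bright interior with a dark rim; each Z-section blurs
    cells in proportion to their distance from that section's focal plane;
    Gaussian noise of sd ``noise_sd`` is added.  Shape: (n_z, H, W).
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    h, w = params.image_shape
    background = 0.5
    stack = np.full((params.n_z, h, w), background, dtype=np.float64)
    span = params.z_spacing * (params.n_z - 1)
    z_positions = (
        np.linspace(-span / 2, span / 2, params.n_z) if params.n_z > 1 else np.array([0.0])
    )
    for m, label in zip(frame.masks, frame.track_labels):
        rim = m & ~ndimage.binary_erosion(m, structure=np.ones((3, 3)), iterations=2)
        interior = m & ~rim
        focal = _cell_focal_plane(label, params)
        sprite = np.zeros((h, w))
        sprite[interior] = 0.22
        sprite[rim] = -0.30
        for zi, z in enumerate(z_positions):
            sigma = 0.5 + 1.2 * abs(z - focal)
            stack[zi] += ndimage.gaussian_filter(sprite, sigma=sigma)
    if params.noise_sd > 0:
        stack += rng.normal(0.0, params.noise_sd, size=stack.shape)
    return stack.astype(np.float32)


# ---------------------------------------------------------------------------
# persistence


_SCHEMA_VERSION = "1"


def emit_ground_truth(movie: SimulatedMovie, out_dir) -> None:
    """Write a movie and its ground truth to ``out_dir``.

    Layout: ``images.tif`` (T pages of (n_z, H, W)); ``masks_t###.tif``
    per non-empty frame (one page per cell, overlap-safe); ``tracks.csv``
    (time, track, label, mask_page); ``lineage.csv`` (bud_track,
    mother_track, cytokinesis_t; -1 if division not observed);
    ``volumes.csv`` (track, time_min, volume); ``params.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out / "images.tif", np.stack(movie.images),
                     photometric="minisblack",
                     metadata={"axes": "TZYX", "schema": _SCHEMA_VERSION})

    track_rows = []
    for t, frame in enumerate(movie.frames):
        if frame.masks:
            arr = np.stack([m.astype(np.uint8) for m in frame.masks])
            tifffile.imwrite(out / f"masks_t{t:03d}.tif", arr, photometric="minisblack")
        for page, label in enumerate(frame.track_labels):
            track_rows.append({"time": t, "track": label, "label": label, "mask_page": page})
    pd.DataFrame(track_rows, columns=["time", "track", "label", "mask_page"]).to_csv(
        out / "tracks.csv", index=False
    )

    pair_rows = []
    for t, frame in enumerate(movie.frames):
        for bud, mother in frame.mother_pairs:
            pair_rows.append({"time": t, "bud_label": bud, "mother_label": mother})
    pd.DataFrame(pair_rows, columns=["time", "bud_label", "mother_label"]).to_csv(
        out / "mother_pairs.csv", index=False
    )

    lin_rows = [
        {
            "bud_track": b,
            "mother_track": m,
            "cytokinesis_t": movie.true_cytokinesis.get(b, -1),
        }
        for b, m in sorted(movie.lineage.items())
    ]
    pd.DataFrame(lin_rows, columns=["bud_track", "mother_track", "cytokinesis_t"]).to_csv(
        out / "lineage.csv", index=False
    )

    vol_rows = []
    dt = movie.params.sampling_interval
    for track in sorted(movie.true_volumes):
        v = movie.true_volumes[track]
        for t in np.flatnonzero(~np.isnan(v)):
            vol_rows.append({"track": track, "time_min": t * dt, "volume": v[t]})
    pd.DataFrame(vol_rows, columns=["track", "time_min", "volume"]).to_csv(
        out / "volumes.csv", index=False
    )

    meta = dataclasses.asdict(movie.params)
    meta["schema"] = _SCHEMA_VERSION
    meta["n_washouts"] = movie.n_washouts
    (out / "params.json").write_text(json.dumps(meta, indent=2))


def load_ground_truth(out_dir) -> SimulatedMovie:
    """Reload a movie written by :func:`emit_ground_truth` (lossless)."""
    out = Path(out_dir)
    meta = json.loads((out / "params.json").read_text())
    n_washouts = meta.pop("n_washouts", 0)
    meta.pop("schema", None)
    for key in ("image_shape", "mother_radius_range", "bud_growth_rate_range",
                "attach_depth_range", "bud_delay_frames", "bud_initial_volume_range"):
        meta[key] = tuple(meta[key])
    params = SimParams(**meta)

    images_arr = tifffile.imread(out / "images.tif")
    if images_arr.ndim == 3:  # single time point collapses
        images_arr = images_arr[None]
    images = [images_arr[t] for t in range(images_arr.shape[0])]
    T = len(images)

    tracks = pd.read_csv(out / "tracks.csv")
    pairs = pd.read_csv(out / "mother_pairs.csv")
    frames = []
    for t in range(T):
        sub = tracks[tracks["time"] == t].sort_values("mask_page")
        masks: List[np.ndarray] = []
        labels: List[int] = []
        if len(sub):
            arr = tifffile.imread(out / f"masks_t{t:03d}.tif")
            if arr.ndim == 2:
                arr = arr[None]
            for _, row in sub.iterrows():
                masks.append(arr[int(row["mask_page"])].astype(bool))
                labels.append(int(row["track"]))
        psub = pairs[pairs["time"] == t]
        mp = [(int(r["bud_label"]), int(r["mother_label"])) for _, r in psub.iterrows()]
        frames.append(AnnotatedFrame(masks=masks, track_labels=labels, mother_pairs=mp))

    lin = pd.read_csv(out / "lineage.csv")
    lineage = {int(r["bud_track"]): int(r["mother_track"]) for _, r in lin.iterrows()}
    cytokinesis = {
        int(r["bud_track"]): int(r["cytokinesis_t"])
        for _, r in lin.iterrows()
        if int(r["cytokinesis_t"]) >= 0
    }

    vols = pd.read_csv(out / "volumes.csv")
    true_volumes: Dict[int, np.ndarray] = {}
    dt = params.sampling_interval
    for track, sub in vols.groupby("track"):
        series = np.full(T, np.nan)
        idx = np.round(sub["time_min"].to_numpy() / dt).astype(int)
        series[idx] = sub["volume"].to_numpy()
        true_volumes[int(track)] = series
    for tr in set(lineage) | {l for f in frames for l in f.track_labels}:
        true_volumes.setdefault(int(tr), np.full(T, np.nan))

    return SimulatedMovie(
        params=params,
        frames=frames,
        images=images,
        true_volumes=true_volumes,
        true_cytokinesis=cytokinesis,
        lineage=lineage,
        n_washouts=n_washouts,
    )


def mean_pairwise_overlap(movie: SimulatedMovie) -> float:
    """Mean per-frame total pairwise mask-overlap area (px^2)."""
    totals = []
    for frame in movie.frames:
        total = 0
        for i in range(len(frame.masks)):
            for j in range(i + 1, len(frame.masks)):
                total += int((frame.masks[i] & frame.masks[j]).sum())
        totals.append(total)
    return float(np.mean(totals)) if totals else 0.0
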