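"""Multi-target semantic maps from annotated (overlapping) cell masks.

The instance-recovery strategy rests on size stratification: cells are
split into small/medium/large categories so that cells overlapping in the
image rarely share a category, and each category's interiors are eroded so
that touching instances separate into distinct seeds.  The fixed 8-channel
target stack is::

    [interior_S, interior_M, interior_L, edge_S, edge_M, edge_L,
     overlap, budneck]

Interiors are per-cell morphological erosions (disc element, per-category
depth, reduced per cell until a minimum seed area survives); edges are the
un-eroded 8-connected outlines; the overlap channel is the union of all
pairwise mask intersections; the bud-neck channel marks the mother-bud
interface for each annotated pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence, Tuple

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from .simulate import AnnotatedFrame


def erosion_element(depth: int) -> np.ndarray:
    """Disc structuring element of radius ``depth``.

    Depth 1 uses the full 3x3 square so that a single erosion step removes
    every 8-connected boundary pixel (skimage's radius-1 disc is the
    4-neighbour cross, which leaves diagonal boundary pixels behind).
    """
    return np.ones((3, 3), dtype=bool) if depth == 1 else disk(depth).astype(bool)

CATEGORIES = ("S", "M", "L")

CHANNEL_NAMES = (
    "interior_S",
    "interior_M",
    "interior_L",
    "edge_S",
    "edge_M",
    "edge_L",
    "overlap",
    "budneck",
)


@dataclass
class SizeCategorySpec:
    """Size-category boundaries and per-category erosion depths.

    ``boundaries`` are two strictly increasing area thresholds (px^2)
    splitting cells into S/M/L by half-open intervals [0,b1), [b1,b2),
    [b2,inf).  ``erosion_depth`` maps category -> disc radius used to erode
    its interiors (and later to reverse the erosion); ``min_seed_area`` is
    the smallest interior a cell may be eroded down to.
    """

    boundaries: Tuple[float, float] = (120.0, 400.0)
    erosion_depth: dict = field(default_factory=lambda: {"S": 1, "M": 2, "L": 3})
    min_seed_area: int = 5

    def __post_init__(self) -> None:
        b1, b2 = self.boundaries
        if not b1 < b2:
            raise ValueError("boundaries must be strictly increasing")
        if any(d < 0 for d in self.erosion_depth.values()):
            raise ValueError("erosion_depth must be >= 0")
        if self.min_seed_area < 1:
            raise ValueError("min_seed_area must be >= 1")


def assign_size_category(mask: np.ndarray, spec: SizeCategorySpec) -> str:
    """Category of a cell by its full (un-eroded) mask area."""
    area = int(np.count_nonzero(mask))
    if area == 0:
        raise ValueError("empty mask has no size category")
    b1, b2 = spec.boundaries
    if area < b1:
        return "S"
    if area < b2:
        return "M"
    return "L"


def _pairwise_overlaps(frames: Iterable[AnnotatedFrame]):
    """Yield (area_i, area_j, overlap_px) for each overlapping cell pair."""
    for frame in frames:
        areas = [int(m.sum()) for m in frame.masks]
        for i, j in combinations(range(len(frame.masks)), 2):
            ov = int((frame.masks[i] & frame.masks[j]).sum())
            if ov:
                yield areas[i], areas[j], ov


def optimize_size_boundaries(
    frames: Sequence[AnnotatedFrame],
    n_categories: int = 3,
    n_quantiles: int = 20,
) -> SizeCategorySpec:
    """Choose category boundaries minimising within-category overlap.

    Candidate boundaries are area quantiles over all cells; all ordered
    pairs of candidates are searched exhaustively for the pair minimising
    the total overlap area between same-category cells.  Ties are broken
    by proximity to the area terciles, making the result deterministic.
    """
    if n_categories != 3:
        raise NotImplementedError("three size categories are supported")
    areas = np.array(
        [int(m.sum()) for frame in frames for m in frame.masks], dtype=float
    )
    if areas.size < 2:
        raise ValueError("need at least two cells to optimise boundaries")
    terciles = np.quantile(areas, [1 / 3, 2 / 3])
    if np.ptp(areas) == 0:
        # all cells identical: fall back to quantile defaults around the area
        a = areas[0]
        return SizeCategorySpec(boundaries=(a * 0.99 + 0.5, a * 1.01 + 1.5))

    qs = np.quantile(areas, np.linspace(0.05, 0.95, n_quantiles))
    candidates = np.unique(qs)
    overlaps = list(_pairwise_overlaps(frames))

    def objective(b1: float, b2: float) -> float:
        total = 0.0
        for a_i, a_j, ov in overlaps:
            ci = 0 if a_i < b1 else (1 if a_i < b2 else 2)
            cj = 0 if a_j < b1 else (1 if a_j < b2 else 2)
            if ci == cj:
                total += ov
        return total

    best = None
    for i, b1 in enumerate(candidates):
        for b2 in candidates[i + 1 :]:
            obj = objective(b1, b2)
            tie = abs(b1 - terciles[0]) + abs(b2 - terciles[1])
            key = (obj, tie, b1, b2)
            if best is None or key < best:
                best = key
    assert best is not None
    return SizeCategorySpec(boundaries=(float(best[2]), float(best[3])))


def _erode_with_floor(mask: np.ndarray, depth: int, min_area: int) -> np.ndarray:
    """Erode by a disc of radius ``depth``, backing off until ``min_area``."""
    d = depth
    while d > 0:
        eroded = ndimage.binary_erosion(mask, structure=erosion_element(d))
        if eroded.sum() >= min_area:
            return eroded
        d -= 1
    return mask.copy()


def outline(mask: np.ndarray) -> np.ndarray:
    """8-connected boundary: mask pixels with any background 8-neighbour."""
    return mask & ~ndimage.binary_erosion(mask, structure=np.ones((3, 3)))


def make_interior_edge_targets(
    frame: AnnotatedFrame, spec: SizeCategorySpec
) -> np.ndarray:
    """The six interior/edge channels (order: interiors S,M,L then edges)."""
    h, w = frame.shape if frame.masks else (0, 0)
    if not frame.masks:
        raise ValueError("frame has no masks; use build_target_stack for empties")
    out = np.zeros((6, h, w), dtype=bool)
    for mask in frame.masks:
        cat = assign_size_category(mask, spec)
        ci = CATEGORIES.index(cat)
        out[ci] |= _erode_with_floor(mask, spec.erosion_depth[cat], spec.min_seed_area)
        out[3 + ci] |= outline(mask)
    return out


def make_overlap_target(frame: AnnotatedFrame) -> np.ndarray:
    """Union over all unordered cell pairs of their mask intersections."""
    h, w = frame.shape
    out = np.zeros((h, w), dtype=bool)
    for i, j in combinations(range(len(frame.masks)), 2):
        out |= frame.masks[i] & frame.masks[j]
    return out


def budneck_region(bud: np.ndarray, mother: np.ndarray, width: int = 3) -> np.ndarray:
    """The neck band at the bud-mother interface.

    The contact zone is the set of pixels within one pixel of both masks;
    the neck is a band of half-width ``width`` pixels around the contact
    zone's centroid, restricted to pixels within ``width`` px of both
    masks.  Returns an all-false map for cells that do not touch.
    """
    grow = np.ones((3, 3))
    contact = ndimage.binary_dilation(bud, grow) & ndimage.binary_dilation(mother, grow)
    if not contact.any():
        return np.zeros_like(bud)
    cy, cx = ndimage.center_of_mass(contact)
    h, w = bud.shape
    yy, xx = np.mgrid[0:h, 0:w]
    near_mid = (yy - cy) ** 2 + (xx - cx) ** 2 <= (width + 1) ** 2
    d_bud = ndimage.distance_transform_edt(~bud)
    d_mother = ndimage.distance_transform_edt(~mother)
    return near_mid & (d_bud <= width) & (d_mother <= width)


def make_budneck_target(frame: AnnotatedFrame, width: int = 3) -> np.ndarray:
    """Union of neck bands over all annotated mother-bud pairs."""
    h, w = frame.shape
    out = np.zeros((h, w), dtype=bool)
    labels = frame.track_labels
    for bud_label, mother_label in frame.mother_pairs:
        if bud_label not in labels or mother_label not in labels:
            raise ValueError(f"pair ({bud_label},{mother_label}) references missing label")
        out |= budneck_region(frame.mask_of(bud_label), frame.mask_of(mother_label), width)
    return out


def build_target_stack(
    frame: AnnotatedFrame,
    spec: SizeCategorySpec,
    shape: Tuple[int, int] | None = None,
) -> np.ndarray:
    """The fixed 8-channel semantic target stack for one frame.

    ``shape`` is required only for frames with no cells (where it cannot
    be inferred from the masks).
    """
    if not frame.masks:
        if shape is None:
            raise ValueError("shape required for an empty frame")
        return np.zeros((8, *shape), dtype=bool)
    h, w = frame.shape
    stack = np.zeros((8, h, w), dtype=bool)
    stack[:6] = make_interior_edge_targets(frame, spec)
    stack[6] = make_overlap_target(frame)
    stack[7] = make_budneck_target(frame)
    return stack
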