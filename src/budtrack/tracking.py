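"""Classifier-based cell tracking and mother-bud lineage assignment.

Tracking links segmented instances across time with a pairwise classifier
that predicts whether two outlines, one from the previous time point and
one from the current, are the same cell.  Two gradient-boosted classifiers
are trained: A uses only morphological features (robust to cells pivoting
about their mothers), B augments them with the centroid distance (sharper
when cells stay put).  A is consulted first; when its verdict is
ambiguous the decision defers to B.  Per-track predictions are aggregated
over the last three time points to ride out transient segmentation
errors, and the frame-level assignment is the optimal one-to-one matching
over pair probabilities.

Lineage assignment scores every ordered (mother, bud) pair per frame with
a third classifier that combines morphology with bud-neck evidence from
the semantic maps, accumulates those probabilities over time, and assigns
each bud to the candidate with the highest accumulated probability --
requiring at least three jointly observed time points before committing.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from scipy.optimize import linear_sum_assignment
from skimage.measure import regionprops

from .segment import SegmentedInstance, mask_iou
from .simulate import AnnotatedFrame, SimulatedMovie
from .targets import CATEGORIES

DEFAULT_MIN_JOINT_FRAMES = 3  # a mother and bud must co-occur this often


@dataclass
class MorphFeatures:
    """Morphological characteristics of one segmented outline."""

    area: float
    perimeter: float
    major_axis: float
    minor_axis: float
    eccentricity: float
    centroid: Tuple[float, float]
    radius_mean: float
    radius_sd: float
    category: int  # index into CATEGORIES

    def vector(self) -> np.ndarray:
        return np.array(
            [
                self.area,
                self.perimeter,
                self.major_axis,
                self.minor_axis,
                self.eccentricity,
                self.radius_mean,
                self.radius_sd,
                float(self.category),
            ]
        )


def extract_morph_features(
    mask: np.ndarray,
    spline_radii: Optional[np.ndarray] = None,
    category: str = "M",
) -> MorphFeatures:
    """Deterministic shape features of a binary mask.

    Radius statistics come from the radial spline when available,
    otherwise from boundary-pixel distances about the centroid.
    """
    if not mask.any():
        raise ValueError("empty mask has no morphology")
    props = regionprops(mask.astype(np.uint8))[0]
    if spline_radii is not None and len(spline_radii) > 0:
        radii = np.asarray(spline_radii, dtype=float)
    else:
        from .targets import outline

        cy, cx = props.centroid
        ys, xs = np.nonzero(outline(mask))
        radii = np.hypot(ys - cy, xs - cx)
    return MorphFeatures(
        area=float(props.area),
        perimeter=float(max(props.perimeter, 1.0)),
        major_axis=float(max(props.axis_major_length, 1.0)),
        minor_axis=float(max(props.axis_minor_length, 1.0)),
        eccentricity=float(props.eccentricity),
        centroid=(float(props.centroid[0]), float(props.centroid[1])),
        radius_mean=float(radii.mean()) if radii.size else 1.0,
        radius_sd=float(radii.std()) if radii.size else 0.0,
        category=CATEGORIES.index(category) if category in CATEGORIES else 1,
    )


def features_of_instance(inst: SegmentedInstance) -> MorphFeatures:
    return extract_morph_features(inst.mask, inst.spline.knot_radii, inst.category)


def pair_features(
    a: MorphFeatures,
    b: MorphFeatures,
    iou: float,
    with_distance: bool,
    gap: int = 1,
) -> np.ndarray:
    """Feature vector describing how two outlines relate.

    Absolute differences and signed log-ratios (first -> second, so that
    plausible growth and implausible shrinkage are distinguishable) of
    the scalar morphologies plus the mask IoU; variant B appends the
    centroid distance.  Difference features are divided by ``gap`` (the
    number of frames between the two observations), turning them into
    per-frame rates, so the same classifier serves comparisons against
    each of the last three time points.
    """
    eps = 1e-6
    gap = max(int(gap), 1)
    scalars_a = np.array([a.area, a.perimeter, a.major_axis, a.minor_axis, a.radius_mean])
    scalars_b = np.array([b.area, b.perimeter, b.major_axis, b.minor_axis, b.radius_mean])
    feats = [
        np.abs(scalars_a - scalars_b) / gap,
        (np.log(scalars_b + eps) - np.log(scalars_a + eps)) / gap,
        [abs(a.eccentricity - b.eccentricity) / gap],
        [abs(a.radius_sd - b.radius_sd) / gap],
        [float(a.category == b.category)],
        [iou],
        # size context: growth tolerances are strongly size-dependent (a
        # young bud doubles in a few frames, a mother barely changes)
        [0.5 * (math.log(a.area + eps) + math.log(b.area + eps))],
        [0.5 * (a.eccentricity + b.eccentricity)],
    ]
    if with_distance:
        d = math.hypot(a.centroid[0] - b.centroid[0], a.centroid[1] - b.centroid[1])
        feats.append([d / gap])
    return np.concatenate([np.asarray(f, dtype=float).ravel() for f in feats])


# ---------------------------------------------------------------------------
# classifiers


@dataclass
class TrackClassifiers:
    """The two tracking classifiers (A: morphology only; B: + distance)."""

    clf_a: object
    clf_b: object
    ambiguity_low: float = 0.25
    ambiguity_high: float = 0.75

    def probability(self, xa: np.ndarray, xb: np.ndarray) -> np.ndarray:
        pa = self.clf_a.predict_proba(np.atleast_2d(xa))[:, 1]
        pb = self.clf_b.predict_proba(np.atleast_2d(xb))[:, 1]
        ambiguous = (pa >= self.ambiguity_low) & (pa <= self.ambiguity_high)
        return np.where(ambiguous, pb, pa)


def _make_gbm(seed: int):
    from sklearn.ensemble import GradientBoostingClassifier

    return GradientBoostingClassifier(
        n_estimators=100, max_depth=3, learning_rate=0.1, random_state=seed
    )


def train_track_classifiers(
    features_a: np.ndarray,
    features_b: np.ndarray,
    labels: np.ndarray,
    seed: int = 0,
) -> TrackClassifiers:
    """Fit classifiers A and B on labelled same/different outline pairs."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("need both same-cell and different-cell pairs")
    clf_a = _make_gbm(seed).fit(np.asarray(features_a), labels)
    clf_b = _make_gbm(seed + 1).fit(np.asarray(features_b), labels)
    return TrackClassifiers(clf_a=clf_a, clf_b=clf_b)


def track_probability(
    prev: MorphFeatures,
    curr: MorphFeatures,
    classifiers: TrackClassifiers,
    iou: float = 0.0,
) -> float:
    """P(same cell) for one pair, with the ambiguity-deferral rule."""
    xa = pair_features(prev, curr, iou, with_distance=False)
    xb = pair_features(prev, curr, iou, with_distance=True)
    return float(classifiers.probability(xa, xb)[0])


def build_tracking_training_set(
    movies: Iterable[SimulatedMovie],
    max_pairs_per_frame: int = 200,
    seed: int = 0,
    rotation_augment: int = 3,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Labelled outline pairs from ground-truth movies.

    Every (cell at t-gap, cell at t) combination at gaps 1-3 is a sample;
    the label says whether the two outlines share a track.  Every
    ``rotation_augment``-th frame additionally contributes pairs against
    a rigidly rotated copy of itself, so the classifiers learn that a
    displaced outline with unchanged morphology is the same cell -- the
    situation colonies produce when they pivot under the medium flow.
    """
    rng = np.random.default_rng(seed)
    xa, xb, ys = [], [], []

    def _add_rotation_pairs(frame: AnnotatedFrame) -> None:
        ang = float(rng.uniform(10.0, 45.0)) * float(rng.choice([-1.0, 1.0]))
        dy, dx = rng.integers(-12, 13, size=2)
        rot = [
            np.roll(
                ndimage.rotate(m.astype(np.uint8), ang, reshape=False, order=0),
                (dy, dx),
                axis=(0, 1),
            ).astype(bool)
            for m in frame.masks
        ]
        keep = [k for k, m in enumerate(rot) if m.any()]
        orig_feats = [extract_morph_features(frame.masks[k]) for k in keep]
        rot_feats = [extract_morph_features(rot[k]) for k in keep]
        for i, ki in enumerate(keep):
            for j, kj in enumerate(keep):
                iou = mask_iou(frame.masks[ki], rot[kj])
                xa.append(pair_features(orig_feats[i], rot_feats[j], iou, False))
                xb.append(pair_features(orig_feats[i], rot_feats[j], iou, True))
                ys.append(int(ki == kj))
    for movie in movies:
        feats_by_t = [
            [(lab, extract_morph_features(m)) for m, lab in zip(f.masks, f.track_labels)]
            for f in movie.frames
        ]
        for t in range(1, movie.n_timepoints):
            curr_f = movie.frames[t]
            curr = feats_by_t[t]
            if rotation_augment and t % rotation_augment == 0 and curr_f.masks:
                _add_rotation_pairs(curr_f)
            for gap in (1, 2, 3):
                if t - gap < 0:
                    continue
                prev_f = movie.frames[t - gap]
                prev = feats_by_t[t - gap]
                combos = [(i, j) for i in range(len(prev)) for j in range(len(curr))]
                if len(combos) > max_pairs_per_frame:
                    idx = rng.choice(len(combos), size=max_pairs_per_frame, replace=False)
                    combos = [combos[k] for k in idx]
                for i, j in combos:
                    iou = mask_iou(prev_f.masks[i], curr_f.masks[j])
                    xa.append(pair_features(prev[i][1], curr[j][1], iou, False, gap=gap))
                    xb.append(pair_features(prev[i][1], curr[j][1], iou, True, gap=gap))
                    ys.append(int(prev[i][0] == curr[j][0]))
    return np.asarray(xa), np.asarray(xb), np.asarray(ys)


# ---------------------------------------------------------------------------
# frame-to-frame tracking


@dataclass
class TrackState:
    """Ring buffer of a track's recent observations (last 3 time points)."""

    track_id: int
    buffer: deque = field(default_factory=lambda: deque(maxlen=3))
    missed: int = 0
    active: bool = True

    def observe(self, t: int, feats: MorphFeatures, mask: np.ndarray) -> None:
        self.buffer.append((t, feats, mask))
        self.missed = 0


class Tracker:
    """Stateful frame-by-frame tracker."""

    def __init__(
        self,
        classifiers: TrackClassifiers,
        p_min: float = 0.3,
        lost_patience: int = 2,
        p_floor: float = 0.005,
        dominance: float = 8.0,
    ):
        self.classifiers = classifiers
        self.p_min = p_min
        self.lost_patience = lost_patience
        self.p_floor = p_floor
        self.dominance = dominance
        self.states: Dict[int, TrackState] = {}
        self._next_track = 1
        self._t = -1

    @property
    def active_tracks(self) -> List[TrackState]:
        return [s for s in self.states.values() if s.active]

    def step(
        self,
        masks: Sequence[np.ndarray],
        features: Optional[Sequence[MorphFeatures]] = None,
    ) -> List[int]:
        """Assign a track label to each current mask; returns the labels.

        Pair probabilities against each active track are averaged over the
        track's (up to three) buffered time points, then a one-to-one
        assignment maximising total probability is taken among pairs with
        p >= p_min.  Unmatched masks open new tracks; tracks unmatched for
        more than ``lost_patience`` frames are closed.
        """
        self._t += 1
        if features is None:
            features = [extract_morph_features(m) for m in masks]
        active = self.active_tracks
        n_cur, n_trk = len(masks), len(active)
        labels = [-1] * n_cur
        if n_cur and n_trk:
            prob = np.zeros((n_trk, n_cur))
            for ti, state in enumerate(active):
                xa_rows, xb_rows, counts = [], [], []
                for ci in range(n_cur):
                    ps_a, ps_b = [], []
                    for (t_obs, f_prev, m_prev) in state.buffer:
                        gap = self._t - t_obs
                        iou = mask_iou(m_prev, masks[ci]) if (m_prev | masks[ci]).any() else 0.0
                        ps_a.append(pair_features(f_prev, features[ci], iou, False, gap=gap))
                        ps_b.append(pair_features(f_prev, features[ci], iou, True, gap=gap))
                    xa_rows.append(ps_a)
                    xb_rows.append(ps_b)
                flat_a = np.array([p for row in xa_rows for p in row])
                flat_b = np.array([p for row in xb_rows for p in row])
                flat_p = self.classifiers.probability(flat_a, flat_b)
                k = 0
                for ci in range(n_cur):
                    m = len(xa_rows[ci])
                    prob[ti, ci] = flat_p[k : k + m].mean() if m else 0.0
                    k += m
            cost = -np.log(np.clip(prob, 1e-9, 1.0))
            rows, cols = linear_sum_assignment(cost)
            matched_tracks = set()
            # Accept assignments in descending probability.  A pairing is
            # accepted when it is confident outright (p >= p_min) or when
            # it dominates every *still-available* alternative for both
            # the track and the instance (likelihood-ratio acceptance,
            # which rescues poorly calibrated but unambiguous links).
            order = sorted(zip(rows, cols), key=lambda rc: -prob[rc[0], rc[1]])
            taken_r, taken_c = set(), set()
            for r, c in order:
                row_alt = max(
                    (prob[r, cc] for cc in range(n_cur) if cc != c and cc not in taken_c),
                    default=0.0,
                )
                col_alt = max(
                    (prob[rr, c] for rr in range(n_trk) if rr != r and rr not in taken_r),
                    default=0.0,
                )
                # dominance acceptance only continues tracks seen in the
                # previous frame: resurrecting a lost track on weak
                # absolute evidence too easily hijacks a later new bud
                dominant = (
                    active[r].missed == 0
                    and prob[r, c] >= self.p_floor
                    and prob[r, c] >= self.dominance * row_alt
                    and prob[r, c] >= self.dominance * col_alt
                )
                if prob[r, c] >= self.p_min or dominant:
                    taken_r.add(r)
                    taken_c.add(c)
                    state = active[r]
                    labels[c] = state.track_id
                    state.observe(self._t, features[c], masks[c])
                    matched_tracks.add(state.track_id)
            for state in active:
                if state.track_id not in matched_tracks:
                    state.missed += 1
                    if state.missed > self.lost_patience:
                        state.active = False
        elif n_trk:
            for state in active:
                state.missed += 1
                if state.missed > self.lost_patience:
                    state.active = False
        for ci in range(n_cur):
            if labels[ci] == -1:
                tid = self._next_track
                self._next_track += 1
                st = TrackState(track_id=tid)
                st.observe(self._t, features[ci], masks[ci])
                self.states[tid] = st
                labels[ci] = tid
        return labels


# ---------------------------------------------------------------------------
# mother-bud lineage


def budneck_evidence(
    mother_mask: np.ndarray,
    bud_mask: np.ndarray,
    budneck_channel: np.ndarray,
    dilation: int = 3,
) -> float:
    """Fraction of bud-neck probability mass near the two masks' contact zone."""
    total = float(budneck_channel.sum())
    if total <= 0:
        return 0.0
    grow = np.ones((3, 3))
    contact = ndimage.binary_dilation(mother_mask, grow) & ndimage.binary_dilation(
        bud_mask, grow
    )
    if not contact.any():
        return 0.0
    zone = ndimage.binary_dilation(contact, grow, iterations=dilation)
    return float(budneck_channel[zone].sum() / total)


def mother_bud_features(
    mother: MorphFeatures,
    bud: MorphFeatures,
    iou: float,
    neck_evidence: float,
) -> np.ndarray:
    base = pair_features(mother, bud, iou, with_distance=True)
    size_ratio = mother.area / max(bud.area, 1.0)
    return np.concatenate([base, [neck_evidence, size_ratio]])


def train_mother_bud_classifier(
    movies: Iterable[SimulatedMovie],
    budneck_channels: Optional[Dict[int, Sequence[np.ndarray]]] = None,
    seed: int = 0,
):
    """Fit the mother-bud pair classifier on ground-truth movies.

    ``budneck_channels`` maps movie index -> per-frame neck maps (e.g.
    oracle targets); without them the neck evidence is zero and ordering
    relies on morphology alone.
    """
    from .targets import make_budneck_target

    xs, ys = [], []
    for mi, movie in enumerate(movies):
        for t, frame in enumerate(movie.frames):
            if len(frame.masks) < 2:
                continue
            if budneck_channels is not None and mi in budneck_channels:
                neck = np.asarray(budneck_channels[mi][t], dtype=float)
            else:
                neck = make_budneck_target(frame).astype(float)
            feats = [extract_morph_features(m) for m in frame.masks]
            truth = set(frame.mother_pairs)
            labels = frame.track_labels
            for i in range(len(frame.masks)):
                for j in range(len(frame.masks)):
                    if i == j:
                        continue
                    iou = mask_iou(frame.masks[i], frame.masks[j])
                    ev = budneck_evidence(frame.masks[i], frame.masks[j], neck)
                    xs.append(mother_bud_features(feats[i], feats[j], iou, ev))
                    ys.append(int((labels[j], labels[i]) in truth))  # (bud, mother)
    ys = np.asarray(ys)
    if len(np.unique(ys)) < 2:
        raise ValueError("need positive and negative mother-bud pairs")
    return _make_gbm(seed + 7).fit(np.asarray(xs), ys)


def mother_bud_probability(
    mother_mask: np.ndarray,
    bud_mask: np.ndarray,
    budneck_channel: np.ndarray,
    classifier,
    mother_feats: Optional[MorphFeatures] = None,
    bud_feats: Optional[MorphFeatures] = None,
) -> float:
    """P(the ordered pair is mother and bud) for one candidate pair."""
    mf = mother_feats or extract_morph_features(mother_mask)
    bf = bud_feats or extract_morph_features(bud_mask)
    iou = mask_iou(mother_mask, bud_mask) if (mother_mask | bud_mask).any() else 0.0
    ev = budneck_evidence(mother_mask, bud_mask, budneck_channel)
    x = mother_bud_features(mf, bf, iou, ev)
    return float(classifier.predict_proba(x[None])[:, 1][0])


class LineageLedger:
    """Accumulated mother-bud pairing probabilities over time."""

    def __init__(self) -> None:
        self.sums: Dict[Tuple[int, int], float] = {}
        self.counts: Dict[Tuple[int, int], int] = {}

    def update(self, frame_pairs: Iterable[Tuple[int, int, float]]) -> None:
        """Add per-frame (mother_track, bud_track, p_pair) observations."""
        for mother, bud, p in frame_pairs:
            key = (mother, bud)
            self.sums[key] = self.sums.get(key, 0.0) + float(p)
            self.counts[key] = self.counts.get(key, 0) + 1

    def assign_mothers(
        self, min_joint_frames: int = DEFAULT_MIN_JOINT_FRAMES
    ) -> Dict[int, int]:
        """Assign each bud to the candidate with highest accumulated probability.

        Candidates observed jointly with the bud for fewer than
        ``min_joint_frames`` time points never qualify; ties break by
        higher mean probability, then lower mother track id.
        """
        buds: Dict[int, List[Tuple[float, float, int]]] = {}
        for (mother, bud), total in self.sums.items():
            n = self.counts[(mother, bud)]
            if n >= min_joint_frames:
                buds.setdefault(bud, []).append((total, total / n, -mother))
        out: Dict[int, int] = {}
        for bud, cands in buds.items():
            total, mean_p, neg_mother = max(cands)
            out[bud] = -neg_mother
        return out


def update_lineage(
    ledger: LineageLedger, frame_pairs: Iterable[Tuple[int, int, float]]
) -> LineageLedger:
    ledger.update(frame_pairs)
    return ledger


def candidate_pairs_for_frame(
    masks: Sequence[np.ndarray],
    track_labels: Sequence[int],
    budneck_channel: np.ndarray,
    classifier,
    max_centroid_distance: float = 40.0,
    p_floor: float = 0.05,
) -> List[Tuple[int, int, float]]:
    """Score all ordered (mother, bud) candidates in one frame.

    The larger cell of each nearby pair is the mother candidate; pairs
    whose probability falls below ``p_floor`` are not recorded.
    """
    feats = [extract_morph_features(m) for m in masks]
    out: List[Tuple[int, int, float]] = []
    for i in range(len(masks)):
        for j in range(len(masks)):
            if i == j or feats[i].area <= feats[j].area:
                continue
            d = math.hypot(
                feats[i].centroid[0] - feats[j].centroid[0],
                feats[i].centroid[1] - feats[j].centroid[1],
            )
            if d > max_centroid_distance:
                continue
            p = mother_bud_probability(
                masks[i], masks[j], budneck_channel, classifier, feats[i], feats[j]
            )
            if p >= p_floor:
                out.append((track_labels[i], track_labels[j], p))
    return out
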