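import itertools

import numpy as np
import pytest

from budtrack.metrics import (
    MatchTable,
    average_precision,
    fraction_complete_tracks,
    frame_label_maps,
    growth_rmse,
    lineage_precision_recall,
    mask_iou,
    match_masks,
    match_masks_exhaustive,
    match_tracks,
    mota,
)
from budtrack.simulate import ellipse_mask


def rect(shape, y0, x0, h, w):
    m = np.zeros(shape, bool)
    m[y0 : y0 + h, x0 : x0 + w] = True
    return m


class TestMaskIoU:
    def test_identical_is_one(self):
        m = rect((16, 16), 2, 2, 5, 5)
        assert mask_iou(m, m) == 1.0

    def test_disjoint_is_zero(self):
        assert mask_iou(rect((16, 16), 0, 0, 4, 4), rect((16, 16), 10, 10, 4, 4)) == 0.0

    def test_half_overlapping_squares(self):
        a = rect((32, 32), 5, 5, 10, 10)
        b = rect((32, 32), 5, 10, 10, 10)
        assert mask_iou(a, b) == pytest.approx(50 / 150)

    def test_both_empty_rejected(self):
        with pytest.raises(ValueError):
            mask_iou(np.zeros((4, 4), bool), np.zeros((4, 4), bool))


class TestMatchMasks:
    def test_identity_matching(self):
        masks = [rect((32, 32), 2, 2, 5, 5), rect((32, 32), 20, 20, 6, 6)]
        table = match_masks(masks, masks)
        assert len(table.pairs) == 2
        assert all(v == 1.0 for _, _, v in table.pairs)
        assert not table.unmatched_preds and not table.unmatched_truths

    def test_extra_prediction_left_unmatched(self):
        truth = [rect((32, 32), 2, 2, 5, 5)]
        preds = truth + [rect((32, 32), 20, 20, 5, 5)]
        table = match_masks(preds, truth)
        assert len(table.pairs) == 1
        assert table.unmatched_preds == [1]

    def test_greedy_vs_exhaustive_on_random_instances(self):
        rng = np.random.default_rng(0)
        n_equal = 0
        for _ in range(20):
            k = int(rng.integers(2, 5))
            preds = [
                rect((24, 24), rng.integers(0, 12), rng.integers(0, 12), 8, 8)
                for _ in range(k)
            ]
            truths = [
                rect((24, 24), rng.integers(0, 12), rng.integers(0, 12), 8, 8)
                for _ in range(k)
            ]
            greedy = sum(v for _, _, v in match_masks(preds, truths).pairs)
            optimal = match_masks_exhaustive(preds, truths)
            assert greedy <= optimal + 1e-9
            n_equal += abs(greedy - optimal) < 1e-9
        assert n_equal >= 15  # greedy nearly always attains the optimum here


class TestAveragePrecision:
    def test_perfect_predictions(self):
        table = MatchTable(pairs=[(0, 0, 1.0), (1, 1, 1.0)], unmatched_preds=[],
                           unmatched_truths=[])
        assert average_precision(table) == pytest.approx(1.0)

    def test_no_predictions(self):
        table = MatchTable(pairs=[], unmatched_preds=[], unmatched_truths=[0, 1])
        assert average_precision(table) == 0.0

    def test_half_recall_hand_computed(self):
        # two truths, one perfect prediction: precision 1, recall 0.5 at
        # every threshold; trapezoid area over [0, 0.5] at precision 1
        table = MatchTable(pairs=[(0, 0, 1.0)], unmatched_preds=[], unmatched_truths=[1])
        assert average_precision(table) == pytest.approx(0.5)

    def test_no_truths_rejected(self):
        with pytest.raises(ValueError):
            average_precision(MatchTable(pairs=[], unmatched_preds=[0], unmatched_truths=[]))


def _track_frames(labels_per_frame, positions):
    """Build per-frame (masks, labels) with 3x3 masks at integer positions."""
    frames = []
    for labels in labels_per_frame:
        masks = [rect((48, 48), *positions[lab], 3, 3) for lab in labels]
        frames.append((masks, list(labels)))
    return frames


POS = {k: (3 + 5 * (k % 8), 3 + 5 * (k // 8)) for k in range(40)}


class TestTrackMetrics:
    def test_identical_tracks_score_one(self):
        truth = _track_frames([[1, 2]] * 10, POS)
        mapping, lookup = match_tracks(truth, truth)
        assert mapping == {1: 1, 2: 2}
        assert all(v == 1.0 for v in lookup.values())
        assert fraction_complete_tracks(truth, truth) == 1.0

    def test_half_covering_track(self):
        truth = _track_frames([[1]] * 10, POS)
        pred = _track_frames([[1]] * 5 + [[2]] * 5, POS)
        _, lookup = match_tracks(pred, truth)
        assert lookup[(1, 1)] == pytest.approx(0.5)

    def test_splitting_penalised_as_one_over_k(self):
        truth = _track_frames([[1]] * 12, POS)
        for k in (2, 3):
            per = 12 // k
            labels = []
            for piece in range(k):
                labels += [[10 + piece]] * per
            pred = _track_frames(labels, POS | {10 + p: POS[1] for p in range(k)})
            mapping, lookup = match_tracks(pred, truth)
            best = max(v for (p, q), v in lookup.items() if q == 1)
            assert best == pytest.approx(1.0 / k)

    def test_split_tracks_incomplete_at_small_tolerance(self):
        truth = _track_frames([[1]] * 10, POS)
        pred = _track_frames([[1]] * 5 + [[2]] * 5, POS)
        assert fraction_complete_tracks(pred, truth, missing_tolerance=2) == 0.0
        assert fraction_complete_tracks(pred, truth, missing_tolerance=10**6) == 1.0


class TestMota:
    def test_perfect_tracking(self):
        frames = _track_frames([[1, 2, 3]] * 5, POS)
        assert mota(frames, frames) == 1.0

    def test_single_identity_swap(self):
        # 10 objects over 10 frames = 100 truth objects; one swap of two
        # labels at frame 5 costs 2 switches... construct a single switch:
        truth = _track_frames([[1]] * 10, POS)
        pred = _track_frames([[1]] * 5 + [[2]] * 5, POS | {2: POS[1]})
        # 10 truth objects, one label change -> 1 ID switch
        assert mota(pred, truth) == pytest.approx(1 - 1 / 10)

    def test_all_missed(self):
        truth = _track_frames([[1, 2]] * 5, POS)
        empty = [([], []) for _ in range(5)]
        assert mota(empty, truth) == 0.0

    def test_no_truth_rejected(self):
        with pytest.raises(ValueError):
            mota([([], [])], [([], [])])


class TestLineage:
    def test_perfect_assignments(self):
        frames = _track_frames([[1, 2, 3, 4]] * 6, POS)
        pred_pairs = {2: 1, 4: 3}
        p, r = lineage_precision_recall(pred_pairs, {2: 1, 4: 3}, frames, frames)
        assert (p, r) == (1.0, 1.0)

    def test_one_wrong_mother_in_ten(self):
        labels = list(range(1, 21))
        frames = _track_frames([labels] * 6, POS)
        truth = {2 * i: 2 * i - 1 for i in range(1, 11)}  # buds 2,4,..20
        pred = dict(truth)
        pred[20] = 1  # wrong mother for one bud
        p, r = lineage_precision_recall(pred, truth, frames, frames)
        assert p == pytest.approx(0.9)
        assert r == pytest.approx(0.9)

    def test_unassigned_bud_counts_as_false_negative_only(self):
        labels = [1, 2, 3, 4]
        frames = _track_frames([labels] * 6, POS)
        truth = {2: 1, 4: 3}
        pred = {2: 1}  # bud 4 unassigned
        p, r = lineage_precision_recall(pred, truth, frames, frames)
        assert p == 1.0
        assert r == pytest.approx(0.5)


class TestGrowthRmse:
    def test_identity_predictions_near_zero(self, small_movie):
        truth_frames = [(f.masks, f.track_labels) for f in small_movie.frames]
        preds = [list(f.masks) for f in small_movie.frames]
        rmse, boot = growth_rmse(
            preds, truth_frames, pixel_size=small_movie.params.pixel_size,
            sampling_interval=small_movie.params.sampling_interval,
            n_bootstrap=50, seed=0,
        )
        assert rmse < 0.5
        assert boot.shape == (50,)
        assert np.all(boot < 0.5)

    def test_dilated_masks_increase_error(self, small_movie):
        from scipy import ndimage

        truth_frames = [(f.masks, f.track_labels) for f in small_movie.frames]
        preds = [
            [ndimage.binary_dilation(m, np.ones((3, 3))) for m in f.masks]
            for f in small_movie.frames
        ]
        rmse_id, _ = growth_rmse(
            [list(f.masks) for f in small_movie.frames], truth_frames,
            small_movie.params.pixel_size, small_movie.params.sampling_interval,
            n_bootstrap=10, seed=0,
        )
        rmse_dil, _ = growth_rmse(
            preds, truth_frames, small_movie.params.pixel_size,
            small_movie.params.sampling_interval, n_bootstrap=10, seed=0,
        )
        assert rmse_dil > rmse_id
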