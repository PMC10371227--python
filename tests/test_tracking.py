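import math

import numpy as np
import pytest

from budtrack.segment import mask_iou
from budtrack.simulate import SimParams, ellipse_mask, simulate_colony
from budtrack.targets import make_budneck_target
from budtrack.tracking import (
    LineageLedger,
    MorphFeatures,
    TrackClassifiers,
    Tracker,
    budneck_evidence,
    build_tracking_training_set,
    candidate_pairs_for_frame,
    extract_morph_features,
    mother_bud_probability,
    pair_features,
    track_probability,
    train_track_classifiers,
)


class TestMorphFeatures:
    def test_disc_closed_form(self):
        disc = ellipse_mask((41, 41), (20, 20), 10, 10, 0)
        f = extract_morph_features(disc)
        assert f.area == pytest.approx(math.pi * 100, rel=0.02)
        assert f.eccentricity < 0.1
        assert f.radius_mean == pytest.approx(9.7, abs=0.5)

    def test_deterministic(self):
        m = ellipse_mask((41, 41), (20, 20), 9, 7, 0.4)
        a, b = extract_morph_features(m), extract_morph_features(m)
        assert a == b

    def test_translation_invariance_except_centroid(self):
        m1 = ellipse_mask((64, 64), (20, 20), 9, 7, 0.4)
        m2 = ellipse_mask((64, 64), (40, 35), 9, 7, 0.4)
        f1, f2 = extract_morph_features(m1), extract_morph_features(m2)
        assert f1.area == f2.area
        assert f1.perimeter == pytest.approx(f2.perimeter, rel=0.02)
        assert f1.centroid != f2.centroid

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            extract_morph_features(np.zeros((8, 8), bool))


class TestClassifierTraining:
    def test_single_class_rejected(self):
        x = np.random.default_rng(0).normal(size=(10, 5))
        with pytest.raises(ValueError):
            train_track_classifiers(x, x, np.ones(10))

    def test_b_at_least_as_good_as_a_without_pivots(self, classifiers):
        """On calm colonies the distance-augmented classifier B should do
        at least as well as morphology-only A."""
        track_clf, _ = classifiers
        movie = simulate_colony(
            SimParams(seed=91, n_timepoints=20, n_mothers=3, pivot_prob=0.0)
        )
        xa, xb, y = build_tracking_training_set([movie], seed=0, rotation_augment=0)
        acc_a = (track_clf.clf_a.predict(xa) == y).mean()
        acc_b = (track_clf.clf_b.predict(xb) == y).mean()
        assert acc_b >= acc_a - 0.01

    def test_a_degrades_less_than_b_under_pivots(self, classifiers):
        calm = simulate_colony(SimParams(seed=92, n_timepoints=20, n_mothers=3))
        wild = simulate_colony(
            SimParams(seed=93, n_timepoints=20, n_mothers=3, pivot_prob=0.6)
        )
        track_clf, _ = classifiers
        accs = {}
        for name, movie in [("calm", calm), ("wild", wild)]:
            xa, xb, y = build_tracking_training_set([movie], seed=0, rotation_augment=0)
            accs[name] = (
                (track_clf.clf_a.predict(xa) == y).mean(),
                (track_clf.clf_b.predict(xb) == y).mean(),
            )
        drop_a = accs["calm"][0] - accs["wild"][0]
        drop_b = accs["calm"][1] - accs["wild"][1]
        assert drop_a <= drop_b + 0.02


class _StubClf:
    def __init__(self, p):
        self.p = p

    def predict_proba(self, x):
        return np.column_stack([1 - np.full(len(x), self.p), np.full(len(x), self.p)])


class TestTrackProbability:
    def test_identical_instance_high_probability(self, classifiers):
        track_clf, _ = classifiers
        m = ellipse_mask((48, 48), (24, 24), 10, 9, 0.2)
        f = extract_morph_features(m)
        assert track_probability(f, f, track_clf, iou=1.0) > 0.9

    def test_bud_vs_mother_low_probability(self, classifiers):
        track_clf, _ = classifiers
        bud = extract_morph_features(ellipse_mask((48, 48), (24, 24), 4, 4, 0))
        mother = extract_morph_features(ellipse_mask((48, 48), (24, 24), 12, 11, 0))
        assert track_probability(bud, mother, track_clf, iou=0.1) < 0.1

    def test_ambiguity_midpoint_defers_to_b(self):
        stub = TrackClassifiers(clf_a=_StubClf(0.5), clf_b=_StubClf(0.93))
        f = extract_morph_features(ellipse_mask((32, 32), (16, 16), 6, 6, 0))
        assert track_probability(f, f, stub) == pytest.approx(0.93)

    def test_confident_a_is_not_overridden(self):
        stub = TrackClassifiers(clf_a=_StubClf(0.95), clf_b=_StubClf(0.1))
        f = extract_morph_features(ellipse_mask((32, 32), (16, 16), 6, 6, 0))
        assert track_probability(f, f, stub) == pytest.approx(0.95)


class TestTracker:
    def test_repeated_frame_keeps_identities(self, classifiers):
        movie = simulate_colony(SimParams(seed=15, n_timepoints=6, n_mothers=3))
        masks = list(movie.frames[-1].masks)
        tracker = Tracker(classifiers[0])
        l1 = tracker.step(masks)
        l2 = tracker.step(masks)
        assert l1 == l2
        assert len(set(l1)) == len(l1)  # one-to-one assignment

    def test_removed_cell_closes_track_after_patience(self, classifiers):
        movie = simulate_colony(SimParams(seed=15, n_timepoints=6, n_mothers=3))
        masks = list(movie.frames[-1].masks)
        tracker = Tracker(classifiers[0], lost_patience=2)
        l1 = tracker.step(masks)
        removed_label = l1[-1]
        for _ in range(4):
            tracker.step(masks[:-1])
        state = tracker.states[removed_label]
        assert not state.active
        # the remaining cells kept their labels throughout
        l_last = tracker.step(masks[:-1])
        assert l_last == l1[:-1]

    def test_labels_unique_per_frame(self, classifiers):
        movie = simulate_colony(
            SimParams(seed=16, n_timepoints=12, n_mothers=3, pivot_prob=0.3)
        )
        tracker = Tracker(classifiers[0])
        for frame in movie.frames:
            labels = tracker.step(list(frame.masks))
            assert len(set(labels)) == len(labels)


class TestMotherBud:
    def test_oracle_neck_ranking(self, classifiers):
        _, mb_clf = classifiers
        movie = simulate_colony(SimParams(seed=31, n_timepoints=12, n_mothers=3))
        checked = 0
        for frame in movie.frames[4:10]:
            if not frame.mother_pairs or len(frame.masks) < 3:
                continue
            neck = make_budneck_target(frame).astype(float)
            for bud, mother in frame.mother_pairs:
                p_true = mother_bud_probability(
                    frame.mask_of(mother), frame.mask_of(bud), neck, mb_clf
                )
                decoys = [
                    mother_bud_probability(frame.mask_of(other), frame.mask_of(bud),
                                           neck, mb_clf)
                    for other in frame.track_labels
                    if other not in (bud, mother)
                ]
                assert p_true > max(decoys)
                checked += 1
        assert checked >= 3

    def test_zero_neck_still_valid_probability(self, classifiers):
        _, mb_clf = classifiers
        a = ellipse_mask((48, 48), (20, 20), 11, 10, 0)
        b = ellipse_mask((48, 48), (20, 33), 5, 4, 0)
        p = mother_bud_probability(a, b, np.zeros((48, 48)), mb_clf)
        assert 0.0 <= p <= 1.0

    def test_far_apart_large_cells_low(self, classifiers):
        _, mb_clf = classifiers
        a = ellipse_mask((96, 96), (20, 20), 12, 11, 0)
        b = ellipse_mask((96, 96), (75, 75), 11, 10, 0)
        assert mother_bud_probability(a, b, np.zeros((96, 96)), mb_clf) < 0.1

    def test_budneck_evidence_concentrated_at_contact(self):
        a = ellipse_mask((48, 48), (20, 20), 10, 10, 0)
        b = ellipse_mask((48, 48), (20, 32), 5, 5, 0)
        neck = np.zeros((48, 48))
        neck[18:23, 26:30] = 1.0  # at the interface
        assert budneck_evidence(a, b, neck) > 0.9
        far = np.zeros((48, 48))
        far[40:44, 2:6] = 1.0
        assert budneck_evidence(a, b, far) == 0.0


class TestLineageLedger:
    def test_empty_update_leaves_ledger_unchanged(self):
        ledger = LineageLedger()
        ledger.update([])
        assert ledger.sums == {} and ledger.counts == {}

    def test_accumulation_arithmetic(self):
        ledger = LineageLedger()
        for _ in range(3):
            ledger.update([(1, 7, 0.8)])
        assert ledger.sums[(1, 7)] == pytest.approx(2.4)
        assert ledger.counts[(1, 7)] == 3

    def test_argmax_selects_higher_sum(self):
        ledger = LineageLedger()
        ledger.update([(1, 7, 0.8)] * 1)
        for _ in range(2):
            ledger.update([(1, 7, 0.8), (2, 7, 0.5)])
        ledger.update([(2, 7, 0.5)])
        assert ledger.counts[(1, 7)] == 3 and ledger.counts[(2, 7)] == 3
        assert ledger.assign_mothers()[7] == 1

    def test_two_joint_frames_never_assigned(self):
        ledger = LineageLedger()
        for _ in range(2):
            ledger.update([(1, 7, 0.99)])
        assert 7 not in ledger.assign_mothers(min_joint_frames=3)

    def test_monotone_in_joint_frames(self):
        ledger = LineageLedger()
        for _ in range(3):
            ledger.update([(1, 7, 0.9)])
        assert ledger.assign_mothers()[7] == 1
        for _ in range(5):
            ledger.update([(1, 7, 0.9)])
        assert ledger.assign_mothers()[7] == 1  # more frames never de-qualify
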