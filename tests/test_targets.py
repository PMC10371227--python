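import math

import numpy as np
import pytest

from budtrack.simulate import AnnotatedFrame, ellipse_mask
from budtrack.targets import (
    CATEGORIES,
    SizeCategorySpec,
    assign_size_category,
    build_target_stack,
    make_budneck_target,
    make_interior_edge_targets,
    make_overlap_target,
    optimize_size_boundaries,
    outline,
)


def square(shape, y0, x0, size):
    m = np.zeros(shape, dtype=bool)
    m[y0 : y0 + size, x0 : x0 + size] = True
    return m


class TestSizeCategories:
    def test_boundaries_must_increase(self):
        with pytest.raises(ValueError):
            SizeCategorySpec(boundaries=(400, 120))

    @pytest.mark.parametrize("side,expected", [(3, "S"), (12, "M"), (40, "L")])
    def test_half_open_intervals(self, side, expected):
        spec = SizeCategorySpec(boundaries=(100, 600))
        m = square((50, 50), 0, 0, side)
        assert assign_size_category(m, spec) == expected

    def test_boundary_value_is_inclusive_upward(self):
        spec = SizeCategorySpec(boundaries=(100, 600))
        m = square((50, 50), 0, 0, 10)  # area exactly 100 = b1
        assert assign_size_category(m, spec) == "M"

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            assign_size_category(np.zeros((5, 5), bool), SizeCategorySpec())


class TestOptimizeBoundaries:
    def test_separates_two_overlapping_cells(self):
        small = ellipse_mask((64, 64), (30, 30), 4, 4, 0)  # ~50 px
        large = ellipse_mask((64, 64), (32, 34), 13, 12, 0)  # ~500 px
        frame = AnnotatedFrame(masks=[small, large], track_labels=[1, 2])
        assert (small & large).any()
        spec = optimize_size_boundaries([frame])
        a_small, a_large = small.sum(), large.sum()
        b1, b2 = spec.boundaries
        cat = lambda a: 0 if a < b1 else (1 if a < b2 else 2)
        assert cat(a_small) != cat(a_large)

    def test_three_cell_brute_force_case(self):
        c1 = ellipse_mask((96, 96), (15, 15), 4, 4, 0)  # ~50
        c2 = ellipse_mask((96, 96), (50, 50), 10, 9.5, 0)  # ~300
        c3 = ellipse_mask((96, 96), (55, 60), 18, 17.5, 0)  # ~1000, overlaps c2
        frame = AnnotatedFrame(masks=[c1, c2, c3], track_labels=[1, 2, 3])
        assert (c2 & c3).any() and not (c1 & c2).any()
        spec = optimize_size_boundaries([frame])
        b1, b2 = spec.boundaries
        assert c2.sum() < b2 <= c3.sum()
        # objective at the chosen boundaries is zero
        cat = lambda a: 0 if a < b1 else (1 if a < b2 else 2)
        assert cat(c2.sum()) != cat(c3.sum())

    def test_no_overlaps_falls_back_to_terciles(self):
        masks = [
            ellipse_mask((128, 128), (20 + 30 * i, 20 + 30 * j), 3 + i + j, 3 + i + j, 0)
            for i in range(3)
            for j in range(3)
        ]
        frame = AnnotatedFrame(masks=masks, track_labels=list(range(9)))
        spec = optimize_size_boundaries([frame])
        areas = np.array([m.sum() for m in masks], dtype=float)
        terciles = np.quantile(areas, [1 / 3, 2 / 3])
        # tie-break keeps boundaries close to the terciles
        assert abs(spec.boundaries[0] - terciles[0]) <= np.ptp(areas) / 2
        assert abs(spec.boundaries[1] - terciles[1]) <= np.ptp(areas) / 2

    def test_optimised_no_worse_than_naive_terciles(self, small_movie):
        frames = [f for f in small_movie.frames if f.masks]
        spec = optimize_size_boundaries(frames)
        areas = np.array([m.sum() for f in frames for m in f.masks], dtype=float)
        naive = np.quantile(areas, [1 / 3, 2 / 3])

        def within_cat_overlap(b1, b2):
            total = 0
            for f in frames:
                ms = f.masks
                arr = [m.sum() for m in ms]
                cat = lambda a: 0 if a < b1 else (1 if a < b2 else 2)
                for i in range(len(ms)):
                    for j in range(i + 1, len(ms)):
                        if cat(arr[i]) == cat(arr[j]):
                            total += int((ms[i] & ms[j]).sum())
            return total

        assert within_cat_overlap(*spec.boundaries) <= within_cat_overlap(*naive)


class TestInteriorEdgeTargets:
    def test_disc_erosion_closed_form(self):
        # 21-px-diameter disc eroded by a radius-2 disc: a ~17-px-diameter disc
        disc = ellipse_mask((41, 41), (20, 20), 10, 10, 0)
        frame = AnnotatedFrame(masks=[disc], track_labels=[1])
        spec = SizeCategorySpec(boundaries=(1e5, 2e5), erosion_depth={"S": 2, "M": 2, "L": 2})
        ch = make_interior_edge_targets(frame, spec)
        interior = ch[0]  # category S
        assert interior.sum() > 0
        assert not (interior & ~disc).any()  # eroded subset of original
        assert math.pi * 7.5**2 <= interior.sum() <= math.pi * 8.7**2

    def test_erosion_backs_off_for_small_cells(self):
        tiny = ellipse_mask((21, 21), (10, 10), 2.2, 2.2, 0)  # ~13 px
        frame = AnnotatedFrame(masks=[tiny], track_labels=[1])
        spec = SizeCategorySpec(erosion_depth={"S": 3, "M": 3, "L": 3}, min_seed_area=5)
        ch = make_interior_edge_targets(frame, spec)
        assert ch[0].sum() >= spec.min_seed_area

    def test_overlapping_same_category_cells_get_disjoint_interiors(self):
        a = ellipse_mask((64, 64), (32, 24), 9, 9, 0)
        b = ellipse_mask((64, 64), (32, 39), 9, 9, 0)  # 3-px overlap strip
        assert 10 < (a & b).sum() < 120
        frame = AnnotatedFrame(masks=[a, b], track_labels=[1, 2])
        spec = SizeCategorySpec(boundaries=(1e5, 2e5), erosion_depth={"S": 3, "M": 3, "L": 3})
        ch = make_interior_edge_targets(frame, spec)
        from scipy import ndimage

        _, n = ndimage.label(ch[0], structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
        assert n == 2

    def test_edge_disjoint_from_own_eroded_interior(self, small_movie, movie_spec):
        from scipy import ndimage

        from budtrack.targets import erosion_element

        for frame in small_movie.frames[:6]:
            for mask in frame.masks:
                cat = assign_size_category(mask, movie_spec)
                depth = movie_spec.erosion_depth[cat]
                if depth == 0:
                    continue
                eroded = ndimage.binary_erosion(mask, structure=erosion_element(depth))
                assert not (outline(mask) & eroded).any()
                assert not (eroded & ~mask).any()  # erode(mask) subset of mask


class TestOverlapTarget:
    def test_disjoint_cells_zero(self):
        frame = AnnotatedFrame(
            masks=[square((32, 32), 2, 2, 5), square((32, 32), 20, 20, 5)],
            track_labels=[1, 2],
        )
        assert make_overlap_target(frame).sum() == 0

    def test_two_squares_sharing_region(self):
        a = square((32, 32), 5, 5, 10)
        b = square((32, 32), 5, 10, 10)  # share a 10x5 block
        frame = AnnotatedFrame(masks=[a, b], track_labels=[1, 2])
        ov = make_overlap_target(frame)
        assert ov.sum() == 50
        assert np.array_equal(ov, a & b)

    def test_triple_overlap_counted_once(self):
        m = [square((16, 16), 4, 4, 3) for _ in range(3)]
        frame = AnnotatedFrame(masks=m, track_labels=[1, 2, 3])
        ov = make_overlap_target(frame)
        assert np.array_equal(ov, m[0])

    def test_equals_multicoverage_oracle(self, small_movie):
        # independent oracle: a pixel lies in some pairwise intersection
        # iff it is covered by at least two masks
        for frame in small_movie.frames:
            if len(frame.masks) < 2:
                continue
            coverage = np.sum([m.astype(int) for m in frame.masks], axis=0)
            assert np.array_equal(make_overlap_target(frame), coverage >= 2)


class TestBudneckTarget:
    def test_no_pairs_zero_map(self, small_movie):
        frame = AnnotatedFrame(
            masks=list(small_movie.frames[0].masks),
            track_labels=list(small_movie.frames[0].track_labels),
            mother_pairs=[],
        )
        assert make_budneck_target(frame).sum() == 0

    def test_neck_adjacent_to_both_masks(self, small_movie):
        from scipy import ndimage

        for frame in small_movie.frames:
            for bud, mother in frame.mother_pairs:
                neck = make_budneck_target(
                    AnnotatedFrame(
                        masks=list(frame.masks),
                        track_labels=list(frame.track_labels),
                        mother_pairs=[(bud, mother)],
                    )
                )
                assert neck.any()
                d_bud = ndimage.distance_transform_edt(~frame.mask_of(bud))
                d_mother = ndimage.distance_transform_edt(~frame.mask_of(mother))
                assert d_bud[neck].max() <= 3.0 + 1e-9
                assert d_mother[neck].max() <= 3.0 + 1e-9

    def test_missing_label_rejected(self):
        frame = AnnotatedFrame(
            masks=[square((16, 16), 2, 2, 5)], track_labels=[1], mother_pairs=[(1, 99)]
        )
        with pytest.raises(ValueError):
            make_budneck_target(frame)


class TestTargetStack:
    def test_empty_frame_all_zero(self):
        frame = AnnotatedFrame(masks=[], track_labels=[])
        stack = build_target_stack(frame, SizeCategorySpec(), shape=(32, 32))
        assert stack.shape == (8, 32, 32)
        assert stack.sum() == 0

    def test_channels_equal_per_cell_union_oracle(self, small_movie, movie_spec):
        """Interior/edge channels equal the union over member cells,
        recomputed independently; each cell contributes to exactly the
        channel pair of its own category."""
        from scipy import ndimage
        from skimage.morphology import disk

        for frame in small_movie.frames[:6]:
            if not frame.masks:
                continue
            stack = build_target_stack(frame, movie_spec)
            from budtrack.targets import erosion_element
            expect_interior = {c: np.zeros(frame.shape, bool) for c in CATEGORIES}
            expect_edge = {c: np.zeros(frame.shape, bool) for c in CATEGORIES}
            for mask in frame.masks:
                cat = assign_size_category(mask, movie_spec)
                d = movie_spec.erosion_depth[cat]
                eroded = (
                    ndimage.binary_erosion(mask, structure=erosion_element(d)) if d else mask
                )
                while eroded.sum() < movie_spec.min_seed_area and d > 0:
                    d -= 1
                    eroded = (
                        ndimage.binary_erosion(mask, structure=erosion_element(d))
                        if d
                        else mask.copy()
                    )
                expect_interior[cat] |= eroded
                expect_edge[cat] |= outline(mask)
            for ci, cat in enumerate(CATEGORIES):
                assert np.array_equal(stack[ci], expect_interior[cat])
                assert np.array_equal(stack[3 + ci], expect_edge[cat])

    def test_overlap_channel_subset_of_union(self, small_movie, movie_spec):
        for frame in small_movie.frames:
            if not frame.masks:
                continue
            stack = build_target_stack(frame, movie_spec)
            union = np.any(frame.masks, axis=0)
            assert not (stack[6] & ~union).any()
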