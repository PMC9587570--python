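import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from angioseg.cover import (
    Cover,
    CoverRuleConfig,
    THREE_DIRECTIONS,
    build_cover_forest,
    cast_covers,
    merge_adjacent_trees,
    prune_mask,
    scan_boundary_pixels,
    select_cover,
    select_main_tree,
)
from angioseg.phantom import bar_mask, jagged_bar_mask, u_mask

from conftest import ray_walk_oracle

SQRT2 = math.sqrt(2.0)


def random_mask(seed, shape=(48, 48), density=0.35):
    rng = np.random.default_rng(seed)
    return rng.random(shape) < density


class TestScanBoundaryPixels:
    def test_solid_block_yields_border_ring(self):
        mask = np.ones((10, 10), dtype=bool)
        pixels = scan_boundary_pixels(mask)
        assert len(pixels) == 36
        assert all(r in (0, 9) or c in (0, 9) for r, c in pixels)
        assert pixels == sorted(pixels)  # row-major order

    def test_single_pixel(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 3] = True
        assert scan_boundary_pixels(mask) == [(2, 3)]

    def test_empty_mask(self):
        assert scan_boundary_pixels(np.zeros((4, 4), dtype=bool)) == []

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(arrays(bool, (12, 14), elements=st.booleans()))
    def test_matches_brute_force_four_neighbor_test(self, mask):
        expected = []
        for r in range(12):
            for c in range(14):
                if not mask[r, c]:
                    continue
                neigh = []
                for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                    rr, cc = r + dr, c + dc
                    neigh.append(
                        0 <= rr < 12 and 0 <= cc < 14 and bool(mask[rr, cc])
                    )
                if not all(neigh):
                    expected.append((r, c))
        assert scan_boundary_pixels(mask) == expected


class TestCastCovers:
    def test_horizontal_bar_from_top_left(self):
        mask = bar_mask((20, 30), 4, "horizontal", length=20, offset=(5, 5))
        covers = {cv.direction: cv for cv in cast_covers(mask, (5, 5))}
        assert set(covers) == {"S", "E", "SE"}
        assert covers["S"].span == 4 and covers["S"].length == 4
        assert covers["E"].span == 20 and covers["E"].length == 20
        assert covers["SE"].span == 4
        assert covers["SE"].length == pytest.approx(4 * SQRT2)

    def test_isolated_pixel_gives_five_span_one(self):
        mask = np.zeros((9, 9), dtype=bool)
        mask[4, 4] = True
        covers = cast_covers(mask, (4, 4))
        assert len(covers) == 5
        assert all(cv.span == 1 and cv.end == (4, 4) for cv in covers)

    def test_non_vessel_anchor_rejected(self):
        with pytest.raises(ValueError, match="not a vessel"):
            cast_covers(np.zeros((4, 4), dtype=bool), (1, 1))

    def test_candidates_revalidate_by_ray_walk(self):
        for seed in range(5):
            mask = random_mask(seed)
            for anchor in scan_boundary_pixels(mask)[::7]:
                for cv in cast_covers(mask, anchor):
                    assert ray_walk_oracle(mask, cv), (seed, cv)


def _mk(direction, span):
    step = SQRT2 if direction in ("SE", "NE") else 1.0
    return Cover(
        anchor=(0, 0), direction=direction, span=span, length=span * step, end=(0, 0)
    )


class TestSelectCover:
    def test_no_previous_takes_shortest(self):
        chosen = select_cover([_mk("S", 4), _mk("E", 20), _mk("SE", 4)], None)
        assert chosen.direction == "S"

    def test_same_direction_admissible_kept(self):
        prev = _mk("E", 6)
        chosen = select_cover([_mk("E", 6), _mk("S", 20), _mk("SE", 8)], prev)
        assert chosen.direction == "E"

    def test_rule1_violation_falls_back_to_shortest(self):
        prev = _mk("S", 4)
        chosen = select_cover([_mk("E", 4)], prev)
        assert chosen.direction == "E"

    def test_empty_candidates_raise(self):
        with pytest.raises(ValueError, match="empty candidate"):
            select_cover([], None)

    def test_region_terminated_preferred_over_frame_clipped(self):
        clipped = Cover((0, 0), "N", 2, 2.0, (0, 0), clipped=True)
        chosen = select_cover([clipped, _mk("E", 9)], None)
        assert chosen.direction == "E"


class TestBuildCoverForest:
    def test_empty_mask_gives_empty_forest(self):
        assert build_cover_forest(np.zeros((8, 8), dtype=bool)) == []

    def test_one_tree_per_region(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[2:6, 2:6] = True
        mask[12:16, 12:16] = True
        forest = build_cover_forest(mask)
        assert len(forest) == 2

    def test_vertical_bar_covered_horizontally(self):
        mask = bar_mask((70, 30), 9, "vertical", length=60, offset=(3, 10))
        (tree,) = build_cover_forest(mask)
        directions = Counter(cv.direction for cv in tree.nodes)
        assert directions["E"] >= 0.9 * tree.size
        lengths = [cv.length for cv in tree.nodes if cv.direction == "E"]
        assert np.median(lengths) == 9.0

    def test_every_region_holds_a_cover_and_covers_revalidate(self):
        for seed in range(8):
            mask = random_mask(seed, (40, 40))
            from scipy import ndimage as ndi

            _, n_regions = ndi.label(mask, structure=np.ones((3, 3)))
            forest = build_cover_forest(mask)
            assert len(forest) == n_regions
            for tree in forest:
                assert tree.size >= 1
                for cv in tree.nodes:
                    assert ray_walk_oracle(mask, cv)

    def test_deterministic(self):
        mask = random_mask(99)
        assert build_cover_forest(mask) == build_cover_forest(mask)

    def test_rule1_compliance_without_fallbacks(self):
        """Consecutive chained covers differ by <= 45 degrees wherever no
        fallback event occurred."""
        from angioseg.cover import orientation_difference

        mask = bar_mask((70, 30), 9, "vertical", length=60, offset=(3, 10))
        (tree,) = build_cover_forest(mask)
        if tree.n_fallbacks == 0:
            for a, b in tree.edges:
                assert (
                    orientation_difference(
                        tree.nodes[a].direction, tree.nodes[b].direction
                    )
                    <= 45.0
                )


class TestMergeAdjacentTrees:
    def test_corner_touching_blobs_merge(self):
        # 8-connected labelling would see one region, so build the two trees
        # from separate sub-masks and let merging unite them
        a = np.zeros((20, 20), dtype=bool)
        a[2:6, 2:6] = True
        b = np.zeros((20, 20), dtype=bool)
        b[6:10, 6:10] = True  # 8-adjacent at the corner
        forest = build_cover_forest(a) + build_cover_forest(b)
        merged = merge_adjacent_trees(forest)
        assert len(merged) == 1
        assert merged[0].size == forest[0].size + forest[1].size

    def test_separated_blobs_unchanged(self):
        a = np.zeros((20, 20), dtype=bool)
        a[2:6, 2:6] = True
        b = np.zeros((20, 20), dtype=bool)
        b[10:14, 10:14] = True
        forest = build_cover_forest(a) + build_cover_forest(b)
        merged = merge_adjacent_trees(forest)
        assert len(merged) == 2

    def test_idempotent(self):
        mask = random_mask(5, (30, 30))
        merged = merge_adjacent_trees(build_cover_forest(mask))
        assert merge_adjacent_trees(merged) == merged


class TestSelectMainTree:
    def test_longest_path_wins(self):
        mask = np.zeros((60, 60), dtype=bool)
        mask[5:55, 10:19] = True  # long bar: ~50 covers
        mask[5:9, 40:44] = True  # small blob
        forest = build_cover_forest(mask)
        main = select_main_tree(forest)
        assert main.path_length == max(t.path_length for t in forest)
        assert all(cv.anchor[1] < 20 for cv in main.nodes)

    def test_single_tree_returned(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[2:5, 2:5] = True
        (tree,) = build_cover_forest(mask)
        assert select_main_tree([tree]) == tree

    def test_empty_forest_raises(self):
        with pytest.raises(ValueError, match="empty forest"):
            select_main_tree([])


class TestPruneMask:
    def test_all_regions_in_main_tree_unchanged(self):
        mask = bar_mask((40, 20), 5, "vertical")
        (tree,) = build_cover_forest(mask)
        assert np.array_equal(prune_mask(mask, tree), mask)

    def test_distractors_removed_exactly(self):
        from scipy import ndimage as ndi

        mask = np.zeros((80, 80), dtype=bool)
        mask[2:78, 30:39] = True  # main vessel
        rng = np.random.default_rng(1)
        for _ in range(5):  # disconnected distractor blobs
            r, c = rng.integers(4, 70, 2)
            if abs(c - 34) < 15:
                c = (c + 30) % 70 + 4
            mask[r : r + 4, c : c + 4] = True
        forest = merge_adjacent_trees(build_cover_forest(mask))
        main = select_main_tree(forest)
        pruned = prune_mask(mask, main)
        # oracle: connected components holding a main-tree cover pixel
        labels, _ = ndi.label(mask, structure=np.ones((3, 3)))
        keep = {labels[px] for cv in main.nodes for px in cv.pixels()}
        assert np.array_equal(pruned, np.isin(labels, sorted(keep)))
        assert pruned.sum() < mask.sum()

    def test_disconnected_second_vessel_also_removed(self):
        main_vessel = np.zeros((80, 80), dtype=bool)
        main_vessel[2:78, 40:49] = True  # 76 rows
        second = np.zeros_like(main_vessel)
        second[2:40, 10:17] = True  # genuine but shorter second vessel
        mask = main_vessel | second
        forest = merge_adjacent_trees(build_cover_forest(mask))
        main = select_main_tree(forest)
        pruned = prune_mask(mask, main)
        assert np.array_equal(pruned, main_vessel)


class TestDirectionSetAndRules:
    def test_five_directions_cover_at_least_as_much_as_three(self):
        mask = u_mask((100, 100), 9.0)
        fractions = {}
        for name, dirs in (("five", None), ("three", THREE_DIRECTIONS)):
            cfg = (
                CoverRuleConfig()
                if dirs is None
                else CoverRuleConfig(directions=dirs)
            )
            covered = np.zeros_like(mask)
            for tree in build_cover_forest(mask, cfg):
                for cv in tree.nodes:
                    for px in cv.pixels():
                        covered[px] = True
            fractions[name] = covered[mask].sum() / mask.sum()
        assert fractions["five"] >= fractions["three"]

    def test_rules_reduce_direction_scatter_on_jagged_bar(self):
        mask = jagged_bar_mask((90, 40), width=9, seed=0)
        variances = {}
        for rules in (True, False):
            cfg = CoverRuleConfig(rules_enabled=rules)
            main = select_main_tree(
                merge_adjacent_trees(build_cover_forest(mask, cfg))
            )
            angles = {"E": 0, "SE": 45, "S": 90, "N": 90, "NE": 135}
            doubled = np.deg2rad([2 * angles[cv.direction] for cv in main.nodes])
            variances[rules] = 1 - abs(np.mean(np.exp(1j * doubled)))
        assert variances[True] < variances[False]

    def test_width_recovery_axis_aligned(self):
        for w in range(3, 32, 4):
            for orientation, crossing in (("vertical", "E"), ("horizontal", "S")):
                mask = bar_mask((80, 80), w, orientation, offset=(3, 3))
                main = select_main_tree(
                    merge_adjacent_trees(build_cover_forest(mask))
                )
                lengths = [
                    cv.length for cv in main.nodes if cv.direction == crossing
                ]
                assert np.median(lengths) == w, (w, orientation)
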