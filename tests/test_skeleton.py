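"""Thinning, staircase removal, keypoints, splitting, burrs and repair."""

import numpy as np
import pytest

from angiotrack import skeleton as sk
from conftest import thin_bruteforce, random_blob_mask, grid_from_coords


class TestThin:
    def test_one_pixel_line_unchanged(self):
        g = grid_from_coords([(x, 3) for x in range(1, 12)], shape=(8, 14))
        assert np.array_equal(sk.thin(g), g)

    def test_isolated_pixel_unchanged(self):
        g = np.zeros((5, 5), np.uint8)
        g[2, 2] = 1
        assert np.array_equal(sk.thin(g), g)

    def test_bar_thins_to_centerline(self):
        g = np.zeros((7, 25), np.uint8)
        g[2:5, 2:23] = 1  # 3x21 bar
        out = sk.thin(g)
        assert np.array_equal(out, thin_bruteforce(g))
        assert out.sum() <= 21
        # single-pixel wide: no 2x2 block survives
        assert not (out[:-1, :-1] & out[1:, :-1] & out[:-1, 1:] & out[1:, 1:]).any()

    def test_empty_mask(self):
        assert sk.thin(np.zeros((5, 5), np.uint8)).sum() == 0

    def test_idempotent(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            m = random_blob_mask(rng)
            once = sk.thin(m)
            assert np.array_equal(sk.thin(once), once)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = random_blob_mask(rng)
        assert np.array_equal(sk.thin(m), thin_bruteforce(m))

    def test_preserves_component_count(self):
        rng = np.random.default_rng(11)
        from scipy import ndimage
        s8 = np.ones((3, 3), int)
        for _ in range(10):
            m = random_blob_mask(rng)
            _, n0 = ndimage.label(m, structure=s8)
            _, n1 = ndimage.label(sk.thin(m), structure=s8)
            assert n0 == n1


class TestStaircase:
    def test_straight_path_unchanged(self):
        g = grid_from_coords([(x, 3) for x in range(1, 10)], shape=(8, 12))
        assert np.array_equal(sk.remove_staircase(g), g)

    def test_corner_pixel_deleted(self):
        # ordered path (0,0),(1,0),(1,1),(2,1) in (x,y): (1,1) matches the
        # second coordinate pattern and its removal keeps connectivity
        g = grid_from_coords([(0, 0), (1, 0), (1, 1), (2, 1)], shape=(4, 4))
        out = sk.remove_staircase(g)
        assert out[1, 1] == 0
        assert out[0, 0] == out[0, 1] == out[1, 2] == 1

    def test_disconnecting_deletion_skipped(self):
        # lone corner of an L whose removal would split the two arms
        g = grid_from_coords([(0, 0), (0, 1), (0, 2), (1, 2), (2, 2)])
        out = sk.remove_staircase(g)
        from scipy import ndimage
        _, n = ndimage.label(out, structure=np.ones((3, 3), int))
        assert n == 1

    def test_double_pixel_staircase_resolved(self):
        # Zhang-Suen leaves two-pixel steps on shallow diagonals; the
        # staircase pass must reduce them to single-pixel chains
        coords = [(0, 0), (1, 0), (2, 0), (2, 1), (3, 1), (4, 1), (4, 2), (5, 2)]
        g = grid_from_coords(coords)
        out = sk.remove_staircase(g)
        from angiotrack.skeleton import _counts
        _, n, _ = _counts(out)
        assert ((out == 1) & (n >= 3)).sum() == 0


class TestKeypoints:
    def _arm(self, cx, cy, dx, dy, n):
        return [(cx + dx * i, cy + dy * i) for i in range(1, n + 1)]

    def test_three_pixel_line(self):
        g = grid_from_coords([(1, 1), (2, 1), (3, 1)], shape=(4, 6))
        kps = sk.detect_keypoints(g)
        assert sorted(kps.endpoints) == [(1, 1), (3, 1)]
        assert kps.intersections == []

    def test_plus_fixture(self):
        c = (5, 5)
        coords = [c]
        for dx, dy in ((0, -1), (0, 1), (-1, 0), (1, 0)):
            coords += self._arm(5, 5, dx, dy, 3)
        kps = sk.detect_keypoints(grid_from_coords(coords, shape=(11, 11)))
        assert kps.intersections == [c]
        assert len(kps.endpoints) == 4

    def test_t_fixture(self):
        coords = [(5, 5)]
        for dx, dy in ((0, -1), (-1, 0), (1, 0)):
            coords += self._arm(5, 5, dx, dy, 3)
        kps = sk.detect_keypoints(grid_from_coords(coords, shape=(11, 11)))
        assert kps.intersections == [(5, 5)]
        assert len(kps.endpoints) == 3

    def test_y_fixture(self):
        # arms up (p2), right (p4) and down-left (p7): every clockwise
        # triple of the junction's neighborhood sums to at most one
        coords = [(5, 5)]
        for dx, dy in ((0, -1), (1, 0), (-1, 1)):
            coords += self._arm(5, 5, dx, dy, 3)
        kps = sk.detect_keypoints(grid_from_coords(coords, shape=(11, 11)))
        assert kps.intersections == [(5, 5)]
        assert len(kps.endpoints) == 3


class TestSplitAndBurrs:
    def test_y_skeleton_three_paths(self):
        coords = [(5, 5)]
        for dx, dy in ((0, -1), (1, 0), (-1, 1)):
            coords += [(5 + dx * i, 5 + dy * i) for i in range(1, 4)]
        g = grid_from_coords(coords, shape=(11, 11))
        paths = sk.split_segments(g, sk.detect_keypoints(g))
        assert len(paths) == 3
        # the junction pixel is shared by every incident path
        assert all((5, 5) in p.pixels for p in paths)

    def test_open_curve_single_path(self):
        coords = [(x, 2 + (x % 3 == 0)) for x in range(1, 12)]
        g = grid_from_coords(coords, shape=(8, 14))
        g = sk.remove_staircase(g)
        paths = sk.split_segments(g, sk.detect_keypoints(g))
        assert len(paths) == 1
        assert paths[0].n_own == int(g.sum())

    def test_cycle_emitted_closed(self):
        coords = [(3, 1), (4, 2), (5, 3), (4, 4), (3, 5), (2, 4), (1, 3), (2, 2)]
        g = grid_from_coords(coords, shape=(8, 8))
        paths = sk.split_segments(g, sk.detect_keypoints(g))
        assert len(paths) == 1 and paths[0].is_closed

    def test_burr_threshold_strictly_less_than(self):
        def path_of(n):
            return sk.CenterlinePath(pixels=[(i, 0) for i in range(n)])
        kept = sk.remove_burrs([path_of(4), path_of(10)])
        assert [p.n_own for p in kept] == [10]
        assert [p.n_own for p in sk.remove_burrs([path_of(6)])] == [6]
        assert sk.remove_burrs([]) == []


class TestRepair:
    def _cross_with_spur(self):
        # horizontal vessel x=2..20 at y=5 with a 3-px spur up at x=10
        coords = [(x, 5) for x in range(2, 21)] + [(10, y) for y in (4, 3, 2)]
        return grid_from_coords(coords, shape=(10, 24))

    def test_identity_when_nothing_removed(self):
        g = self._cross_with_spur()
        assert np.array_equal(sk.repair(g, g), g)

    def test_junction_pixel_restored_between_components(self):
        g = self._cross_with_spur()
        deb = g.copy()
        deb[2:5, 10] = 0   # spur gone
        deb[5, 10] = 0     # junction pixel gone: vessel cut in two
        out = sk.repair(g, deb)
        assert out[5, 10] == 1          # reconnected
        assert out[2, 10] == out[3, 10] == out[4, 10] == 0  # spur stays out

    def test_far_deleted_pixels_never_restored(self):
        g = self._cross_with_spur()
        deb = g.copy()
        deb[5, 15:19] = 0  # interior gap not at a former junction endpoint pair
        deb[2:5, 10] = 0
        out = sk.repair(g, deb)
        assert out[2, 10] == 0 and out[3, 10] == 0

    def test_collinear_paths_merge_after_deburr_and_repair(self):
        g = self._cross_with_spur()
        kps = sk.detect_keypoints(g)
        paths = sk.split_segments(g, kps)
        assert len(paths) == 3
        kept = sk.remove_burrs(paths)
        removed = [p for p in paths if p not in kept]
        repaired = sk.repair(g, sk.deburred_skeleton(g, removed))
        paths2 = sk.split_segments(repaired, sk.detect_keypoints(repaired))
        assert len(paths2) == 1
        assert paths2[0].n_own == 19
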