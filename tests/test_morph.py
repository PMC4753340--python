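import numpy as np
import pytest

from dcfseg import (
    blob_label,
    boundary_pixel_set,
    bridge_neighbor_gaps,
    contour_trace_4dir,
    expand,
    fill_between_boundaries,
    remove_noise_objects,
)

from oracles import boundary_set_bruteforce, flood_fill_partition


def bin_img(mask):
    return np.where(np.asarray(mask, dtype=bool), 255, 0).astype(np.uint8)


def random_blobs(rng, shape=(20, 20), p=0.4):
    return bin_img(rng.random(shape) < p)


class TestBlobLabel:
    def test_empty(self):
        objs = blob_label(bin_img(np.zeros((5, 5))))
        assert objs.n_objects == 0

    def test_diagonal_connectivity_semantics(self):
        mask = np.zeros((3, 3))
        mask[0, 0] = mask[1, 1] = 1
        assert blob_label(bin_img(mask), connectivity=4).n_objects == 2
        assert blob_label(bin_img(mask), connectivity=8).n_objects == 1

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_partition_matches_flood_fill(self, connectivity):
        rng = np.random.default_rng(0)
        for _ in range(25):
            img = random_blobs(rng)
            objs = blob_label(img, connectivity)
            got = set()
            for o in objs.objects:
                ys, xs = np.nonzero(objs.label_map == o.label)
                got.add(frozenset(zip(xs.tolist(), ys.tolist())))
            expected = set(flood_fill_partition(img > 0, connectivity))
            assert got == expected

    def test_stats_consistent(self):
        mask = np.zeros((6, 8))
        mask[1:3, 2:7] = 1
        objs = blob_label(bin_img(mask))
        o = objs.objects[0]
        assert (o.size, o.x_left, o.y_top, o.x_right, o.y_bottom) == (10, 2, 1, 6, 2)
        assert o.width == 5 and o.height == 2

    def test_labels_in_raster_order(self):
        mask = np.zeros((5, 9))
        mask[0, 7] = 1   # first in raster order
        mask[2, 0] = 1
        mask[4, 4] = 1
        objs = blob_label(bin_img(mask))
        coords = [(o.x_left, o.y_top) for o in objs.objects]
        assert coords == [(7, 0), (0, 2), (4, 4)]


class TestNoiseRemoval:
    ROI = (100, 100)  # S(ROI) = 10000 -> size threshold 850

    def rect(self, x0, y0, w, h, shape=(100, 100)):
        m = np.zeros(shape)
        m[y0:y0 + h, x0:x0 + w] = 1
        return bin_img(m)

    def test_small_object_removed(self):
        img = self.rect(40, 40, 30, 28)  # 840 < 850
        out = remove_noise_objects(blob_label(img), *self.ROI)
        assert out.n_objects == 0

    def test_left_skewed_narrow_removed(self):
        img = self.rect(5, 20, 40, 50)   # size 2000, left 5 < 10, width 40 < 50
        out = remove_noise_objects(blob_label(img), *self.ROI)
        assert out.n_objects == 0

    def test_left_but_wide_kept(self):
        img = self.rect(5, 20, 60, 34)   # width 60 >= 50: second conjunct fails
        out = remove_noise_objects(blob_label(img), *self.ROI)
        assert out.n_objects == 1

    def test_all_clause_combinations(self):
        # Enumerate (small?, left?, narrow?) and check removal = A or (B and C).
        for small in (False, True):
            for left in (False, True):
                for narrow in (False, True):
                    w = 40 if narrow else 60
                    x0 = 5 if left else 20
                    h = 12 if small else 40  # 40*12=480 / 60*12=720 both < 850
                    img = self.rect(x0, 10, w, h)
                    out = remove_noise_objects(blob_label(img), *self.ROI)
                    removed = small or (left and narrow)
                    assert out.n_objects == (0 if removed else 1), (small, left, narrow)

    def test_survivor_pixels_unaltered(self):
        rng = np.random.default_rng(2)
        img = random_blobs(rng, (40, 40), p=0.45)
        objs = blob_label(img)
        out = remove_noise_objects(objs, 40, 40)
        for o in out.objects:
            new = out.label_map == o.label
            # the same pixel set exists under some original label
            old_lab = objs.label_map[new][0]
            assert np.array_equal(new, objs.label_map == old_lab)


class TestFillBetweenBoundaries:
    def test_column_gap_filled(self):
        m = np.zeros((12, 1))
        m[3, 0] = m[9, 0] = 1
        out = fill_between_boundaries(bin_img(m))
        assert np.array_equal(np.nonzero(out[:, 0])[0], np.arange(3, 10))

    def test_solid_column_unchanged_and_idempotent(self):
        rng = np.random.default_rng(4)
        img = random_blobs(rng, (15, 15))
        once = fill_between_boundaries(img)
        assert np.array_equal(fill_between_boundaries(once), once)

    def test_empty_unchanged(self):
        img = bin_img(np.zeros((7, 7)))
        assert np.array_equal(fill_between_boundaries(img), img)


class TestBridgeAndExpand:
    def test_single_pixel_becomes_block(self):
        m = np.zeros((5, 5))
        m[2, 2] = 1
        out = bridge_neighbor_gaps(bin_img(m), 1)
        expected = np.zeros((5, 5))
        expected[1:4, 1:4] = 1
        assert np.array_equal(out, bin_img(expected))

    def test_two_pixel_gap_connected(self):
        m = np.zeros((3, 5))
        m[1, 1] = m[1, 3] = 1
        out = bridge_neighbor_gaps(bin_img(m), 1)
        assert blob_label(out, connectivity=4).n_objects == 1

    def test_saturation(self):
        img = bin_img(np.ones((4, 4)))
        assert np.array_equal(bridge_neighbor_gaps(img, 2), img)

    def test_iterations_validated(self):
        with pytest.raises(ValueError):
            bridge_neighbor_gaps(bin_img(np.zeros((3, 3))), 0)

    def test_radius1_equals_one_bridge_step(self):
        rng = np.random.default_rng(6)
        img = random_blobs(rng, (16, 16), p=0.2)
        assert np.array_equal(expand(img, 1), bridge_neighbor_gaps(img, 1))

    def test_radius2_equals_two_radius1(self):
        rng = np.random.default_rng(7)
        img = random_blobs(rng, (16, 16), p=0.15)
        assert np.array_equal(expand(img, 2), expand(expand(img, 1), 1))

    def test_empty_stays_empty(self):
        img = bin_img(np.zeros((6, 6)))
        assert np.array_equal(expand(img, 3), img)


class TestContourTrace:
    def test_single_pixel(self):
        m = np.zeros((4, 4))
        m[1, 2] = 1
        [(label, loops)] = contour_trace_4dir(bin_img(m))
        assert len(loops) == 1
        assert loops[0].tolist() == [[2, 1]]

    def test_solid_square_perimeter(self):
        m = np.zeros((5, 5))
        m[1:4, 1:4] = 1
        [(_, loops)] = contour_trace_4dir(bin_img(m))
        assert len(loops) == 1
        pts = {tuple(p) for p in loops[0]}
        assert pts == {(x, y) for x in (1, 2, 3) for y in (1, 2, 3)} - {(2, 2)}
        assert loops[0].shape[0] == 8

    def test_loop_is_closed_and_8_connected(self):
        rng = np.random.default_rng(8)
        img = random_blobs(rng, (15, 15), p=0.45)
        for _, loops in contour_trace_4dir(img):
            for loop in loops:
                pts = np.vstack([loop, loop[:1]])
                steps = np.abs(np.diff(pts, axis=0)).max(axis=1)
                assert np.all(steps <= 1)

    def test_boundary_set_matches_brute_force(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            img = random_blobs(rng, (18, 18), p=0.5)
            objs = blob_label(img)
            traced = contour_trace_4dir(img)
            for (label, loops), o in zip(traced, objs.objects):
                got = set()
                for loop in loops:
                    got |= {tuple(p) for p in loop}
                mask = objs.label_map == o.label
                assert got == boundary_set_bruteforce(mask)

    def test_hole_boundary_traced(self):
        m = np.ones((5, 5))
        m[2, 2] = 0
        [(_, loops)] = contour_trace_4dir(bin_img(m))
        got = set()
        for loop in loops:
            got |= {tuple(p) for p in loop}
        assert got == boundary_set_bruteforce(m.astype(bool))
        assert len(loops) == 2  # outer contour + the hole

    def test_boundary_pixel_set_helper(self):
        rng = np.random.default_rng(10)
        mask = rng.random((12, 12)) < 0.5
        got = boundary_pixel_set(mask)
        expected = boundary_set_bruteforce(mask)
        assert {(x, y) for y, x in zip(*np.nonzero(got))} == expected
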