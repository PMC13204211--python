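import math

import numpy as np
import pytest
from scipy import ndimage
from skimage.draw import disk as draw_disk
from skimage.draw import line

from astromorph.sholl import (
    classify_skeleton,
    last_intersection_radius_um,
    rasterize_ring,
    skeletonize_processes,
    sholl_profile,
)
from astromorph.types import ShollProfile

STRUCT8 = np.ones((3, 3), dtype=bool)


def neighbor_count_oracle(mask):
    """Brute-force per-pixel 8-neighbor counting."""
    ends, branches = set(), set()
    ys, xs = np.nonzero(mask)
    pix = set(zip(ys.tolist(), xs.tolist()))
    for y, x in pix:
        n = sum((y + dy, x + dx) in pix
                for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dy, dx) != (0, 0))
        if n <= 1:
            ends.add((y, x))
        if n >= 3:
            branches.add((y, x))
    return ends, branches


class TestSkeletonize:
    def test_empty_mask(self):
        skel = skeletonize_processes(np.zeros((20, 20), dtype=bool))
        assert skel.is_empty
        assert len(skel.endpoints) == len(skel.branch_points) == 0
        assert skel.n_primaries == 0

    def test_straight_thick_arm(self):
        mask = np.zeros((40, 60), dtype=bool)
        mask[19:21, 10:50] = True  # 2 px thick
        skel = skeletonize_processes(mask)
        ends, branches = neighbor_count_oracle(skel.mask)
        assert {tuple(p) for p in skel.endpoints} == ends
        assert {tuple(p) for p in skel.branch_points} == branches
        assert len(ends) == 2 and len(branches) == 0

    def test_y_shape(self):
        mask = np.zeros((60, 60), dtype=bool)
        for end in ((10, 10), (10, 50), (50, 30)):
            rr, cc = line(30, 30, *end)
            mask[rr, cc] = True
        skel = skeletonize_processes(mask)
        ends, branches = neighbor_count_oracle(skel.mask)
        assert {tuple(p) for p in skel.endpoints} == ends
        assert len(skel.endpoints) == 3
        # branch pixels may form a small cluster; count clusters
        bmask = np.zeros_like(mask)
        for y, x in skel.branch_points:
            bmask[y, x] = True
        assert ndimage.label(bmask, structure=STRUCT8)[1] == 1

    def test_classification_recomputable(self, star_analysis):
        _, _, seg, skel, _ = star_analysis
        again = classify_skeleton(skel.mask, seg.soma_mask)
        np.testing.assert_array_equal(np.sort(again.endpoints, 0),
                                      np.sort(skel.endpoints, 0))
        assert again.n_primaries == skel.n_primaries

    def test_attachments_without_soma(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[10, 2:18] = True
        skel = skeletonize_processes(mask, soma_mask=None)
        assert skel.n_primaries == 0 and len(skel.primary_attachments) == 0


class TestRasterizeRing:
    def test_radius_one_dialect(self):
        ring = rasterize_ring((10, 10), 1, (21, 21))
        assert ring.sum() == 8  # the 8-neighborhood of the center
        assert not ring[10, 10]

    def test_ring_is_single_closed_cycle(self):
        for r in (3, 7, 15, 31):
            ring = rasterize_ring((40, 40), r, (81, 81))
            assert ndimage.label(ring, structure=STRUCT8)[1] == 1
            # closed: the interior does not leak to the border
            filled = ndimage.binary_fill_holes(ring)
            assert filled.sum() > ring.sum()

    def test_clipping_near_border(self):
        ring = rasterize_ring((2, 2), 10, (30, 30))
        assert ring.any()
        full = rasterize_ring((15, 15), 10, (40, 40))
        assert ring.sum() < full.sum()

    def test_fully_outside_grid(self):
        ring = rasterize_ring((100, 100), 5, (20, 20))
        assert not ring.any()

    def test_invalid_radius(self):
        with pytest.raises(ValueError):
            rasterize_ring((5, 5), 0, (10, 10))

    def test_crossing_guarantee(self, rng):
        """Any 8-connected radial path must intersect the ring (no pinholes)."""
        ring = rasterize_ring((60, 60), 25, (121, 121))
        for _ in range(200):
            ang = rng.uniform(0, 2 * math.pi)
            er = int(round(60 + 55 * math.sin(ang)))
            ec = int(round(60 + 55 * math.cos(ang)))
            rr, cc = line(60, 60, er, ec)
            path = np.zeros_like(ring)
            path[rr, cc] = True
            assert (ring & path).any()


class TestShollProfile:
    def test_empty_skeleton(self):
        skel = skeletonize_processes(np.zeros((50, 50), dtype=bool))
        prof = sholl_profile(skel, (25, 25), interval=10, mode="run")
        assert (prof.counts == 0).all()
        assert prof.last_intersection_radius == 0

    def test_star_run_mode(self, star_analysis):
        _, _, _, skel, prof = star_analysis
        by_radius = dict(zip(prof.radii.tolist(), prof.counts.tolist()))
        for r in range(20, 71, 10):
            assert by_radius[r] == 4
        assert all(v == 0 for k, v in by_radius.items() if k > 70)
        assert prof.last_intersection_radius == 70

    def test_pixel_dominates_run(self, star_analysis):
        _, _, seg, skel, _ = star_analysis
        pix = sholl_profile(skel, seg.soma_center, 10, "pixel")
        run = sholl_profile(skel, seg.soma_center, 10, "run")
        assert (pix.counts >= run.counts).all()

    def test_pixel_total_against_pixelwise_oracle(self, star_analysis):
        """Ring-major counting must equal an independent pixel-major
        enumeration (for each skeleton pixel, count radii whose circle
        passes through its unit square)."""
        _, _, seg, skel, _ = star_analysis
        prof = sholl_profile(skel, seg.soma_center, 10, "pixel")
        cy, cx = seg.soma_center
        total = 0
        for y, x in zip(*np.nonzero(skel.mask)):
            dy, dx = abs(y - cy), abs(x - cx)
            near = math.hypot(max(dy - 0.5, 0), max(dx - 0.5, 0))
            far = math.hypot(dy + 0.5, dx + 0.5)
            total += sum(1 for r in prof.radii if near <= r <= far)
        assert prof.counts.sum() == total

    def test_single_radial_arm_run_count_one(self, rng):
        """Run-mode count is exactly 1 at every ring strictly between the
        arm start and tip radii, over 120 random angles."""
        for _ in range(120):
            ang = rng.uniform(0, 2 * math.pi)
            start_r, tip_r = 12.0, rng.uniform(40, 55)
            c = 64
            mask = np.zeros((129, 129), dtype=bool)
            rr, cc = line(int(round(c + start_r * math.sin(ang))),
                          int(round(c + start_r * math.cos(ang))),
                          int(round(c + tip_r * math.sin(ang))),
                          int(round(c + tip_r * math.cos(ang))))
            mask[rr, cc] = True
            skel = skeletonize_processes(mask)
            prof = sholl_profile(skel, (c, c), interval=10, mode="run")
            for r, n in zip(prof.radii, prof.counts):
                if start_r < r < tip_r - 1:
                    assert n == 1, (ang, r, n)

    def test_rotation_invariance_90deg(self, star_analysis):
        _, _, seg, skel, _ = star_analysis
        for mode in ("pixel", "run"):
            prof = sholl_profile(skel, seg.soma_center, 10, mode)
            rot_mask = np.rot90(skel.mask)
            h = skel.mask.shape[1]
            rc = (h - 1 - seg.soma_center[1], seg.soma_center[0])
            rot = sholl_profile(skeletonize_processes(rot_mask), rc, 10, mode)
            assert prof.counts.sum() == rot.counts.sum()

    def test_rings_independent_of_enumeration_order(self, star_analysis):
        _, _, seg, skel, prof = star_analysis
        from astromorph.sholl import rasterize_ring as ring

        for r, n in zip(prof.radii[::-1], prof.counts[::-1]):
            inter = skel.mask & ring(seg.soma_center, int(r), skel.mask.shape)
            assert ndimage.label(inter, structure=STRUCT8)[1] == n

    def test_invalid_args(self, star_analysis):
        _, _, seg, skel, _ = star_analysis
        with pytest.raises(ValueError):
            sholl_profile(skel, seg.soma_center, 0)
        with pytest.raises(ValueError):
            sholl_profile(skel, seg.soma_center, 10, mode="banana")


class TestLastRadiusUm:
    def test_arithmetic(self):
        prof = ShollProfile((0, 0), 10, [10, 70], [1, 2], "run")
        assert last_intersection_radius_um(prof, 0.5) == pytest.approx(35.0)
        assert last_intersection_radius_um(prof, 1.0) == pytest.approx(
            2 * last_intersection_radius_um(prof, 0.5))

    def test_all_zero_profile(self):
        prof = ShollProfile((0, 0), 10, [10, 20], [0, 0], "pixel")
        assert last_intersection_radius_um(prof, 0.5) == 0.0

    def test_invalid_calibration(self):
        prof = ShollProfile((0, 0), 10, [10], [1], "run")
        with pytest.raises(ValueError):
            last_intersection_radius_um(prof, 0)
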