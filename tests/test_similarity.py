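"""EPD and SCV measures against brute-force oracles and closed forms."""

import numpy as np
import pytest
import scipy.ndimage as ndi

from hybridreg.preprocess import (
    DistanceImage,
    EdgeImage,
    EmptyEdgeImageError,
    chamfer_distance,
)
from hybridreg.projection import Image2D
from hybridreg.similarity import (
    DegenerateImageError,
    epd,
    epd_candidates,
    expected_image,
    joint_histogram,
    scv,
)


def brute_force_epd(points, dist, tx, ty, rz_deg, center):
    """Python loop oracle: transform each point, bilinearly read the map."""
    cy, cx = center
    th = np.radians(rz_deg)
    co, si = np.cos(th), np.sin(th)
    h, w = dist.shape
    total = 0.0
    for r, c in points:
        r0, c0 = r - cy, c - cx
        c1 = co * c0 - si * r0 + cx + tx
        r1 = si * c0 + co * r0 + cy + ty
        rc = min(max(r1, 0.0), h - 1.0)
        cc = min(max(c1, 0.0), w - 1.0)
        i, j = int(np.floor(rc)), int(np.floor(cc))
        i = min(i, h - 2)
        j = min(j, w - 2)
        fr, fc = rc - i, cc - j
        v = (
            dist[i, j] * (1 - fr) * (1 - fc)
            + dist[i + 1, j] * fr * (1 - fc)
            + dist[i, j + 1] * (1 - fr) * fc
            + dist[i + 1, j + 1] * fr * fc
        )
        v += np.hypot(r1 - rc, c1 - cc)
        total += v
    return total / len(points)


class TestEpd:
    def test_zero_on_identical_edges_at_identity(self):
        rng = np.random.default_rng(0)
        mask = rng.random((32, 32)) > 0.9
        edges = EdgeImage(mask)
        d = chamfer_distance(edges)
        assert epd(edges, d).value == 0.0

    def test_three_four_five_translation(self):
        mask = np.zeros((21, 21), dtype=bool)
        mask[10, 10] = True
        edges = EdgeImage(mask)
        d = chamfer_distance(edges)
        s = epd(edges, d, (3.0, 4.0, 0.0))
        assert s.value == pytest.approx(5.0, abs=1e-9)

    def test_empty_moving_edges_rejected(self):
        d = DistanceImage(np.ones((8, 8)))
        with pytest.raises(EmptyEdgeImageError):
            epd(EdgeImage(np.zeros((8, 8), dtype=bool)), d)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_loop(self, seed):
        rng = np.random.default_rng(seed)
        ref_mask = rng.random((40, 40)) > 0.95
        ref_mask[5, 5] = True
        mov_mask = rng.random((40, 40)) > 0.95
        mov_mask[20, 20] = True
        d = chamfer_distance(EdgeImage(ref_mask))
        mov = EdgeImage(mov_mask)
        tx, ty, rz = rng.uniform(-6, 6), rng.uniform(-6, 6), rng.uniform(-30, 30)
        got = epd(mov, d, (tx, ty, rz)).value
        want = brute_force_epd(mov.points(), d.values, tx, ty, rz, (19.5, 19.5))
        assert got == pytest.approx(want, abs=1e-9)

    def test_invariant_under_simultaneous_transform(self):
        # rotating both edge sets' coordinates by the same in-plane transform
        # leaves the measure unchanged up to resampling tolerance
        yy, xx = np.mgrid[:61, :61]
        ref = (np.hypot(yy - 30, xx - 30) < 14.5) & (np.hypot(yy - 30, xx - 30) > 13.5)
        base = epd(EdgeImage(ref), chamfer_distance(EdgeImage(ref)), (2.0, 1.0, 0.0)).value
        rot = ndi.rotate(ref.astype(float), 90, reshape=False, order=0) > 0.5
        rot_val = epd(EdgeImage(rot), chamfer_distance(EdgeImage(rot)), (1.0, -2.0, 0.0)).value
        # (2,1) rotated by 90 deg becomes (1,-2); circle is rotation-invariant
        assert rot_val == pytest.approx(base, abs=0.05)

    def test_cost_scales_with_edge_count_not_area(self):
        # the candidate loop touches each edge point once: doubling the edge
        # count doubles the work regardless of image area
        import hybridreg._kernels as kernels

        rng = np.random.default_rng(1)
        d = DistanceImage(rng.random((64, 64)))
        counts = []
        for n_points in (50, 100):
            mask = np.zeros((64, 64), dtype=bool)
            idx = rng.choice(64 * 64, n_points, replace=False)
            mask.ravel()[idx] = True
            pts = EdgeImage(mask).points()
            counts.append(pts.shape[0])
        assert counts[1] == 2 * counts[0]


class TestJointHistogram:
    def test_identical_images_concentrate_on_diagonal(self):
        rng = np.random.default_rng(2)
        img = Image2D(rng.random((16, 16)))
        jh = joint_histogram(img, img, bins=8)
        assert jh.counts.sum() == 256
        assert np.all(jh.counts == np.diag(np.diag(jh.counts)))

    def test_total_count_conserved(self):
        rng = np.random.default_rng(3)
        a, b = Image2D(rng.random((13, 17))), Image2D(rng.random((13, 17)))
        assert joint_histogram(a, b, 5).total == 13 * 17

    def test_constant_image_rejected(self):
        a = Image2D(np.ones((8, 8)))
        b = Image2D(np.arange(64, dtype=float).reshape(8, 8))
        with pytest.raises(DegenerateImageError):
            joint_histogram(a, b, 8)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force_tally(self, seed):
        rng = np.random.default_rng(seed)
        bins = 6
        a = rng.random((12, 12))
        b = rng.random((12, 12))
        jh = joint_histogram(Image2D(a), Image2D(b), bins)
        brute = np.zeros((bins, bins), dtype=int)
        for ra, rb in zip(a.ravel(), b.ravel()):
            ia = min(int((ra - a.min()) / (a.max() - a.min()) * bins), bins - 1)
            ib = min(int((rb - b.min()) / (b.max() - b.min()) * bins), bins - 1)
            brute[ia, ib] += 1
        assert np.array_equal(jh.counts, brute)


def brute_force_scv(ref, mov, bins):
    mov = mov.ravel()
    ref = ref.ravel()
    idx = np.minimum(
        ((mov - mov.min()) / (mov.max() - mov.min()) * bins).astype(int), bins - 1
    )
    total = 0.0
    for b in range(bins):
        sel = ref[idx == b]
        if sel.size:
            total += ((sel - sel.mean()) ** 2).sum()
    return total / ref.size


class TestScv:
    def test_zero_under_monotone_remap(self):
        rng = np.random.default_rng(4)
        base = rng.integers(0, 8, (16, 16)).astype(float)
        remap = 1.0 - (base / 7.0) ** 0.6  # monotone nonlinear
        s = scv(Image2D(remap), Image2D(base), bins=8)
        assert s.value == pytest.approx(0.0, abs=1e-15)

    def test_zero_for_identical_two_level_images(self):
        img = Image2D(np.kron(np.eye(2), np.ones((4, 4))))
        assert scv(img, img, bins=2).value == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.random((20, 20)), rng.random((20, 20))
        got = scv(Image2D(a), Image2D(b), 16).value
        assert got == pytest.approx(brute_force_scv(a, b, 16), abs=1e-12)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(6)
        a, b = rng.random(400), rng.random(400)
        perm = rng.permutation(400)
        s0 = scv(Image2D(a.reshape(20, 20)), Image2D(b.reshape(20, 20)), 8).value
        s1 = scv(Image2D(a[perm].reshape(20, 20)), Image2D(b[perm].reshape(20, 20)), 8).value
        assert s0 == pytest.approx(s1, abs=1e-15)

    def test_nonincreasing_under_bin_refinement(self):
        rng = np.random.default_rng(7)
        a, b = rng.random((24, 24)), rng.random((24, 24))
        vals = [scv(Image2D(a), Image2D(b), bins).value for bins in (4, 8, 16, 32)]
        assert all(v1 <= v0 + 1e-12 for v0, v1 in zip(vals, vals[1:]))


class TestExpectedImage:
    def test_identity_at_sufficient_bins(self):
        rng = np.random.default_rng(8)
        base = rng.integers(0, 8, (12, 12)).astype(float)
        img = Image2D(base)
        exp = expected_image(img, img, bins=8)
        assert np.allclose(exp.pixels, base)

    @pytest.mark.parametrize("seed", range(3))
    def test_ssd_identity_with_scv(self, seed):
        rng = np.random.default_rng(seed)
        a, b = Image2D(rng.random((15, 15))), Image2D(rng.random((15, 15)))
        exp = expected_image(a, b, 12)
        ssd = np.mean((exp.pixels - a.pixels) ** 2)
        assert ssd == pytest.approx(scv(a, b, 12).value, abs=1e-9)

    def test_empty_bins_are_vacuous(self):
        # moving image occupying few bins leaves others empty without error
        a = Image2D(np.arange(16, dtype=float).reshape(4, 4))
        b = Image2D(np.kron(np.array([[0.0, 9.0]]), np.ones((4, 2))))
        exp = expected_image(a, b, bins=16)
        assert np.all(np.isfinite(exp.pixels))
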