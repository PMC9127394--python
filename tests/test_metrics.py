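"""Metric battery vs independent brute-force (direct-loop) oracles."""

import numpy as np
import pytest
from scipy import ndimage

import pseudomod as pm
from pseudomod.metrics import (build_cnr_rois, cnr, dice, error_map,
                               gaussian_window_radius, mae_relative, mssim,
                               mutual_information)

from conftest import full_mask

# ---------------------------------------------------------------------------
# brute-force oracles: naive loops, written independently of the implementation


def oracle_mae(a, b, mask, scale):
    total, n = 0.0, 0
    X, Y, Z = a.shape
    for i in range(X):
        for j in range(Y):
            for k in range(Z):
                if mask[i, j, k]:
                    total += abs(float(a[i, j, k]) - float(b[i, j, k]))
                    n += 1
    return total / n / scale * 100.0


def oracle_dice(a, b):
    inter, na, nb = 0, 0, 0
    for va, vb in zip(a.ravel(), b.ravel()):
        na += bool(va)
        nb += bool(vb)
        inter += bool(va) and bool(vb)
    return 1.0 if (na + nb) == 0 else 2.0 * inter / (na + nb)


def oracle_cnr(vol, gm, wm):
    g = [float(vol[i]) for i in zip(*np.nonzero(gm))]
    w = [float(vol[i]) for i in zip(*np.nonzero(wm))]
    mg, mw = sum(g) / len(g), sum(w) / len(w)
    vg = sum((x - mg) ** 2 for x in g) / len(g)
    vw = sum((x - mw) ** 2 for x in w) / len(w)
    return abs(mg - mw) / np.sqrt((vg + vw) / 2.0)


def oracle_mi(a, b, mask, bins):
    x = a[mask]
    y = b[mask]
    lox, hix = x.min(), x.max()
    loy, hiy = y.min(), y.max()
    joint = np.zeros((bins, bins))
    for xv, yv in zip(x, y):
        bi = min(int((xv - lox) / (hix - lox) * bins), bins - 1)
        bj = min(int((yv - loy) / (hiy - loy) * bins), bins - 1)
        joint[bi, bj] += 1
    p = joint / joint.sum()
    mi = 0.0
    px = p.sum(1)
    py = p.sum(0)
    for i in range(bins):
        for j in range(bins):
            if p[i, j] > 0:
                mi += p[i, j] * np.log(p[i, j] / (px[i] * py[j]))
    return mi


def oracle_mssim(a, b, mask, sigma=1.5, k1=0.01, k2=0.03, L=2000.0):
    r = gaussian_window_radius(sigma)
    w1 = np.exp(-0.5 * (np.arange(-r, r + 1) / sigma) ** 2)
    w1 /= w1.sum()
    w3 = w1[:, None, None] * w1[None, :, None] * w1[None, None, :]
    c1, c2 = (k1 * L) ** 2, (k2 * L) ** 2
    vals = []
    X, Y, Z = a.shape
    for i in range(r, X - r):
        for j in range(r, Y - r):
            for k in range(r, Z - r):
                block = mask[i - r:i + r + 1, j - r:j + r + 1, k - r:k + r + 1]
                if not block.all():
                    continue
                pa = a[i - r:i + r + 1, j - r:j + r + 1, k - r:k + r + 1]
                pb = b[i - r:i + r + 1, j - r:j + r + 1, k - r:k + r + 1]
                mx = (w3 * pa).sum()
                my = (w3 * pb).sum()
                vx = (w3 * pa * pa).sum() - mx * mx
                vy = (w3 * pb * pb).sum() - my * my
                cov = (w3 * pa * pb).sum() - mx * my
                vals.append(((2 * mx * my + c1) * (2 * cov + c2)) /
                            ((mx * mx + my * my + c1) * (vx + vy + c2)))
    return float(np.mean(vals))


# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def fixture_pairs():
    rng = np.random.default_rng(2024)
    pairs = []
    for _ in range(10):
        a = rng.uniform(0, 2000, (12, 12, 12))
        b = np.clip(a + rng.normal(0, 300, (12, 12, 12)), 0, 2000)
        mask = np.ones((12, 12, 12), bool)
        pairs.append((a, b, mask))
    return pairs


class TestOracleEquivalence:
    def test_mae_matches_bruteforce(self, fixture_pairs):
        for a, b, m in fixture_pairs:
            got = mae_relative(pm.ScalarVolume(a), pm.ScalarVolume(b),
                               pm.BinaryMask(m))
            want = oracle_mae(a, b, m, 2000.0)
            assert got == pytest.approx(want, rel=1e-8)

    def test_mssim_matches_bruteforce(self, fixture_pairs):
        for a, b, m in fixture_pairs[:3]:  # loops are slow; 3 fixtures suffice
            got = mssim(pm.ScalarVolume(a), pm.ScalarVolume(b), pm.BinaryMask(m))
            want = oracle_mssim(a, b, m)
            assert got == pytest.approx(want, rel=1e-7)

    def test_dice_matches_bruteforce(self, fixture_pairs):
        for a, b, m in fixture_pairs:
            ma, mb = a > 1000, b > 1000
            got = dice(pm.BinaryMask(ma), pm.BinaryMask(mb))
            assert got == pytest.approx(oracle_dice(ma, mb), rel=1e-12)

    def test_cnr_matches_bruteforce(self, fixture_pairs):
        rng = np.random.default_rng(7)
        for a, _, _ in fixture_pairs:
            gm = rng.random((12, 12, 12)) < 0.3
            wm = ~gm & (rng.random((12, 12, 12)) < 0.3)
            got = cnr(pm.ScalarVolume(a), pm.BinaryMask(gm), pm.BinaryMask(wm))
            assert got == pytest.approx(oracle_cnr(a, gm, wm), rel=1e-8)

    def test_mi_matches_bruteforce(self, fixture_pairs):
        for a, b, m in fixture_pairs:
            got = mutual_information(pm.ScalarVolume(a), pm.ScalarVolume(b),
                                     pm.BinaryMask(m))
            assert got == pytest.approx(oracle_mi(a, b, m, 64), rel=1e-3, abs=1e-9)


class TestErrorMap:
    def test_identical_zero_and_offset_constant(self, rng):
        a = pm.ScalarVolume(rng.uniform(0, 2000, (10, 10, 10)))
        mask = pm.BinaryMask(rng.random((10, 10, 10)) < 0.7)
        assert (error_map(a, a, mask).data == 0).all()
        b = pm.ScalarVolume(a.data + 7.0)
        em = error_map(a, b, mask)
        assert (em.data[mask.data] == pytest.approx(7.0))
        assert (em.data[~mask.data] == 0).all()

    def test_symmetric(self, rng):
        a = pm.ScalarVolume(rng.uniform(0, 2000, (10, 10, 10)))
        b = pm.ScalarVolume(rng.uniform(0, 2000, (10, 10, 10)))
        mask = full_mask((10, 10, 10))
        np.testing.assert_array_equal(error_map(a, b, mask).data,
                                      error_map(b, a, mask).data)


class TestClosedForms:
    def test_mae_constant_offset(self):
        mask = full_mask((8, 8, 8))
        a = pm.ScalarVolume(np.full((8, 8, 8), 500.0))
        b = pm.ScalarVolume(np.full((8, 8, 8), 520.0))
        assert mae_relative(a, b, mask) == pytest.approx(1.0)

    def test_cnr_hand_example(self):
        """GM {98,100,102}, WM {48,50,52}: 50 / sqrt((8/3 + 8/3)/2) ≈ 30.619."""
        vol = np.zeros((3, 3, 3))
        gm = np.zeros((3, 3, 3), bool)
        wm = np.zeros((3, 3, 3), bool)
        vol[0, 0, :] = [98, 100, 102]
        gm[0, 0, :] = True
        vol[1, 0, :] = [48, 50, 52]
        wm[1, 0, :] = True
        got = cnr(pm.ScalarVolume(vol), pm.BinaryMask(gm), pm.BinaryMask(wm))
        assert got == pytest.approx(30.619, abs=1e-3)

    def test_cnr_zero_contrast(self):
        vol = np.zeros((4, 4, 4))
        vol[0] = [[1, 2, 3, 4]] * 4
        vol[1] = [[2, 3, 4, 1]] * 4
        gm = np.zeros((4, 4, 4), bool); gm[0] = True
        wm = np.zeros((4, 4, 4), bool); wm[1] = True
        assert cnr(pm.ScalarVolume(vol), pm.BinaryMask(gm),
                   pm.BinaryMask(wm)) == pytest.approx(0.0)

    def test_dice_half_overlap(self):
        a = np.zeros((10, 10, 10), bool)
        b = np.zeros((10, 10, 10), bool)
        a.ravel()[:100] = True
        b.ravel()[50:150] = True
        assert dice(pm.BinaryMask(a), pm.BinaryMask(b)) == pytest.approx(0.5)

    def test_dice_identical_and_disjoint(self):
        a = np.zeros((6, 6, 6), bool); a[0] = True
        b = np.zeros((6, 6, 6), bool); b[1] = True
        assert dice(pm.BinaryMask(a), pm.BinaryMask(a)) == 1.0
        assert dice(pm.BinaryMask(a), pm.BinaryMask(b)) == 0.0


class TestMssimProperties:
    def test_self_similarity_is_one(self, rng):
        x = pm.ScalarVolume(rng.uniform(0, 2000, (14, 14, 14)))
        assert mssim(x, x, full_mask((14, 14, 14))) == pytest.approx(1.0)

    def test_anticorrelation_negative(self):
        """Inverting a zero-mean pattern drives the structure term negative."""
        # frequency high enough that windowed local means stay near zero
        idx = np.meshgrid(*[np.arange(16)] * 3, indexing="ij")
        x = 800.0 * np.sin(2.0 * idx[0]) * np.cos(1.7 * idx[1])
        a = pm.ScalarVolume(x)
        b = pm.ScalarVolume(-x)
        assert mssim(a, b, full_mask((16, 16, 16))) < 0

    def test_symmetric(self, rng):
        a = pm.ScalarVolume(rng.uniform(0, 2000, (14, 14, 14)))
        b = pm.ScalarVolume(rng.uniform(0, 2000, (14, 14, 14)))
        mask = full_mask((14, 14, 14))
        assert mssim(a, b, mask) == pytest.approx(mssim(b, a, mask), rel=1e-12)

    def test_thin_mask_rejected(self):
        mask = pm.BinaryMask(np.zeros((12, 12, 12), bool))
        mask.data[6, 6, 6] = True
        x = pm.ScalarVolume(np.random.default_rng(0).random((12, 12, 12)))
        with pytest.raises(ValueError, match="thin"):
            mssim(x, x, mask)


class TestCnrRois:
    def test_gm_slab_one_voxel_shell(self):
        """A thick GM slab yields a single-voxel sheet strictly inside GM."""
        labels = np.zeros((20, 12, 12), np.int16)
        labels[2:12] = 2    # 10-voxel-thick GM slab
        labels[12:18] = 3   # WM to satisfy the recipe (eroded away -> error)
        lab = pm.LabelVolume(labels)
        with pytest.raises(ValueError, match="vanished"):
            build_cnr_rois(lab)  # WM slab too thin for 5-voxel erosion
        labels2 = np.zeros((40, 14, 14), np.int16)
        labels2[2:12] = 2
        labels2[12:38] = 3
        gm_roi, wm_roi = build_cnr_rois(pm.LabelVolume(labels2))
        gm = labels2 == 2
        # shell voxels are inside GM, exactly the erode(1) \ erode(2) band
        assert gm_roi.data[~gm].sum() == 0
        e1 = ndimage.binary_erosion(gm, ndimage.generate_binary_structure(3, 1), 1)
        e2 = ndimage.binary_erosion(gm, ndimage.generate_binary_structure(3, 1), 2)
        np.testing.assert_array_equal(gm_roi.data, e1 & ~e2)
        assert not (gm_roi.data & wm_roi.data).any()

    def test_small_wm_ball_raises(self):
        labels = np.zeros((20, 20, 20), np.int16)
        labels[4:16, 4:16, 4:16] = 2
        c = np.array([10, 10, 10])
        idx = np.indices((20, 20, 20))
        ball = ((idx - c[:, None, None, None]) ** 2).sum(0) <= 9
        labels[ball] = 3
        with pytest.raises(ValueError, match="vanished"):
            build_cnr_rois(pm.LabelVolume(labels))

    def test_phantom_rois_disjoint(self, base_anatomy):
        labels, _ = base_anatomy
        gm_roi, wm_roi = build_cnr_rois(labels)
        assert not (gm_roi.data & wm_roi.data).any()
        assert gm_roi.n_voxels > 0 and wm_roi.n_voxels > 0


class TestCnrInvariance:
    def test_affine_intensity_invariance(self, base_anatomy, default_spec):
        labels, _ = base_anatomy
        vol = pm.render_modality(labels, default_spec, "T2w", 5)
        gm_roi, wm_roi = build_cnr_rois(labels)
        base = cnr(vol, gm_roi, wm_roi)
        scaled = pm.ScalarVolume(3.7 * vol.data + 250.0)
        assert cnr(scaled, gm_roi, wm_roi) == pytest.approx(base, rel=1e-12)


class TestMutualInformation:
    def test_identity_equals_marginal_entropy(self, rng):
        a = pm.ScalarVolume(rng.uniform(0, 2000, (12, 12, 12)))
        mask = full_mask((12, 12, 12))
        mi = mutual_information(a, a, mask)
        hist, _ = np.histogram(a.data[mask.data], bins=64)
        p = hist / hist.sum()
        h = -(p[p > 0] * np.log(p[p > 0])).sum()
        assert mi == pytest.approx(h, rel=1e-10)

    def test_monotone_transform_preserves_mi(self, rng):
        a = pm.ScalarVolume(rng.uniform(0, 2000, (12, 12, 12)))
        b = pm.ScalarVolume(2000.0 - a.data)
        mask = full_mask((12, 12, 12))
        assert mutual_information(a, b, mask) == pytest.approx(
            mutual_information(a, a, mask), rel=1e-10)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(0)
        shape = (50, 50, 40)  # 1e5 voxels
        a = pm.ScalarVolume(rng.uniform(0, 2000, shape))
        b = pm.ScalarVolume(rng.uniform(0, 2000, shape))
        mask = pm.BinaryMask(np.ones(shape, bool))
        assert mutual_information(a, b, mask) < 0.05

    def test_constant_image_warns_zero(self):
        mask = full_mask((8, 8, 8))
        a = pm.ScalarVolume(np.full((8, 8, 8), 3.0))
        b = pm.ScalarVolume(np.arange(512, dtype=float).reshape(8, 8, 8))
        with pytest.warns(UserWarning, match="constant"):
            assert mutual_information(a, b, mask) == 0.0

    def test_symmetric_and_bounded(self, rng):
        a = pm.ScalarVolume(rng.uniform(0, 2000, (12, 12, 12)))
        b = pm.ScalarVolume(np.clip(a.data + rng.normal(0, 200, a.shape), 0, 2000))
        mask = full_mask((12, 12, 12))
        mab = mutual_information(a, b, mask)
        mba = mutual_information(b, a, mask)
        assert mab == pytest.approx(mba, rel=1e-10)
        ha = mutual_information(a, a, mask)
        hb = mutual_information(b, b, mask)
        assert 0 <= mab <= min(ha, hb) + 1e-9
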