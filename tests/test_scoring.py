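"""Overlap metrics, surface distances and the uncertainty score."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from sphereseg.images import BinaryMask, UncertaintyMap
from sphereseg.scoring import (
    confusion_counts,
    dice,
    evaluate_case,
    hausdorff,
    surface_points,
    uscore,
    uscore_curves,
)


def unc_from_normalized(norm: np.ndarray, support: int = 4) -> UncertaintyMap:
    return UncertaintyMap(
        entropy=norm / 100.0 * np.log(2),
        normalized=norm,
        value_bins=2,
        support=support,
    )


def mask(arr) -> BinaryMask:
    return BinaryMask(np.asarray(arr, dtype=np.uint8))


class TestConfusion:
    def test_identical_masks(self):
        m = mask(np.eye(6, dtype=int))
        assert confusion_counts(m, m) == (6, 30, 0, 0)

    def test_complement(self):
        g = mask(np.eye(6, dtype=int))
        p = mask(1 - np.eye(6, dtype=int))
        assert confusion_counts(p, g) == (0, 0, 30, 6)

    def test_matches_naive_tally(self):
        rng = np.random.default_rng(2)
        p = mask(rng.integers(0, 2, (16, 16)))
        g = mask(rng.integers(0, 2, (16, 16)))
        tp = tn = fp = fn = 0
        for i in range(16):
            for j in range(16):
                if p.pixels[i, j] and g.pixels[i, j]:
                    tp += 1
                elif not p.pixels[i, j] and not g.pixels[i, j]:
                    tn += 1
                elif p.pixels[i, j]:
                    fp += 1
                else:
                    fn += 1
        assert confusion_counts(p, g) == (tp, tn, fp, fn)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            confusion_counts(mask(np.zeros((4, 4))), mask(np.zeros((5, 5))))


class TestDice:
    def test_identical_nonempty(self):
        m = mask(np.ones((3, 3)))
        assert dice(m, m) == 1.0

    def test_disjoint(self):
        a = np.zeros((4, 4)); a[0, 0] = 1
        b = np.zeros((4, 4)); b[3, 3] = 1
        assert dice(mask(a), mask(b)) == 0.0

    def test_half_overlap(self):
        a = np.zeros((4, 4)); a[0, :4] = 1
        b = np.zeros((4, 4)); b[0, 2:4] = 1; b[1, 0:2] = 1
        assert dice(mask(a), mask(b)) == 0.5

    def test_both_empty_convention(self):
        z = mask(np.zeros((4, 4)))
        assert dice(z, z) == 1.0


class TestUScoreCurves:
    def test_zero_uncertainty_gives_flat_curves(self):
        rng = np.random.default_rng(4)
        p = mask(rng.integers(0, 2, (8, 8)))
        g = mask(rng.integers(0, 2, (8, 8)))
        u = unc_from_normalized(np.zeros((8, 8)))
        curves = uscore_curves(p, g, u)
        np.testing.assert_allclose(curves.dsc_curve, dice(p, g))
        np.testing.assert_allclose(curves.ftp_curve, 0.0)
        np.testing.assert_allclose(curves.ftn_curve, 0.0)

    def test_tau_100_is_unfiltered(self):
        rng = np.random.default_rng(5)
        p = mask(rng.integers(0, 2, (8, 8)))
        g = mask(rng.integers(0, 2, (8, 8)))
        u = unc_from_normalized(rng.uniform(0, 100, (8, 8)))
        curves = uscore_curves(p, g, u)
        assert curves.ftp_curve[-1] == 0.0
        assert curves.ftn_curve[-1] == 0.0
        assert curves.dsc_curve[-1] == pytest.approx(dice(p, g))

    def test_worked_4x4_fixture_matches_brute_force(self):
        pred = mask([[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 0, 0], [0, 1, 0, 1]])
        gt = mask([[1, 1, 0, 0], [1, 0, 0, 0], [0, 0, 0, 0], [0, 0, 1, 1]])
        norm = np.array(
            [
                [5.0, 10.0, 0.0, 0.0],
                [20.0, 80.0, 0.0, 15.0],
                [0.0, 30.0, 55.0, 0.0],
                [45.0, 95.0, 70.0, 25.0],
            ]
        )
        u = unc_from_normalized(norm)
        curves = uscore_curves(pred, gt, u)
        for i, tau in enumerate(range(1, 101)):
            inc = np.ones((4, 4), bool) if tau == 100 else (norm < tau)
            tp = int(np.sum(pred.pixels.astype(bool) & gt.pixels.astype(bool) & inc))
            tn = int(np.sum(~pred.pixels.astype(bool) & ~gt.pixels.astype(bool) & inc))
            fp = int(np.sum(pred.pixels.astype(bool) & ~gt.pixels.astype(bool) & inc))
            fn = int(np.sum(~pred.pixels.astype(bool) & gt.pixels.astype(bool) & inc))
            assert curves.tp_counts[i] == tp
            assert curves.tn_counts[i] == tn
            d = 1.0 if (2 * tp + fp + fn) == 0 else 2 * tp / (2 * tp + fp + fn)
            assert curves.dsc_curve[i] == pytest.approx(d)
        tp100, tn100 = curves.unfiltered
        np.testing.assert_allclose(curves.ftp_curve, (tp100 - curves.tp_counts) / tp100)
        np.testing.assert_allclose(curves.ftn_curve, (tn100 - curves.tn_counts) / tn100)

    def test_no_true_positives_flagged_degenerate(self):
        p = mask(np.zeros((4, 4)))
        g = mask(np.ones((4, 4)))
        u = unc_from_normalized(np.zeros((4, 4)))
        curves = uscore_curves(p, g, u)
        assert curves.degenerate
        np.testing.assert_allclose(curves.ftp_curve, 0.0)


class TestUScore:
    def test_perfect_prediction_zero_uncertainty(self):
        g = mask([[1, 1, 0, 0]] * 4)
        u = unc_from_normalized(np.zeros((4, 4)))
        report = uscore(uscore_curves(g, g, u))
        assert report.auc1 == 1.0
        assert report.auc2 == 0.0
        assert report.auc3 == 0.0
        assert report.u_score == 1.0

    def test_constant_curves_composite(self):
        from sphereseg.scoring import UScoreCurves

        curves = UScoreCurves(
            thresholds=np.arange(1, 101),
            dsc_curve=np.full(100, 0.5),
            ftp_curve=np.zeros(100),
            ftn_curve=np.zeros(100),
            tp_counts=np.ones(100, dtype=int),
            tn_counts=np.ones(100, dtype=int),
            unfiltered=(1, 1),
        )
        assert uscore(curves).u_score == pytest.approx((0.5 + 1 + 1) / 3)

    def test_auc_matches_dense_rectangle_oracle(self):
        rng = np.random.default_rng(6)
        p = mask(rng.integers(0, 2, (12, 12)))
        g = mask(rng.integers(0, 2, (12, 12)))
        u = unc_from_normalized(rng.uniform(0, 100, (12, 12)))
        curves = uscore_curves(p, g, u)
        report = uscore(curves)
        x = (curves.thresholds - 1) / 99.0
        fine = np.linspace(0, 1, 2_000_001)
        for curve, got in [
            (curves.dsc_curve, report.auc1),
            (curves.ftp_curve, report.auc2),
            (curves.ftn_curve, report.auc3),
        ]:
            rect = np.interp(fine, x, curve).mean()
            assert got == pytest.approx(rect, abs=1e-6)

    def test_uncertainty_on_errors_never_hurts(self):
        """Raising uncertainty only on erroneous pixels cannot lower the
        U-score: errors get excluded earlier, TP/TN counts are untouched."""
        pred = mask([[1, 1, 0, 0], [1, 0, 0, 0], [0, 0, 1, 0], [0, 0, 0, 0]])
        gt = mask([[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 0, 0], [0, 0, 0, 0]])
        base = np.full((4, 4), 10.0)
        raised = base.copy()
        errors = pred.pixels.astype(bool) ^ gt.pixels.astype(bool)
        raised[errors] = 90.0
        s0 = uscore(uscore_curves(pred, gt, unc_from_normalized(base))).u_score
        s1 = uscore(uscore_curves(pred, gt, unc_from_normalized(raised))).u_score
        assert s1 >= s0


class TestSurfacePoints:
    def test_single_pixel(self):
        m = np.zeros((5, 5)); m[2, 3] = 1
        np.testing.assert_array_equal(surface_points(mask(m)), [[2, 3]])

    def test_filled_square_perimeter(self):
        m = np.zeros((8, 8)); m[2:6, 2:6] = 1
        pts = surface_points(mask(m))
        assert len(pts) == 12
        assert not any((r, c) in [(3, 3), (3, 4), (4, 3), (4, 4)] for r, c in map(tuple, pts))

    def test_matches_naive_neighbor_scan(self):
        rng = np.random.default_rng(8)
        m = (rng.random((20, 20)) > 0.6).astype(np.uint8)
        pts = set(map(tuple, surface_points(mask(m))))
        expected = set()
        for i in range(20):
            for j in range(20):
                if not m[i, j]:
                    continue
                on_border = i in (0, 19) or j in (0, 19)
                nbrs = [
                    m[i + di, j + dj]
                    for di, dj in [(-1, 0), (1, 0), (0, -1), (0, 1)]
                    if 0 <= i + di < 20 and 0 <= j + dj < 20
                ]
                if on_border or 0 in nbrs:
                    expected.add((i, j))
        assert pts == expected

    def test_empty_mask(self):
        assert len(surface_points(mask(np.zeros((4, 4))))) == 0


def brute_force_hausdorff(pred: BinaryMask, gt: BinaryMask):
    sp = surface_points(pred).astype(float)
    sg = surface_points(gt).astype(float)
    d = cdist(sp, sg)
    pooled = np.concatenate([d.min(axis=1), d.min(axis=0)])
    spacing_cm = pred.pixel_spacing / 10.0
    return pooled.mean() * spacing_cm, np.percentile(pooled, 95) * spacing_cm


class TestHausdorff:
    def test_identical_masks_zero_distance(self):
        m = mask(np.pad(np.ones((4, 4)), 2).astype(int))
        mhd, hd95, ok = hausdorff(m, m)
        assert (mhd, hd95, ok) == (0.0, 0.0, True)

    def test_two_pixels_30px_apart(self):
        a = np.zeros((64, 64)); a[10, 10] = 1
        b = np.zeros((64, 64)); b[10, 40] = 1
        mhd, hd95, ok = hausdorff(mask(a), mask(b))
        assert mhd == pytest.approx(3.0)
        assert hd95 == pytest.approx(3.0)

    def test_shifted_square_matches_brute_force(self):
        a = np.zeros((24, 24)); a[5:14, 5:14] = 1
        b = np.zeros((24, 24)); b[8:17, 5:14] = 1
        got = hausdorff(mask(a), mask(b))[:2]
        expected = brute_force_hausdorff(mask(a), mask(b))
        np.testing.assert_allclose(got, expected, atol=1e-9)

    def test_random_masks_match_brute_force(self):
        rng = np.random.default_rng(10)
        for _ in range(10):
            a = (rng.random((32, 32)) > 0.7).astype(np.uint8)
            b = (rng.random((32, 32)) > 0.7).astype(np.uint8)
            got = hausdorff(mask(a), mask(b))[:2]
            expected = brute_force_hausdorff(mask(a), mask(b))
            np.testing.assert_allclose(got, expected, atol=1e-9)

    def test_symmetry_and_translation_invariance(self):
        rng = np.random.default_rng(12)
        a = np.zeros((40, 40)); a[5:15, 5:15] = rng.integers(0, 2, (10, 10))
        b = np.zeros((40, 40)); b[8:18, 10:20] = rng.integers(0, 2, (10, 10))
        ma, mb = mask(a), mask(b)
        np.testing.assert_allclose(hausdorff(ma, mb)[:2], hausdorff(mb, ma)[:2], rtol=1e-12)
        ta, tb = mask(np.roll(a, (4, 6), (0, 1))), mask(np.roll(b, (4, 6), (0, 1)))
        np.testing.assert_allclose(hausdorff(ma, mb)[:2], hausdorff(ta, tb)[:2], atol=1e-9)

    def test_empty_mask_flagged(self):
        mhd, hd95, ok = hausdorff(mask(np.zeros((8, 8))), mask(np.ones((8, 8))))
        assert not ok and np.isinf(mhd) and np.isinf(hd95)

    def test_spacing_scales_distances(self):
        a = np.zeros((32, 32)); a[10, 10] = 1
        b = np.zeros((32, 32)); b[10, 20] = 1
        m1 = hausdorff(BinaryMask(a.astype(np.uint8), 1.0), BinaryMask(b.astype(np.uint8), 1.0))[0]
        m2 = hausdorff(BinaryMask(a.astype(np.uint8), 2.0), BinaryMask(b.astype(np.uint8), 2.0))[0]
        assert m2 == pytest.approx(2 * m1)


class TestEvaluateCase:
    def test_perfect_prediction(self):
        g = mask(np.pad(np.ones((5, 5)), 3).astype(int))
        report, _ = evaluate_case(g, g)
        r = report.per_slice[0]
        assert r.accuracy == r.sensitivity == r.specificity == r.dsc == 1.0
        assert r.mhd_cm == r.hd95_cm == 0.0

    def test_all_background_prediction(self):
        g = mask(np.pad(np.ones((4, 4)), 2).astype(int))
        p = mask(np.zeros_like(g.pixels))
        report, _ = evaluate_case(p, g)
        r = report.per_slice[0]
        assert r.sensitivity == 0.0
        assert r.specificity == 1.0
        assert not r.distance_valid
        assert report.n_distance_excluded == 1

    def test_aggregates_match_hand_computation(self):
        rng = np.random.default_rng(13)
        preds, gts = [], []
        for _ in range(10):
            g = np.zeros((24, 24)); g[4:14, 4:14] = 1
            p = g.copy()
            flip = rng.integers(0, 24, size=(6, 2))
            p[flip[:, 0], flip[:, 1]] = 1 - p[flip[:, 0], flip[:, 1]]
            preds.append(mask(p)); gts.append(mask(g))
        report, _ = evaluate_case(preds, gts)
        dscs = [dice(p, g) for p, g in zip(preds, gts)]
        assert report.aggregate["dsc"][0] == pytest.approx(np.mean(dscs))
        assert report.aggregate["dsc"][1] == pytest.approx(np.std(dscs, ddof=1))
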