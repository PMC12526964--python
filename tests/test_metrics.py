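"""Metric closed forms and independent-oracle cross-checks (including a
loop-based MS-SSIM reference and scipy's paired t-test)."""

import numpy as np
import pytest
import scipy.stats

from dualdecomp import metrics as mk


class TestMAE:
    def test_identical_images_give_zero(self):
        img = np.random.default_rng(0).integers(0, 256, (8, 8))
        assert mk.mae(img, img) == 0.0

    def test_constant_offset(self):
        assert mk.mae(np.full((4, 4), 61), np.full((4, 4), 10)) == 51.0

    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(1)
        a = rng.integers(0, 256, (16, 16))
        b = rng.integers(0, 256, (16, 16))
        ref = sum(abs(int(x) - int(y)) for x, y in zip(a.ravel(), b.ravel())) / 256
        assert mk.mae(a, b) == pytest.approx(ref, abs=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mk.mae(np.zeros((2, 2)), np.zeros((3, 3)))


class TestPSNR:
    def test_full_scale_difference_is_zero_db(self):
        assert mk.psnr(np.full((4, 4), 255.0), np.zeros((4, 4))) == pytest.approx(0.0)

    def test_unit_difference_closed_form(self):
        a = np.zeros((4, 4))
        assert mk.psnr(a + 1.0, a) == pytest.approx(10 * np.log10(255 ** 2), abs=1e-9)
        assert mk.psnr(a + 1.0, a) == pytest.approx(48.13, abs=0.01)

    def test_identical_images_report_infinity(self):
        img = np.random.default_rng(2).integers(0, 256, (8, 8))
        assert mk.psnr(img, img) == np.inf

    def test_strictly_decreasing_in_mse(self):
        base = np.zeros((4, 4))
        vals = [mk.psnr(base + d, base) for d in (1.0, 2.0, 4.0)]
        assert vals[0] > vals[1] > vals[2]


class TestPearson:
    def test_positive_affine_invariance(self):
        g = np.random.default_rng(3).normal(size=(8, 8))
        assert mk.pearson_r(2 * g + 5, g) == pytest.approx(1.0)

    def test_sign_flip(self):
        g = np.random.default_rng(4).normal(size=(8, 8))
        assert mk.pearson_r(-g, g) == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=(8, 8)), rng.normal(size=(8, 8))
        x, y = a.ravel(), b.ravel()
        ref = (np.sum((x - x.mean()) * (y - y.mean()))
               / np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)))
        assert mk.pearson_r(a, b) == pytest.approx(ref, abs=1e-12)

    def test_constant_image_gives_nan_sentinel(self):
        assert np.isnan(mk.pearson_r(np.full((4, 4), 3.0),
                                     np.random.default_rng(6).normal(size=(4, 4))))


def _msssim_oracle(x, y, scales, window=11, sigma=1.5, max_value=255.0):
    """Direct per-pixel windowed implementation of the multi-scale product."""
    gx = np.arange(window) - (window - 1) / 2
    k1d = np.exp(-(gx ** 2) / (2 * sigma ** 2))
    k1d /= k1d.sum()
    kern = np.outer(k1d, k1d)
    c1 = (0.01 * max_value) ** 2
    c2 = (0.03 * max_value) ** 2
    weights = np.asarray(mk.MSSSIM_WEIGHTS[:scales])
    weights = weights / weights.sum()
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    result = 1.0
    for j in range(scales):
        h, w = x.shape
        lums, css = [], []
        for r in range(h - window + 1):
            for c in range(w - window + 1):
                px = x[r:r + window, c:c + window]
                py = y[r:r + window, c:c + window]
                mx = float((px * kern).sum())
                my = float((py * kern).sum())
                vx = float((px * px * kern).sum()) - mx * mx
                vy = float((py * py * kern).sum()) - my * my
                cov = float((px * py * kern).sum()) - mx * my
                lums.append((2 * mx * my + c1) / (mx ** 2 + my ** 2 + c1))
                css.append((2 * cov + c2) / (vx + vy + c2))
        lums, css = np.asarray(lums), np.asarray(css)
        if j == scales - 1:
            result *= max((lums * css).mean(), 0.0) ** weights[j]
        else:
            result *= max(css.mean(), 0.0) ** weights[j]
            h2, w2 = (h // 2) * 2, (w // 2) * 2
            x = x[:h2, :w2].reshape(h2 // 2, 2, w2 // 2, 2).mean(axis=(1, 3))
            y = y[:h2, :w2].reshape(h2 // 2, 2, w2 // 2, 2).mean(axis=(1, 3))
    return result


class TestMSSSIM:
    def test_identical_images_give_one(self):
        img = np.random.default_rng(7).integers(0, 256, (64, 64))
        assert mk.ms_ssim(img, img, scales=3) == pytest.approx(1.0, abs=1e-12)

    def test_negative_image_scores_below_one(self):
        img = np.random.default_rng(8).integers(0, 256, (64, 64))
        assert mk.ms_ssim(255 - img, img, scales=3) < 1.0

    def test_matches_independent_loop_oracle_on_64x64_pair(self):
        rng = np.random.default_rng(9)
        gt = rng.integers(0, 256, (64, 64)).astype(float)
        pred = np.clip(gt + rng.normal(0, 20, (64, 64)), 0, 255)
        ours = mk.ms_ssim(pred, gt, scales=3)
        ref = _msssim_oracle(pred, gt, scales=3)
        assert ours == pytest.approx(ref, abs=1e-6)

    def test_single_scale_close_to_skimage_ssim(self):
        from skimage.metrics import structural_similarity

        rng = np.random.default_rng(10)
        gt = rng.integers(0, 256, (64, 64)).astype(float)
        pred = np.clip(gt + rng.normal(0, 15, (64, 64)), 0, 255)
        ours = mk.ms_ssim(pred, gt, scales=1)
        ref = structural_similarity(pred, gt, gaussian_weights=True, sigma=1.5,
                                    use_sample_covariance=False, data_range=255)
        # conventions differ slightly at the borders; agreement is approximate
        assert ours == pytest.approx(ref, abs=0.01)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(11)
        a = rng.integers(0, 256, (64, 64)).astype(float)
        b = rng.integers(0, 256, (64, 64)).astype(float)
        assert mk.ms_ssim(a, b, scales=3) == pytest.approx(
            mk.ms_ssim(b, a, scales=3), abs=1e-9)

    def test_too_small_image_names_minimum_size(self):
        with pytest.raises(ValueError, match="176"):
            mk.ms_ssim(np.zeros((64, 64)), np.zeros((64, 64)), scales=5)


class TestEvaluatePairs:
    def test_identical_pairs_give_perfect_aggregates(self):
        rng = np.random.default_rng(12)
        imgs = [rng.integers(0, 256, (64, 64)) for _ in range(3)]
        rep = mk.evaluate_pairs(imgs, imgs, scales=3)
        assert rep.aggregates["mae"] == (0.0, 0.0)
        assert rep.aggregates["ms_ssim"][0] == pytest.approx(1.0)
        assert rep.n == 3

    def test_mean_and_sample_std_of_known_maes(self):
        gt = [np.zeros((64, 64)), np.zeros((64, 64))]
        pred = [np.full((64, 64), 2.0), np.full((64, 64), 4.0)]
        rep = mk.evaluate_pairs(pred, gt, scales=3)
        mean, std = rep.aggregates["mae"]
        assert mean == pytest.approx(3.0)
        assert std == pytest.approx(np.sqrt(2.0))

    def test_aggregates_permutation_invariant(self):
        rng = np.random.default_rng(13)
        gts = [rng.integers(0, 256, (64, 64)) for _ in range(4)]
        preds = [np.clip(g + rng.integers(-9, 10, g.shape), 0, 255) for g in gts]
        r1 = mk.evaluate_pairs(preds, gts, scales=3)
        r2 = mk.evaluate_pairs(preds[::-1], gts[::-1], scales=3)
        for k in r1.aggregates:
            assert r1.aggregates[k] == pytest.approx(r2.aggregates[k])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mk.evaluate_pairs([np.zeros((8, 8))], [])


class TestPairedTTest:
    def test_identical_lists_give_t0_p1(self):
        res = mk.paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0 and res.p_value == 1.0 and res.df == 2

    def test_constant_nonzero_difference_is_tie_sentinel(self):
        res = mk.paired_t_test([2.0, 3.0, 4.0, 5.0], [1.0, 2.0, 3.0, 4.0])
        assert res.tie and res.p_value == 0.0 and np.isinf(res.t)

    def test_hand_computed_example(self):
        # differences (1, 2, 3): mean 2, sd 1, t = 2 * sqrt(3)
        res = mk.paired_t_test([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert res.t == pytest.approx(2 * np.sqrt(3), abs=1e-9)
        assert res.t == pytest.approx(3.4641, abs=1e-4)
        assert res.df == 2

    def test_matches_scipy_on_random_samples(self):
        rng = np.random.default_rng(14)
        for _ in range(100):
            n = int(rng.integers(3, 30))
            a = rng.normal(size=n)
            b = a + rng.normal(0.2, 0.5, size=n)
            ours = mk.paired_t_test(a, b)
            ref = scipy.stats.ttest_rel(a, b)
            assert ours.t == pytest.approx(ref.statistic, abs=1e-9)
            assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-9)

    def test_significance_tiers(self):
        res = mk.TTestResult(t=9.0, df=10, p_value=3e-5)
        assert res.significant and res.extremely_significant


class TestLineProfile:
    def test_constant_image_gives_constant_profile(self):
        prof = mk.line_profile(np.full((16, 16), 7.0), (8, 1), (8, 14), 10)
        np.testing.assert_allclose(prof.values, 7.0)

    def test_axis_aligned_line_on_ramp_is_linear(self):
        img = np.tile(np.arange(16, dtype=float), (16, 1))
        prof = mk.line_profile(img, (5, 0), (5, 15), 16)
        np.testing.assert_allclose(prof.values, np.arange(16), atol=1e-12)

    def test_diagonal_line_matches_bilinear_oracle(self):
        rng = np.random.default_rng(15)
        img = rng.normal(size=(16, 16))
        p0, p1, n = (2.0, 3.0), (13.0, 11.0), 9
        prof = mk.line_profile(img, p0, p1, n)
        for j, t in enumerate(np.linspace(0, 1, n)):
            r = p0[0] + t * (p1[0] - p0[0])
            c = p0[1] + t * (p1[1] - p0[1])
            r0, c0 = int(np.floor(r)), int(np.floor(c))
            fr, fc = r - r0, c - c0
            r1c, c1c = min(r0 + 1, 15), min(c0 + 1, 15)
            ref = (img[r0, c0] * (1 - fr) * (1 - fc) + img[r1c, c0] * fr * (1 - fc)
                   + img[r0, c1c] * (1 - fr) * fc + img[r1c, c1c] * fr * fc)
            assert prof.values[j] == pytest.approx(ref, abs=1e-9)

    def test_endpoints_sampled_exactly(self):
        img = np.arange(64, dtype=float).reshape(8, 8)
        prof = mk.line_profile(img, (1, 1), (6, 5), 5)
        assert prof.values[0] == pytest.approx(img[1, 1])
        assert prof.values[-1] == pytest.approx(img[6, 5])

    def test_out_of_bounds_endpoint_rejected(self):
        with pytest.raises(ValueError):
            mk.line_profile(np.zeros((8, 8)), (0, 0), (9, 2), 4)


class TestSeparationReport:
    def test_ideal_decomposition_scores_zero(self):
        rng = np.random.default_rng(16)
        conv = rng.integers(0, 256, (32, 32)).astype(float)
        rep = mk.separation_report(conv, conv, np.full((32, 32), 4.0),
                                   bone_line=((5, 2), (5, 29)),
                                   iodine_line=((20, 2), (20, 29)))
        assert rep["bone_retention"] == 0.0
        assert rep["bone_suppression_var"] == 0.0

    def test_constant_offset_retention(self):
        conv = np.zeros((32, 32))
        rep = mk.separation_report(conv, conv + 5.0, conv,
                                   bone_line=((5, 2), (5, 29)),
                                   iodine_line=((20, 2), (20, 29)))
        assert rep["bone_retention"] == pytest.approx(5.0)

    def test_exact_decomposition_separates_single_material_rois(self, table, test_spec):
        """On a noiseless phantom, lines through bone-only / iodine-only
        regions show flat contaminant-channel profiles and lower
        matched-channel distance than the swapped assignment."""
        from dualdecomp.phantom import (conv_projection, counts_to_log_projection,
                                        exact_decompose, forward_counts,
                                        generate_phantom)

        mm = generate_phantom(test_spec)
        counts = forward_counts(mm, table, noise=False)
        p_low, p_high = counts_to_log_projection(counts)
        tb, ti = exact_decompose(p_low, p_high, table, mm.t_soft)
        conv = conv_projection(counts)

        def norm(a):
            return (a - a.min()) / (a.max() - a.min() + 1e-12)

        def roi_line(target, other, min_t):
            # longest contiguous single-material run in the densest row
            mask = (target > min_t) & (other < 1e-9)
            row = np.argmax(mask.sum(axis=1))
            best, run = None, []
            for c in range(mask.shape[1]):
                if mask[row, c]:
                    run.append(c)
                    if best is None or len(run) > len(best):
                        best = list(run)
                else:
                    run = []
            return (float(row), float(best[0])), (float(row), float(best[-1]))

        bone_line = roi_line(mm.t_bone, mm.t_iodine, 0.02)
        iodine_line = roi_line(mm.t_iodine, mm.t_bone, 0.01)
        rep = mk.separation_report(norm(conv), norm(tb), norm(ti),
                                   bone_line, iodine_line)
        swapped = mk.separation_report(norm(conv), norm(ti), norm(tb),
                                       bone_line, iodine_line)
        # matched channel tracks the conventional image better than the
        # contaminant channel along each single-material line
        assert rep["bone_retention"] < swapped["bone_retention"]
        assert rep["iodine_retention"] < swapped["iodine_retention"]
        # contaminant channels are flatter than the conventional image
        for name, line in (("bone", bone_line), ("iodine", iodine_line)):
            conv_var = float(np.var(mk.line_profile(norm(conv), *line, 64).values))
            assert rep[f"{name}_suppression_var"] < conv_var
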