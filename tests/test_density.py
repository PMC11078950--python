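"""Density metrics: ROI means, layer ratios, multiscale variance, FWHM, SSIM."""

import warnings

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from musical.core import MusicalParams, image_threshold, reconstruct
from musical.density import (GeometryError, InsufficientDataError, LayerMask,
                             ROISpec, density_fidelity, fibril_width,
                             group_comparison, layer_ratio,
                             multiscale_variance, paired_ttest,
                             roi_mean_density, ssim, width_histogram)
from musical.phantom import (CameraModel, FibrilPhantom, FluctuationModel,
                             _count_raster, blur_density, generate_fibrils,
                             place_emitters, render_stack,
                             simulate_fluctuations)


class TestRoiMeanDensity:
    def test_uniform_image(self):
        img = np.full((50, 50), 3.25)
        assert roi_mean_density(img, ROISpec((5, 5), (20, 20))) == 3.25

    def test_checkerboard(self):
        img = np.indices((40, 40)).sum(axis=0) % 2
        assert roi_mean_density(img, ROISpec((0, 0), (10, 10))) == 0.5

    def test_matches_naive_double_loop(self, rng):
        img = rng.uniform(size=(30, 30))
        roi = ROISpec((4, 7), (11, 13))
        acc = 0.0
        for i in range(4, 15):
            for j in range(7, 20):
                acc += img[i, j]
        assert roi_mean_density(img, roi) == pytest.approx(acc / (11 * 13),
                                                           abs=1e-12)

    def test_mostly_masked_roi_rejected(self, rng):
        img = rng.uniform(size=(20, 20))
        mask = np.zeros((20, 20), dtype=bool)
        mask[:3] = True
        with pytest.raises(InsufficientDataError):
            roi_mean_density(img, ROISpec((0, 0), (10, 10)), valid_mask=mask)

    def test_out_of_bounds_roi_rejected(self, rng):
        with pytest.raises(GeometryError):
            roi_mean_density(rng.uniform(size=(10, 10)),
                             ROISpec((5, 5), (10, 10)))

    def test_camera_roi_scales_to_subpixel_grid(self):
        roi = ROISpec((2, 3), (4, 5))
        scaled = roi.scaled(10)
        assert scaled.origin == (20, 30) and scaled.size == (40, 50)


class TestLayerRatio:
    def test_identical_masks(self, rng):
        img = rng.uniform(1, 2, (20, 20))
        m = LayerMask("E", np.ones((20, 20), bool))
        assert layer_ratio(img, m, m) == 1.0

    def test_two_to_one(self):
        img = np.ones((10, 10))
        img[:5] = 2.0
        top = LayerMask("SE", np.arange(10)[:, None] < 5 * np.ones(10, bool))
        bot = LayerMask("E", ~top.mask)
        assert layer_ratio(img, top, bot) == 2.0

    def test_scale_free(self, rng):
        img = rng.uniform(1, 5, (20, 20))
        a = LayerMask("a", rng.uniform(size=(20, 20)) < 0.4)
        b = LayerMask("b", rng.uniform(size=(20, 20)) < 0.4)
        assert layer_ratio(7.3 * img, a, b) \
            == pytest.approx(layer_ratio(img, a, b), rel=1e-12)

    def test_degenerate_denominator(self):
        img = np.zeros((8, 8))
        m = LayerMask("z", np.ones((8, 8), bool))
        with pytest.raises(ZeroDivisionError):
            layer_ratio(img, m, m)

    def test_reconstruction_preserves_known_density_ratio(self, optics_100x):
        """Two layers with 2:1 emitter density give a map ratio near 2."""
        pitch = optics_100x.pixel_pitch_object
        h, s, n = 48, 10, 13
        ratios = []
        for seed in range(5):
            left = generate_fibrils((h * pitch, h * pitch), 6,
                                    dense_fraction=1.0, seed=900 + seed,
                                    dense_region_frac=0.5,
                                    raster_pitch=pitch / s)
            right = generate_fibrils((h * pitch, h * pitch), 6,
                                     dense_fraction=0.0, seed=950 + seed,
                                     dense_region_frac=0.5,
                                     raster_pitch=pitch / s)
            place_emitters(left, 30.0, jitter_sd=0.03, seed=960 + seed,
                           brightness=400)
            place_emitters(right, 15.0, jitter_sd=0.03, seed=970 + seed,
                           brightness=400)
            ph = FibrilPhantom(field_size=(h * pitch, h * pitch),
                               centerlines=(left.centerlines
                                            + right.centerlines),
                               raster_pitch=pitch / s)
            ph.emitters = np.vstack([left.emitters, right.emitters])
            ph.emitter_brightness = np.concatenate(
                [left.emitter_brightness, right.emitter_brightness])
            ph.density_raster = _count_raster(ph)
            b = simulate_fluctuations(ph.emitter_brightness,
                                      FluctuationModel(), 200,
                                      seed=980 + seed)
            stack = render_stack(ph, b, optics_100x,
                                 CameraModel(read_noise_sd=2.0, offset=100.0),
                                 seed=990 + seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                thr = image_threshold(stack, n, seed=seed)
                imap = reconstruct(
                    stack, MusicalParams(window_size=n, subpixels=s,
                                         threshold_mode="manual",
                                         threshold_value=thr), optics_100x)
            m = np.where(imap.valid_mask, imap.values, 0.0)
            border = (n // 2 + 1) * s
            lm = np.zeros(m.shape, bool)
            lm[border:-border, border:s * h // 2] = True
            rm = np.zeros(m.shape, bool)
            rm[border:-border, s * h // 2:-border] = True
            ratios.append(layer_ratio(m, LayerMask("dense", lm),
                                      LayerMask("sparse", rm),
                                      valid_mask=imap.valid_mask))
        # the α=4 indicator is heavy-tailed, so individual draws scatter;
        # the central tendency must sit near the true 2:1
        assert 1.5 <= np.median(ratios) <= 2.5


class TestMultiscaleVariance:
    def test_constant_image(self):
        rep = multiscale_variance(np.full((100, 100), 2.0), [20, 10, 5], 1.0)
        assert all(v == 0 for v in rep.between_variance)
        assert all(np.all(w == 0) for w in rep.within_variances)

    def test_iid_noise_between_variance_shrinks_with_window(self):
        for seed in range(20):
            img = np.random.default_rng(seed).normal(size=(128, 128))
            rep = multiscale_variance(img, [32, 16, 8, 4], 1.0)
            # sizes are reported descending; var of the mean grows as
            # windows shrink
            assert np.all(np.diff(rep.between_variance) > 0)

    def test_within_variance_matches_two_pass(self, rng):
        img = rng.uniform(size=(24, 24))
        rep = multiscale_variance(img, [8], 1.0)
        patch = img[:8, :8]
        mu = sum(patch.ravel()) / 64
        var = sum((x - mu) ** 2 for x in patch.ravel()) / 64
        assert rep.within_variances[0][0] == pytest.approx(var, abs=1e-10)

    def test_window_larger_than_image_rejected(self, rng):
        with pytest.raises(GeometryError):
            multiscale_variance(rng.uniform(size=(20, 20)), [50], 1.0)

    def test_report_serialises(self, rng):
        rep = multiscale_variance(rng.uniform(size=(64, 64)), [16, 8], 1.0)
        d = rep.as_dict()
        assert len(d["between_variance"]) == 2
        assert d["n_windows"] == [16, 64]


class TestFibrilWidth:
    def test_gaussian_ridge_closed_form(self):
        sigma = 0.8  # µm
        x = np.arange(200) * 0.05
        img = np.tile(np.exp(-0.5 * ((x - 5.0) / sigma) ** 2), (50, 1))
        w = fibril_width(img, (1.25, 2.0), (1.25, 8.0), 0.05, n_samples=256)
        assert w == pytest.approx(2.3548 * sigma, rel=0.02)

    def test_rectangular_ridge_limit(self):
        x = np.arange(400) * 0.025
        profile = ((x > 4.0) & (x < 6.5)).astype(float)
        img = np.tile(profile, (20, 1))
        widths = [fibril_width(img, (0.25, 1.0), (0.25, 9.0), 0.025,
                               n_samples=n) for n in (64, 256, 1024)]
        errors = [abs(w - 2.5) for w in widths]
        assert errors[-1] <= errors[0]
        assert widths[-1] == pytest.approx(2.5, abs=0.05)

    def test_width_histogram_rejects_nonpositive(self, rng):
        h = width_histogram(rng.uniform(0.1, 0.5, 300), bins=15)
        assert h.n == 300 and len(h.bin_edges) == 16
        with pytest.raises(ValueError):
            width_histogram([0.2, -0.1])

    def test_flat_profile_rejected(self):
        with pytest.raises(ValueError):
            fibril_width(np.ones((10, 10)), (0.5, 0.1), (0.5, 0.9), 0.1)

    def test_reconstruction_narrows_fibril(self, optics_100x):
        """Measured FWHM is smaller on the map than on the mean frame."""
        pitch = optics_100x.pixel_pitch_object
        h, s = 24, 10
        line = np.column_stack([
            np.linspace(2 * pitch, (h - 2) * pitch, 200),
            np.full(200, h / 2 * pitch)])
        ph = FibrilPhantom(field_size=(h * pitch, h * pitch),
                           centerlines=[line], raster_pitch=pitch / s)
        place_emitters(ph, 40.0, jitter_sd=0.02, seed=31, brightness=500)
        b = simulate_fluctuations(ph.emitter_brightness, FluctuationModel(),
                                  300, seed=32)
        stack = render_stack(ph, b, optics_100x,
                             CameraModel(read_noise_sd=2.0, offset=100.0),
                             seed=33)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            imap = reconstruct(stack, MusicalParams(window_size=13,
                                                    subpixels=s), optics_100x)
        m = np.where(imap.valid_mask, imap.values, 0.0)
        p0, p1 = (h / 2 * pitch, 4 * pitch), (h / 2 * pitch, (h - 4) * pitch)
        w_map = fibril_width(m, p0, p1, imap.pixel_pitch)
        w_mean = fibril_width(stack.mean_frame(), p0, p1, pitch)
        assert w_map < w_mean


class TestSSIM:
    def test_identical_images(self, rng):
        img = rng.uniform(size=(64, 64))
        assert ssim(img, img) == pytest.approx(1.0, abs=1e-12)

    def test_negated_zero_mean_image_scores_nonpositive(self):
        # local (window-scale) means must vanish so only the covariance
        # term carries the sign
        img = (-1.0) ** np.indices((64, 64)).sum(axis=0)
        assert ssim(img, -img) <= 0.0

    def test_matches_independent_implementation(self, rng):
        """Gaussian-window SSIM recomputed from its definition."""
        a = rng.uniform(0, 1, (48, 48))
        b = np.clip(a + rng.normal(0, 0.15, (48, 48)), 0, 1)
        data_range = float(max(a.max(), b.max()) - min(a.min(), b.min()))
        sig, trunc = 1.5, 3.5
        g = lambda x: gaussian_filter(x, sig, truncate=trunc)  # noqa: E731
        ux, uy = g(a), g(b)
        vx = g(a * a) - ux * ux
        vy = g(b * b) - uy * uy
        cov = g(a * b) - ux * uy
        c1, c2 = (0.01 * data_range) ** 2, (0.03 * data_range) ** 2
        smap = ((2 * ux * uy + c1) * (2 * cov + c2)) \
            / ((ux * ux + uy * uy + c1) * (vx + vy + c2))
        pad = int(trunc * sig + 0.5)
        ref = smap[pad:-pad, pad:-pad].mean()
        assert ssim(a, b) == pytest.approx(ref, abs=1e-6)

    def test_shape_mismatch(self, rng):
        with pytest.raises(GeometryError):
            ssim(rng.uniform(size=(10, 10)), rng.uniform(size=(10, 11)))


def _fidelity_fixture(seed, raster_pitch=0.1):
    ph = generate_fibrils((25.6, 25.6), 14, dense_fraction=0.75, seed=seed,
                          raster_pitch=raster_pitch)
    place_emitters(ph, 4.0, jitter_sd=0.05, seed=seed + 1000)
    gt = ph.density_raster
    masks = ph.region_masks(gt.shape, ph.raster_pitch)
    rois = [ROISpec((i, j), (16, 16)) for i in range(0, 240, 16)
            for j in range(0, 240, 16)]
    return ph, gt, masks, rois


class TestDensityFidelity:
    def test_ground_truth_is_perfect_candidate(self):
        _, gt, masks, rois = _fidelity_fixture(0)
        rep = density_fidelity(gt, {"self": gt}, rois, masks)
        for region in ("dense", "sparse"):
            assert rep["self"][region]["pearson_r"] == pytest.approx(1.0)
            assert rep["self"][region]["mae"] == pytest.approx(0.0, abs=1e-9)

    def test_light_blur_beats_heavy_blur(self):
        """Ordering: small blur tracks density better than large blur."""
        wins = {"dense": 0, "sparse": 0}
        for seed in range(20):
            _, gt, masks, rois = _fidelity_fixture(seed)
            cands = {"light": blur_density(gt, 2.0),
                     "heavy": blur_density(gt, 25.0)}
            rep = density_fidelity(gt, cands, rois, masks)
            for region in wins:
                wins[region] += (rep["light"][region]["pearson_r"]
                                 > rep["heavy"][region]["pearson_r"])
        assert wins["dense"] >= 18 and wins["sparse"] >= 18

    def test_shuffled_rois_destroy_correlation(self):
        rs = []
        for seed in range(10):
            _, gt, masks, rois = _fidelity_fixture(seed)
            cand = blur_density(gt, 2.0)
            rng = np.random.default_rng(seed)
            shuffled = list(rois)
            rng.shuffle(shuffled)
            gt_means = np.array([roi_mean_density(gt, r) for r in rois])
            cd_means = np.array([roi_mean_density(cand, r)
                                 for r in shuffled])
            rs.append(np.corrcoef(gt_means, cd_means)[0, 1])
        assert np.mean(np.abs(rs)) < 0.3

    def test_too_few_rois_rejected(self):
        _, gt, masks, _ = _fidelity_fixture(0)
        rois = [ROISpec((0, 0), (16, 16)), ROISpec((0, 200), (16, 16))]
        with pytest.raises(InsufficientDataError):
            density_fidelity(gt, {"self": gt}, rois, masks)


class TestGroupStatistics:
    def test_thin_wrappers_return_sane_pvalues(self, rng):
        groups = {"a": rng.normal(0, 1, 30), "b": rng.normal(0.2, 1, 30),
                  "c": rng.normal(2.5, 1, 30)}
        out = group_comparison(groups)
        assert 0 <= out["anova_p"] <= 1
        assert out["tukey_p"]["a vs c"] < 0.01
        t = paired_ttest(groups["a"], groups["a"] + 0.01)
        assert 0 <= t["p"] <= 1
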