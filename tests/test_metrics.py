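import numpy as np
import pytest
from scipy import ndimage

from mridenoise.metrics import (MSSSIM_WEIGHTS, FeatureExtractor, SSIMConfig,
                                dice_iou, feature_loss, lpips_like, mae, mse,
                                msssim, paired_compare, psnr, ssim)


@pytest.fixture(scope="module")
def img_pair():
    rng = np.random.default_rng(0)
    x = rng.random((48, 48))
    y = np.clip(x + 0.1 * rng.standard_normal((48, 48)), 0, 1)
    return x, y


# -- brute-force oracles ----------------------------------------------------

def gaussian_kernel(size=11, sigma=1.5):
    r = size // 2
    g = np.exp(-0.5 * (np.arange(-r, r + 1) / sigma) ** 2)
    k = np.outer(g, g)
    return k / k.sum()


def ssim_bruteforce(x, y, config=SSIMConfig()):
    """Per-window loop implementation of the structural similarity index."""
    k = gaussian_kernel(config.window_size, config.window_sigma)
    L = config.data_range
    c1, c2 = (config.k1 * L) ** 2, (config.k2 * L) ** 2
    size = config.window_size
    vals = []
    for i in range(x.shape[0] - size + 1):
        for j in range(x.shape[1] - size + 1):
            wx = x[i:i + size, j:j + size]
            wy = y[i:i + size, j:j + size]
            mx, my = (k * wx).sum(), (k * wy).sum()
            vx = (k * wx * wx).sum() - mx ** 2
            vy = (k * wy * wy).sum() - my ** 2
            vxy = (k * wx * wy).sum() - mx * my
            vals.append(((2 * mx * my + c1) * (2 * vxy + c2)) /
                        ((mx ** 2 + my ** 2 + c1) * (vx + vy + c2)))
    return float(np.mean(vals))


def msssim_bruteforce(x, y, config=SSIMConfig()):
    """Compose per-scale luminance/contrast/structure terms directly."""
    M = config.n_scales
    w = np.array(MSSSIM_WEIGHTS[:M])
    w = w / w.sum()
    k = gaussian_kernel(config.window_size, config.window_sigma)
    L = config.data_range
    c1, c2 = (config.k1 * L) ** 2, (config.k2 * L) ** 2
    c3 = c2 / 2.0
    value = 1.0
    for j in range(M):
        size = config.window_size
        lums, css = [], []
        for i0 in range(x.shape[0] - size + 1):
            for j0 in range(x.shape[1] - size + 1):
                wx = x[i0:i0 + size, j0:j0 + size]
                wy = y[i0:i0 + size, j0:j0 + size]
                mx, my = (k * wx).sum(), (k * wy).sum()
                vx = max((k * wx * wx).sum() - mx ** 2, 0.0)
                vy = max((k * wy * wy).sum() - my ** 2, 0.0)
                vxy = (k * wx * wy).sum() - mx * my
                sx, sy = np.sqrt(vx), np.sqrt(vy)
                lums.append((2 * mx * my + c1) / (mx ** 2 + my ** 2 + c1))
                contrast = (2 * sx * sy + c2) / (vx + vy + c2)
                structure = (vxy + c3) / (sx * sy + c3)
                css.append(contrast * structure)
        mcs = max(float(np.mean(css)), 0.0)
        if j == M - 1:
            value *= max(float(np.mean(lums)), 0.0) ** w[j]
        value *= mcs ** w[j]
        if j < M - 1:
            h, wd = (x.shape[0] // 2) * 2, (x.shape[1] // 2) * 2
            x = x[:h, :wd].reshape(h // 2, 2, wd // 2, 2).mean(axis=(1, 3))
            y = y[:h, :wd].reshape(h // 2, 2, wd // 2, 2).mean(axis=(1, 3))
    return float(value)


def feature_maps_bruteforce(img, extractor):
    """Evaluate the extractor's first conv layer with scipy correlate."""
    x = np.repeat(img[None], 3, axis=0)
    w = extractor.conv1.weight.data
    b = extractor.conv1.bias.data
    out = np.zeros((w.shape[0],) + img.shape)
    for o in range(w.shape[0]):
        acc = sum(ndimage.correlate(x[c], w[o, c], mode="constant")
                  for c in range(3))
        out[o] = acc + b[o]
    return np.maximum(out, 0.0)


# -- tests ------------------------------------------------------------------

class TestPixelwise:
    def test_identity_and_constant_offset(self, img_pair):
        x, _ = img_pair
        assert mae(x, x) == 0.0 and mse(x, x) == 0.0
        y = x + 0.25
        assert mae(x, y) == pytest.approx(0.25, abs=1e-7)
        assert mse(x, y) == pytest.approx(0.0625, abs=1e-7)

    def test_matches_bruteforce(self, img_pair):
        x, y = img_pair
        assert mae(x, y) == pytest.approx(np.abs(x - y).mean(), abs=1e-7)
        assert mse(x, y) == pytest.approx(((x - y) ** 2).mean(), abs=1e-7)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mae(np.zeros((4, 4)), np.zeros((4, 5)))


class TestPSNR:
    def test_identity_gives_infinity(self, img_pair):
        x, _ = img_pair
        assert psnr(x, x) == float("inf")

    def test_constant_difference_closed_form(self):
        x = np.zeros((16, 16))
        y = np.full((16, 16), 128.0)
        assert psnr(x, y, data_range=255.0) == \
            pytest.approx(20 * np.log10(255 / 128), rel=1e-9)

    def test_scale_invariance(self, img_pair):
        x, y = img_pair
        assert psnr(x, y, 1.0) == pytest.approx(
            psnr(10 * x, 10 * y, 10.0), rel=1e-9)


class TestSSIM:
    def test_self_similarity_is_one(self, img_pair):
        x, _ = img_pair
        assert ssim(x, x) == pytest.approx(1.0, abs=1e-9)

    def test_symmetry(self, img_pair):
        x, y = img_pair
        assert ssim(x, y) == pytest.approx(ssim(y, x), abs=1e-12)

    def test_matches_sliding_window_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.random((32, 32))
        y = np.clip(x + 0.15 * rng.standard_normal((32, 32)), 0, 1)
        assert ssim(x, y) == pytest.approx(ssim_bruteforce(x, y), abs=1e-6)

    def test_close_to_scikit_image(self, img_pair):
        skimage = pytest.importorskip("skimage.metrics")
        x, y = img_pair
        ref = skimage.structural_similarity(
            x, y, data_range=1.0, gaussian_weights=True, sigma=1.5,
            use_sample_covariance=False)
        assert ssim(x, y) == pytest.approx(ref, abs=5e-3)

    def test_bounded_above_by_one(self, img_pair):
        x, y = img_pair
        assert ssim(x, y) <= 1.0 + 1e-9

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            ssim(np.zeros((8, 8)), np.zeros((8, 8)))


class TestMSSSIM:
    def test_self_similarity_is_one(self, img_pair):
        x, _ = img_pair
        assert msssim(x, x) == pytest.approx(1.0, abs=1e-9)

    def test_single_scale_collapses_to_ssim(self, img_pair):
        x, y = img_pair
        cfg = SSIMConfig(n_scales=1)
        assert msssim(x, y, cfg) == pytest.approx(
            max(ssim(x, y, cfg), 0.0), abs=1e-6)

    def test_matches_compositional_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.random((64, 64))
        y = np.clip(x + 0.1 * rng.standard_normal((64, 64)), 0, 1)
        assert msssim(x, y) == pytest.approx(msssim_bruteforce(x, y),
                                             abs=1e-6)

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            msssim(np.zeros((16, 16)), np.zeros((16, 16)))


class TestFeatureLosses:
    @pytest.fixture(scope="class")
    def extractor(self):
        return FeatureExtractor(seed=0, n_filt=8)

    def test_identity_is_zero(self, img_pair, extractor):
        x, _ = img_pair
        assert feature_loss(x, x, extractor) == 0.0
        assert lpips_like(x, x, extractor) == 0.0

    def test_symmetric_and_nonnegative(self, img_pair, extractor):
        x, y = img_pair
        assert feature_loss(x, y, extractor) >= 0.0
        assert feature_loss(x, y, extractor) == pytest.approx(
            feature_loss(y, x, extractor), rel=1e-6)
        assert lpips_like(x, y, extractor) == pytest.approx(
            lpips_like(y, x, extractor), rel=1e-6)

    def test_matches_direct_formula(self, img_pair, extractor):
        x, y = img_pair
        fx = feature_maps_bruteforce(x, extractor)
        fy = feature_maps_bruteforce(y, extractor)
        assert feature_loss(x, y, extractor) == pytest.approx(
            np.abs(fx - fy).mean(), abs=1e-6)
        assert lpips_like(x, y, extractor) == pytest.approx(
            ((fx - fy) ** 2).mean(), abs=1e-6)

    def test_pretrained_origin_raises_actionable_error(self):
        with pytest.raises(RuntimeError, match="fixed_random_seeded"):
            FeatureExtractor(origin="pretrained_classifier")


class TestDiceIou:
    def test_closed_forms(self):
        a = np.zeros((4, 4), dtype=int)
        b = np.zeros((4, 4), dtype=int)
        a[0, :2] = 1
        b[0, 1:3] = 1  # |A| = |B| = 2, overlap 1
        dice, iou = dice_iou(a, b)
        assert dice == pytest.approx(2 * 1 / (2 + 2))
        assert iou == pytest.approx(1 / 3)

    def test_identical_and_disjoint(self):
        a = np.eye(5, dtype=int)
        assert dice_iou(a, a) == (1.0, 1.0)
        b = 1 - a
        assert dice_iou(a, b) == (0.0, 0.0)

    def test_both_empty_defined_as_one(self):
        z = np.zeros((3, 3), dtype=int)
        assert dice_iou(z, z) == (1.0, 1.0)

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            dice_iou(np.arange(4).reshape(2, 2), np.zeros((2, 2)))


class TestPairedCompare:
    def test_identical_method_is_ns(self):
        vals = {"ref": [1.0, 2.0, 3.0, 4.0], "same": [1.0, 2.0, 3.0, 4.0]}
        report = paired_compare(vals, reference="ref")
        row = report.comparisons.iloc[0]
        assert row["p"] == 1.0 and row["label"] == "ns"

    def test_strong_shift_flagged_significant(self):
        rng = np.random.default_rng(0)
        ref = rng.standard_normal(20)
        shifted = ref + 10.0  # ten-sigma shift
        report = paired_compare({"ref": ref, "up": shifted}, reference="ref")
        row = report.comparisons.iloc[0]
        assert row["q"] < 0.05 and row["label"] == "better"
        report2 = paired_compare({"ref": ref, "up": shifted}, reference="ref",
                                 higher_is_better=False)
        assert report2.comparisons.iloc[0]["label"] == "worse"

    def test_bh_step_up_arithmetic(self):
        from statsmodels.stats.multitest import multipletests
        p = np.array([0.01, 0.02, 0.03, 0.04])
        _, q, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_q_values_monotone_in_report(self):
        rng = np.random.default_rng(1)
        ref = rng.standard_normal(15)
        methods = {"ref": ref}
        for k in range(4):
            methods[f"m{k}"] = ref + 0.2 * k * np.abs(rng.standard_normal(15))
        rep = paired_compare(methods, reference="ref")
        tab = rep.comparisons.sort_values("p")
        assert (np.diff(tab["q"].to_numpy()) >= -1e-12).all()

    def test_unequal_pairing_rejected(self):
        with pytest.raises(ValueError):
            paired_compare({"ref": [1, 2, 3], "m": [1, 2]}, reference="ref")


class TestMetricProperties:
    """Randomized invariants of the pixelwise metrics."""

    from hypothesis import given, settings, strategies as st

    @given(seed=st.integers(0, 10 ** 6), offset=st.floats(0.01, 0.5))
    @settings(max_examples=30, deadline=None)
    def test_constant_offset_closed_forms(self, seed, offset):
        rng = np.random.default_rng(seed)
        x = rng.random((12, 12))
        y = x + offset
        assert mae(x, y) == pytest.approx(offset, rel=1e-6)
        assert mse(x, y) == pytest.approx(offset ** 2, rel=1e-6)
        assert psnr(x, y, 1.0) == pytest.approx(-20 * np.log10(offset),
                                                rel=1e-6)

    @given(seed=st.integers(0, 10 ** 6))
    @settings(max_examples=20, deadline=None)
    def test_symmetry_and_nonnegativity(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.random((10, 10)), rng.random((10, 10))
        assert mae(x, y) == mae(y, x) >= 0
        assert mse(x, y) == mse(y, x) >= 0


def test_report_export_round_trip(tmp_path):
    vals = {"ref": [1.0, 2.0, 3.0], "m": [1.1, 2.2, 3.1]}
    rep = paired_compare(vals, reference="ref")
    csv_path = tmp_path / "report.csv"
    rep.to_csv(str(csv_path))
    import pandas as pd
    back = pd.read_csv(csv_path)
    assert set(back.columns) == {"image", "method", "metric", "value"}
    blob = rep.to_json()
    assert "comparisons" in blob
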