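"""Metric correctness against independent brute-force and reference oracles."""

import numpy as np
import pytest
from skimage.metrics import structural_similarity

from spike2image.images import GrayImage
from spike2image.metrics import (
    MetricConstants,
    mse,
    pair_stats,
    psnr,
    ssim_components,
    ssim_global,
    ssim_windowed,
    vifp,
    metric_report,
)


def loop_mse(x, y):
    total = 0.0
    for i in range(x.shape[0]):
        for j in range(x.shape[1]):
            total += (x[i, j] - y[i, j]) ** 2
    return total / x.size


def loop_stats(x, y):
    n = x.size
    mx = sum(x[i, j] for i in range(x.shape[0]) for j in range(x.shape[1])) / n
    my = sum(y[i, j] for i in range(y.shape[0]) for j in range(y.shape[1])) / n
    vx = sum((x[i, j] - mx) ** 2 for i in range(x.shape[0]) for j in range(x.shape[1])) / n
    vy = sum((y[i, j] - my) ** 2 for i in range(y.shape[0]) for j in range(y.shape[1])) / n
    cov = (
        sum(
            (x[i, j] - mx) * (y[i, j] - my)
            for i in range(x.shape[0])
            for j in range(x.shape[1])
        )
        / n
    )
    return mx, my, vx, vy, cov


def loop_ssim(x, y, c1, c2):
    mx, my, vx, vy, cov = loop_stats(x, y)
    return ((2 * mx * my + c1) * (2 * cov + c2)) / (
        (mx**2 + my**2 + c1) * (vx + vy + c2)
    )


class TestMse:
    def test_identity_is_zero(self, image_pair_factory):
        x, _ = image_pair_factory()
        assert mse(x, x) == 0.0

    def test_full_range_constant_pair(self):
        x = np.zeros((5, 5))
        y = np.full((5, 5), 255.0)
        assert mse(x, y) == pytest.approx(65025.0)
        assert mse(x, y, reduction="sum") == pytest.approx(65025.0 * 25)

    def test_matches_double_loop_oracle(self, image_pair_factory):
        x, y = image_pair_factory((8, 8))
        assert mse(x, y) == pytest.approx(loop_mse(x, y), abs=1e-9)
        assert mse(x, y, reduction="sum") == pytest.approx(loop_mse(x, y) * 64, abs=1e-6)

    def test_symmetry(self, image_pair_factory):
        x, y = image_pair_factory()
        assert mse(x, y) == mse(y, x)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="shapes differ"):
            mse(np.zeros((4, 4)), np.zeros((4, 5)))


class TestPsnr:
    def test_identical_images_give_inf(self, image_pair_factory):
        x, _ = image_pair_factory()
        assert psnr(x, x) == float("inf")

    def test_closed_form_anchors(self):
        # mean MSE = P^2 -> 0 dB; MSE = P^2/100 -> 20 dB
        x = np.zeros((10, 10))
        assert psnr(x, np.full_like(x, 255.0)) == pytest.approx(0.0, abs=1e-12)
        y = np.full_like(x, 25.5)
        assert mse(x, y) == pytest.approx(255.0**2 / 100.0)
        assert psnr(x, y) == pytest.approx(20.0, abs=1e-12)

    def test_strictly_decreasing_in_mse(self, rng):
        x = rng.uniform(0, 255, (12, 12))
        noisy = [np.clip(x + rng.normal(0, s, x.shape), 0, 255) for s in (5, 20, 60)]
        errs = [mse(x, n) for n in noisy]
        snrs = [psnr(x, n) for n in noisy]
        assert errs == sorted(errs)
        assert snrs == sorted(snrs, reverse=True)


class TestPairStats:
    def test_constant_self_pair(self):
        c = np.full((6, 6), 42.0)
        st = pair_stats(c, c)
        assert (st.mean_x, st.mean_y) == (42.0, 42.0)
        assert st.std_x == st.std_y == st.cov_xy == 0.0

    def test_matches_loop_oracle(self, image_pair_factory):
        x, y = image_pair_factory((16, 16))
        st = pair_stats(x, y)
        mx, my, vx, vy, cov = loop_stats(x, y)
        assert st.mean_x == pytest.approx(mx)
        assert st.std_x == pytest.approx(np.sqrt(vx))
        assert st.std_y == pytest.approx(np.sqrt(vy))
        assert st.cov_xy == pytest.approx(cov)

    def test_affine_pair_covariance_identity(self, image_pair_factory):
        x, _ = image_pair_factory((16, 16))
        y = 1.7 * x + 3.0
        st = pair_stats(x, y)
        assert st.cov_xy == pytest.approx(1.7 * st.std_x**2, rel=1e-9)

    def test_cauchy_schwarz(self, image_pair_factory):
        x, y = image_pair_factory((16, 16))
        st = pair_stats(x, y)
        assert abs(st.cov_xy) <= st.std_x * st.std_y + 1e-9


class TestSsim:
    consts = MetricConstants.for_range(255.0)

    def test_self_pair_components_are_unity(self, image_pair_factory):
        x, _ = image_pair_factory()
        comp = ssim_components(pair_stats(x, x), self.consts)
        assert comp == pytest.approx((1.0, 1.0, 1.0))

    def test_zero_mean_pair_luminance_is_one(self):
        st = pair_stats(np.array([[-1.0, 1.0]]), np.array([[-2.0, 2.0]]))
        lum, _, _ = ssim_components(st, self.consts)
        assert lum == 1.0

    def test_component_product_equals_global(self, image_pair_factory):
        x, y = image_pair_factory((16, 16), correlated=True)
        lum, con, struct = ssim_components(pair_stats(x, y), self.consts)
        assert lum * con * struct == pytest.approx(
            ssim_global(x, y, self.consts), abs=1e-12
        )

    def test_self_similarity_is_exactly_one(self, image_pair_factory):
        x, _ = image_pair_factory()
        assert ssim_global(x, x, self.consts) == pytest.approx(1.0, abs=1e-12)

    def test_constant_extremes_closed_form(self):
        x = np.zeros((8, 8))
        y = np.full((8, 8), 255.0)
        c1 = self.consts.c1
        expected = c1 / (255.0**2 + c1)  # sigma terms vanish; c2 cancels
        assert ssim_global(x, y, self.consts) == pytest.approx(expected, abs=1e-12)

    def test_matches_loop_oracle(self, image_pair_factory):
        x, y = image_pair_factory((12, 12), correlated=True)
        ref = loop_ssim(x, y, self.consts.c1, self.consts.c2)
        assert ssim_global(x, y, self.consts) == pytest.approx(ref, abs=1e-9)

    def test_symmetry(self, image_pair_factory):
        x, y = image_pair_factory((10, 10))
        assert ssim_global(x, y, self.consts) == pytest.approx(
            ssim_global(y, x, self.consts), abs=1e-12
        )

    def test_bounded_on_nonnegative_images(self, rng):
        for _ in range(20):
            x = rng.uniform(0, 255, (9, 9))
            y = np.clip(x + rng.normal(0, rng.uniform(1, 80), x.shape), 0, 255)
            assert 0.0 <= ssim_global(x, y, self.consts) <= 1.0

    def test_anticorrelated_pair_is_negative_but_bounded(self):
        x = np.tile([0.0, 255.0], (8, 4))
        y = 255.0 - x
        val = ssim_global(x, y, self.consts)
        assert -1.0 <= val < 0.0


class TestSsimWindowed:
    consts = MetricConstants.for_range(255.0)

    def test_identity(self, image_pair_factory):
        x, _ = image_pair_factory((32, 32))
        assert ssim_windowed(x, x, self.consts) == pytest.approx(1.0, abs=1e-9)

    def test_matches_reference_implementation(self, image_pair_factory):
        x, y = image_pair_factory((32, 32), correlated=True)
        ref = structural_similarity(
            x, y, data_range=255.0, gaussian_weights=True, sigma=1.5,
            use_sample_covariance=False,
        )
        assert ssim_windowed(x, y, self.consts) == pytest.approx(ref, abs=1e-6)

    def test_small_shift_stays_near_one(self, image_pair_factory):
        x, _ = image_pair_factory((32, 32))
        assert ssim_windowed(x, x + 0.05, self.consts) > 0.99

    def test_window_larger_than_image_raises(self):
        with pytest.raises(ValueError, match="exceeds image extent"):
            ssim_windowed(np.zeros((8, 8)), np.zeros((8, 8)), self.consts, 11)


class TestVifp:
    def test_self_fidelity_is_one(self, image_pair_factory):
        x, _ = image_pair_factory((40, 40))
        assert vifp(x, x) == pytest.approx(1.0, abs=1e-6)

    def test_decreases_with_noise(self, rng):
        x = rng.uniform(0, 255, (48, 48))
        vals = [
            vifp(x, np.clip(x + rng.normal(0, s, x.shape), 0, 255))
            for s in (5, 20, 50)
        ]
        assert vals[0] > vals[1] > vals[2]

    def test_constant_image_destroys_information(self, rng):
        x = rng.uniform(0, 255, (40, 40))
        assert vifp(x, np.full_like(x, x.mean())) < 0.1

    def test_too_small_image_raises(self):
        with pytest.raises(ValueError, match="too small"):
            vifp(np.zeros((8, 8)), np.zeros((8, 8)), n_scales=4)


def test_metric_report_schema_and_self_comparison(image_pair_factory):
    x, _ = image_pair_factory((32, 32))
    rep = metric_report(GrayImage.from_uint8(x.astype(np.uint8)),
                        GrayImage.from_uint8(x.astype(np.uint8)))
    assert set(rep) == {"mse", "mse_sum", "psnr_db", "ssim", "vifp"}
    assert rep["mse"] == 0.0
    assert rep["psnr_db"] == float("inf")
    assert rep["ssim"] == pytest.approx(1.0, abs=1e-9)
    assert rep["vifp"] == pytest.approx(1.0, abs=1e-6)


def test_noise_degrades_ssim_and_vifp_monotonically(rng):
    x = rng.uniform(0, 255, (48, 48))
    consts = MetricConstants.for_range(255.0)
    ssims, vifps = [], []
    for s in (5, 20, 50):
        acc_s, acc_v = [], []
        for rep in range(3):
            y = np.clip(x + rng.normal(0, s, x.shape), 0, 255)
            acc_s.append(ssim_windowed(x, y, consts))
            acc_v.append(vifp(x, y))
        ssims.append(np.mean(acc_s))
        vifps.append(np.mean(acc_v))
    assert ssims[0] > ssims[1] > ssims[2]
    assert vifps[0] > vifps[1] > vifps[2]
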