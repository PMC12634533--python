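"""Noise injection, SNR/PSNR/SSIM metrics, and the robustness sweep."""

import math

import numpy as np
import pytest

import sobelnet as sn
from sobelnet.robustness import NoiseCondition, robustness_sweep
from sobelnet.training import epochs_to_arrays


def gaussian_window(size=11, sigma=1.5):
    r = np.arange(size) - size // 2
    g = np.exp(-(r**2) / (2 * sigma**2))
    k = np.outer(g, g)
    return k / k.sum()


def ssim_oracle(ref, test, win=11, sigma=1.5, k1=0.01, k2=0.03):
    """Direct windowed SSIM: gaussian-weighted stats over every valid window."""
    w = gaussian_window(win, sigma)
    data_range = ref.max() - ref.min()
    c1, c2 = (k1 * data_range) ** 2, (k2 * data_range) ** 2
    h, wd = ref.shape
    vals = []
    for i in range(h - win + 1):
        for j in range(wd - win + 1):
            a = ref[i:i + win, j:j + win]
            b = test[i:i + win, j:j + win]
            mu_a, mu_b = (w * a).sum(), (w * b).sum()
            var_a = (w * a * a).sum() - mu_a**2
            var_b = (w * b * b).sum() - mu_b**2
            cov = (w * a * b).sum() - mu_a * mu_b
            vals.append(
                ((2 * mu_a * mu_b + c1) * (2 * cov + c2))
                / ((mu_a**2 + mu_b**2 + c1) * (var_a + var_b + c2))
            )
    return float(np.mean(vals))


class TestAddNoise:
    def test_target_snr_hit_exactly(self, rng):
        clean = rng.standard_normal((8, 64)) * 5
        for target in (20.0, 0.0, -5.0):
            noisy = sn.add_noise_at_snr(clean, target, rng)
            assert sn.snr_db(clean, noisy) == pytest.approx(target, abs=0.01)

    def test_zero_db_means_equal_powers(self, rng):
        clean = rng.standard_normal((4, 128))
        noisy = sn.add_noise_at_snr(clean, 0.0, rng)
        p_sig = np.mean(clean**2)
        p_noise = np.mean((noisy - clean) ** 2)
        assert p_noise == pytest.approx(p_sig, rel=0.005)

    def test_seeds_change_realization_not_power(self, rng):
        clean = rng.standard_normal((4, 64))
        n1 = sn.add_noise_at_snr(clean, 10.0, np.random.default_rng(1)) - clean
        n2 = sn.add_noise_at_snr(clean, 10.0, np.random.default_rng(2)) - clean
        assert not np.allclose(n1, n2)
        assert np.mean(n1**2) == pytest.approx(np.mean(n2**2), rel=1e-9)

    def test_clean_input_not_modified(self, rng):
        clean = rng.standard_normal((4, 64))
        before = clean.copy()
        sn.add_noise_at_snr(clean, 5.0, rng)
        assert np.array_equal(clean, before)

    def test_zero_power_rejected(self, rng):
        with pytest.raises(ValueError):
            sn.add_noise_at_snr(np.zeros((4, 8)), 10.0, rng)


class TestSNR:
    def test_equal_powers_zero_db(self, rng):
        ref = rng.standard_normal(4096)
        noise = rng.standard_normal(4096)
        noise *= np.sqrt(np.mean(ref**2) / np.mean(noise**2))
        assert sn.snr_db(ref, ref + noise) == pytest.approx(0.0, abs=1e-9)

    def test_tenth_power_is_ten_db(self, rng):
        ref = rng.standard_normal(4096)
        noise = rng.standard_normal(4096)
        noise *= np.sqrt(np.mean(ref**2) / 10.0 / np.mean(noise**2))
        assert sn.snr_db(ref, ref + noise) == pytest.approx(10.0, abs=1e-9)

    def test_identical_signals_give_inf_sentinel(self, rng):
        ref = rng.standard_normal(32)
        assert sn.snr_db(ref, ref.copy()) == math.inf


class TestPSNR:
    def test_identical_gives_inf_sentinel(self, rng):
        ref = rng.standard_normal((8, 8))
        assert sn.psnr_db(ref, ref.copy()) == math.inf

    def test_unit_range_centivariance_is_twenty_db(self):
        ref = np.zeros((10, 10))
        ref[0, 0] = 1.0  # range exactly 1
        test = ref + 0.1  # MSE exactly 0.01
        assert sn.psnr_db(ref, test) == pytest.approx(20.0, abs=1e-9)

    def test_psnr_minus_snr_constant_for_fixed_reference(self, rng):
        ref = rng.standard_normal((16, 16))
        diffs = []
        for target in (15.0, 5.0, -5.0):
            noisy = sn.add_noise_at_snr(ref, target, rng)
            diffs.append(sn.psnr_db(ref, noisy) - sn.snr_db(ref, noisy))
        assert np.ptp(diffs) < 1e-9

    def test_zero_range_rejected(self):
        with pytest.raises(ValueError):
            sn.psnr_db(np.ones((4, 4)), np.zeros((4, 4)))


class TestSSIM:
    def test_self_similarity_is_one(self, rng):
        x = rng.standard_normal((16, 16))
        assert sn.ssim(x, x.copy()) == pytest.approx(1.0)

    def test_anticorrelated_structure_negative(self):
        # checkerboard: every local window has (weighted) mean ~0 but unit
        # variance, so sign inversion flips the structure term to ~-1
        i, j = np.meshgrid(np.arange(16), np.arange(16), indexing="ij")
        x = (-1.0) ** (i + j)
        assert sn.ssim(x, -x) < -0.9

    def test_matches_windowed_oracle(self, rng):
        ref = rng.standard_normal((12, 12))
        test = ref + 0.4 * rng.standard_normal((12, 12))
        assert sn.ssim(ref, test) == pytest.approx(ssim_oracle(ref, test), abs=1e-7)

    def test_map_smaller_than_window_rejected(self, rng):
        with pytest.raises(ValueError):
            sn.ssim(rng.standard_normal((8, 12)), rng.standard_normal((8, 12)))


@pytest.fixture(scope="module")
def clean_epochs():
    recs = sn.generate_dataset((2, 2), seed=9, duration_s=12.0,
                               sampling_rate=32.0, n_channels=12)
    return sn.dataset_epochs(recs, window_s=4.0, stride_s=4.0)


class TestSweep:
    def test_identity_transform_all_deltas_zero(self, clean_epochs):
        bank = sn.build_filter_bank(1)
        conds = [NoiseCondition(10.0, seed=1), NoiseCondition(0.0, seed=2)]
        report = robustness_sweep(None, bank, clean_epochs, conds,
                                  transform=lambda x: x)
        assert np.all(report["delta_snr_db"] == 0.0)
        assert np.all(report["delta_psnr_db"] == 0.0)
        assert np.all(report["delta_ssim"] == 0.0)
        assert report["accuracy"].isna().all()

    def test_one_row_per_condition_and_measured_snr(self, clean_epochs):
        bank = sn.build_filter_bank(1)
        conds = [NoiseCondition(s, seed=i) for i, s in enumerate((20.0, 5.0, -5.0))]
        report = robustness_sweep(None, bank, clean_epochs, conds)
        assert list(report["nominal_snr_db"]) == [20.0, 5.0, -5.0]
        np.testing.assert_allclose(report["measured_input_snr_db"],
                                   report["nominal_snr_db"], atol=0.01)
        assert (report["n_epochs"] == len(clean_epochs)).all()

    def test_aggregation_matches_bruteforce_recompute(self, clean_epochs):
        bank = sn.build_filter_bank(1)
        cond = NoiseCondition(5.0, seed=33)
        report = robustness_sweep(None, bank, clean_epochs, [cond])
        x, _ = epochs_to_arrays(clean_epochs)
        x = x.astype(float)
        rng2 = np.random.default_rng(cond.seed)
        in_snrs, out_snrs = [], []
        for i in range(x.shape[0]):
            noisy = sn.add_noise_at_snr(x[i], 5.0, rng2)
            g_clean = sn.sobel_forward(x[i][None], bank).values
            g_noisy = sn.sobel_forward(noisy[None], bank).values
            in_snrs.append(sn.snr_db(x[i], noisy))
            out_snrs.append(sn.snr_db(g_clean, g_noisy))
        assert report["measured_input_snr_db"].iloc[0] == pytest.approx(np.mean(in_snrs))
        assert report["output_snr_db"].iloc[0] == pytest.approx(np.mean(out_snrs))

    def test_empty_conditions_rejected(self, clean_epochs):
        with pytest.raises(ValueError):
            robustness_sweep(None, sn.build_filter_bank(1), clean_epochs, [])
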