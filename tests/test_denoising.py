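"""IMF classification, wavelet shrinkage and the hybrid denoiser."""

import numpy as np
import pytest

from emgkin.decomposition import CeemdanConfig, Signal, ceemdan
from emgkin.denoising import (DenoiseConfig, LABEL_DRIFT, LABEL_NOISY,
                              LABEL_SIGNAL, butterworth_bandpass,
                              classify_imfs, denoise, mean_frequency, mse,
                              pearson_corr, wavelet_only_denoise,
                              wavelet_threshold)
from emgkin.synthetic import GaitProfile, gen_angles, gen_emg

FS = 1000.0


class TestPearson:
    @pytest.mark.parametrize("x,y,r", [
        ([1, 2, 3], [1, 2, 3], 1.0),
        ([1, 2, 3], [3, 2, 1], -1.0),
        ([1, 2, 3, 4], [1, 3, 2, 4], 0.8),  # hand: cov 4/3, sd^2 5/3 each
    ])
    def test_examples(self, x, y, r):
        assert pearson_corr(np.array(x, float), np.array(y, float)) == pytest.approx(r, abs=1e-9)

    def test_degenerate_constant_pairs(self):
        with pytest.warns(UserWarning):
            assert pearson_corr(np.ones(5), np.ones(5)) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            pearson_corr(np.ones(3), np.ones(4))


class TestMeanFrequency:
    def test_tone_frequencies(self):
        t = np.arange(0, 1, 1 / FS)
        assert mean_frequency(np.sin(2 * np.pi * 10 * t), FS) == pytest.approx(10, abs=0.5)
        t2 = np.arange(0, 2, 1 / FS)
        f2 = mean_frequency(np.sin(2 * np.pi * 2 * t2), FS)
        assert f2 == pytest.approx(2, abs=0.5) and f2 < 5.0

    def test_constant_is_zero(self):
        assert mean_frequency(np.zeros(100), FS) == 0.0


class TestClassify:
    def test_rule_assignment(self, two_tone, fast_ceemdan):
        sig, _, _ = two_tone
        dec = ceemdan(sig, fast_ceemdan)
        cls = classify_imfs(dec, sig)
        # every sub-5 Hz mode is drift, independent of correlation
        for lab, f in zip(cls.labels, cls.mean_freqs):
            if f < 5.0:
                assert lab == LABEL_DRIFT
        assert cls.correlations.min() >= -1 and cls.correlations.max() <= 1

    def test_uncorrelated_noise_mode_flagged(self, two_tone, fast_ceemdan):
        sig, _, _ = two_tone
        dec = ceemdan(sig, fast_ceemdan)
        # forge a mode of independent white noise: correlation ~ 0 < 0.5
        rng = np.random.default_rng(1)
        dec.imfs[0] = rng.standard_normal(dec.source_length)
        cls = classify_imfs(dec, sig)
        assert cls.labels[0] == LABEL_NOISY

    def test_identical_mode_is_signal(self, two_tone, fast_ceemdan):
        sig, fast, _ = two_tone
        dec = ceemdan(sig, fast_ceemdan)
        dec.imfs[0] = sig.samples.copy()
        cls = classify_imfs(dec, sig)
        assert cls.labels[0] == LABEL_SIGNAL
        assert cls.correlations[0] == pytest.approx(1.0)


class TestWaveletThreshold:
    def test_zero_in_zero_out(self):
        assert not wavelet_threshold(np.zeros(256)).any()

    def test_hard_zero_threshold_is_identity(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(256)
        cfg = DenoiseConfig(threshold_mode="hard")
        out = wavelet_threshold(x, cfg, threshold=0.0)
        assert np.allclose(out, x, atol=1e-10)

    def test_monte_carlo_noise_reduction(self):
        t = np.arange(0, 1, 1 / FS)
        clean = np.sin(2 * np.pi * 20 * t)
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            noisy = clean + 0.3 * rng.standard_normal(t.size)
            out = wavelet_threshold(noisy)
            wins += mse(out, clean) < mse(noisy, clean)
        assert wins >= 18

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            wavelet_threshold(np.zeros(4))


class TestHybridDenoise:
    def test_pure_drift_maps_to_zero(self, fast_ceemdan):
        t = np.arange(0, 2, 1 / FS)
        x = np.sin(2 * np.pi * 2 * t)
        den, cls = denoise(Signal(x, FS), ceemdan_cfg=fast_ceemdan)
        assert np.sum(den.samples**2) / np.sum(x**2) < 0.05

    def test_clean_emg_energy_retained(self, short_trial, fast_ceemdan):
        clean = short_trial["clean"][0]
        den, _ = denoise(Signal(clean, FS), ceemdan_cfg=fast_ceemdan)
        ratio = np.sum(den.samples**2) / np.sum(clean**2)
        assert ratio > 0.9

    def test_energy_non_creation(self, short_trial, fast_ceemdan):
        noisy = short_trial["noisy"][0]
        den, _ = denoise(Signal(noisy, FS), ceemdan_cfg=fast_ceemdan)
        # mode non-orthogonality allows a small (<2%) cross-term excess
        assert np.sum(den.samples**2) <= 1.02 * np.sum(noisy**2)

    def test_mse_improves_over_noisy(self, short_trial, fast_ceemdan):
        clean, noisy = short_trial["clean"][0], short_trial["noisy"][0]
        den, _ = denoise(Signal(noisy, FS), ceemdan_cfg=fast_ceemdan)
        assert mse(den.samples, clean) < mse(noisy, clean)

    def test_idempotence_tendency(self):
        # a second pass removes much less than the first (median across seeds)
        ratios = []
        for seed in range(5):
            angles = gen_angles(GaitProfile(n_cycles=2), seed=seed)
            clean, noisy, _, _ = gen_emg(angles, seed=seed)
            cfg = CeemdanConfig(k=12, eps0=0.2, seed=seed)
            d1, _ = denoise(Signal(noisy[0], FS), ceemdan_cfg=cfg)
            d2, _ = denoise(d1, ceemdan_cfg=cfg)
            e_in = np.sum(noisy[0] ** 2)
            e1 = np.sum(d1.samples**2)
            e2 = np.sum(d2.samples**2)
            ratios.append(abs(e1 - e2) / (e_in - e1))
        assert np.median(ratios) < 0.25

    def test_comparator_harness(self, short_trial, fast_ceemdan):
        # hybrid vs wavelet-only vs Butterworth: all three produce a finite
        # MSE against the clean truth (ordering is data-dependent)
        clean, noisy = short_trial["clean"][0], short_trial["noisy"][0]
        hybrid, _ = denoise(Signal(noisy, FS), ceemdan_cfg=fast_ceemdan)
        results = {
            "hybrid": mse(hybrid.samples, clean),
            "wavelet": mse(wavelet_only_denoise(noisy), clean),
            "butterworth": mse(butterworth_bandpass(noisy, FS), clean),
        }
        assert all(np.isfinite(v) and v >= 0 for v in results.values())


class TestMse:
    @pytest.mark.parametrize("a,b,expected", [
        ([1, 2, 3], [1, 2, 3], 0.0),
        ([1, 2], [0, 0], 2.5),
        ([3], [0], 9.0),
    ])
    def test_examples(self, a, b, expected):
        assert mse(np.array(a, float), np.array(b, float)) == pytest.approx(expected)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            mse(np.ones(2), np.ones(3))
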