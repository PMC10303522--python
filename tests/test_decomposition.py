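"""Sifting, EMD and CEEMDAN behaviour on signals with known structure."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emgkin.decomposition import (CeemdanConfig, Signal, ceemdan, emd,
                                  emd_mode_j, find_extrema, sift_once)
from emgkin.denoising import mean_frequency


def _rel_rms(a, b):
    return np.sqrt(np.mean((a - b) ** 2)) / max(np.sqrt(np.mean(b**2)), 1e-300)


class TestFindExtrema:
    @pytest.mark.parametrize("x,max_idx,min_idx", [
        ([0, 1, 0, -1, 0], [1], [3]),
        ([5, 5, 5, 5], [], []),
        ([0, 1, 1, 0, -1, -1, 0], [1], [4]),  # plateau midpoints
        ([0, 1, 2, 3], [], []),  # monotone
    ])
    def test_examples(self, x, max_idx, min_idx):
        mi, mv, ni, nv = find_extrema(np.array(x, dtype=float))
        assert list(mi) == max_idx
        assert list(ni) == min_idx

    def test_single_period_sine(self):
        # one period sampled at 16 points: exactly one max, one min
        x = np.sin(2 * np.pi * np.arange(16) / 16)
        mi, _, ni, _ = find_extrema(x)
        assert mi.size == 1 and ni.size == 1

    def test_plateau_value_unchanged(self):
        x = np.array([0.0, 2.0, 2.0, 2.0, 0.0, -1.0, 0.0])
        mi, mv, _, _ = find_extrema(x)
        assert list(mi) == [2] and mv[0] == 2.0


class TestSiftOnce:
    def test_pure_sinusoid_is_near_fixed_point(self):
        # envelopes of a dense pure tone are ±1, their mean ~0
        t = np.arange(256)
        x = np.sin(2 * np.pi * t / 8)
        out = sift_once(x)
        assert _rel_rms(out, x) < 0.05

    def test_offset_removed(self):
        t = np.arange(256)
        x = np.sin(2 * np.pi * t / 8) + 3.0
        out = sift_once(x)
        # envelope mean ~3, so output is the zero-mean sinusoid
        assert abs(np.mean(out[8:-8])) < 0.05
        assert _rel_rms(out[8:-8], (x - 3.0)[8:-8]) < 0.05

    def test_monotone_refused(self):
        with pytest.raises(ValueError):
            sift_once(np.arange(10.0))


class TestEmd:
    def test_two_tone_first_mode_is_fast(self, two_tone):
        sig, fast, _ = two_tone
        dec = emd(sig)
        assert np.corrcoef(dec.imfs[0], fast)[0, 1] > 0.95

    def test_monotone_ramp(self):
        dec = emd(np.linspace(0, 1, 64))
        assert dec.n_modes == 0
        assert np.allclose(dec.residual, np.linspace(0, 1, 64))

    def test_reconstruction_identity(self, two_tone):
        sig, _, _ = two_tone
        dec = emd(sig)
        assert _rel_rms(dec.reconstruct(), sig.samples) < 1e-10

    def test_imf_criteria_on_modes(self, two_tone):
        # extrema and zero-crossing counts differ by at most 1 per mode
        sig, _, _ = two_tone
        dec = emd(sig)
        for mode in dec.imfs[:2]:
            mi, _, ni, _ = find_extrema(mode)
            s = np.sign(mode)
            s = s[s != 0]
            zc = np.count_nonzero(np.diff(s))
            assert abs((mi.size + ni.size) - zc) <= 1

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            emd(np.array([0.0, np.nan, 1.0, 0.0]))

    def test_csv_export_round_trip(self, two_tone, tmp_path):
        import pandas as pd

        sig, _, _ = two_tone
        dec = emd(sig)
        path = tmp_path / "imfs.csv"
        dec.to_csv(path)
        df = pd.read_csv(path)
        assert list(df.columns) == [f"IMF{i+1}" for i in range(dec.n_modes)] + ["residual"]
        assert np.allclose(df["IMF1"], dec.imfs[0])


class TestEmdModeJ:
    def test_mode_one_is_fast_component(self, two_tone):
        sig, fast, _ = two_tone
        m1 = emd_mode_j(sig.samples, 1)
        assert np.corrcoef(m1, fast)[0, 1] > 0.95

    def test_j_beyond_modes_is_zero(self, two_tone):
        sig, _, _ = two_tone
        assert not emd_mode_j(sig.samples, 40).any()

    def test_e1_of_pure_imf_is_itself(self):
        t = np.arange(512)
        imf = np.sin(2 * np.pi * t / 16)
        m1 = emd_mode_j(imf, 1)
        assert _rel_rms(m1[16:-16], imf[16:-16]) < 0.05


class TestCeemdan:
    def test_noise_free_degenerates_to_emd(self, two_tone):
        sig, _, _ = two_tone
        d_plain = emd(sig)
        d_ens = ceemdan(sig, CeemdanConfig(k=1, eps0=0.0, seed=9))
        assert np.array_equal(d_ens.imfs, d_plain.imfs)
        assert np.array_equal(d_ens.residual, d_plain.residual)

    def test_reconstruction(self, two_tone, fast_ceemdan):
        sig, _, _ = two_tone
        dec = ceemdan(sig, fast_ceemdan)
        assert _rel_rms(dec.reconstruct(), sig.samples) < 1e-8

    def test_deterministic_in_seed(self, two_tone, fast_ceemdan):
        sig, _, _ = two_tone
        a = ceemdan(sig, fast_ceemdan)
        b = ceemdan(sig, fast_ceemdan)
        assert np.array_equal(a.imfs, b.imfs)
        c = ceemdan(sig, CeemdanConfig(k=12, eps0=0.2, seed=1))
        assert not np.array_equal(a.imfs, c.imfs)

    def test_two_tone_separation(self, two_tone):
        # the dominant high-frequency mode carries the 50 Hz tone; the
        # ensemble noise occupies the (negligible-energy) faster modes
        sig, fast, slow = two_tone
        dec = ceemdan(sig, CeemdanConfig(k=30, eps0=0.2, seed=1))
        energies = np.sum(dec.imfs**2, axis=1)
        dominant = int(np.argmax(energies[: dec.n_modes // 2]))
        assert np.corrcoef(dec.imfs[dominant], fast)[0, 1] > 0.9
        # slow content sits in the trailing modes/residual
        tail = dec.imfs[dominant + 1:].sum(axis=0) + dec.residual
        assert np.corrcoef(tail, slow)[0, 1] > 0.9

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            CeemdanConfig(k=0)
        with pytest.raises(ValueError):
            CeemdanConfig(eps0=-0.1)

    def test_mode_ordering_zero_crossing_rate(self, fast_ceemdan):
        # mean zero-crossing rate decreases along the mode index, with a
        # 10% violation allowance for mode mixing
        rng = np.random.default_rng(0)
        t = np.arange(2048) / 1000.0
        x = (np.sin(2 * np.pi * 80 * t) + np.sin(2 * np.pi * 11 * t)
             + 0.5 * rng.standard_normal(t.size))
        dec = ceemdan(Signal(x, 1000.0), fast_ceemdan)
        freqs = [mean_frequency(m, 1000.0) for m in dec.imfs]
        pairs = list(zip(freqs[:-1], freqs[1:]))
        violations = sum(a < b for a, b in pairs)
        assert violations <= max(1, int(0.1 * len(pairs)))


@settings(max_examples=15, deadline=None)
@given(st.integers(min_value=0, max_value=10_000))
def test_reconstruction_property(seed):
    """Modes plus residual reconstruct any random signal (conservation)."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(64, 400))
    x = np.cumsum(rng.standard_normal(n))  # random walk: broadband + trend
    dec = ceemdan(Signal(x, 100.0), CeemdanConfig(k=4, eps0=0.1, seed=seed))
    assert _rel_rms(dec.reconstruct(), x) < 1e-8
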