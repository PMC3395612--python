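"""Usage profiles, display normalization, modulation spectra, separability, SNR curves."""

import numpy as np
import pytest
from scipy import stats

from sparsespec.analysis import (
    display_normalize,
    modulation_spectrum,
    separability_index,
    snr_sparsity_curve,
    usage_profile,
)
from sparsespec.lca import LcaConfig
from sparsespec.synthetic import make_planted_problem


@pytest.fixture
def grating_axes():
    # 1 s x 4 octaves, resolutions chosen so integer modulations land on bins
    freqs = 200.0 * 2 ** (np.arange(64) / 16.0)  # 1/16 octave per channel
    times = np.arange(50) / 50.0  # 20 ms frames over 1 s
    return freqs, times


def grating(freqs, times, temporal_cps, spectral_cpo):
    octaves = np.log2(freqs / freqs[0])[:, None]
    return np.cos(2 * np.pi * (temporal_cps * times[None, :] + spectral_cpo * octaves))


class TestUsageProfile:
    def test_element_orthogonal_to_all_patches_is_never_used(self):
        phi = np.eye(4)
        patches = np.zeros((10, 4))
        patches[:, :2] = np.random.default_rng(0).laplace(size=(10, 2)) + 2.0
        usage = usage_profile(phi, patches, LcaConfig(mode="l1", lam=0.05, n_steps=500))
        assert usage.counts[3] == 0
        assert usage.n_stimuli == 10

    def test_single_patch_recruits_exactly_its_atom(self):
        phi = np.eye(5)
        patch = 2.0 * phi[:, 2]
        usage = usage_profile(phi, patch[None], LcaConfig(mode="l1", lam=0.1, n_steps=500))
        np.testing.assert_array_equal(usage.counts, [0, 0, 1, 0, 0])

    def test_ordering_is_deterministic_permutation_with_index_ties(self):
        phi = np.eye(3)
        usage = usage_profile(phi, np.zeros((4, 3)), LcaConfig(mode="l1", lam=0.1))
        np.testing.assert_array_equal(np.sort(usage.order), [0, 1, 2])
        np.testing.assert_array_equal(usage.order, [0, 1, 2])  # ties -> index order

    def test_counts_follow_binomial_under_uniform_atom_choice(self):
        prob = make_planted_problem(8, 8, 1000, 1, 0.0, seed=31)
        q, _ = np.linalg.qr(prob.true_dictionary)  # orthonormalize for exactness
        X = (q @ prob.codes).T
        usage = usage_profile(q, X, LcaConfig(mode="l1", lam=0.01, n_steps=800, tol=1e-9))
        p_active = 1.0 / 8.0  # uniform atom choice (amplitudes ~ always above lam)
        n = 1000
        sd = np.sqrt(n * p_active * (1 - p_active))
        assert np.all(np.abs(usage.counts - n * p_active) <= 3 * sd)


class TestDisplayNormalize:
    def test_scales_to_unit_peak_without_flip_for_positive_skew(self, rng):
        img = rng.uniform(-0.2, 0.6, size=(8, 10)) ** 3 + 0.1
        out = display_normalize(img)
        assert np.max(np.abs(out)) == pytest.approx(1.0)
        assert stats.skew(out.ravel()) >= 0

    def test_flip_is_an_involution(self, rng):
        img = rng.uniform(-0.2, 0.6, size=(8, 10))
        img = img - np.median(img) + 0.3  # force positive skew side
        out = display_normalize(img)
        out_neg = display_normalize(-img)
        np.testing.assert_allclose(out_neg, out, atol=1e-12)

    def test_zero_skew_image_keeps_sign(self):
        img = np.array([[1.0, -1.0], [-0.5, 0.5]])
        assert stats.skew(img.ravel()) == pytest.approx(0.0)
        out = display_normalize(img)
        assert out[0, 0] > 0  # unchanged polarity

    def test_constant_image_returned_unchanged(self):
        img = np.full((4, 4), 2.5)
        np.testing.assert_array_equal(display_normalize(img), img)


class TestModulationSpectrum:
    def test_constant_image_flags_zero_power(self, grating_axes):
        freqs, times = grating_axes
        mod = modulation_spectrum(np.ones((64, 50)), freqs, times)
        assert mod.zero_power
        assert (mod.temporal_peak, mod.spectral_peak) == (0.0, 0.0)
        assert (mod.temporal_centroid, mod.spectral_centroid) == (0.0, 0.0)

    @pytest.mark.parametrize("t_cps,s_cpo", [(4.0, 2.0), (10.0, 1.0), (4.0, -2.0)])
    def test_pure_grating_peak(self, grating_axes, t_cps, s_cpo):
        freqs, times = grating_axes
        mod = modulation_spectrum(grating(freqs, times, t_cps, s_cpo), freqs, times)
        assert mod.temporal_peak == pytest.approx(abs(t_cps))
        assert mod.spectral_peak == pytest.approx(abs(s_cpo))

    def test_two_grating_centroid_matches_brute_force(self, grating_axes):
        freqs, times = grating_axes
        img = grating(freqs, times, 4.0, 2.0) + 0.5 * grating(freqs, times, 10.0, 0.5)
        mod = modulation_spectrum(img, freqs, times)
        # independent centroid over the full DFT grid
        P = np.abs(np.fft.fft2(img - img.mean())) ** 2
        fs = np.fft.fftfreq(64, d=1 / 16.0)
        ft = np.fft.fftfreq(50, d=times[1] - times[0])
        keep = fs >= 0
        W = P[keep]
        t_exp = (W * np.abs(ft)[None, :]).sum() / W.sum()
        s_exp = (W * fs[keep][:, None]).sum() / W.sum()
        assert mod.temporal_centroid == pytest.approx(t_exp)
        assert mod.spectral_centroid == pytest.approx(s_exp)
        # power-weighted centroid lies between the two component peaks
        assert 4.0 < mod.temporal_centroid < 10.0
        assert 0.5 < mod.spectral_centroid < 2.0

    def test_invariant_to_sign_and_scale(self, grating_axes, rng):
        freqs, times = grating_axes
        img = rng.standard_normal((64, 50))
        m1 = modulation_spectrum(img, freqs, times)
        m2 = modulation_spectrum(-3.0 * img, freqs, times)
        assert m1.temporal_centroid == pytest.approx(m2.temporal_centroid)
        assert m1.spectral_centroid == pytest.approx(m2.spectral_centroid)
        assert m1.temporal_peak == pytest.approx(m2.temporal_peak)

    def test_linear_frequency_axis_rejected(self):
        with pytest.raises(ValueError, match="log"):
            modulation_spectrum(
                np.ones((16, 10)), np.linspace(100, 4000, 16), np.arange(10) * 0.01
            )


class TestSeparabilityIndex:
    def test_outer_product_is_perfectly_separable(self, rng):
        img = np.outer(rng.standard_normal(12), rng.standard_normal(20))
        assert separability_index(img) == pytest.approx(1.0, abs=1e-10)

    def test_two_equal_orthogonal_modes_give_half(self):
        u = np.array([1.0, 0.0]); v = np.array([0.0, 1.0])
        img = np.outer(u, [1.0, 0.0, 0.0]) + np.outer(v, [0.0, 1.0, 0.0])
        assert separability_index(img) == pytest.approx(0.5)

    def test_matches_gram_matrix_eigensolve(self, rng):
        img = rng.standard_normal((9, 14))
        eig = np.linalg.eigvalsh(img @ img.T)
        expected = eig.max() / eig.sum()
        assert separability_index(img) == pytest.approx(expected, rel=1e-10)

    def test_zero_image_raises(self):
        with pytest.raises(ValueError):
            separability_index(np.zeros((4, 4)))


class TestSnrSparsityCurve:
    def test_huge_lambda_gives_zero_active_and_zero_db(self):
        prob = make_planted_problem(6, 6, 20, 2, 0.0, seed=3)
        curve = snr_sparsity_curve(
            prob.true_dictionary,
            prob.observations.T,
            [1e6],
            LcaConfig(mode="l1", lam=1.0, n_steps=100),
        )
        assert curve["active_fraction"].iloc[0] == 0.0
        assert curve["snr_db"].iloc[0] == pytest.approx(0.0)

    def test_small_lambda_orthonormal_reconstructs_above_40_db(self, rng):
        q, _ = np.linalg.qr(rng.standard_normal((10, 10)))
        codes = rng.laplace(size=(10, 30)) * (rng.random((10, 30)) < 0.2)
        X = (q @ codes).T
        X = X[np.any(X, axis=1)]
        curve = snr_sparsity_curve(
            q, X, [1e-4], LcaConfig(mode="l1", lam=1.0, n_steps=3000, tol=1e-12)
        )
        assert curve["snr_db"].iloc[0] > 40.0

    def test_active_fraction_nonincreasing_in_lambda(self):
        prob = make_planted_problem(8, 12, 30, 3, 0.05, seed=9)
        curve = snr_sparsity_curve(
            prob.true_dictionary,
            prob.observations.T,
            [0.01, 0.05, 0.2, 0.5, 1.0],
            LcaConfig(mode="l1", lam=1.0, n_steps=300),
        )
        fracs = curve["active_fraction"].to_numpy()
        assert np.all(np.diff(fracs) <= 1e-12)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            snr_sparsity_curve(np.eye(3), np.ones((2, 3)), [], LcaConfig())
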