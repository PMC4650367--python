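"""Smoothed CDFs, kernel copula density, bandwidths, empirical tau."""

import numpy as np
import pytest

from copsep.copula_models import CopulaSpec, copula_sample
from copsep.nonparam_estimation import (
    BandwidthSet,
    fit_pseudo_observations,
    kendall_tau_empirical,
    kernel_copula_density,
    marginal_bandwidths,
    pseudo_observations,
    silverman_bandwidths,
    smoothed_marginal_cdf,
)


class TestSilvermanBandwidths:
    def test_marginal_formula_direct(self, rng):
        """h = (4/3)^(1/5) N^(-1/5) sigma, evaluated directly."""
        y = rng.standard_normal(1000)
        y = (y - y.mean()) / y.std(ddof=1)  # sample std exactly 1
        h = marginal_bandwidths(y[None, :])[0]
        assert h == pytest.approx((4.0 / 3.0) ** 0.2 * 1000 ** (-0.2), rel=1e-12)

    def test_copula_bandwidth_formula_direct(self, rng):
        Y = rng.standard_normal((2, 500))
        U, bw = fit_pseudo_observations(Y)
        p, N = Y.shape
        expected = (4.0 / (p + 2)) ** (1.0 / (p + 4)) * N ** (-1.0 / (p + 4)) * U.U.std(axis=0, ddof=1)
        np.testing.assert_allclose(bw.H, expected, rtol=1e-12)

    def test_scale_equivariance(self, rng):
        Y = rng.standard_normal((2, 400))
        U1, bw1 = fit_pseudo_observations(Y)
        U2, bw2 = fit_pseudo_observations(2.0 * Y)
        np.testing.assert_allclose(bw2.h, 2.0 * bw1.h, rtol=1e-12)
        np.testing.assert_allclose(bw2.H, bw1.H, rtol=1e-12)
        np.testing.assert_allclose(U2.U, U1.U, rtol=1e-12)

    def test_bandwidth_decreases_with_n(self, rng):
        y = rng.standard_normal(4000)
        hs = [marginal_bandwidths(y[None, :n])[0] for n in (500, 1000, 2000, 4000)]
        # compare at equal sigma by rescaling out the sample-std factor
        sig = [y[:n].std(ddof=1) for n in (500, 1000, 2000, 4000)]
        pure = [h / s for h, s in zip(hs, sig)]
        assert all(a > b for a, b in zip(pure, pure[1:]))

    def test_zero_variance_channel_rejected(self):
        with pytest.raises(ValueError):
            marginal_bandwidths(np.ones((1, 100)))


class TestSmoothedMarginalCdf:
    def test_limits(self, rng):
        y = rng.standard_normal(50)
        assert smoothed_marginal_cdf(y, -1e6, 0.5) == pytest.approx(0.0, abs=1e-12)
        assert smoothed_marginal_cdf(y, 1e6, 0.5) == pytest.approx(1.0, abs=1e-12)

    def test_single_sample_at_origin(self):
        assert smoothed_marginal_cdf(np.array([0.0]), 0.0, 0.3) == pytest.approx(0.5)

    def test_monotone_nondecreasing(self, rng):
        y = rng.standard_normal(200)
        x = np.linspace(-3, 3, 101)
        F = smoothed_marginal_cdf(y, x, 0.2)
        assert np.all(np.diff(F) >= 0)

    def test_small_bandwidth_matches_ecdf_oracle(self, rng):
        """As h -> 0 the estimate converges to the empirical CDF."""
        y = np.sort(rng.standard_normal(40))
        x = 0.5 * (y[:-1] + y[1:])  # between order statistics
        F = smoothed_marginal_cdf(y, x, 1e-6)
        ecdf = np.searchsorted(y, x, side="right") / y.size
        np.testing.assert_allclose(F, ecdf, atol=1e-6)


class TestPseudoObservations:
    def test_monotone_in_sample(self):
        Y = np.linspace(0, 1, 50)[None, :] ** 2
        U, _ = fit_pseudo_observations(np.vstack([Y, Y + 1]))
        assert np.all(np.diff(U.U[:, 0]) > 0)

    def test_identical_channels_identical_columns(self, rng):
        y = rng.standard_normal(300)
        U, _ = fit_pseudo_observations(np.vstack([y, y]))
        np.testing.assert_array_equal(U.U[:, 0], U.U[:, 1])

    def test_uniform_data_close_to_uniform(self, rng):
        from scipy.stats import kstest

        Y = rng.uniform(size=(2, 2000))
        U, _ = fit_pseudo_observations(Y)
        assert kstest(U.U[:, 0], "uniform").statistic <= 0.05

    def test_affine_invariance(self, rng):
        """Positive affine maps of a channel leave pseudo-observations unchanged."""
        Y = rng.standard_normal((2, 300))
        Y2 = Y.copy()
        Y2[0] = 3.5 * Y2[0] - 1.2
        U1, _ = fit_pseudo_observations(Y)
        U2, _ = fit_pseudo_observations(Y2)
        np.testing.assert_allclose(U1.U, U2.U, atol=1e-10)


class TestKernelCopulaDensity:
    def test_single_observation_closed_form(self):
        """N=1, evaluation at the observation itself, no boundary terms."""
        U = pseudo_observations(np.array([[0.0], [0.0]]) + 0.5, BandwidthSet(H=[1, 1], h=[1, 1]))
        H = np.array([0.2, 0.3])
        val = kernel_copula_density(U, U.U[0], H, boundary="none")
        expected = np.prod(1.0 / (np.sqrt(2 * np.pi) * H))
        assert val == pytest.approx(expected)

    def test_independent_uniforms_near_one(self, rng):
        Y = rng.uniform(size=(2, 5000))
        U, bw = fit_pseudo_observations(Y)
        val = kernel_copula_density(U, np.array([0.5, 0.5]), bw.H)
        assert abs(val - 1.0) <= 0.15

    def test_integrates_to_one_with_reflection(self, rng):
        Y = rng.uniform(size=(2, 1000))
        U, bw = fit_pseudo_observations(Y)
        g = (np.arange(100) + 0.5) / 100.0
        gx, gy = np.meshgrid(g, g)
        pts = np.column_stack([gx.ravel(), gy.ravel()])
        integral = kernel_copula_density(U, pts, bw.H, boundary="reflect").mean()
        assert integral == pytest.approx(1.0, abs=0.02)
        raw = kernel_copula_density(U, pts, bw.H, boundary="none").mean()
        assert raw < integral  # raw estimator loses mass at the edges

    def test_nonnegative(self, rng):
        Y = rng.standard_normal((2, 200))
        U, bw = fit_pseudo_observations(Y)
        pts = rng.uniform(0.05, 0.95, size=(50, 2))
        assert np.all(kernel_copula_density(U, pts, bw.H) >= 0)


class TestKendallTau:
    def test_monotone_curves(self):
        x = np.linspace(0, 1, 50)
        assert kendall_tau_empirical(np.column_stack([x, x**3])) == 1.0
        assert kendall_tau_empirical(np.column_stack([x, -np.sqrt(x)])) == -1.0

    def test_matches_bruteforce_oracle(self, rng):
        """tau-a equals the O(N^2) pairwise count, including tied data."""
        for trial in range(5):
            n = 120
            x = rng.integers(0, 25, size=n).astype(float)  # forces ties
            y = rng.standard_normal(n) + 0.5 * x
            num = 0
            for i in range(n):
                for j in range(i + 1, n):
                    num += np.sign((x[i] - x[j]) * (y[i] - y[j]))
            expected = num / (n * (n - 1) / 2.0)
            got = kendall_tau_empirical(np.column_stack([x, y]))
            assert got == pytest.approx(expected, abs=1e-12)

    def test_clayton_sample_tau(self):
        s = copula_sample(CopulaSpec("clayton", 0.5), 5000, seed=3)
        assert kendall_tau_empirical(s) == pytest.approx(0.2, abs=0.03)

    def test_invariance_and_sign_flip(self, rng):
        pairs = rng.standard_normal((200, 2))
        tau = kendall_tau_empirical(pairs)
        monotone = np.column_stack([np.exp(pairs[:, 0]), pairs[:, 1] ** 3 + pairs[:, 1]])
        assert kendall_tau_empirical(monotone) == pytest.approx(tau, abs=1e-12)
        flipped = pairs * np.array([1.0, -1.0])
        assert kendall_tau_empirical(flipped) == pytest.approx(-tau, abs=1e-12)

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            kendall_tau_empirical(np.column_stack([np.ones(10), np.arange(10.0)]))


def test_plugin_mutual_information_shrinks_with_n():
    """Mean log c-hat over pseudo-observations of independent data decreases
    with the sample size (the kernel plug-in bias vanishes asymptotically)."""
    from copsep.bss_separation import klm_criterion
    from copsep.copula_models import CopulaSpec

    vals = {}
    for n in (500, 2000):
        acc = []
        for seed in (0, 1, 2):
            Y = np.random.default_rng(seed).uniform(size=(2, n))
            acc.append(klm_criterion(Y, CopulaSpec("product"), subsample=None))
        vals[n] = np.mean(acc)
    assert vals[2000] < vals[500]
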