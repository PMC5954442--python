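"""Bayesian scoring: sigma_SEM, likelihood, marginalized erf score, gradients,
Gibbs sampling of noise parameters, and a posteriori noise estimation."""

import numpy as np
import pytest
from scipy import integrate

from cryometa.forward import OverlapCalculator
from cryometa.gmm import DensityMap, GaussianMixture, self_overlaps
from cryometa.scoring import (
    KB,
    MetaInfParams,
    NoiseEstimate,
    StaleNeighborListError,
    error_density_map,
    estimate_noise_posterior,
    gaussian_likelihood,
    gibbs_sample_sigma,
    marginal_score,
    score_gradient,
    sigma_sem,
)

from conftest import random_component


def jeffreys_marginal_quadrature(delta, sem, kbt=1.0):
    """Independent oracle: -kBT log of the Eq.-style likelihood marginalized
    over the total sigma in [sem, inf) under a Jeffreys prior, computed by
    quadrature after the substitution u = 1/sigma (plain Gaussian integrand).
    """
    b = 1.0 / sem
    f = lambda u: np.exp(-(delta**2) * u**2 / 2.0) / np.sqrt(2.0 * np.pi)
    if delta != 0 and 10.0 / abs(delta) < b:
        split = 10.0 / abs(delta)
        val = (
            integrate.quad(f, 0.0, split, limit=200)[0]
            + integrate.quad(f, split, b, limit=200)[0]
        )
    else:
        val = integrate.quad(f, 0.0, b, limit=200)[0]
    return -kbt * np.log(val)


class TestSigmaSem:
    @pytest.mark.parametrize("alpha,expected", [(0.01, 0.05), (0.1, 0.5)])
    def test_scales_with_ovdd(self, alpha, expected):
        assert sigma_sem(np.array([5.0]), alpha)[0] == pytest.approx(expected)

    def test_singular_limit_guarded(self):
        with pytest.raises(ValueError, match="singular"):
            sigma_sem(np.array([5.0]), 1e-7)


class TestGaussianLikelihood:
    def test_zero_deviation_closed_form(self):
        val = gaussian_likelihood(1.0, 1.0, 0.0, 0.1)
        assert val == pytest.approx(1.0 / (np.sqrt(2 * np.pi) * 0.1), rel=1e-12)

    def test_one_sigma_deviation_factor(self):
        v0 = gaussian_likelihood(1.0, 1.0, 0.0, 0.1)
        v1 = gaussian_likelihood(1.1, 1.0, 0.0, 0.1)
        assert v1 == pytest.approx(v0 * np.exp(-0.5), rel=1e-12)

    def test_normalization_over_deviation(self):
        sem, sb = 0.07, 0.03
        total, _ = integrate.quad(
            lambda d: gaussian_likelihood(d, 0.0, sb, sem), -np.inf, np.inf
        )
        assert total == pytest.approx(1.0, rel=1e-9)


class TestMarginalScore:
    def test_zero_deviation_limit(self):
        e = marginal_score(np.array([1.0]), np.array([1.0]), np.array([0.1]), 1.0)
        assert e == pytest.approx(-np.log(1.0 / (np.sqrt(2 * np.pi) * 0.1)), rel=1e-12)

    def test_large_deviation_log_asymptote(self):
        delta = 50.0
        e = marginal_score(np.array([delta]), np.array([0.0]), np.array([0.1]), 1.0)
        assert e == pytest.approx(np.log(2 * delta), rel=1e-9)

    def test_even_increasing_and_continuous_at_zero(self):
        sem = np.array([0.05])
        deltas = np.array([1e-12, 1e-8, 1e-5, 1e-3, 0.01, 0.1, 1.0])
        e0 = marginal_score(np.array([0.0]), np.array([0.0]), sem, 1.0)
        prev = e0
        for d in deltas:
            ep = marginal_score(np.array([d]), np.array([0.0]), sem, 1.0)
            em = marginal_score(np.array([-d]), np.array([0.0]), sem, 1.0)
            assert ep == pytest.approx(em, rel=1e-12)
            assert ep >= prev - 1e-12  # strictly increasing in |delta|
            prev = ep
        near0 = marginal_score(np.array([1e-12]), np.array([0.0]), sem, 1.0)
        assert near0 == pytest.approx(e0, abs=1e-10)

    def test_matches_jeffreys_quadrature_on_grid(self):
        # the erf identity over a (delta, sigma_SEM) grid including delta = 0
        deltas = np.concatenate([[0.0], np.geomspace(1e-6, 10.0, 12)])
        sems = np.geomspace(1e-3, 1.0, 8)
        for d in deltas:
            for s in sems:
                mine = marginal_score(np.array([d]), np.array([0.0]), np.array([s]), 1.0)
                ref = jeffreys_marginal_quadrature(d, s)
                assert mine == pytest.approx(ref, rel=1e-6, abs=1e-10)


def _toy_system(rng, n_part=10, n_comp=6, n_rep=2):
    comps = [random_component(rng, aniso=0.1, base_var=0.02) for _ in range(n_comp)]
    w = np.array([c.weight for c in comps])
    data = GaussianMixture(
        w / w.sum(), [c.mean for c in comps], [c.cov for c in comps], normalized=True
    )
    calc = OverlapCalculator(data, np.full(n_part, 0.1), np.full(n_part, 0.02))
    coords = rng.uniform(-0.4, 0.4, (n_rep, n_part, 3))
    nl = calc.build_neighbor_list(coords, 1e-4)
    ovdd = self_overlaps(data)
    sig = sigma_sem(ovdd, 0.1)
    return data, calc, coords, nl, ovdd, sig


class TestScoreGradient:
    def test_finite_difference_consistency(self, rng):
        data, calc, coords, nl, ovdd, sig = _toy_system(rng)
        kbt = KB * 300
        _, forces, _ = score_gradient(coords, calc, nl, ovdd, sig, kbt)
        h = 1e-5
        for r in range(coords.shape[0]):
            for k in range(coords.shape[1]):
                for d in range(3):
                    cp, cm_ = coords.copy(), coords.copy()
                    cp[r, k, d] += h
                    cm_[r, k, d] -= h
                    ep, _, _ = score_gradient(cp, calc, nl, ovdd, sig, kbt)
                    em, _, _ = score_gradient(cm_, calc, nl, ovdd, sig, kbt)
                    num = -(ep - em) / (2 * h)
                    if abs(num) > 1e-8:
                        assert forces[r, k, d] == pytest.approx(num, rel=1e-5)

    def test_all_zero_deviation_gives_finite_zero_forces(self, rng):
        # ovMD_bar == ovDD: every Delta_i = 0; the erf limit must be finite
        # with vanishing dE/dDelta
        data, calc, _, _, ovdd, sig = _toy_system(rng)
        from cryometa.scoring import score_terms

        e, dEdD = score_terms(ovdd, ovdd, sig, KB * 300)
        assert np.all(np.isfinite(e))
        np.testing.assert_allclose(dEdD, 0.0, atol=1e-12)

    def test_stale_neighbor_list_refused(self, rng):
        data, calc, coords, nl, ovdd, sig = _toy_system(rng)
        with pytest.raises(StaleNeighborListError):
            score_gradient(coords, calc, nl, ovdd, sig, 1.0, step=nl.update_every + 1)


class TestGibbsSampling:
    def test_large_deviation_posterior_mode_near_delta(self):
        chain, acc = gibbs_sample_sigma(
            np.array([5.0]), 0.01, (1e-4, 1e3), n_steps=20000, seed=1
        )
        med = np.median(chain[5000:])
        assert 2.0 < med < 15.0  # total sigma concentrates near |Delta| = 5
        assert acc > 0.05

    def test_zero_deviation_concentrates_at_lower_bound(self):
        chain, _ = gibbs_sample_sigma(
            np.zeros(50), 0.1, (1e-3, 1e2), n_steps=20000, seed=2
        )
        assert np.median(chain[5000:]) < 5e-3

    def test_chain_matches_quadrature_posterior(self):
        deltas = np.array([0.3, -0.1, 0.25, 0.05, -0.3])
        sem = 0.05
        lo, hi = 1e-3, 10.0
        chain, _ = gibbs_sample_sigma(deltas, sem, (lo, hi), n_steps=100000, seed=3)
        # quadrature posterior on log grid
        grid = np.geomspace(lo, hi, 2000)
        var = grid**2 + sem**2
        ll = np.sum(
            -0.5 * np.log(2 * np.pi * var[:, None]) - deltas[None, :] ** 2 / (2 * var[:, None]),
            axis=1,
        )
        mass = np.exp(ll - ll.max())  # Jeffreys x log-grid measure
        mass /= mass.sum()
        edges = np.geomspace(lo, hi, 41)
        hist, _ = np.histogram(chain[20000:], bins=edges)
        hist = hist / hist.sum()
        ref = np.add.reduceat(mass, np.searchsorted(grid, edges[:-1]))
        ref = ref / ref.sum()
        tv = 0.5 * np.abs(hist - ref).sum()
        assert tv < 0.03

    def test_bounds_validated(self):
        with pytest.raises(ValueError):
            gibbs_sample_sigma(np.array([1.0]), 0.1, (1.0, 0.5))


class TestNoiseEstimator:
    def test_recovers_injected_noise_scale(self):
        sem = 0.05
        ovdd = np.array([1.0])
        sig = np.array([sem])
        for seed in (0, 1):
            rng = np.random.default_rng(seed)
            # total sigma = 2 sem  =>  sigma_B = sqrt(3) sem
            deltas = rng.normal(0.0, 2 * sem, 10000)
            traj = ovdd[0] - deltas[:, None]
            est = estimate_noise_posterior(traj, ovdd, sig)
            assert est.sigma_b[0] == pytest.approx(np.sqrt(3) * sem, rel=0.10)

    def test_zero_deviation_estimates_below_tenth_of_sem(self):
        ovdd = np.array([1.0, 2.0])
        sig = sigma_sem(ovdd, 0.1)
        traj = np.repeat(ovdd[None], 500, axis=0)
        est = estimate_noise_posterior(traj, ovdd, sig)
        assert np.all(est.sigma_b < sig / 10)

    def test_too_few_frames_refused(self):
        with pytest.raises(ValueError, match="100"):
            estimate_noise_posterior(np.zeros((50, 2)) + 1.0, np.ones(2), np.ones(2))


class TestErrorDensityMap:
    def _template(self):
        return DensityMap.empty((24, 16, 16), 0.1, (-1.2, -0.8, -0.8))

    def _two_comp_data(self):
        means = np.array([[-0.5, 0, 0], [0.5, 0, 0]])
        covs = np.repeat((0.02 * np.eye(3))[None], 2, axis=0)
        return GaussianMixture(np.array([0.5, 0.5]), means, covs, normalized=True)

    def test_uniform_relative_error_gives_constant_map(self):
        data = self._two_comp_data()
        noise = NoiseEstimate(np.array([0.3, 0.3]), np.array([0.3, 0.3]), 1000)
        emap = error_density_map(noise, data, self._template())
        support = emap.values[emap.values != 0]
        np.testing.assert_allclose(support, 0.3, atol=1e-9)

    def test_peaks_at_noisy_component_and_monotone_between(self):
        data = self._two_comp_data()
        noise = NoiseEstimate(np.array([0.05, 0.5]), np.array([0.05, 0.5]), 1000)
        emap = error_density_map(noise, data, self._template())
        x_axis = emap.values[:, 8, 8]
        xs = self._template().axis_coords(0)
        i_left = np.argmin(np.abs(xs + 0.5))
        i_right = np.argmin(np.abs(xs - 0.5))
        assert x_axis[i_right] > x_axis[i_left]
        seg = x_axis[i_left: i_right + 1]
        assert np.all(np.diff(seg) >= -1e-9)  # monotone along the joining axis
        assert np.all((emap.values >= 0) & (emap.values <= 0.5 + 1e-9))


class TestParams:
    def test_metainf_params_validation(self):
        with pytest.raises(ValueError):
            MetaInfParams(alpha=-1)
        with pytest.raises(ValueError):
            MetaInfParams(stride=0)
        assert MetaInfParams().kbt == pytest.approx(KB * 300)
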