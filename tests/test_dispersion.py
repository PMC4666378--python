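"""Empirical-Bayes dispersion machinery: naive estimates, prior fits,
penalized MAP and genome-wide fields."""

import numpy as np
import pytest

from methsingle.betabinom import PHI_MAX, PHI_MIN, bb_loglik
from methsingle.dispersion import (
    PriorHyper,
    estimate_dispersion_field,
    estimate_dispersion_multi,
    fit_prior,
    fit_prior_marginal,
    naive_dispersion,
    shrink_phi,
    _loglik_grid,
)
from methsingle.errors import ValidationError
from methsingle.io import SiteCounts
from methsingle.smoothing import smooth_moving_average


def grid_map_oracle(x, n, mu, prior, n_grid=10_000):
    """Independent oracle: argmax of the penalized likelihood on a dense grid."""
    grid = np.geomspace(PHI_MIN, PHI_MAX, n_grid)
    obj = np.array(
        [bb_loglik(x, n, mu, g) for g in grid]
    ) + prior.logpdf(grid)
    return grid[int(np.argmax(obj))]


class TestNaiveDispersion:
    def test_centered_observation_clamps_to_floor(self):
        # (5 - 10*0.5)^2/(2.5) - 1 = -1 -> negative -> floor
        assert naive_dispersion(5, 10, 0.5) == pytest.approx(PHI_MIN)

    def test_extreme_observation_clamps_to_ceiling(self):
        # (25/2.5 - 1)/9 = 1.0 -> ceiling 0.99
        assert naive_dispersion(10, 10, 0.5) == pytest.approx(PHI_MAX)

    def test_interior_value(self):
        # (9 - 5)^2/2.5 = 6.4; (6.4 - 1)/9 = 0.6
        assert naive_dispersion(9, 10, 0.5) == pytest.approx(0.6)

    @pytest.mark.parametrize("x,n,mu", [(1, 1, 0.5), (0, 0, 0.5), (3, 10, 0.0), (3, 10, 1.0)])
    def test_undefined_cases_return_nan(self, x, n, mu):
        assert np.isnan(naive_dispersion(x, n, mu))


class TestFitPrior:
    def test_recovers_lognormal_sample_moments(self, rng):
        sample = rng.lognormal(-2.5, 1.0, 10_000)
        prior = fit_prior(sample)
        assert prior.m0 == pytest.approx(-2.5, abs=3 * 1.0 / np.sqrt(10_000) + 0.01)
        assert prior.r0_sq == pytest.approx(1.0, abs=0.06)

    def test_constant_input_floors_variance(self):
        prior = fit_prior(np.full(2000, 0.05))
        assert prior.m0 == pytest.approx(np.log(0.05))
        assert prior.r0_sq == 0.1

    def test_too_few_values_falls_back(self):
        prior = fit_prior(np.full(10, 0.05))
        assert (prior.m0, prior.r0_sq) == (-3.0, 1.0)

    def test_marginal_fit_recovers_hyperparameters(self, rng):
        """EB fit from raw counts finds the generating (m0, r0_sq)."""
        n_sites = 4000
        phi = np.clip(rng.lognormal(-2.5, 1.0, n_sites), PHI_MIN, PHI_MAX)
        mu = np.full(n_sites, 0.5)
        n = rng.poisson(20, n_sites)
        a = mu * (1 - phi) / phi
        b = (1 - mu) * (1 - phi) / phi
        x = rng.binomial(n, rng.beta(a, b))
        keep = n > 0
        owner = np.flatnonzero(keep)
        L = _loglik_grid(x[keep].astype(float), n[keep].astype(float), mu[keep], owner, n_sites)
        prior = fit_prior_marginal(L)
        assert prior.m0 == pytest.approx(-2.5, abs=0.25)
        assert prior.r0_sq == pytest.approx(1.0, abs=0.35)


class TestShrinkPhi:
    def test_tight_prior_dominates(self):
        prior = PriorHyper(-2.5, 0.01)
        assert shrink_phi(7, 10, 0.5, prior) == pytest.approx(prior.mode, abs=1e-2)

    def test_no_data_returns_prior_mode(self):
        prior = PriorHyper(-2.0, 0.5)
        assert shrink_phi(0, 0, 0.5, prior) == pytest.approx(np.exp(-2.0 - 0.5))

    def test_monotone_in_data_signal(self):
        prior = PriorHyper(-2.5, 4.0)  # diffuse
        hi = shrink_phi(9, 10, 0.5, prior)
        lo = shrink_phi(5, 10, 0.5, prior)
        assert hi > lo
        # oracle confirms both points
        assert hi == pytest.approx(grid_map_oracle(9, 10, 0.5, prior), abs=1e-3)
        assert lo == pytest.approx(grid_map_oracle(5, 10, 0.5, prior), abs=1e-3)

    def test_pseudo_replicates_pool_into_likelihood(self):
        prior = PriorHyper(-2.5, 4.0)
        solo = shrink_phi(9, 10, 0.5, prior)
        with_pseudo = shrink_phi(9, 10, 0.5, prior, pseudo=[(5, 10, 0.5), (5, 10, 0.5)])
        assert with_pseudo < solo  # centered neighbors argue for less dispersion

    def test_matches_grid_oracle_on_random_configurations(self, rng):
        """Bounded-maximization MAP equals a 10^4-point grid argmax."""
        for _ in range(200):
            n = int(rng.integers(2, 40))
            x = int(rng.integers(0, n + 1))
            mu = float(rng.uniform(0.05, 0.95))
            prior = PriorHyper(float(rng.uniform(-4, -1)), float(rng.uniform(0.2, 4)))
            got = shrink_phi(x, n, mu, prior)
            want = grid_map_oracle(x, n, mu, prior)
            assert got == pytest.approx(want, abs=1e-3)


class TestDispersionField:
    def test_identical_sites_give_constant_field(self):
        sc = SiteCounts.from_arrays(
            "chr1", np.arange(1, 3001) * 10_000, np.full(3000, 10), np.full(3000, 7)
        )
        means = smooth_moving_average(sc, half_width=500)
        fld = estimate_dispersion_field(sc, means, prior=PriorHyper(-2.5, 1.0))
        assert np.allclose(fld.phi_hat, fld.phi_hat[0])

    def test_bounds_respected(self, small_sim):
        counts = small_sim.counts1[0]
        means = smooth_moving_average(counts, 500)
        fld = estimate_dispersion_field(counts, means)
        assert np.all(fld.phi_hat >= PHI_MIN) and np.all(fld.phi_hat <= PHI_MAX)

    def test_index_mismatch_rejected(self, small_sim):
        counts = small_sim.counts1[0]
        other = SiteCounts.from_arrays("chr1", [10, 20], [5, 5], [1, 1])
        means = smooth_moving_average(other, 500)
        with pytest.raises(ValidationError):
            estimate_dispersion_field(counts, means)

    def test_window_mode_pools_neighbors(self, small_sim):
        counts = small_sim.counts1[0]
        means = smooth_moving_average(counts, 500)
        single = estimate_dispersion_field(counts, means, mode="single")
        window = estimate_dispersion_field(counts, means, mode="window")
        assert window.n_pseudo.max() > single.n_pseudo.max()
        assert np.all(window.phi_hat >= PHI_MIN) and np.all(window.phi_hat <= PHI_MAX)

    def test_recovery_improves_with_replicates(self, null_sim):
        """Truth correlation is positive and higher with three replicates."""
        reps = null_sim.counts1
        means1 = smooth_moving_average(reps[0], 500)
        single = estimate_dispersion_field(reps[0], means1)
        pooled = SiteCounts.from_arrays(
            reps[0].chrom,
            reps[0].pos,
            sum(r.n_total for r in reps),
            sum(r.n_meth for r in reps),
        )
        means3 = smooth_moving_average(pooled, 500)
        multi = estimate_dispersion_multi(reps, means3)
        phi_true = null_sim.phi1
        r1 = np.corrcoef(single.phi_hat, phi_true)[0, 1]
        r3 = np.corrcoef(multi.phi_hat, phi_true)[0, 1]
        assert 0 < r1 < r3

    def test_single_beats_constant_dispersion_mse(self, null_sim):
        counts = null_sim.counts1[0]
        means = smooth_moving_average(counts, 500)
        fld = estimate_dispersion_field(counts, means)
        phi_true = null_sim.phi1
        const = np.median(phi_true)
        assert np.mean((fld.phi_hat - phi_true) ** 2) < np.mean((const - phi_true) ** 2)
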