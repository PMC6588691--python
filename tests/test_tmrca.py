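"""TMRCA posteriors: IAM/SMM likelihoods against Monte-Carlo oracles,
posterior summaries, coverage, deviation and regression diagnostics."""

import numpy as np
import pytest
from scipy import special

from ystrped.tmrca import (DEFAULT_TAU_GRID, TMRCAEstimate, TMRCAObservation,
                           compute_posterior, coverage_fraction,
                           deviation_statistic, flag_nonpaternity_tmrca,
                           iam_likelihood, regress_observed_on_expected,
                           smm_likelihood, summarize_posterior)


def make_obs(k, n, mu, steps=None):
    if steps is None:
        steps = [1] * k + [0] * (n - k)
    return TMRCAObservation("p", "All", n, k, steps, mu)


class TestIAMLikelihood:
    def test_no_differences_is_decaying_exponential(self):
        tau = np.arange(1, 100)
        like = iam_likelihood(0, 15, 0.01, tau)
        assert np.allclose(like, np.exp(-15 * 0.01 * tau))
        assert np.all(np.diff(like) < 0)

    def test_zero_time_with_differences_impossible(self):
        assert iam_likelihood(3, 15, 0.01, 0.0) == 0.0

    def test_k_cannot_exceed_n(self):
        with pytest.raises(ValueError):
            iam_likelihood(16, 15, 0.01, 10.0)

    def test_against_poisson_simulation_oracle(self):
        """P(a specific set of 3 of 15 loci differ) after tau=20 meioses
        at mu=0.01369, estimated from Poisson mutation counts."""
        k, n, mu, tau = 3, 15, 0.01369, 20.0
        rng = np.random.default_rng(314)
        reps = 100_000
        hits = rng.poisson(mu * tau, size=(reps, n)) > 0
        pattern = np.all(hits[:, :k], axis=1) & ~np.any(hits[:, k:], axis=1)
        est = pattern.mean()
        se = np.sqrt(est * (1 - est) / reps)
        assert abs(iam_likelihood(k, n, mu, tau) - est) <= 3 * se


class TestSMMLikelihood:
    def test_identical_profile_limit(self):
        assert smm_likelihood([0, 0, 0], 0.01, 1e-9)[0] == pytest.approx(1.0)

    def test_single_step_small_time_expansion(self):
        # e^-x I_1(x) ~ x/2 for small x
        x = 1e-4
        like = smm_likelihood([1], 1.0, x)[0]
        assert like == pytest.approx(x / 2, rel=1e-3)

    def test_non_integer_steps_rejected(self):
        with pytest.raises(ValueError):
            smm_likelihood([0.5], 0.01, 10.0)

    def test_displacement_law_sums_to_one(self):
        """Sum over d of e^-x I_d(x) = 1 (symmetric walk total mass)."""
        for x in (0.1, 1.0, 5.0, 20.0):
            total = special.ive(0, x) + 2 * sum(
                special.ive(d, x) for d in range(1, 51))
            assert total == pytest.approx(1.0, abs=1e-10)

    def test_against_random_walk_simulation_oracle(self):
        """Per-locus net displacement of a +-1 walk with Poisson event
        counts, compared locus-wise at mu=0.01, tau=30."""
        mu, tau = 0.01, 30.0
        rng = np.random.default_rng(99)
        reps = 100_000
        events = rng.poisson(mu * tau, size=reps)
        steps = np.where(rng.random((reps, events.max() if events.max() else 1)) < 0.5, -1, 1)
        mask = np.arange(steps.shape[1]) < events[:, None]
        net = (steps * mask).sum(axis=1)
        for d in (0, 1, 2):
            est = (np.abs(net) == d).mean() / (2 if d else 1)  # P(net == +d)
            se = np.sqrt(est * (1 - est) / reps)
            assert abs(smm_likelihood([d], mu, tau)[0] - est) <= 3 * se


class TestPosterior:
    def test_uniform_prior_constant_likelihood_gives_uniform(self):
        post = compute_posterior(make_obs(0, 1, 1e-12), model="IAM")
        assert np.allclose(post.probabilities, 1 / len(DEFAULT_TAU_GRID))

    def test_posterior_normalised(self):
        post = compute_posterior(make_obs(3, 15, 0.01), model="SMM")
        assert post.probabilities.sum() == pytest.approx(1.0, abs=1e-12)

    def test_identical_pair_median_matches_closed_form(self):
        """IAM with k=0 is a truncated exponential in tau: median at
        ln 2 / (n mu), within one grid step."""
        n, mu = 15, 0.01369
        grid = np.arange(1, 2001)
        post = compute_posterior(make_obs(0, n, mu), model="IAM", tau_grid=grid)
        est = summarize_posterior(post)
        expected_tau = np.log(2) / (n * mu)
        assert abs(2 * est.median - expected_tau) <= 1.0

    def test_skewed_posterior_summary_ordering(self):
        for k in (1, 3, 6):
            post = compute_posterior(make_obs(k, 15, 0.008), model="IAM")
            est = summarize_posterior(post)
            assert est.mean >= est.median >= est.mode

    def test_grid_refinement_stability(self):
        obs = make_obs(3, 15, 0.01)
        coarse = summarize_posterior(compute_posterior(
            obs, tau_grid=np.arange(1, 601, 1.0)))
        fine = summarize_posterior(compute_posterior(
            obs, tau_grid=np.arange(0.5, 600.5, 0.5)))
        assert abs(fine.mean - coarse.mean) / coarse.mean < 0.01

    def test_degenerate_likelihood_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            compute_posterior(make_obs(15, 15, 1e-9),
                              tau_grid=np.array([1e-12]))


class TestSummaries:
    @staticmethod
    def _post(grid, probs, model="IAM"):
        from ystrped.tmrca import TMRCAPosterior
        return TMRCAPosterior(np.asarray(grid, float), np.asarray(probs), model)

    def test_point_mass(self):
        est = summarize_posterior(self._post([10, 20, 30], [0, 1, 0]))
        assert (est.mean, est.median, est.mode) == (10, 10, 10)
        assert est.ci == (10, 10)

    def test_two_point_tie_resolves_to_smaller_atom(self):
        est = summarize_posterior(self._post([10, 30], [0.5, 0.5]))
        assert est.mean == 10
        assert est.median == 5
        assert est.mode == 5

    def test_monotone_posterior_mode_at_grid_minimum(self):
        post = compute_posterior(make_obs(0, 15, 0.01), model="IAM")
        assert summarize_posterior(post).mode == DEFAULT_TAU_GRID[0] / 2


class TestEvaluation:
    @staticmethod
    def _est(mean, lo, hi, observed):
        return TMRCAEstimate("p", "IAM", mean, mean, mean, (lo, hi), observed,
                             lo <= observed <= hi)

    def test_coverage_extremes(self):
        all_in = [self._est(5, 2, 9, 4) for _ in range(4)]
        none_in = [self._est(5, 2, 9, 12) for _ in range(4)]
        assert coverage_fraction(all_in) == 100.0
        assert coverage_fraction(none_in) == 0.0
        with pytest.raises(ValueError):
            coverage_fraction([])

    def test_deviation_convention(self):
        perfect = [self._est(4, 1, 9, 4), self._est(6, 2, 11, 6)]
        assert deviation_statistic(perfect) == 0.0
        over = [self._est(6, 1, 9, 4), self._est(10, 2, 11, 6)]
        assert deviation_statistic(over, "mean") == pytest.approx(6.0)

    def test_regression_identity_and_scaling(self):
        ests = [self._est(v, v - 1, v + 1, v) for v in (2.0, 4.0, 6.0, 8.0)]
        fit = regress_observed_on_expected(ests)
        assert fit["slope"] == pytest.approx(1.0)
        assert fit["r2_multiple"] == pytest.approx(1.0)
        halved = [self._est(v, v - 1, v + 1, v / 2) for v in (2.0, 4.0, 6.0, 8.0)]
        assert regress_observed_on_expected(halved)["slope"] == pytest.approx(0.5)

    def test_through_origin_closed_form(self):
        # slope = sum(xy)/sum(x^2) = (2*1 + 4*2)/(4 + 16) = 0.5
        ests = [self._est(2, 1, 3, 1), self._est(4, 3, 5, 2),
                self._est(2, 1, 3, 1)]
        fit = regress_observed_on_expected(ests, through_origin=True)
        assert fit["slope"] == pytest.approx(0.5)

    def test_nonpaternity_flag(self):
        assert flag_nonpaternity_tmrca(self._est(20, 9, 40, 5)) is True
        assert flag_nonpaternity_tmrca(self._est(12, 4, 25, 10)) is False
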