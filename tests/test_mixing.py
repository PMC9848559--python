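"""Mixing-model likelihood, sampler, diagnostics and the grid oracle."""

import math

import numpy as np
import pytest
from scipy import stats
from scipy.special import gammaln

from isoweb.mixing import (
    gelman_rubin,
    grid_posterior_oracle,
    log_posterior,
    mixture_moments,
    posterior_summary,
    run_mcmc,
)
from isoweb.synthetic import reference_problem
from isoweb.types import McmcSettings, MixingProblem, PosteriorDraws, SourceSpec


def make_problem(sources, obs):
    return MixingProblem("c", np.asarray(obs, float), sources)


def independent_log_posterior(p, sigma, problem, s0=10.0):
    """From-scratch density with explicit loops, as the oracle."""
    total = 0.0
    for k in range(2):
        num = den = var_num = 0.0
        for i, s in enumerate(problem.sources):
            mu = [s.mean_d13C, s.mean_d15N][k]
            om = [s.sd_d13C, s.sd_d15N][k]
            de = [s.tef_d13C, s.tef_d15N][k]
            ta = [s.tef_sd_d13C, s.tef_sd_d15N][k]
            q = [s.conc_C, s.conc_N][k]
            num += p[i] * q * (mu + de)
            den += p[i] * q
            var_num += p[i] ** 2 * q**2 * (om**2 + ta**2)
        mean = num / den
        var = var_num / den**2 + sigma[k] ** 2
        for y in problem.observations[:, k]:
            total += stats.norm.logpdf(y, mean, math.sqrt(var))
    total += gammaln(len(problem.sources))  # Dirichlet(1,...,1)
    for sk in sigma:
        total += stats.halfnorm.logpdf(sk, scale=s0)
    return total


class TestLogPosterior:
    def test_single_source_mean_is_source_plus_tef(self):
        src = [SourceSpec("A", -28.0, 1.0, 4.0, 1.0, 0.5, 0.2, 2.0, 0.3)]
        mean, _ = mixture_moments(np.array([1.0]), src, 0.0)
        assert mean == pytest.approx([-27.5, 6.0])

    def test_equal_concentrations_cancel(self):
        base = dict(sd_d13C=1.0, sd_d15N=1.0)
        a = [
            SourceSpec("A", -30, mean_d15N=2, conc_C=0.37, conc_N=0.08, **base),
            SourceSpec("B", -20, mean_d15N=8, conc_C=0.37, conc_N=0.08, **base),
        ]
        b = [
            SourceSpec("A", -30, mean_d15N=2, **base),
            SourceSpec("B", -20, mean_d15N=8, **base),
        ]
        p = np.array([0.3, 0.7])
        np.testing.assert_allclose(
            mixture_moments(p, a, 0.0)[0], mixture_moments(p, b, 0.0)[0]
        )

    def test_matches_independent_implementation(self):
        rng = np.random.default_rng(3)
        src = [
            SourceSpec("A", -30, 1.2, 2, 0.8, 0.4, 1.3, 2.5, 0.7, 0.4, 0.08),
            SourceSpec("B", -22, 0.9, 6, 1.1, 0.4, 1.3, 3.4, 1.0, 0.5, 0.11),
            SourceSpec("C", -26, 1.0, 10, 0.9, 0.4, 1.3, 2.2, 0.6, 0.3, 0.05),
        ]
        prob = make_problem(src, rng.normal([-25, 7], 1.5, (6, 2)))
        for _ in range(10):
            p = rng.dirichlet(np.ones(3))
            sigma = rng.uniform(0.2, 3.0, 2)
            assert log_posterior(p, sigma, prob) == pytest.approx(
                independent_log_posterior(p, sigma, prob), abs=1e-10
            )

    def test_rejects_invalid_inputs(self):
        src = [SourceSpec("A", -30, 1, 2, 1), SourceSpec("B", -20, 1, 8, 1)]
        prob = make_problem(src, [[-25.0, 5.0]] * 3)
        with pytest.raises(ValueError):
            log_posterior(np.array([0.7, 0.7]), np.array([1.0, 1.0]), prob)
        with pytest.raises(ValueError):
            log_posterior(np.array([0.5, 0.5]), np.array([1.0, -1.0]), prob)


class TestRunMcmc:
    def test_two_source_midpoint_symmetry(self):
        src = [
            SourceSpec("A", -30, 1, 0, 1, 0, 0, 0, 0),
            SourceSpec("B", -20, 1, 0, 1, 0, 0, 0, 0),
        ]
        obs = np.random.default_rng(1).normal([-25, 0], 0.3, (10, 2))
        draws = run_mcmc(
            make_problem(src, obs),
            McmcSettings(iterations=12_000, burn_in=4_000, chains=4, seed=0),
        )
        med = posterior_summary(draws)["median"].to_numpy()
        assert med[0] == pytest.approx(0.5, abs=0.05)

    def test_parameter_recovery_three_sources(self):
        problem, truth = reference_problem(seed=7)
        draws = run_mcmc(
            problem, McmcSettings(iterations=12_000, burn_in=4_000, chains=4, seed=1)
        )
        med = posterior_summary(draws)["median"].to_numpy()
        assert np.all(np.abs(med - truth) < 0.1)

    def test_seed_determinism(self):
        problem, _ = reference_problem(seed=3)
        st_ = McmcSettings(iterations=3_000, burn_in=1_000, chains=2, seed=9)
        a, b = run_mcmc(problem, st_), run_mcmc(problem, st_)
        np.testing.assert_array_equal(a.p, b.p)
        np.testing.assert_array_equal(a.sigma, b.sigma)

    def test_draws_on_simplex_and_acceptance_in_band(self):
        problem, _ = reference_problem(seed=5)
        draws = run_mcmc(
            problem, McmcSettings(iterations=8_000, burn_in=3_000, chains=2, seed=2)
        )
        np.testing.assert_allclose(draws.p.sum(axis=2), 1.0, atol=1e-9)
        assert np.all(draws.sigma > 0)
        assert np.all((draws.acceptance_rate > 0.2) & (draws.acceptance_rate < 0.5))

    def test_duplicate_source_aliasing(self):
        """Splitting one source into two identical copies leaves the
        posterior of the pair's summed contribution unchanged."""
        base = [
            SourceSpec("A", -30, 1, 2, 1, 0, 0, 0, 0),
            SourceSpec("B", -20, 1, 8, 1, 0, 0, 0, 0),
        ]
        split = base + [SourceSpec("B2", -20, 1, 8, 1, 0, 0, 0, 0)]
        obs = np.random.default_rng(4).normal([-26, 4.4], 0.5, (15, 2))
        st_ = McmcSettings(iterations=12_000, burn_in=4_000, chains=4, seed=3)
        d2 = run_mcmc(make_problem(base, obs), st_)
        d3 = run_mcmc(make_problem(split, obs), st_)
        b_single = posterior_summary(d2)["median"].to_numpy()[1]
        pooled = d3.pooled_p()
        b_pair = float(np.median(pooled[:, 1] + pooled[:, 2]))
        assert b_pair == pytest.approx(b_single, abs=0.05)

    def test_interval_coverage_over_many_problems(self):
        """95% credible intervals contain truth in ≥ 85% of cases."""
        rng = np.random.default_rng(12)
        hits = total = 0
        for rep in range(50):
            truth = rng.dirichlet(np.ones(3) * 2)
            src = [
                SourceSpec("A", -30, 0.5, 2, 0.5, 0.4, 0.3, 3.4, 0.3),
                SourceSpec("B", -20, 0.5, 5, 0.5, 0.4, 0.3, 3.4, 0.3),
                SourceSpec("C", -26, 0.5, 11, 0.5, 0.4, 0.3, 3.4, 0.3),
            ]
            mean, var = mixture_moments(truth, src, np.array([0.3, 0.3]))
            obs = rng.normal(mean, np.sqrt(var), (20, 2))
            draws = run_mcmc(
                make_problem(src, obs),
                McmcSettings(iterations=4_000, burn_in=1_500, chains=2,
                             thin=5, seed=100 + rep),
            )
            s = posterior_summary(draws)
            for i in range(3):
                hits += s["q2.5"][i] <= truth[i] <= s["q97.5"][i]
                total += 1
        assert hits / total >= 0.85


class TestGelmanRubin:
    def test_well_mixed_split_chain_near_one(self):
        rng = np.random.default_rng(0)
        long = rng.dirichlet(np.ones(2), size=4000)
        p = long.reshape(2, 2000, 2)
        sigma = np.abs(rng.normal(1, 0.1, (2, 2000, 2))) + 0.1
        draws = PosteriorDraws(["A", "B"], p, sigma, np.array([0.3, 0.3]))
        assert np.all(np.abs(gelman_rubin(draws) - 1.0) < 0.01)

    def test_divergent_chains_flagged(self):
        rng = np.random.default_rng(1)
        a = np.clip(rng.normal(0.01, 0.001, (1, 500, 1)), 1e-4, 1)
        b = np.clip(rng.normal(0.99, 0.001, (1, 500, 1)), 0, 1 - 1e-4)
        p = np.concatenate([np.concatenate([a, 1 - a], axis=2),
                            np.concatenate([b, 1 - b], axis=2)])
        sigma = np.abs(rng.normal(1, 0.1, (2, 500, 2))) + 0.1
        draws = PosteriorDraws(["A", "B"], p, sigma, np.array([0.3, 0.3]))
        assert gelman_rubin(draws)["A"] > 1.1

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(2)
        raw = rng.beta(2, 3, size=(3, 200, 1))
        p = np.concatenate([raw, 1 - raw], axis=2)
        sigma = np.abs(rng.normal(1, 0.2, (3, 200, 2))) + 0.1
        draws = PosteriorDraws(["A", "B"], p, sigma, np.zeros(3))
        r = gelman_rubin(draws)
        chains = raw[:, :, 0]
        m, n = chains.shape
        w = chains.var(axis=1, ddof=1).mean()
        b = n * chains.mean(axis=1).var(ddof=1)
        expected = np.sqrt(((n - 1) / n * w + b / n) / w)
        assert r["A"] == pytest.approx(expected, abs=1e-8)

    def test_matches_arviz_identity_method(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(8)
        raw = rng.beta(5, 2, size=(4, 300, 1))
        p = np.concatenate([raw, 1 - raw], axis=2)
        sigma = np.abs(rng.normal(1, 0.2, (4, 300, 2))) + 0.1
        draws = PosteriorDraws(["A", "B"], p, sigma, np.zeros(4))
        ours = gelman_rubin(draws)["A"]
        theirs = float(az.rhat(raw[:, :, 0], method="identity"))
        assert ours == pytest.approx(theirs, abs=1e-8)

    def test_single_chain_rejected(self):
        p = np.full((1, 100, 2), 0.5)
        sigma = np.ones((1, 100, 2))
        draws = PosteriorDraws(["A", "B"], p, sigma, np.zeros(1))
        with pytest.raises(ValueError, match="chains"):
            gelman_rubin(draws)


class TestPosteriorSummary:
    def test_constant_draws(self):
        p = np.tile([0.6, 0.4], (2, 50, 1))
        sigma = np.ones((2, 50, 2))
        s = posterior_summary(PosteriorDraws(["A", "B"], p, sigma, np.zeros(2)))
        assert s["median"].tolist() == [0.6, 0.4]
        assert s["q2.5"].tolist() == s["q97.5"].tolist() == [0.6, 0.4]

    def test_matches_independent_percentiles(self):
        rng = np.random.default_rng(6)
        raw = rng.dirichlet(np.ones(3), size=1000).reshape(2, 500, 3)
        sigma = np.abs(rng.normal(1, 0.1, (2, 500, 2))) + 0.1
        s = posterior_summary(PosteriorDraws(["A", "B", "C"], raw, sigma, np.zeros(2)))
        pooled = raw.reshape(-1, 3)
        for i in range(3):
            srt = np.sort(pooled[:, i])
            med = 0.5 * (srt[499] + srt[500])  # even-length median
            assert s["median"][i] == pytest.approx(med, abs=1e-12)
        assert s["median_renorm"].sum() == pytest.approx(1.0, abs=1e-9)


class TestGridOracle:
    def test_flat_likelihood_recovers_prior_mean(self):
        src = [
            SourceSpec("A", -30, 1, 2, 1, 0, 0, 0, 0),
            SourceSpec("B", -20, 1, 8, 1, 0, 0, 0, 0),
        ]
        prob = make_problem(src, [[-25.0, 5.0]])
        mean = grid_posterior_oracle(
            prob, resolution=200, sigma_grid=np.array([1e6])
        )
        assert mean == pytest.approx([0.5, 0.5], abs=0.005)

    def test_grid_refinement_stability(self, toy_two_source):
        coarse = grid_posterior_oracle(toy_two_source, resolution=50)
        fine = grid_posterior_oracle(toy_two_source, resolution=100)
        assert np.max(np.abs(coarse - fine)) < 0.005

    def test_mcmc_agrees_with_oracle(self, toy_two_source):
        oracle = grid_posterior_oracle(toy_two_source, resolution=100)
        draws = run_mcmc(
            toy_two_source,
            McmcSettings(iterations=20_000, burn_in=5_000, chains=4, seed=11),
        )
        mcmc_mean = draws.pooled_p().mean(axis=0)
        assert np.max(np.abs(mcmc_mean - oracle)) < 0.02

    def test_four_sources_unsupported(self):
        src = [SourceSpec(f"S{i}", -30 + i, 1, i, 1) for i in range(4)]
        prob = make_problem(src, [[-27.0, 2.0]] * 3)
        with pytest.raises(ValueError):
            grid_posterior_oracle(prob)
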