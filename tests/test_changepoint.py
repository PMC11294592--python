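"""Changepoint model: NB2 pmf, joint density, oracle, sampler, diagnostics."""

import math

import numpy as np
import pytest
import scipy.stats

from patenttrends import (
    ChangepointPriors,
    SamplerConfig,
    exact_changepoint_posterior,
    log_joint,
    nb_log_pmf,
    sample_changepoint_posterior,
    segment_changepoints,
    simulate_count_series,
    SimSeriesConfig,
)
from patenttrends.changepoint import compute_diagnostics, split_rhat

from conftest import make_series


def tv(p, q):
    return 0.5 * float(np.abs(np.asarray(p) - np.asarray(q)).sum())


class TestNbLogPmf:
    def test_closed_form_at_zero(self):
        # P(Y=0) = (phi/(mu+phi))^phi = 0.5 at mu=phi=1
        assert nb_log_pmf(0, 1.0, 1.0) == pytest.approx(math.log(0.5), abs=1e-12)

    @pytest.mark.parametrize(
        "mu,phi", [(5, 2), (0.5, 0.1), (10, 1), (2, 4), (50, 3)]
    )
    def test_normalizes_over_support(self, mu, phi):
        ys = np.arange(0, 10_001)
        total = np.exp(nb_log_pmf(ys, mu, phi)).sum()
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_matches_term_by_term_log_gamma_composition(self):
        # independent evaluation: each term assembled from math.lgamma
        y, mu, phi = 3, 2.0, 4.0
        expected = (
            math.lgamma(y + phi)
            - math.lgamma(phi)
            - math.lgamma(y + 1)
            + phi * math.log(phi / (mu + phi))
            + y * math.log(mu / (mu + phi))
        )
        assert nb_log_pmf(y, mu, phi) == pytest.approx(expected, abs=1e-10)

    def test_matches_scipy_nbinom_parameterization(self):
        # NB2(mu, phi) == nbinom(n=phi, p=phi/(phi+mu))
        ys = np.arange(0, 50)
        mine = nb_log_pmf(ys, 7.0, 2.5)
        ref = scipy.stats.nbinom.logpmf(ys, 2.5, 2.5 / 9.5)
        assert np.allclose(mine, ref, atol=1e-10)

    def test_rejects_nonpositive_parameters(self):
        with pytest.raises(ValueError):
            nb_log_pmf(1, 0.0, 1.0)
        with pytest.raises(ValueError):
            nb_log_pmf(1, 1.0, -1.0)


class TestLogJoint:
    priors = ChangepointPriors()

    def test_two_month_series_unrolls_to_definition(self):
        series = make_series([0, 0])
        params = (2.0, 8.0, 1.0, 1.0)
        expected = (
            nb_log_pmf(0, 2.0, 1.0)
            + nb_log_pmf(0, 8.0, 1.0)
            + self.priors.log_density(*params)
            - math.log(1)
        )
        assert log_joint(series, 1, params, self.priors) == pytest.approx(expected)

    def test_time_reversal_with_swapped_params_is_invariant(self):
        series = make_series([3, 7, 1, 0, 9, 2])
        rev = series.reversed()
        fwd = log_joint(series, 2, (2.0, 8.0, 1.0, 3.0), self.priors)
        bwd = log_joint(rev, 4, (8.0, 2.0, 3.0, 1.0), self.priors)
        assert fwd == pytest.approx(bwd, abs=1e-10)

    def test_spot_value_from_term_by_term_oracle(self):
        series = make_series([3, 7])
        params = (2.0, 8.0, 1.0, 1.0)
        expected = (
            float(nb_log_pmf(3, 2.0, 1.0))
            + float(nb_log_pmf(7, 8.0, 1.0))
            + self.priors.log_density(*params)
        )
        assert log_joint(series, 1, params, self.priors) == pytest.approx(expected)

    def test_tau_out_of_range_rejected(self):
        series = make_series([1, 2, 3])
        with pytest.raises(ValueError):
            log_joint(series, 0, (1, 1, 1, 1), self.priors)
        with pytest.raises(ValueError):
            log_joint(series, 3, (1, 1, 1, 1), self.priors)


class TestExactPosterior:
    def test_tau_probs_normalized(self):
        post = exact_changepoint_posterior(make_series([1, 3, 2, 8, 9, 7]))
        assert post.tau_probs.sum() == pytest.approx(1.0, abs=1e-8)
        assert (post.tau_probs >= 0).all()

    def test_reversal_symmetry_is_exact(self):
        series = make_series([0, 2, 1, 5, 9, 12, 8, 3])
        fwd = exact_changepoint_posterior(series)
        bwd = exact_changepoint_posterior(series.reversed())
        assert np.abs(fwd.tau_probs - bwd.tau_probs[::-1]).max() < 1e-8

    def test_obvious_step_localized_at_boundary(self):
        series = make_series([0] * 5 + [10] * 5)
        post = exact_changepoint_posterior(series)
        assert post.map_index == 5

    def test_argmax_stable_under_grid_refinement(self):
        from patenttrends.changepoint import QuadratureGrid

        series = make_series([0] * 5 + [10] * 5)
        coarse = exact_changepoint_posterior(series, grid=QuadratureGrid(40, 30))
        fine = exact_changepoint_posterior(series, grid=QuadratureGrid(96, 72))
        assert coarse.map_index == fine.map_index == 5
        assert tv(coarse.tau_probs, fine.tau_probs) < 0.01

    def test_refuses_overlong_series(self):
        with pytest.raises(ValueError, match="oracle"):
            exact_changepoint_posterior(make_series(np.ones(121, dtype=int)))


class TestSampler:
    def test_agrees_with_oracle_on_jump_series(self):
        cfg = SimSeriesConfig(n_months=40, mu_early=2, mu_late=10,
                              changepoint_month=20, seed=3)
        series = simulate_count_series(cfg)
        exact = exact_changepoint_posterior(series)
        mcmc = sample_changepoint_posterior(
            series, config=SamplerConfig(iterations=1000, chains=2, seed=5)
        )
        assert tv(exact.tau_probs, mcmc.tau_probs) < 0.05

    def test_seeded_reproducibility(self):
        series = make_series([1, 2, 0, 3, 8, 9, 7, 11])
        cfg = SamplerConfig(iterations=300, chains=2, seed=9)
        a = sample_changepoint_posterior(series, config=cfg)
        b = sample_changepoint_posterior(series, config=cfg)
        assert np.array_equal(a.tau_probs, b.tau_probs)
        assert all(
            np.array_equal(a.draws[k], b.draws[k]) for k in a.draws
        )

    def test_default_config_converges_on_well_behaved_series(self):
        cfg = SimSeriesConfig(n_months=60, mu_early=3, mu_late=12,
                              changepoint_month=30, seed=1)
        series = simulate_count_series(cfg)
        post = sample_changepoint_posterior(series, config=SamplerConfig(seed=2))
        assert post.converged
        assert all(d["rhat"] < 1.01 for d in post.diagnostics.values())

    def test_rejects_tiny_series(self):
        with pytest.raises(ValueError):
            sample_changepoint_posterior(make_series([1, 2, 3]))


class TestDiagnostics:
    def test_same_distribution_chains_near_one(self):
        rng = np.random.default_rng(0)
        draws = rng.normal(size=(2, 1000))
        assert abs(split_rhat(draws) - 1.0) < 0.01

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(1)
        draws = np.stack([rng.normal(0, 1, 500), rng.normal(100, 1, 500)])
        assert split_rhat(draws) > 1.1

    def test_hand_computed_eight_number_example(self):
        # chains [1,2,3,4] and [2,3,4,7]; split halves [1,2],[3,4],[2,3],[4,7]
        draws = np.array([[1.0, 2.0, 3.0, 4.0], [2.0, 3.0, 4.0, 7.0]])
        halves = np.array([[1, 2], [3, 4], [2, 3], [4, 7]], dtype=float)
        w = halves.var(axis=1, ddof=1).mean()
        b = 2 * halves.mean(axis=1).var(ddof=1)
        expected = math.sqrt(((2 - 1) / 2 * w + b / 2) / w)
        assert split_rhat(draws) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_gives_nan_sentinel_not_crash(self):
        draws = np.ones((2, 100))
        out = compute_diagnostics(draws)
        assert math.isnan(out["param"]["rhat"])
        assert math.isnan(out["param"]["ess"])

    def test_matches_arviz_cross_check(self):
        arviz = pytest.importorskip("arviz")
        rng = np.random.default_rng(3)
        # AR(1) chains: autocorrelated, nontrivial ESS
        x = np.zeros((4, 2000))
        for c in range(4):
            eps = rng.normal(size=2000)
            for t in range(1, 2000):
                x[c, t] = 0.7 * x[c, t - 1] + eps[t]
        out = compute_diagnostics(x)
        assert out["param"]["rhat"] == pytest.approx(
            float(arviz.rhat(arviz.convert_to_dataset(x)).x), abs=1e-3
        )
        assert out["param"]["ess"] == pytest.approx(
            float(arviz.ess(arviz.convert_to_dataset(x)).x), rel=0.1
        )

    def test_traceplot_arrays_exported(self):
        rng = np.random.default_rng(4)
        draws = rng.normal(size=(2, 50))
        out = compute_diagnostics({"mu": draws})
        assert np.array_equal(out["mu"]["trace"], draws)


class TestProperties:
    def test_monotone_evidence_in_jump_size(self):
        # posterior mass near the planted changepoint does not drop as the
        # rate ratio grows (median over seeds)
        medians = []
        for ratio in (1, 2, 4, 8):
            masses = []
            for seed in range(8):
                cfg = SimSeriesConfig(
                    n_months=40, mu_early=2, mu_late=2 * ratio,
                    changepoint_month=20, seed=seed,
                )
                post = exact_changepoint_posterior(simulate_count_series(cfg))
                masses.append(post.mass_within(20, 6))
            medians.append(float(np.median(masses)))
        assert all(b >= a - 0.02 for a, b in zip(medians, medians[1:]))

    def test_prior_predictive_calibration_recovers_uniform_tau(self):
        # data drawn from the model's own prior predictive: the average
        # posterior over tau must match the uniform prior
        rng = np.random.default_rng(0)
        n, sims = 16, 120
        acc = np.zeros(n - 1)
        for i in range(sims):
            mu_e, mu_l = np.maximum(rng.exponential(10, 2), 1e-2)
            phi_e, phi_l = np.maximum(rng.exponential(1, 2), 1e-2)
            tau = int(rng.integers(1, n))
            cfg = SimSeriesConfig(
                n_months=n, mu_early=mu_e, mu_late=mu_l, phi_early=phi_e,
                phi_late=phi_l, changepoint_month=tau, seed=10_000 + i,
            )
            acc += exact_changepoint_posterior(simulate_count_series(cfg)).tau_probs
        assert tv(acc / sims, np.full(n - 1, 1 / (n - 1))) < 0.08


class TestSegmentation:
    def test_max_segments_one_is_a_single_fit(self):
        series = make_series(np.r_[np.ones(15, int), np.full(15, 8)])
        cfg = SamplerConfig(iterations=400, chains=2, seed=1)
        fits = segment_changepoints(series, config=cfg, max_segments=1)
        assert len(fits) == 1
        assert fits[0].map_index == 15

    def test_short_series_not_recursed(self):
        series = make_series(np.r_[np.ones(10, int), np.full(10, 9)])
        cfg = SamplerConfig(iterations=400, chains=2, seed=1)
        fits = segment_changepoints(
            series, config=cfg, max_segments=5, min_segment_length=24
        )
        assert len(fits) == 1

    def test_two_planted_jumps_recovered(self):
        a = simulate_count_series(
            SimSeriesConfig(n_months=150, mu_early=2, mu_late=10,
                            changepoint_month=50, seed=11)
        )
        b = simulate_count_series(
            SimSeriesConfig(n_months=150, mu_early=10, mu_late=3,
                            changepoint_month=100, seed=12)
        )
        series = make_series(np.r_[a.counts[:100], b.counts[100:]])
        cfg = SamplerConfig(iterations=800, chains=2, seed=3)
        fits = segment_changepoints(
            series, config=cfg, max_segments=3, min_segment_length=24
        )
        found = [f.segment_offset + f.map_index for f in fits]
        assert any(abs(m - 50) <= 5 for m in found)
        assert any(abs(m - 100) <= 5 for m in found)
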