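"""Convergence diagnostics, thinning, posterior predictive, goodness of fit."""

import numpy as np
import pytest

import mblrc
from mblrc import (
    FitConfig,
    PriorSpec,
    SimulationConfig,
    bgr_diagnostic,
    fit_mblrc,
    goodness_of_fit,
    posterior_predictive,
    simulate_dataset,
    thin,
)
from conftest import draws_from_states, scalar_draws

ZERO_SDS = {"a_max": 0.0, "alpha": 0.0, "r_d": 0.0, "theta": 0.0}


class TestBgrDiagnostic:
    def test_identical_chains_give_psrf_below_one(self):
        n = 100
        chain = np.random.default_rng(0).normal(size=n)
        report = bgr_diagnostic(scalar_draws([chain, chain]))
        assert report.psrf["x"] == pytest.approx(np.sqrt((n - 1) / n))
        assert report.converged

    def test_hand_evaluated_psrf(self):
        report = bgr_diagnostic(scalar_draws([[1, 2, 3], [1, 2, 3]]))
        assert report.psrf["x"] == pytest.approx(np.sqrt(2 / 3))

    def test_zero_within_variance_is_degenerate_not_failed(self):
        report = bgr_diagnostic(scalar_draws([[0, 0, 0, 0], [10, 10, 10, 10]]))
        assert report.degenerate == ["x"]
        assert np.isnan(report.psrf["x"])
        assert report.converged  # nothing non-degenerate failed

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 200)
        b = rng.normal(5, 1, 200)
        report = bgr_diagnostic(scalar_draws([a, b]))
        assert report.psrf["x"] > 1.5
        assert not report.converged

    def test_single_chain_raises(self):
        with pytest.raises(ValueError, match="2 chains"):
            bgr_diagnostic(scalar_draws([[1.0, 2.0]]))

    def test_agrees_qualitatively_with_arviz(self):
        import arviz as az

        rng = np.random.default_rng(2)
        chains = rng.normal(size=(3, 400))
        ours = bgr_diagnostic(scalar_draws(chains)).psrf["x"]
        theirs = float(az.rhat(chains[None, ...][0]))
        assert ours == pytest.approx(1.0, abs=0.05)
        assert theirs == pytest.approx(1.0, abs=0.05)

    def test_psrf_approaches_one_with_longer_chains(self):
        cfg = SimulationConfig(
            n_genotypes=2, n_replicates=2,
            design=mblrc.SequentialDesign(mblrc.GREENHOUSE_LADDER),
            seed=33, environment="greenhouse",
        )
        data, _ = simulate_dataset(cfg)
        worst = []
        for n_iter in (100, 400, 1600):
            draws = fit_mblrc(
                data, PriorSpec(),
                FitConfig(n_chains=2, n_adapt=800, n_iter=n_iter, thin=2, seed=4),
            )
            psrf = [v for v in bgr_diagnostic(draws).psrf.values() if not np.isnan(v)]
            worst.append(max(psrf))
        assert worst[2] < worst[0]
        assert worst[2] < 1.1


class TestThin:
    def test_identity_at_k_one(self, small_fit):
        out = thin(small_fit, 1)
        np.testing.assert_array_equal(out.draws, small_fit.draws)

    def test_keeps_every_kth_from_zero(self):
        chains = np.arange(100.0)[None, :]
        d = scalar_draws(np.vstack([chains, chains]))
        out = thin(d, 10)
        assert out.n_retained == 10
        np.testing.assert_array_equal(out.pooled("x")[:10], np.arange(0.0, 100.0, 10.0))

    def test_k_exceeding_chain_length_raises(self, small_fit):
        with pytest.raises(ValueError, match="exceeds"):
            thin(small_fit, small_fit.n_retained + 1)

    def test_thinning_reduces_autocorrelation_of_ar1_series(self):
        rng = np.random.default_rng(5)
        n, rho = 20_000, 0.9
        x = np.empty(n)
        x[0] = rng.normal()
        for t in range(1, n):  # AR(1) oracle series
            x[t] = rho * x[t - 1] + rng.normal()
        def lag1(v):
            return np.corrcoef(v[:-1], v[1:])[0, 1]
        d = scalar_draws(np.vstack([x, x]))
        assert lag1(thin(d, 10).pooled("x")[: n // 10]) <= lag1(x)


class TestPosteriorPredictive:
    def _setup(self, noise_sd=1.0, n_obs=30, seed=3):
        cfg = SimulationConfig(
            n_genotypes=1, n_replicates=1,
            design=mblrc.NonSequentialDesign(n_measurements_per_plant=n_obs),
            noise_sd=noise_sd, hyper_sds=ZERO_SDS, plant_sds=ZERO_SDS, seed=seed,
        )
        return simulate_dataset(cfg)

    def test_degenerate_draws_reproduce_the_mean_curve(self):
        data, truth = self._setup()
        truth.obs_precision = 1e12  # effectively noise-free predictive
        ppc = posterior_predictive(
            draws_from_states([truth, truth]), data, np.random.default_rng(0)
        )
        par, _, _ = data.arrays()
        mu = mblrc.nrh_mean(truth.params_for(data.plant_labels[0]), par)
        np.testing.assert_allclose(ppc.mean, mu, atol=1e-4)
        assert np.max(ppc.upper - ppc.lower) < 1e-4

    def test_interval_ordering_invariant(self, small_fit, small_study):
        data, _ = small_study
        ppc = posterior_predictive(small_fit, data, np.random.default_rng(1))
        assert np.all(ppc.lower <= ppc.mean) and np.all(ppc.mean <= ppc.upper)

    def test_nominal_coverage_when_draws_equal_truth(self):
        data, truth = self._setup(noise_sd=1.0, n_obs=1000, seed=9)
        states = [truth] * 300  # truth known exactly, predictive noise only
        ppc = posterior_predictive(
            draws_from_states(states, n_chains=2), data, np.random.default_rng(2)
        )
        _, a_n, _ = data.arrays()
        inside = np.mean((a_n >= ppc.lower) & (a_n <= ppc.upper))
        assert 0.93 <= inside <= 0.97

    def test_mismatched_plants_raise(self, small_fit):
        cfg = SimulationConfig(n_genotypes=4, n_replicates=1, seed=3)
        data, _ = simulate_dataset(cfg)  # G4-P1 absent from the small fit
        with pytest.raises(KeyError):
            posterior_predictive(small_fit, data, np.random.default_rng(0))


class TestGoodnessOfFit:
    def test_perfect_prediction(self):
        g = goodness_of_fit([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (g.r2, g.slope, g.intercept) == pytest.approx((1.0, 1.0, 0.0))

    def test_matches_pearson_oracle(self):
        obs = np.array([1.0, 2.0, 3.0])
        pred = np.array([1.1, 1.9, 3.2])
        g = goodness_of_fit(obs, pred)
        assert g.r2 == pytest.approx(np.corrcoef(obs, pred)[0, 1] ** 2, abs=1e-12)
        assert g.r2 == pytest.approx(0.981, abs=1e-3)

    def test_anticorrelation_r2_is_signless(self):
        g = goodness_of_fit([1.0, 2.0, 3.0], [3.0, 2.0, 1.0])
        assert g.r2 == pytest.approx(1.0)
        assert g.slope == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            goodness_of_fit([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="3 points"):
            goodness_of_fit([1.0, 2.0], [1.0, 2.0])
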