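"""Hierarchical inference: densities, sampler contracts, oracle equivalence."""

import numpy as np
import pytest
from scipy import stats

import mblrc
from mblrc import (
    FitConfig,
    PriorSpec,
    SequentialDesign,
    SimulationConfig,
    fit_mblrc,
    fit_reduced_two_param,
    grid_posterior_oracle,
    log_likelihood,
    log_prior,
    simulate_dataset,
)
from mblrc.data import Dataset, Observation
from mblrc.model import nrh_mean
from mblrc.state import MblrcState

ZERO_SDS = {"a_max": 0.0, "alpha": 0.0, "r_d": 0.0, "theta": 0.0}


def single_plant_state(params=(20.0, 0.05, 1.5, 0.8), obs_precision=1.0):
    return MblrcState(
        plant_labels=["G1-P1"],
        genotype_labels=["G1"],
        plant_genotype=np.array([0]),
        plant_params=np.array([params]),
        genotype_means=np.array([params]),
        genotype_precisions=np.array([1.0, 100.0, 4.0, 50.0]),
        obs_precision=obs_precision,
    )


def obs(i, par, a_n, plant="G1-P1", geno="G1"):
    return Observation(obs_id=i, genotype_id=geno, plant_id=plant,
                       environment="field", par=par, a_n=a_n)


class TestLogLikelihood:
    def test_single_observation_at_the_mean(self):
        state = single_plant_state()
        mu = nrh_mean(state.params_for("G1-P1"), 400.0)
        data = Dataset([obs(0, 400.0, mu)])
        assert log_likelihood(state, data) == pytest.approx(
            np.log(1.0 / np.sqrt(2 * np.pi)), abs=1e-12
        )

    def test_doubling_data_doubles_log_likelihood(self):
        state = single_plant_state()
        d1 = Dataset([obs(0, 400.0, 15.0)])
        d2 = Dataset([obs(0, 400.0, 15.0), obs(1, 400.0, 15.0)])
        assert log_likelihood(state, d2) == pytest.approx(
            2 * log_likelihood(state, d1), rel=1e-12
        )

    def test_matches_normal_logpdf_sum_oracle(self):
        state = single_plant_state(obs_precision=4.0)
        rows = [(100.0, 3.2), (800.0, 14.1), (2000.0, 17.9)]
        data = Dataset([obs(i, p, a) for i, (p, a) in enumerate(rows)])
        p_ = state.params_for("G1-P1")
        expected = sum(
            stats.norm.logpdf(a, loc=nrh_mean(p_, par), scale=0.5)
            for par, a in rows
        )
        assert log_likelihood(state, data) == pytest.approx(expected, abs=1e-10)

    def test_unknown_plant_raises(self):
        state = single_plant_state()
        data = Dataset([obs(0, 400.0, 15.0, plant="G9-P1", geno="G9")])
        with pytest.raises(KeyError, match="G9-P1"):
            log_likelihood(state, data)


class TestLogPrior:
    def test_truncation_violation_is_rejected(self):
        state = single_plant_state(params=(20.0, 0.05, 1.5, 1.2))
        assert log_prior(state, PriorSpec()) == -np.inf

    def test_matches_per_term_oracle(self):
        priors = PriorSpec()
        state = single_plant_state()
        expected = 0.0
        for j in range(4):
            lo, hi = priors.lower[j], priors.upper[j]
            sd = 1.0 / np.sqrt(state.genotype_precisions[j])
            m = state.genotype_means[0, j]
            x = state.plant_params[0, j]
            a, b = (lo - m) / sd, (hi - m) / sd
            expected += stats.truncnorm.logpdf(x, a, b, loc=m, scale=sd)
            a, b = (lo - priors.means[j]) / priors.sds[j], (hi - priors.means[j]) / priors.sds[j]
            expected += stats.truncnorm.logpdf(m, a, b, loc=priors.means[j], scale=priors.sds[j])
        for tau in [*state.genotype_precisions, state.obs_precision]:
            expected += stats.gamma.logpdf(tau, 0.01, scale=100.0)
        assert log_prior(state, priors) == pytest.approx(expected, rel=1e-12)

    def test_tightening_precision_off_mean_lowers_plant_term(self):
        # at fixed deviation, beyond the normalisation gain, a much tighter
        # genotype precision must eventually lower the density of an
        # off-mean plant (finite-difference sign check)
        priors = PriorSpec()
        base = single_plant_state(params=(23.0, 0.05, 1.5, 0.8))
        base.genotype_means[0, 0] = 20.0  # plant 3 units off its genotype mean
        lp = []
        for tau_a in (1.0, 100.0):
            s = single_plant_state(params=(23.0, 0.05, 1.5, 0.8))
            s.genotype_means[0, 0] = 20.0
            s.genotype_precisions[0] = tau_a
            lp.append(log_prior(s, priors))
        assert lp[1] < lp[0]


class TestFitConfig:
    def test_rejects_single_chain(self):
        with pytest.raises(ValueError, match="n_chains"):
            FitConfig(n_chains=1)

    def test_rejects_nothing_to_retain(self):
        with pytest.raises(ValueError, match="retain"):
            FitConfig(n_iter=0)

    def test_rejects_zero_thin(self):
        with pytest.raises(ValueError):
            FitConfig(thin=0)


@pytest.fixture(scope="module")
def tiny_fit():
    cfg = SimulationConfig(
        n_genotypes=2, n_replicates=2,
        design=SequentialDesign(mblrc.GREENHOUSE_LADDER),
        seed=21, environment="greenhouse",
    )
    data, truth = simulate_dataset(cfg)
    config = FitConfig(n_chains=2, n_adapt=600, n_iter=300, thin=2, seed=9)
    return data, truth, config, fit_mblrc(data, PriorSpec(), config)


class TestFitContracts:
    def test_retained_draw_counts(self, tiny_fit):
        data, _, config, draws = tiny_fit
        assert draws.n_chains == config.n_chains
        assert draws.n_retained == config.n_iter
        assert draws.n_pooled == config.n_chains * config.n_iter

    def test_deterministic_given_seed(self, tiny_fit):
        data, _, config, draws = tiny_fit
        again = fit_mblrc(data, PriorSpec(), config)
        np.testing.assert_array_equal(draws.draws, again.draws)

    def test_every_draw_satisfies_truncation(self, tiny_fit):
        _, _, _, draws = tiny_fit
        priors = PriorSpec()
        params = draws.plant_param_draws()  # (D, P, 4)
        for j in range(4):
            assert params[:, :, j].min() >= priors.lower[j]
            assert params[:, :, j].max() <= priors.upper[j]
        assert draws.pooled("tau.obs").min() > 0

    def test_label_permutation_permutes_posteriors(self, tiny_fit):
        data, _, config, draws = tiny_fit
        swap = {"G1": "G2", "G2": "G1"}
        renamed = Dataset(
            [
                Observation(
                    obs_id=o.obs_id,
                    genotype_id=swap[o.genotype_id],
                    plant_id=o.plant_id.replace(o.genotype_id, swap[o.genotype_id]),
                    environment=o.environment,
                    par=o.par,
                    a_n=o.a_n,
                )
                for o in data.observations
            ]
        )
        draws2 = fit_mblrc(renamed, PriorSpec(), config)
        np.testing.assert_array_equal(
            draws.pooled("mu.a_max[G1]"), draws2.pooled("mu.a_max[G2]")
        )
        np.testing.assert_array_equal(
            draws.pooled("mu.theta[G2]"), draws2.pooled("mu.theta[G1]")
        )

    def test_single_genotype_recovery_within_ten_percent(self):
        # 5 plants x 11 levels = 55 observations, known truth
        ladder = SequentialDesign(mblrc.CHAMBER_LADDER + (0.0,))
        cfg = SimulationConfig(
            n_genotypes=1, n_replicates=5, design=ladder, noise_sd=0.5,
            hyper_sds=ZERO_SDS, seed=13, environment="growth_chamber",
        )
        data, truth = simulate_dataset(cfg)
        assert len(data) == 55
        draws = fit_mblrc(
            data, PriorSpec(),
            FitConfig(n_chains=3, n_adapt=1000, n_iter=800, thin=3, seed=3),
        )
        post_mean = draws.pooled("mu.a_max[G1]").mean()
        assert post_mean == pytest.approx(truth.genotype_means[0, 0], rel=0.10)


class TestGridOracle:
    def _single_plant_data(self, noise_sd=0.5, seed=7):
        cfg = SimulationConfig(
            n_genotypes=1, n_replicates=1,
            design=SequentialDesign(mblrc.GREENHOUSE_LADDER + mblrc.CHAMBER_LADDER),
            noise_sd=noise_sd, hyper_sds=ZERO_SDS, plant_sds=ZERO_SDS,
            seed=seed, environment="greenhouse",
        )
        return simulate_dataset(cfg)[0]

    def test_mass_normalised(self):
        data = self._single_plant_data()
        grid = grid_posterior_oracle(data, PriorSpec(), 0.05, 0.8, 0.5, n_grid=101)
        assert grid.posterior.sum() == pytest.approx(1.0, abs=1e-9)

    def test_flat_likelihood_returns_the_prior(self):
        data = self._single_plant_data()
        priors = PriorSpec()
        grid = grid_posterior_oracle(data, priors, 0.05, 0.8, obs_sd=1e9, n_grid=401)
        a, b = -priors.means[0] / priors.sds[0], (100 - priors.means[0]) / priors.sds[0]
        prior_mean = stats.truncnorm.mean(a, b, loc=priors.means[0], scale=priors.sds[0])
        assert grid.mean("a_max") == pytest.approx(prior_mean, rel=0.01)

    def test_rejects_coarse_grid(self):
        data = self._single_plant_data()
        with pytest.raises(ValueError, match="coarse"):
            grid_posterior_oracle(data, PriorSpec(), 0.05, 0.8, 0.5, n_grid=40)

    def test_mcmc_matches_grid_marginals(self):
        data = self._single_plant_data()
        priors = PriorSpec()
        grid = grid_posterior_oracle(data, priors, 0.05, 0.8, 0.5, n_grid=401)
        draws = fit_reduced_two_param(
            data, priors, 0.05, 0.8, 0.5,
            FitConfig(n_chains=3, n_adapt=1000, n_iter=4000, thin=2, seed=3),
        )
        am = draws.pooled("a_max[G1-P1]")
        rd = draws.pooled("r_d[G1-P1]")
        assert am.mean() == pytest.approx(grid.mean("a_max"), rel=0.02)
        assert rd.mean() == pytest.approx(grid.mean("r_d"), rel=0.02)
        assert am.std() == pytest.approx(grid.sd("a_max"), rel=0.10)
        assert rd.std() == pytest.approx(grid.sd("r_d"), rel=0.10)
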