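import numpy as np
import pytest

import mblrc
from mblrc.state import MblrcState, PosteriorDraws, parameter_names


def state_vector(state: MblrcState) -> np.ndarray:
    """Flatten a state in the sampler's storage layout."""
    return np.concatenate(
        [
            state.plant_params.reshape(-1),
            state.genotype_means.reshape(-1),
            np.asarray(state.genotype_precisions, dtype=float),
            [state.obs_precision],
        ]
    )


def draws_from_states(states, n_chains=2):
    """PosteriorDraws whose chains all replay the given list of states."""
    first = states[0]
    vecs = np.stack([state_vector(s) for s in states])
    return PosteriorDraws(
        draws=np.tile(vecs, (n_chains, 1, 1)),
        names=parameter_names(first.plant_labels, first.genotype_labels),
        plant_labels=first.plant_labels,
        genotype_labels=first.genotype_labels,
        plant_genotype=first.plant_genotype,
    )


def scalar_draws(chains, name="x"):
    """PosteriorDraws holding a single scalar parameter."""
    arr = np.asarray(chains, dtype=float)[:, :, None]
    return PosteriorDraws(
        draws=arr,
        names=[name],
        plant_labels=[],
        genotype_labels=[],
        plant_genotype=np.array([], dtype=np.int64),
    )


@pytest.fixture(scope="session")
def small_study():
    """A small sequential-design simulation with its ground truth."""
    cfg = mblrc.SimulationConfig(
        n_genotypes=3,
        n_replicates=3,
        design=mblrc.SequentialDesign(mblrc.GREENHOUSE_LADDER),
        noise_sd=1.0,
        environment="greenhouse",
        seed=42,
    )
    return mblrc.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_fit(small_study):
    """A converged scaled-down fit of the small study, shared across tests."""
    data, _ = small_study
    config = mblrc.FitConfig(n_chains=3, n_adapt=1000, n_iter=600, thin=3, seed=7)
    return mblrc.fit_mblrc(data, mblrc.PriorSpec(), config)
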