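"""Hierarchical Bayesian fitting of light response curves by MCMC.

The model has three parts:

1. **likelihood** — each observed net photosynthesis value is Normal around
   the non-rectangular hyperbola mean for its plant, with a shared
   observation precision τ (1/variance);
2. **process model** — the NRH mean as a function of PAR, with plant-level
   curve parameters;
3. **parameter model** — plant parameters scatter (truncated-normally)
   around genotype-level means with per-parameter precisions; genotype means
   get informative truncated-normal priors centred on literature-typical
   rice values with deliberately large (±200%) spread, and all precisions
   get vague gamma priors.

The joint posterior is sampled by an adaptive Metropolis-within-Gibbs
sampler (numba-compiled, see :mod:`mblrc._kernel`), run as several
independent chains with seeds derived from one master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .data import Dataset
from .model import PARAM_NAMES, nrh_mean_arrays
from .state import MblrcState, PosteriorDraws, parameter_names

__all__ = [
    "PriorSpec",
    "FitConfig",
    "log_likelihood",
    "log_prior",
    "fit_mblrc",
    "fit_reduced_two_param",
    "grid_posterior_oracle",
    "GridPosterior",
]


def _default_arr(vals) -> np.ndarray:
    return np.asarray(vals, dtype=float)


@dataclass(frozen=True)
class PriorSpec:
    """Priors for genotype-level means and all precision terms.

    ``means``/``sds``/``lower``/``upper`` are length-4 vectors in the
    canonical parameter order (a_max, alpha, r_d, theta).  Defaults centre
    on literature-typical rice values with sd = 2 × mean (the "±200%
    variance" convention) truncated to each parameter's physical support:
    a_max ∈ (0, 100], alpha ∈ (0, 0.125] (theoretical quantum-yield
    ceiling), r_d ∈ [0, 10], theta ∈ (0, 1].  Precisions get a vague
    Gamma(0.01, 0.01).
    """

    means: np.ndarray = field(default_factory=lambda: _default_arr([25.0, 0.05, 1.5, 0.8]))
    sds: np.ndarray = field(default_factory=lambda: _default_arr([50.0, 0.10, 3.0, 1.6]))
    lower: np.ndarray = field(default_factory=lambda: _default_arr([1e-6, 1e-6, 0.0, 1e-6]))
    upper: np.ndarray = field(default_factory=lambda: _default_arr([100.0, 0.125, 10.0, 1.0]))
    prec_shape: float = 0.01
    prec_rate: float = 0.01

    def __post_init__(self):
        for name in ("means", "sds", "lower", "upper"):
            object.__setattr__(self, name, _default_arr(getattr(self, name)))
        if np.any(self.sds <= 0):
            raise ValueError("prior sds must be > 0")
        if np.any(self.lower >= self.upper):
            raise ValueError("lower truncation must be < upper")
        if self.prec_shape <= 0 or self.prec_rate <= 0:
            raise ValueError("precision prior shape/rate must be > 0")


@dataclass(frozen=True)
class FitConfig:
    """MCMC protocol.

    ``n_iter`` counts RETAINED draws per chain after thinning (the
    convention in which "10,000 iterations, thinned every 10th" yields
    10,000 values per chain); the sampler therefore runs
    ``n_adapt + n_iter × thin`` raw iterations per chain.
    """

    n_chains: int = 3
    n_adapt: int = 1500
    n_iter: int = 10_000
    thin: int = 10
    seed: int = 0
    target_accept: float = 0.3

    def __post_init__(self):
        if self.n_chains < 2:
            raise ValueError("n_chains must be >= 2 (convergence diagnostics need multiple chains)")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1: nothing to retain")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if not 0 < self.target_accept < 1:
            raise ValueError("target_accept must be in (0, 1)")

    def with_seed(self, seed: int) -> "FitConfig":
        return replace(self, seed=seed)


#: Scaled-down protocol for tests and quick runs.
def small_fit_config(seed: int = 0, n_chains: int = 3) -> FitConfig:
    return FitConfig(n_chains=n_chains, n_adapt=1000, n_iter=1000, thin=2, seed=seed)


def _align(state: MblrcState, data: Dataset) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(par, a_n, plant rows in state order) with label checking."""
    par, a_n, _ = data.arrays()
    pos = {p: i for i, p in enumerate(state.plant_labels)}
    try:
        plant_idx = np.array([pos[o.plant_id] for o in data.observations], dtype=np.int64)
    except KeyError as e:
        raise KeyError(f"plant {e.args[0]!r} in data has no parameters in state") from None
    return par, a_n, plant_idx


def log_likelihood(state: MblrcState, data: Dataset) -> float:
    """Gaussian log likelihood of the data given the latent state."""
    par, a_n, plant_idx = _align(state, data)
    mu = nrh_mean_arrays(state.plant_params[plant_idx], par)
    sd = 1.0 / np.sqrt(state.obs_precision)
    return float(np.sum(stats.norm.logpdf(a_n, loc=mu, scale=sd)))


def _truncnorm_logpdf(x, mean, sd, lo, hi):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.logpdf(x, a, b, loc=mean, scale=sd)


def log_prior(state: MblrcState, priors: PriorSpec) -> float:
    """Log density of the hierarchy: plant params | genotype means &
    precisions, genotype means | priors, gamma densities of all precisions.

    Returns −inf for states violating any truncation bound.
    """
    lp = 0.0
    sds = 1.0 / np.sqrt(np.asarray(state.genotype_precisions, dtype=float))
    for j in range(4):
        lo, hi = priors.lower[j], priors.upper[j]
        gm = state.genotype_means[:, j]
        pp = state.plant_params[:, j]
        if np.any(gm < lo) or np.any(gm > hi) or np.any(pp < lo) or np.any(pp > hi):
            return -np.inf
        lp += float(np.sum(_truncnorm_logpdf(
            pp, state.genotype_means[state.plant_genotype, j], sds[j], lo, hi
        )))
        lp += float(np.sum(_truncnorm_logpdf(gm, priors.means[j], priors.sds[j], lo, hi)))
    prec = np.append(np.asarray(state.genotype_precisions, dtype=float),
                     state.obs_precision)
    lp += float(np.sum(stats.gamma.logpdf(
        prec, priors.prec_shape, scale=1.0 / priors.prec_rate
    )))
    return lp


def _chain_seeds(seed: int, n_chains: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n_chains)]


def _initial_values(priors: PriorSpec, G: int, P: int, plant_geno: np.ndarray,
                    rng: np.random.Generator):
    """Overdispersed chain start: genotype means scattered around the prior
    centre, plants jittered around their genotype mean."""
    centre = np.clip(priors.means, priors.lower, priors.upper)
    width = np.minimum(priors.sds, 0.25 * (priors.upper - priors.lower))
    geno0 = np.clip(
        centre[None, :] + rng.uniform(-0.5, 0.5, size=(G, 4)) * width[None, :],
        priors.lower + 1e-6 * (priors.upper - priors.lower),
        priors.upper - 1e-6 * (priors.upper - priors.lower),
    )
    jitter = 0.02 * (priors.upper - priors.lower)
    plant0 = np.clip(
        geno0[plant_geno] + rng.normal(0.0, 1.0, size=(P, 4)) * jitter[None, :],
        priors.lower + 1e-6 * (priors.upper - priors.lower),
        priors.upper - 1e-6 * (priors.upper - priors.lower),
    )
    tau0 = 1.0 / (0.2 * centre) ** 2
    return plant0, geno0, tau0


def fit_mblrc(
    data: Dataset,
    priors: PriorSpec | None = None,
    config: FitConfig | None = None,
) -> PosteriorDraws:
    """Sample the joint posterior of the multilevel model for one dataset.

    Runs ``config.n_chains`` independent adaptive Metropolis-within-Gibbs
    chains with seeds derived from ``config.seed``, discards the adaptation
    phase, and retains ``config.n_iter`` draws per chain after thinning by
    ``config.thin``.  Deterministic given the seed.

    Raises if the data are empty or if any chain's post-adaptation
    Metropolis acceptance rate falls outside (0.05, 0.95), which signals
    broken proposal tuning rather than a usable posterior.
    """
    from ._kernel import run_chain

    priors = priors or PriorSpec()
    config = config or FitConfig()
    if len(data) == 0:
        raise ValueError("empty dataset")

    par, a_n, plant_idx = data.arrays()
    plant_geno = data.plant_genotype
    P, G = data.n_plants, data.n_genotypes
    upd_plant = np.ones(4, dtype=np.bool_)

    seeds = _chain_seeds(config.seed, config.n_chains)
    chains = []
    rates = []
    for c, s in enumerate(seeds):
        rng = np.random.default_rng(s)
        plant0, geno0, tau0 = _initial_values(priors, G, P, plant_geno, rng)
        out, rate = run_chain(
            par, a_n, plant_idx, plant_geno,
            priors.means, priors.sds, priors.lower, priors.upper,
            priors.prec_shape, priors.prec_rate,
            plant0, geno0, tau0, 1.0,
            upd_plant, True, True, True,
            config.n_adapt, config.n_iter, config.thin,
            config.target_accept, s,
        )
        if not 0.05 < rate < 0.95:
            raise RuntimeError(
                f"chain {c}: post-adaptation acceptance rate {rate:.3f} "
                "outside (0.05, 0.95); proposal tuning failed"
            )
        chains.append(out)
        rates.append(rate)

    return PosteriorDraws(
        draws=np.stack(chains),
        names=parameter_names(data.plant_labels, data.genotype_labels),
        plant_labels=data.plant_labels,
        genotype_labels=data.genotype_labels,
        plant_genotype=plant_geno,
        meta={
            "seed": config.seed,
            "chain_seeds": seeds,
            "n_chains": config.n_chains,
            "n_adapt": config.n_adapt,
            "n_iter": config.n_iter,
            "thin": config.thin,
            "acceptance_rates": rates,
            "environment": data.environment,
        },
    )


def fit_reduced_two_param(
    data: Dataset,
    priors: PriorSpec,
    alpha: float,
    theta: float,
    obs_sd: float,
    config: FitConfig | None = None,
) -> PosteriorDraws:
    """Posterior over (a_max, r_d) only, for a single-plant dataset.

    alpha, theta and the observation sd are held fixed, the hierarchy is
    collapsed (one genotype whose mean is pinned at the prior centre with
    precision 1/prior_sd², so the plant-level prior is exactly the
    truncated-normal PriorSpec prior).  Runs the same compiled update
    kernel as :func:`fit_mblrc`, restricted to the two free coordinates —
    which is what lets a brute-force grid posterior act as an independent
    check on the sampler (see :func:`grid_posterior_oracle`).
    """
    from ._kernel import run_chain

    config = config or FitConfig(n_chains=3, n_adapt=1000, n_iter=4000, thin=2)
    if data.n_plants != 1:
        raise ValueError("reduced model is defined for a single plant")

    par, a_n, plant_idx = data.arrays()
    plant_geno = data.plant_genotype
    upd_plant = np.array([True, False, True, False])
    geno0 = priors.means.reshape(1, 4).copy()
    tau0 = 1.0 / priors.sds**2
    obstau = 1.0 / obs_sd**2

    seeds = _chain_seeds(config.seed, config.n_chains)
    chains = []
    for c, s in enumerate(seeds):
        rng = np.random.default_rng(s)
        plant0 = geno0.copy()
        plant0[0, 1] = alpha
        plant0[0, 3] = theta
        plant0[0, 0] = float(np.clip(
            priors.means[0] * rng.uniform(0.5, 1.5), priors.lower[0], priors.upper[0]
        ))
        plant0[0, 2] = float(np.clip(
            priors.means[2] * rng.uniform(0.5, 1.5) + 0.1, priors.lower[2], priors.upper[2]
        ))
        out, rate = run_chain(
            par, a_n, plant_idx, plant_geno,
            priors.means, priors.sds, priors.lower, priors.upper,
            priors.prec_shape, priors.prec_rate,
            plant0, geno0, tau0, obstau,
            upd_plant, False, False, False,
            config.n_adapt, config.n_iter, config.thin,
            config.target_accept, s,
        )
        if not 0.05 < rate < 0.95:
            raise RuntimeError(f"chain {c}: acceptance rate {rate:.3f} out of range")
        chains.append(out)

    return PosteriorDraws(
        draws=np.stack(chains),
        names=parameter_names(data.plant_labels, data.genotype_labels),
        plant_labels=data.plant_labels,
        genotype_labels=data.genotype_labels,
        plant_genotype=plant_geno,
        meta={"seed": config.seed, "reduced": True, "alpha": alpha,
              "theta": theta, "obs_sd": obs_sd},
    )


@dataclass
class GridPosterior:
    """Brute-force posterior over (a_max, r_d) on a rectangular grid."""

    a_max_grid: np.ndarray
    r_d_grid: np.ndarray
    posterior: np.ndarray  # (len(a_max_grid), len(r_d_grid)), sums to 1

    @property
    def marginal_a_max(self) -> np.ndarray:
        return self.posterior.sum(axis=1)

    @property
    def marginal_r_d(self) -> np.ndarray:
        return self.posterior.sum(axis=0)

    def mean(self, which: str) -> float:
        if which == "a_max":
            return float(np.sum(self.a_max_grid * self.marginal_a_max))
        if which == "r_d":
            return float(np.sum(self.r_d_grid * self.marginal_r_d))
        raise KeyError(which)

    def sd(self, which: str) -> float:
        g = self.a_max_grid if which == "a_max" else self.r_d_grid
        w = self.marginal_a_max if which == "a_max" else self.marginal_r_d
        m = self.mean(which)
        return float(np.sqrt(np.sum(w * (g - m) ** 2)))


def grid_posterior_oracle(
    data: Dataset,
    priors: PriorSpec,
    alpha: float,
    theta: float,
    obs_sd: float,
    n_grid: int = 201,
    a_max_range: Sequence[float] | None = None,
    r_d_range: Sequence[float] | None = None,
) -> GridPosterior:
    """Independent brute-force posterior for the two-parameter reduced model.

    Evaluates prior × likelihood on an ``n_grid × n_grid`` rectangle and
    normalises to total mass 1; used to verify the MCMC sampler against an
    implementation that shares none of its machinery.
    """
    if len(data) > 30:
        raise ValueError("grid oracle is for small datasets (<= 30 observations)")
    if data.n_plants != 1:
        raise ValueError("grid oracle is defined for a single plant")
    if n_grid < 50:
        raise ValueError("grid too coarse: need >= 50 points per axis")

    par, a_n, _ = data.arrays()
    lo_a, hi_a = (a_max_range if a_max_range is not None
                  else (priors.lower[0], priors.upper[0]))
    lo_r, hi_r = (r_d_range if r_d_range is not None
                  else (priors.lower[2], priors.upper[2]))
    a_grid = np.linspace(lo_a, hi_a, n_grid)
    r_grid = np.linspace(lo_r, hi_r, n_grid)

    lp_a = _truncnorm_logpdf(a_grid, priors.means[0], priors.sds[0],
                             priors.lower[0], priors.upper[0])
    lp_r = _truncnorm_logpdf(r_grid, priors.means[2], priors.sds[2],
                             priors.lower[2], priors.upper[2])

    # log likelihood on the grid: loop over a_max (gross curve depends on it),
    # r_d enters as a pure offset
    s = alpha * par[None, :] + a_grid[:, None]
    disc = np.maximum(
        s * s - 4.0 * theta * alpha * par[None, :] * a_grid[:, None], 0.0
    )
    gross = (s - np.sqrt(disc)) / (2.0 * theta)  # (n_grid, N)
    logpost = np.empty((n_grid, n_grid))
    inv2v = 0.5 / obs_sd**2
    for k, r_d in enumerate(r_grid):
        resid = a_n[None, :] - (gross - r_d)
        logpost[:, k] = -inv2v * np.sum(resid * resid, axis=1)
    logpost += lp_a[:, None] + lp_r[None, :]

    logpost -= logpost.max()
    post = np.exp(logpost)
    post /= post.sum()
    return GridPosterior(a_max_grid=a_grid, r_d_grid=r_grid, posterior=post)
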