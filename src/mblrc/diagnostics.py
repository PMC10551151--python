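"""Convergence diagnostics, thinning, and posterior predictive evaluation.

Convergence is assessed with the multi-chain potential scale reduction
factor (PSRF, the Brooks–Gelman–Rubin statistic): for each scalar
parameter, with n draws per chain, W the mean within-chain variance and
B/n the variance of the chain means,

    V̂ = ((n − 1)/n)·W + B/n,      PSRF = sqrt(V̂ / W),

which approaches 1 from either side as the chains mix over the same
distribution.  Goodness of fit follows the observed-vs-modelled convention:
the posterior predictive mean of every observation is regressed on the
observed value and R² of that line is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
from scipy import stats

from .data import Dataset
from .model import nrh_mean_arrays
from .state import PosteriorDraws

__all__ = [
    "ConvergenceReport",
    "PosteriorPredictive",
    "GoodnessOfFit",
    "bgr_diagnostic",
    "thin",
    "posterior_predictive",
    "goodness_of_fit",
]

PSRF_THRESHOLD = 1.1


@dataclass
class ConvergenceReport:
    psrf: dict[str, float]  # NaN for degenerate (zero within-chain variance)
    threshold: float
    degenerate: list[str]
    converged: bool

    def worst(self) -> tuple[str, float]:
        name = max(self.psrf, key=lambda k: -1.0 if np.isnan(self.psrf[k]) else self.psrf[k])
        return name, self.psrf[name]


def bgr_diagnostic(
    draws: PosteriorDraws, threshold: float = PSRF_THRESHOLD
) -> ConvergenceReport:
    """PSRF per scalar parameter; converged iff all PSRF < threshold.

    Parameters whose within-chain variance is exactly zero are reported as
    degenerate (PSRF undefined), not as failed.
    """
    if draws.n_chains < 2:
        raise ValueError("PSRF requires at least 2 chains")
    n = draws.n_retained
    if n < 2:
        raise ValueError("PSRF requires at least 2 draws per chain")

    x = draws.draws  # (C, n, K)
    W = x.var(axis=1, ddof=1).mean(axis=0)  # (K,)
    B_over_n = x.mean(axis=1).var(axis=0, ddof=1)  # (K,)
    psrf_values = np.full(x.shape[2], np.nan)
    ok = W > 0
    vhat = (n - 1) / n * W[ok] + B_over_n[ok]
    psrf_values[ok] = np.sqrt(vhat / W[ok])

    psrf = dict(zip(draws.names, psrf_values))
    degenerate = [nm for nm, w in zip(draws.names, W) if w == 0]
    converged = bool(np.all(psrf_values[ok] < threshold))
    return ConvergenceReport(
        psrf=psrf, threshold=threshold, degenerate=degenerate, converged=converged
    )


def thin(draws: PosteriorDraws, k: int) -> PosteriorDraws:
    """Keep iterations 0, k, 2k, … of each chain."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > draws.n_retained:
        raise ValueError(f"k={k} exceeds chain length {draws.n_retained}")
    meta = dict(draws.meta)
    meta["thin_applied"] = meta.get("thin_applied", 1) * k
    return replace(draws, draws=draws.draws[:, ::k, :].copy(), meta=meta)


@dataclass
class PosteriorPredictive:
    """Per-observation predictive mean and central 95% credible bounds."""

    obs_id: np.ndarray
    mean: np.ndarray
    lower: np.ndarray  # 2.5%
    upper: np.ndarray  # 97.5%
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        if not (np.all(self.lower <= self.mean + 1e-12)
                and np.all(self.mean <= self.upper + 1e-12)):
            raise ValueError("interval ordering violated: need lower <= mean <= upper")


def posterior_predictive(
    draws: PosteriorDraws,
    data: Dataset,
    rng: np.random.Generator | None = None,
    chunk: int = 2000,
) -> PosteriorPredictive:
    """Simulate replicated data for every observation under every retained
    draw (NRH mean plus Gaussian noise at the drawn observation precision)
    and summarise as mean and empirical 2.5/97.5 percentiles."""
    if rng is None:
        rng = np.random.default_rng(0)
    if set(data.plant_labels) - set(draws.plant_labels):
        missing = sorted(set(data.plant_labels) - set(draws.plant_labels))
        raise KeyError(f"plants {missing} in data but not in draws")

    par, _, _ = data.arrays()
    pos = {p: i for i, p in enumerate(draws.plant_labels)}
    plant_idx = np.array([pos[o.plant_id] for o in data.observations], dtype=np.int64)

    all_params = draws.plant_param_draws()  # (D, P, 4)
    tau_obs = draws.obs_precision_draws()  # (D,)
    D, N = all_params.shape[0], len(par)
    sims = np.empty((D, N))
    for start in range(0, D, chunk):
        stop = min(start + chunk, D)
        block = all_params[start:stop][:, plant_idx, :]  # (d, N, 4)
        mu = nrh_mean_arrays(
            block.reshape(-1, 4), np.tile(par, stop - start)
        ).reshape(stop - start, N)
        sd = 1.0 / np.sqrt(tau_obs[start:stop])
        sims[start:stop] = mu + rng.normal(size=(stop - start, N)) * sd[:, None]

    lower, upper = np.percentile(sims, [2.5, 97.5], axis=0)
    return PosteriorPredictive(
        obs_id=np.array([o.obs_id for o in data.observations]),
        mean=sims.mean(axis=0),
        lower=lower,
        upper=upper,
        meta={"n_draws": D, "orientation": "predicted-on-observed"},
    )


@dataclass
class GoodnessOfFit:
    r2: float
    slope: float
    intercept: float
    n: int


def goodness_of_fit(observed, predictive) -> GoodnessOfFit:
    """OLS of the predictive mean on the observed values.

    ``predictive`` may be a :class:`PosteriorPredictive` or a plain vector
    of predicted means.  R² is the squared Pearson correlation (signless;
    the slope carries direction).
    """
    pred = predictive.mean if isinstance(predictive, PosteriorPredictive) else np.asarray(
        predictive, dtype=float
    )
    obs = np.asarray(observed, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted lengths differ")
    if len(obs) < 3:
        raise ValueError("need at least 3 points")
    if np.var(obs) == 0 or np.var(pred) == 0:
        raise ValueError("zero variance: goodness of fit undefined")
    res = stats.linregress(obs, pred)
    return GoodnessOfFit(
        r2=float(res.rvalue**2),
        slope=float(res.slope),
        intercept=float(res.intercept),
        n=len(obs),
    )
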