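"""Synthetic gas-exchange data with the multilevel structure the model assumes.

Two measurement designs are emulated:

* **non-sequential (survey)** curves — each plant is measured a few times at
  the ambient light it is acclimated to, so a genotype's curve is assembled
  from many leaves across the diurnal light range (the field design: 7
  genotypes × 5 replicate plants × 3 measurements, PAR spanning 1–2400);
* **sequential** curves — one leaf stepped through a fixed ladder of chamber
  light levels (10-step ladders by default).

Plant-level curve parameters scatter around genotype means, genotype means
around global hyper-means, and observed net photosynthesis around the
non-rectangular hyperbola mean with Gaussian noise — exactly the generative
structure the hierarchical fit assumes, so ground truth is returned alongside
the data for recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .data import Dataset, Observation
from .model import PARAM_NAMES, LrcParameters, nrh_mean
from .state import MblrcState

__all__ = [
    "SequentialDesign",
    "NonSequentialDesign",
    "SimulationConfig",
    "CHAMBER_LADDER",
    "GREENHOUSE_LADDER",
    "diurnal_par_sampler",
    "draw_genotype_params",
    "draw_plant_params",
    "simulate_dataset",
]

# Chamber auto-program ladder (µmol photon m⁻² s⁻¹), high to low.
CHAMBER_LADDER = (2000.0, 1600.0, 1400.0, 1200.0, 1000.0, 800.0, 600.0, 400.0, 200.0, 50.0)
# Greenhouse rapid-curve ladder, ending in darkness.
GREENHOUSE_LADDER = (1400.0, 1200.0, 1000.0, 800.0, 600.0, 400.0, 200.0, 100.0, 50.0, 0.0)

# Parameter support used when truncating hierarchy draws: the model
# invariants (a_max, alpha strictly positive; r_d non-negative; theta in (0, 1]).
_LOWER = np.array([1e-9, 1e-9, 0.0, 1e-9])
_UPPER = np.array([np.inf, np.inf, np.inf, 1.0])

_MAX_REJECTIONS = 1000


@dataclass(frozen=True)
class SequentialDesign:
    """Each plant measured once at every level of a light ladder, in order."""

    light_levels: tuple[float, ...] = GREENHOUSE_LADDER

    def validate(self) -> list[str]:
        bad = []
        if len(self.light_levels) < 1:
            bad.append("light_levels must be non-empty")
        if any(lv < 0 for lv in self.light_levels):
            bad.append("light_levels must all be >= 0")
        return bad


@dataclass(frozen=True)
class NonSequentialDesign:
    """Each plant measured at ambient light a few times across the day."""

    n_measurements_per_plant: int = 3
    par_min: float = 1.0
    par_max: float = 2400.0

    def validate(self) -> list[str]:
        bad = []
        if self.n_measurements_per_plant < 1:
            bad.append("n_measurements_per_plant must be >= 1")
        if not self.par_min < self.par_max:
            bad.append("par_min must be < par_max")
        if self.par_min < 0:
            bad.append("par_min must be >= 0")
        return bad


def _default_hyper_means() -> dict[str, float]:
    return {"a_max": 25.0, "alpha": 0.05, "r_d": 1.5, "theta": 0.8}


def _default_hyper_sds() -> dict[str, float]:
    return {"a_max": 3.0, "alpha": 0.005, "r_d": 0.3, "theta": 0.05}


@dataclass(frozen=True)
class SimulationConfig:
    """Study geometry and generative truth for one simulated environment.

    Defaults reproduce the field survey design: 7 genotypes × 5 replicate
    plants × 3 ambient-light measurements, observation noise 1.0
    µmol CO₂ m⁻² s⁻¹, genotype means scattered around realistic rice values
    (a_max 25±3, alpha 0.05±0.005, r_d 1.5±0.3, theta 0.8±0.05) with
    plant-level scatter half the genotype-level scatter.
    """

    n_genotypes: int = 7
    n_replicates: int = 5
    design: SequentialDesign | NonSequentialDesign = field(
        default_factory=NonSequentialDesign
    )
    noise_sd: float = 1.0
    hyper_means: dict[str, float] = field(default_factory=_default_hyper_means)
    hyper_sds: dict[str, float] = field(default_factory=_default_hyper_sds)
    plant_sds: dict[str, float] | None = None  # default: half the hyper sds
    environment: str = "field"
    seed: int = 0

    def resolved_plant_sds(self) -> dict[str, float]:
        if self.plant_sds is not None:
            return dict(self.plant_sds)
        return {k: v / 2.0 for k, v in self.hyper_sds.items()}

    def validate(self) -> list[str]:
        bad = []
        if self.n_genotypes < 1:
            bad.append("n_genotypes must be >= 1")
        if self.n_replicates < 1:
            bad.append("n_replicates must be >= 1")
        if self.noise_sd < 0:
            bad.append("noise_sd must be >= 0")
        for name in PARAM_NAMES:
            if name not in self.hyper_means or name not in self.hyper_sds:
                bad.append(f"hyper_means/hyper_sds missing {name}")
            elif self.hyper_sds[name] < 0:
                bad.append(f"hyper sd for {name} must be >= 0")
        bad.extend(self.design.validate())
        return bad

    def check(self) -> None:
        bad = self.validate()
        if bad:
            raise ValueError("invalid SimulationConfig: " + "; ".join(bad))

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


def _rng(config_or_seed, rng: np.random.Generator | None) -> np.random.Generator:
    if rng is not None:
        return rng
    seed = config_or_seed.seed if hasattr(config_or_seed, "seed") else config_or_seed
    return np.random.default_rng(seed)


def _truncated_normal(mean: float, sd: float, lo: float, hi: float,
                      rng: np.random.Generator) -> float:
    """One truncated-normal draw by rejection; exact and simple."""
    if sd == 0.0:
        if not (lo <= mean <= hi):
            raise ValueError(f"degenerate mean {mean} outside [{lo}, {hi}]")
        return mean
    for _ in range(_MAX_REJECTIONS):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return x
    raise RuntimeError(
        f"truncated-normal rejection failed after {_MAX_REJECTIONS} tries "
        f"(mean={mean}, sd={sd}, support=[{lo}, {hi}])"
    )


def draw_genotype_params(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> list[LrcParameters]:
    """Genotype-level mean parameters: Normal(hyper mean, hyper sd) per
    parameter, truncated to the model support by rejection."""
    config.check()
    rng = _rng(config, rng)
    out = []
    for _ in range(config.n_genotypes):
        vals = [
            _truncated_normal(
                config.hyper_means[q], config.hyper_sds[q], _LOWER[j], _UPPER[j], rng
            )
            for j, q in enumerate(PARAM_NAMES)
        ]
        out.append(LrcParameters(*vals))
    return out


def draw_plant_params(
    genotype_means: list[LrcParameters],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> list[list[LrcParameters]]:
    """Per-plant parameters: Normal(genotype mean, plant sd), truncated.

    Returns one list of ``n_replicates`` parameter sets per genotype.
    """
    config.check()
    rng = _rng(config, rng)
    plant_sds = config.resolved_plant_sds()
    out = []
    for gm in genotype_means:
        gvals = gm.as_array()
        plants = []
        for _ in range(config.n_replicates):
            vals = [
                _truncated_normal(gvals[j], plant_sds[q], _LOWER[j], _UPPER[j], rng)
                for j, q in enumerate(PARAM_NAMES)
            ]
            plants.append(LrcParameters(*vals))
        out.append(plants)
    return out


def diurnal_par_sampler(
    n: int, par_min: float, par_max: float, rng: np.random.Generator
) -> np.ndarray:
    """Ambient-light values proxying a diurnal irradiance course.

    Each value is par_min + (par_max − par_min)·sin(π·u)·(1 + j) with
    u ~ U(0,1) a time-of-day proxy and j ~ U(−0.1, 0.1) sky jitter,
    clipped to [par_min, par_max]; low and high light both get covered.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    u = rng.uniform(0.0, 1.0, size=n)
    j = rng.uniform(-0.1, 0.1, size=n)
    par = par_min + (par_max - par_min) * np.sin(np.pi * u) * (1.0 + j)
    return np.clip(par, par_min, par_max)


def simulate_dataset(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[Dataset, MblrcState]:
    """Simulate one environment's dataset plus the generating ground truth.

    Observed ``a_n`` is the non-rectangular-hyperbola mean for the plant's
    true parameters plus Normal(0, noise_sd) noise.  The returned
    :class:`~mblrc.state.MblrcState` carries the exact parameters used, for
    parameter-recovery testing.
    """
    config.check()
    rng = _rng(config, rng)
    genotype_means = draw_genotype_params(config, rng)
    plant_params = draw_plant_params(genotype_means, config, rng)

    genotype_labels = [f"G{g + 1}" for g in range(config.n_genotypes)]
    observations: list[Observation] = []
    plant_labels: list[str] = []
    plant_genotype: list[int] = []
    flat_params: list[np.ndarray] = []
    obs_id = 0
    for g, glabel in enumerate(genotype_labels):
        for r in range(config.n_replicates):
            plabel = f"{glabel}-P{r + 1}"
            params = plant_params[g][r]
            plant_labels.append(plabel)
            plant_genotype.append(g)
            flat_params.append(params.as_array())
            if isinstance(config.design, SequentialDesign):
                par_values = np.asarray(config.design.light_levels, dtype=float)
            else:
                par_values = diurnal_par_sampler(
                    config.design.n_measurements_per_plant,
                    config.design.par_min,
                    config.design.par_max,
                    rng,
                )
            mu = np.atleast_1d(nrh_mean(params, par_values))
            noise = (
                rng.normal(0.0, config.noise_sd, size=mu.shape)
                if config.noise_sd > 0
                else np.zeros_like(mu)
            )
            for par_v, a_v in zip(par_values, mu + noise):
                observations.append(
                    Observation(
                        obs_id=obs_id,
                        genotype_id=glabel,
                        plant_id=plabel,
                        environment=config.environment,
                        par=float(par_v),
                        a_n=float(a_v),
                    )
                )
                obs_id += 1

    plant_sds = config.resolved_plant_sds()
    precisions = np.array(
        [
            1.0 / plant_sds[q] ** 2 if plant_sds[q] > 0 else np.inf
            for q in PARAM_NAMES
        ]
    )
    truth = MblrcState(
        plant_labels=plant_labels,
        genotype_labels=genotype_labels,
        plant_genotype=np.array(plant_genotype, dtype=np.int64),
        plant_params=np.vstack(flat_params),
        genotype_means=np.vstack([gm.as_array() for gm in genotype_means]),
        genotype_precisions=precisions,
        obs_precision=1.0 / config.noise_sd**2 if config.noise_sd > 0 else np.inf,
    )
    return Dataset(observations, environment=config.environment), truth
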