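"""Latent-state and posterior-draw containers for the multilevel model.

The model has two stochastic levels — plants nested in genotypes — plus an
observation level.  A full latent state holds the four curve parameters for
every plant, per-genotype means of those parameters, one precision per
parameter governing plant scatter around its genotype mean, and the
observation precision (1/variance) of measured net photosynthesis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .model import PARAM_NAMES, LrcParameters, validate_params

__all__ = ["MblrcState", "PosteriorDraws", "parameter_names"]


@dataclass
class MblrcState:
    """Full latent state of the multilevel light-response model.

    Arrays are ordered consistently: ``plant_params[p]`` is the (a_max,
    alpha, r_d, theta) row for ``plant_labels[p]``, which belongs to
    ``genotype_labels[plant_genotype[p]]``.
    """

    plant_labels: list[str]
    genotype_labels: list[str]
    plant_genotype: np.ndarray  # (P,) int
    plant_params: np.ndarray  # (P, 4) float
    genotype_means: np.ndarray  # (G, 4) float
    genotype_precisions: np.ndarray  # (4,) float, tau per curve parameter
    obs_precision: float

    def params_for(self, plant_label: str) -> LrcParameters:
        p = self.plant_labels.index(plant_label)
        return LrcParameters(*self.plant_params[p])

    def validate(self) -> list[str]:
        """All violated invariants; empty iff the state is valid."""
        bad: list[str] = []
        if np.any(np.asarray(self.genotype_precisions) <= 0):
            bad.append("genotype precisions must be > 0")
        if self.obs_precision <= 0:
            bad.append("obs_precision must be > 0")
        for p, label in enumerate(self.plant_labels):
            v = validate_params(LrcParameters(*self.plant_params[p]))
            bad.extend(f"plant {label}: {msg}" for msg in v)
        return bad

    def to_dict(self) -> dict[str, Any]:
        return {
            "plant_labels": list(self.plant_labels),
            "genotype_labels": list(self.genotype_labels),
            "plant_genotype": np.asarray(self.plant_genotype).tolist(),
            "plant_params": np.asarray(self.plant_params).tolist(),
            "genotype_means": np.asarray(self.genotype_means).tolist(),
            "genotype_precisions": np.asarray(self.genotype_precisions).tolist(),
            "obs_precision": float(self.obs_precision),
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "MblrcState":
        return cls(
            plant_labels=list(d["plant_labels"]),
            genotype_labels=list(d["genotype_labels"]),
            plant_genotype=np.asarray(d["plant_genotype"], dtype=int),
            plant_params=np.asarray(d["plant_params"], dtype=float),
            genotype_means=np.asarray(d["genotype_means"], dtype=float),
            genotype_precisions=np.asarray(d["genotype_precisions"], dtype=float),
            obs_precision=float(d["obs_precision"]),
        )


def parameter_names(
    plant_labels: list[str], genotype_labels: list[str]
) -> list[str]:
    """Flat parameter-name vector matching the sampler's storage layout.

    Order: plant-level curve parameters (plant-major), genotype means
    (genotype-major), the four genotype precisions, the observation precision.
    """
    names = [f"{q}[{pl}]" for pl in plant_labels for q in PARAM_NAMES]
    names += [f"mu.{q}[{g}]" for g in genotype_labels for q in PARAM_NAMES]
    names += [f"tau.{q}" for q in PARAM_NAMES]
    names += ["tau.obs"]
    return names


@dataclass
class PosteriorDraws:
    """Retained MCMC draws: ``draws[c, i, k]`` is chain ``c``, retained
    iteration ``i``, flattened-state coordinate ``k`` (see
    :func:`parameter_names`)."""

    draws: np.ndarray  # (n_chains, n_retained, K)
    names: list[str]
    plant_labels: list[str]
    genotype_labels: list[str]
    plant_genotype: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.draws = np.asarray(self.draws, dtype=float)
        if self.draws.ndim != 3:
            raise ValueError("draws must be (chains, iterations, parameters)")
        if self.draws.shape[2] != len(self.names):
            raise ValueError("parameter-name index does not match draw width")
        self._index = {n: k for k, n in enumerate(self.names)}

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_retained(self) -> int:
        return self.draws.shape[1]

    @property
    def n_pooled(self) -> int:
        return self.draws.shape[0] * self.draws.shape[1]

    def get(self, name: str) -> np.ndarray:
        """Draws of one scalar parameter, shape (chains, iterations)."""
        try:
            return self.draws[:, :, self._index[name]]
        except KeyError:
            raise KeyError(f"unknown parameter {name!r}") from None

    def pooled(self, name: str) -> np.ndarray:
        """Draws of one scalar parameter pooled over chains, 1-D."""
        return self.get(name).reshape(-1)

    def state_at(self, chain: int, iteration: int) -> MblrcState:
        """Reassemble the full latent state for one retained draw."""
        P = len(self.plant_labels)
        G = len(self.genotype_labels)
        v = self.draws[chain, iteration]
        return MblrcState(
            plant_labels=self.plant_labels,
            genotype_labels=self.genotype_labels,
            plant_genotype=self.plant_genotype,
            plant_params=v[: 4 * P].reshape(P, 4).copy(),
            genotype_means=v[4 * P : 4 * P + 4 * G].reshape(G, 4).copy(),
            genotype_precisions=v[4 * P + 4 * G : 4 * P + 4 * G + 4].copy(),
            obs_precision=float(v[-1]),
        )

    def plant_param_draws(self) -> np.ndarray:
        """All plant-level curve parameters, shape (pooled draws, P, 4)."""
        P = len(self.plant_labels)
        return self.draws[:, :, : 4 * P].reshape(self.n_pooled, P, 4)

    def obs_precision_draws(self) -> np.ndarray:
        return self.pooled("tau.obs")

    def to_dataframe(self):
        import pandas as pd

        c, i = np.meshgrid(
            np.arange(self.n_chains), np.arange(self.n_retained), indexing="ij"
        )
        df = pd.DataFrame(
            self.draws.reshape(self.n_pooled, -1), columns=self.names
        )
        df.insert(0, "iteration", i.reshape(-1))
        df.insert(0, "chain", c.reshape(-1))
        return df
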