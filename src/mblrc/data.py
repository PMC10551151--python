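"""Gas-exchange observation containers.

A :class:`Dataset` is an ordered collection of single-leaf measurements,
one growing environment per dataset; the model is fitted separately per
environment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = ["Observation", "Dataset", "ENVIRONMENTS"]

ENVIRONMENTS = ("field", "growth_chamber", "greenhouse")


@dataclass(frozen=True)
class Observation:
    """One gas-exchange measurement on one leaf.

    ``par`` is incident photosynthetically active radiation
    (µmol photon m⁻² s⁻¹) and ``a_n`` the measured net photosynthesis
    (µmol CO₂ m⁻² s⁻¹).  Air temperature (°C) and vapour pressure deficit
    (kPa) are optional covariates carried through untouched.
    """

    obs_id: int
    genotype_id: str
    plant_id: str
    environment: str
    par: float
    a_n: float
    air_temp: float | None = None
    vpd: float | None = None

    def validate(self) -> list[str]:
        bad = []
        if not self.genotype_id:
            bad.append("empty genotype_id")
        if not self.plant_id:
            bad.append("empty plant_id")
        if not np.isfinite(self.par) or self.par < 0:
            bad.append("par must be finite and >= 0")
        if not np.isfinite(self.a_n):
            bad.append("a_n must be finite")
        return bad


class Dataset:
    """Ordered gas-exchange observations for one growing environment.

    Enforces: unique ``obs_id``; every plant belongs to exactly one
    genotype; valid observations.  Plant and genotype orderings follow
    first appearance, which keeps downstream results invariant under
    pure relabelling.
    """

    def __init__(self, observations: Iterable[Observation], environment: str | None = None):
        self.observations: list[Observation] = list(observations)
        if not self.observations:
            raise ValueError("Dataset requires at least one observation")
        envs = {o.environment for o in self.observations}
        if environment is None:
            if len(envs) != 1:
                raise ValueError(
                    f"one environment per Dataset; found {sorted(envs)}"
                )
            environment = next(iter(envs))
        self.environment = environment

        ids = [o.obs_id for o in self.observations]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate obs_id in Dataset")

        self.genotype_index: dict[str, list[str]] = {}
        plant_geno: dict[str, str] = {}
        for o in self.observations:
            bad = o.validate()
            if bad:
                raise ValueError(f"obs_id {o.obs_id}: " + "; ".join(bad))
            if o.plant_id in plant_geno:
                if plant_geno[o.plant_id] != o.genotype_id:
                    raise ValueError(
                        f"plant {o.plant_id!r} mapped to two genotypes"
                    )
            else:
                plant_geno[o.plant_id] = o.genotype_id
                self.genotype_index.setdefault(o.genotype_id, []).append(o.plant_id)

        self.genotype_labels = list(self.genotype_index)
        self.plant_labels = [p for g in self.genotype_labels for p in self.genotype_index[g]]
        self._plant_pos = {p: i for i, p in enumerate(self.plant_labels)}
        self._geno_pos = {g: i for i, g in enumerate(self.genotype_labels)}
        self.plant_genotype = np.array(
            [self._geno_pos[plant_geno[p]] for p in self.plant_labels], dtype=np.int64
        )

    def __len__(self) -> int:
        return len(self.observations)

    def __iter__(self):
        return iter(self.observations)

    @property
    def n_plants(self) -> int:
        return len(self.plant_labels)

    @property
    def n_genotypes(self) -> int:
        return len(self.genotype_labels)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(par, a_n, plant index) arrays in observation order."""
        par = np.array([o.par for o in self.observations], dtype=float)
        a_n = np.array([o.a_n for o in self.observations], dtype=float)
        plant_idx = np.array(
            [self._plant_pos[o.plant_id] for o in self.observations], dtype=np.int64
        )
        return par, a_n, plant_idx

    def subset(self, plant_ids: Iterable[str]) -> "Dataset":
        keep = set(plant_ids)
        return Dataset(
            [o for o in self.observations if o.plant_id in keep],
            environment=self.environment,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "obs_id": [o.obs_id for o in self.observations],
                "genotype": [o.genotype_id for o in self.observations],
                "plant": [o.plant_id for o in self.observations],
                "environment": [o.environment for o in self.observations],
                "PARi": [o.par for o in self.observations],
                "A": [o.a_n for o in self.observations],
                "Tair": [o.air_temp for o in self.observations],
                "VPD": [o.vpd for o in self.observations],
            }
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, Dataset):
            return NotImplemented
        return (
            self.environment == other.environment
            and self.observations == other.observations
        )
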