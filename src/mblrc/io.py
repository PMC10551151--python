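"""Readers and writers for gas-exchange data, posteriors, and run metadata.

The tabular dialect follows LI-6400-style column names: ``PARi`` for
irradiance, ``A`` for net photosynthesis, ``Tair`` and ``VPD`` for the
optional covariates, plus ``genotype``, ``plant``, ``environment`` and
``obs_id``.  Common aliases (``PAR``, ``Photo``, ``A_N``, ...) are accepted
on read.  All formats are plain text (CSV / JSON).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .data import Dataset, Observation
from .state import MblrcState, PosteriorDraws

__all__ = [
    "read_gas_exchange_csv",
    "write_dataset",
    "write_truth",
    "read_truth",
    "write_posterior",
    "read_posterior",
]

log = logging.getLogger("mblrc")

_PAR_ALIASES = ("PARi", "PAR", "par", "Qin")
_A_ALIASES = ("A", "Photo", "A_N", "a_n", "An")
_TAIR_ALIASES = ("Tair", "air_temp", "Tleaf_air")
_VPD_ALIASES = ("VPD", "vpd", "VpdL")


def _pick(df: pd.DataFrame, aliases, required_name=None):
    for a in aliases:
        if a in df.columns:
            return a
    if required_name is not None:
        raise ValueError(
            f"missing mandatory column {required_name!r} "
            f"(accepted names: {', '.join(aliases)})"
        )
    return None


def read_gas_exchange_csv(path) -> Dataset:
    """Parse a gas-exchange CSV into a validated :class:`Dataset`.

    Rows violating the observation invariants (negative PAR, non-finite
    A_N, empty labels) are rejected individually with a logged warning
    naming the file line; a missing mandatory column raises naming it.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("genotype", "plant", "environment"):
        if col not in df.columns:
            raise ValueError(f"missing mandatory column {col!r}")
    par_col = _pick(df, _PAR_ALIASES, "PARi")
    a_col = _pick(df, _A_ALIASES, "A")
    tair_col = _pick(df, _TAIR_ALIASES)
    vpd_col = _pick(df, _VPD_ALIASES)

    observations = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        obs_id = int(d["obs_id"]) if "obs_id" in d and pd.notna(d["obs_id"]) else row_no - 2
        try:
            par = float(d[par_col])
            a_n = float(d[a_col])
        except (TypeError, ValueError):
            log.warning("%s line %d: non-numeric PAR/A, row rejected", path.name, row_no)
            continue
        obs = Observation(
            obs_id=obs_id,
            genotype_id=str(d["genotype"]),
            plant_id=str(d["plant"]),
            environment=str(d["environment"]),
            par=par,
            a_n=a_n,
            air_temp=_opt_float(d.get(tair_col)) if tair_col else None,
            vpd=_opt_float(d.get(vpd_col)) if vpd_col else None,
        )
        bad = obs.validate()
        if bad:
            log.warning("%s line %d: %s; row rejected", path.name, row_no, "; ".join(bad))
            continue
        observations.append(obs)
    if not observations:
        raise ValueError(f"{path}: no valid observations")
    return Dataset(observations)


def _opt_float(v):
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return None
    try:
        f = float(v)
    except (TypeError, ValueError):
        return None
    return None if np.isnan(f) else f


def write_dataset(dataset: Dataset, path) -> Path:
    """Write a Dataset as CSV (LI-6400-style column names); inverse of
    :func:`read_gas_exchange_csv`."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    dataset.to_frame().to_csv(path, index=False)
    return path


def write_truth(state: MblrcState, path) -> Path:
    """Ground-truth sidecar for a simulated dataset (JSON)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(state.to_dict(), indent=1))
    return path


def read_truth(path) -> MblrcState:
    return MblrcState.from_dict(json.loads(Path(path).read_text()))


def write_posterior(draws: PosteriorDraws, csv_path, meta_path=None) -> Path:
    """Persist retained draws as CSV (chain, iteration, one column per
    parameter) plus a JSON metadata sidecar (seed, protocol, labels)."""
    csv_path = Path(csv_path)
    csv_path.parent.mkdir(parents=True, exist_ok=True)
    draws.to_dataframe().to_csv(csv_path, index=False)
    meta_path = Path(meta_path) if meta_path else csv_path.with_suffix(".meta.json")
    meta = {
        "meta": _jsonable(draws.meta),
        "plant_labels": draws.plant_labels,
        "genotype_labels": draws.genotype_labels,
        "plant_genotype": np.asarray(draws.plant_genotype).tolist(),
    }
    meta_path.write_text(json.dumps(meta, indent=1))
    return csv_path


def read_posterior(csv_path, meta_path=None) -> PosteriorDraws:
    csv_path = Path(csv_path)
    meta_path = Path(meta_path) if meta_path else csv_path.with_suffix(".meta.json")
    df = pd.read_csv(csv_path)
    meta = json.loads(meta_path.read_text())
    chains = np.sort(df["chain"].unique())
    names = [c for c in df.columns if c not in ("chain", "iteration")]
    per_chain = [
        df[df["chain"] == c].sort_values("iteration")[names].to_numpy()
        for c in chains
    ]
    return PosteriorDraws(
        draws=np.stack(per_chain),
        names=names,
        plant_labels=meta["plant_labels"],
        genotype_labels=meta["genotype_labels"],
        plant_genotype=np.asarray(meta["plant_genotype"], dtype=np.int64),
        meta=meta["meta"],
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
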