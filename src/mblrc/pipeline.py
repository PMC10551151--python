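"""End-to-end multi-environment workflow.

For each growing environment: load (or simulate) the dataset, fit the
multilevel model, check convergence with the PSRF diagnostic, optionally
thin further, compute posterior predictive distributions and the
observed-vs-modelled goodness of fit, and persist every artifact.  Then
compare genotype-level parameter posteriors across environments (and across
genotypes within each environment) with the subsample ANOVA + Tukey
procedure.  All randomness derives from one global seed; a manifest lists
every output file with a checksum.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from . import __version__
from .compare import compare_genotypes, compare_parameters
from .data import Dataset
from .diagnostics import (
    PSRF_THRESHOLD,
    bgr_diagnostic,
    goodness_of_fit,
    posterior_predictive,
    thin,
)
from .inference import FitConfig, PriorSpec, fit_mblrc
from .io import read_gas_exchange_csv, write_dataset, write_posterior, write_truth
from .model import PARAM_NAMES
from .simulate import SimulationConfig, simulate_dataset

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "ConvergenceError"]

log = logging.getLogger("mblrc")


class ConvergenceError(RuntimeError):
    """Raised when a fit fails the PSRF convergence check."""


@dataclass
class RunConfig:
    """One pipeline run: per-environment inputs, protocol, outputs.

    Exactly one of ``input_csvs`` / ``simulations`` must describe each
    environment: ``input_csvs`` maps environment label → CSV path,
    ``simulations`` maps environment label → :class:`SimulationConfig`.
    """

    out_dir: Path
    input_csvs: dict[str, Any] = field(default_factory=dict)
    simulations: dict[str, SimulationConfig] = field(default_factory=dict)
    fit: FitConfig = field(default_factory=FitConfig)
    priors: PriorSpec = field(default_factory=PriorSpec)
    compare_params: tuple[str, ...] = PARAM_NAMES
    subsample_n: int = 50
    alpha: float = 0.05
    extra_thin: int = 1
    psrf_threshold: float = PSRF_THRESHOLD
    on_unconverged: str = "raise"  # or "warn"
    seed: int = 0

    def validate(self) -> list[str]:
        bad = []
        overlap = set(self.input_csvs) & set(self.simulations)
        if overlap:
            bad.append(f"environments defined both as input and simulation: {sorted(overlap)}")
        if not self.input_csvs and not self.simulations:
            bad.append("no inputs: provide input_csvs or simulations")
        if self.on_unconverged not in ("raise", "warn"):
            bad.append("on_unconverged must be 'raise' or 'warn'")
        return bad


@dataclass
class PipelineResult:
    out_dir: Path
    fits: dict
    reports: dict
    gof: dict
    comparisons: list
    manifest_path: Path


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full per-environment fit / evaluate / compare workflow.

    Deterministic given ``config.seed``; raises with a stage-tagged message
    on any failure.  Returns in-memory results alongside the on-disk
    artifacts listed in the manifest.
    """
    bad = config.validate()
    if bad:
        raise ValueError("[config] " + "; ".join(bad))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    envs = list(config.input_csvs) + list(config.simulations)
    ss = np.random.SeedSequence(config.seed)
    env_seeds = {e: int(s.generate_state(1)[0] % (2**31 - 1)) for e, s in
                 zip(envs, ss.spawn(len(envs)))}
    compare_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31 - 1))

    datasets: dict[str, Dataset] = {}
    fits, reports, gofs = {}, {}, {}
    for env in envs:
        log.info("[%s] loading data", env)
        try:
            if env in config.input_csvs:
                data = read_gas_exchange_csv(config.input_csvs[env])
            else:
                sim = config.simulations[env].with_seed(env_seeds[env])
                data, truth = simulate_dataset(sim)
                written.append(write_dataset(data, out / f"{env}_data.csv"))
                written.append(write_truth(truth, out / f"{env}_truth.json"))
        except Exception as e:
            raise RuntimeError(f"[load:{env}] {e}") from e
        datasets[env] = data

        log.info("[%s] fitting (%d obs, %d plants)", env, len(data), data.n_plants)
        try:
            draws = fit_mblrc(data, config.priors, config.fit.with_seed(env_seeds[env]))
        except Exception as e:
            raise RuntimeError(f"[fit:{env}] {e}") from e

        report = bgr_diagnostic(draws, threshold=config.psrf_threshold)
        reports[env] = report
        if not report.converged:
            name, worst = report.worst()
            msg = (f"[convergence:{env}] PSRF {worst:.3f} for {name} exceeds "
                   f"{config.psrf_threshold}")
            if config.on_unconverged == "raise":
                raise ConvergenceError(msg)
            log.warning("%s (continuing)", msg)

        if config.extra_thin > 1:
            draws = thin(draws, config.extra_thin)
        fits[env] = draws
        written.append(write_posterior(draws, out / f"{env}_posterior.csv"))
        written.append(out / f"{env}_posterior.meta.json")

        ppc_rng = np.random.default_rng(env_seeds[env] + 1)
        ppc = posterior_predictive(draws, data, rng=ppc_rng)
        _, a_n, _ = data.arrays()
        gof = goodness_of_fit(a_n, ppc)
        gofs[env] = gof
        pd_rows = {"obs_id": ppc.obs_id, "mean": ppc.mean,
                   "lo2.5": ppc.lower, "hi97.5": ppc.upper}
        import pandas as pd

        p = out / f"{env}_posterior_predictive.csv"
        pd.DataFrame(pd_rows).to_csv(p, index=False)
        written.append(p)
        psrf_path = out / f"{env}_convergence.csv"
        pd.DataFrame(
            {"parameter": list(report.psrf), "psrf": list(report.psrf.values())}
        ).to_csv(psrf_path, index=False)
        written.append(psrf_path)
        log.info("[%s] R2=%.4f slope=%.3f", env, gof.r2, gof.slope)

    comparisons = []
    rng = np.random.default_rng(compare_seed)
    for q in config.compare_params:
        # across environments: pool each fit's genotype-mean posterior per genotype
        if len(fits) >= 2:
            shared = set.intersection(*(set(f.genotype_labels) for f in fits.values()))
            for g in sorted(shared):
                comparisons.append(
                    compare_parameters(
                        fits, f"mu.{q}[{g}]", factor="environment",
                        n=config.subsample_n, alpha=config.alpha, rng=rng,
                    )
                )
        for env, draws in fits.items():
            if len(draws.genotype_labels) >= 2:
                res = compare_genotypes(
                    draws, q, n=config.subsample_n, alpha=config.alpha, rng=rng
                )
                res.meta["environment"] = env
                comparisons.append(res)

    if comparisons:
        import pandas as pd

        frames = []
        for res in comparisons:
            f = res.to_frame()
            f.insert(0, "environment", res.meta.get("environment", "all"))
            frames.append(f)
        cmp_path = out / "comparisons.csv"
        pd.concat(frames, ignore_index=True).to_csv(cmp_path, index=False)
        written.append(cmp_path)

    manifest = {
        "mblrc_version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "environment_seeds": env_seeds,
        "fit": {"n_chains": config.fit.n_chains, "n_adapt": config.fit.n_adapt,
                "n_iter": config.fit.n_iter, "thin": config.fit.thin},
        "goodness_of_fit": {e: {"r2": g.r2, "slope": g.slope,
                                "intercept": g.intercept, "n": g.n}
                            for e, g in gofs.items()},
        "files": {str(p.relative_to(out)): _sha256(p) for p in written if p.exists()},
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return PipelineResult(
        out_dir=out, fits=fits, reports=reports, gof=gofs,
        comparisons=comparisons, manifest_path=manifest_path,
    )
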