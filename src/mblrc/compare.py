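"""Cross-genotype / method / environment comparison of parameter posteriors.

The procedure treats a small fixed-size random subsample of posterior draws
(default 50 per group) as data points for a one-way ANOVA followed by Tukey
HSD pairwise tests.  The subsample size is capped deliberately: p-values on
tens of thousands of posterior draws would flag trivial differences.  Note
the interpretation caveat carried in the output metadata: posterior draws
are not independent observations, so these frequentist p-values are a
heuristic screening device, not a calibrated error rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Any, Mapping, Sequence

import numpy as np
from scipy import stats

from .state import PosteriorDraws

__all__ = [
    "AnovaResult",
    "PairwiseComparison",
    "ComparisonResult",
    "subsample_posterior",
    "anova_oneway",
    "tukey_hsd",
    "compare_parameters",
    "compare_genotypes",
]

_CAVEAT = (
    "frequentist tests applied to posterior draws treated as data points; "
    "p-values are a screening heuristic, not calibrated error rates"
)


def subsample_posterior(
    draws: PosteriorDraws,
    parameter: str,
    n: int = 50,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """n draws of one parameter, uniform without replacement over pooled chains."""
    if rng is None:
        rng = np.random.default_rng(0)
    pooled = draws.pooled(parameter)
    if n > pooled.size:
        raise ValueError(f"requested {n} draws but only {pooled.size} available")
    return rng.choice(pooled, size=n, replace=False)


@dataclass
class AnovaResult:
    f_statistic: float
    p_value: float
    df_between: int
    df_within: int
    degenerate: bool = False


def _group_arrays(groups: Sequence) -> list[np.ndarray]:
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 2 for g in gs):
        raise ValueError("every group needs at least 2 values")
    return gs


def anova_oneway(groups: Sequence) -> AnovaResult:
    """Standard one-way ANOVA; degenerate zero-within-variance cases are
    reported as F=inf, p=0 (separated) or F=0, p=1 (identical)."""
    gs = _group_arrays(groups)
    k = len(gs)
    n_total = sum(len(g) for g in gs)
    grand = np.concatenate(gs).mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in gs)
    ssw = sum(np.sum((g - g.mean()) ** 2) for g in gs)
    df_b, df_w = k - 1, n_total - k
    if ssw == 0:
        if ssb == 0:
            return AnovaResult(0.0, 1.0, df_b, df_w, degenerate=True)
        return AnovaResult(np.inf, 0.0, df_b, df_w, degenerate=True)
    f, p = stats.f_oneway(*gs)
    return AnovaResult(float(f), float(p), df_b, df_w)


@dataclass
class PairwiseComparison:
    group_a: str
    group_b: str
    mean_difference: float  # mean(a) − mean(b)
    p_adjusted: float
    significant: bool


def tukey_hsd(
    groups: Sequence,
    alpha: float = 0.05,
    labels: Sequence[str] | None = None,
) -> list[PairwiseComparison]:
    """All pairwise mean differences with studentized-range (Tukey HSD)
    adjusted p-values; C(g, 2) rows for g groups."""
    gs = _group_arrays(groups)
    if labels is None:
        labels = [f"group{i}" for i in range(len(gs))]
    if len(labels) != len(gs):
        raise ValueError("labels length must match number of groups")

    ssw = sum(np.sum((g - g.mean()) ** 2) for g in gs)
    rows: list[PairwiseComparison] = []
    if ssw == 0:
        for i, j in combinations(range(len(gs)), 2):
            diff = float(gs[i].mean() - gs[j].mean())
            p = 1.0 if diff == 0 else 0.0
            rows.append(PairwiseComparison(labels[i], labels[j], diff, p, p < alpha))
        return rows

    res = stats.tukey_hsd(*gs)
    for i, j in combinations(range(len(gs)), 2):
        diff = float(gs[i].mean() - gs[j].mean())
        p = float(res.pvalue[i, j])
        rows.append(PairwiseComparison(labels[i], labels[j], diff, p, p < alpha))
    return rows


@dataclass
class ComparisonResult:
    parameter: str
    factor: str
    groups: list[str]
    subsample_size: int
    anova: AnovaResult
    tukey: list[PairwiseComparison]
    alpha: float
    meta: dict[str, Any] = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return self.anova.p_value < self.alpha

    def significant_pairs(self) -> list[PairwiseComparison]:
        return [r for r in self.tukey if r.significant]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "parameter": self.parameter,
                "factor": self.factor,
                "group_a": [r.group_a for r in self.tukey],
                "group_b": [r.group_b for r in self.tukey],
                "mean_difference": [r.mean_difference for r in self.tukey],
                "p_adjusted": [r.p_adjusted for r in self.tukey],
                "significant": [r.significant for r in self.tukey],
            }
        )


def compare_parameters(
    fits: Mapping[str, PosteriorDraws],
    parameter: str,
    factor: str = "environment",
    n: int = 50,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
) -> ComparisonResult:
    """Subsample each fit's posterior for one parameter, then ANOVA + Tukey.

    ``fits`` maps group labels (genotypes, methods or environments) to
    fitted posteriors that all contain ``parameter``.  Each group gets an
    independent subsample stream derived from ``rng``.
    """
    if len(fits) < 2:
        raise ValueError("need at least 2 fits to compare")
    if rng is None:
        rng = np.random.default_rng(0)
    labels = list(fits)
    groups = [
        subsample_posterior(fits[lbl], parameter, n=n, rng=rng) for lbl in labels
    ]
    return ComparisonResult(
        parameter=parameter,
        factor=factor,
        groups=labels,
        subsample_size=n,
        anova=anova_oneway(groups),
        tukey=tukey_hsd(groups, alpha=alpha, labels=labels),
        alpha=alpha,
        meta={"note": _CAVEAT},
    )


def compare_genotypes(
    draws: PosteriorDraws,
    parameter: str,
    n: int = 50,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
) -> ComparisonResult:
    """Within one fit, compare a genotype-level mean across genotypes.

    ``parameter`` is the curve-parameter name (e.g. ``"a_max"``); the
    groups are the posterior subsamples of ``mu.<parameter>[<genotype>]``
    for every genotype in the fit.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if len(draws.genotype_labels) < 2:
        raise ValueError("need at least 2 genotypes to compare")
    labels = list(draws.genotype_labels)
    groups = [
        subsample_posterior(draws, f"mu.{parameter}[{g}]", n=n, rng=rng)
        for g in labels
    ]
    return ComparisonResult(
        parameter=parameter,
        factor="genotype",
        groups=labels,
        subsample_size=n,
        anova=anova_oneway(groups),
        tukey=tukey_hsd(groups, alpha=alpha, labels=labels),
        alpha=alpha,
        meta={"note": _CAVEAT},
    )
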