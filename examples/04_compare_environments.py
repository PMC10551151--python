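"""Compare parameter posteriors across growing environments.

Simulates growth-chamber and greenhouse ladder studies in which the
greenhouse truly has a lower light-saturated capacity (a_max) but the same
quantum yield (alpha), fits both, and runs the subsample ANOVA + Tukey HSD
procedure: 50 random posterior draws per group keep the tests from flagging
trivial differences.
"""

import numpy as np

from mblrc import (
    CHAMBER_LADDER,
    FitConfig,
    GREENHOUSE_LADDER,
    PriorSpec,
    SequentialDesign,
    SimulationConfig,
    compare_parameters,
    fit_mblrc,
    simulate_dataset,
)

ZERO = {"a_max": 0.0, "alpha": 0.0, "r_d": 0.0, "theta": 0.0}
fit_cfg = FitConfig(n_chains=2, n_adapt=1000, n_iter=800, thin=2, seed=0)

chamber, _ = simulate_dataset(SimulationConfig(
    n_genotypes=2, n_replicates=3, design=SequentialDesign(CHAMBER_LADDER),
    environment="growth_chamber", hyper_sds=ZERO, seed=1))
greenhouse, _ = simulate_dataset(SimulationConfig(
    n_genotypes=2, n_replicates=3, design=SequentialDesign(GREENHOUSE_LADDER),
    environment="greenhouse", hyper_sds=ZERO, seed=2,
    hyper_means={"a_max": 15.0, "alpha": 0.05, "r_d": 1.5, "theta": 0.8}))

fits = {
    "growth_chamber": fit_mblrc(chamber, PriorSpec(), fit_cfg),
    "greenhouse": fit_mblrc(greenhouse, PriorSpec(), fit_cfg.with_seed(5)),
}

for q in ("a_max", "alpha"):
    res = compare_parameters(fits, f"mu.{q}[G1]", factor="environment",
                             rng=np.random.default_rng(3))
    row = res.tukey[0]
    print(f"{q}: ANOVA F={res.anova.f_statistic:9.2f} p={res.anova.p_value:.3g}; "
          f"chamber-greenhouse diff={row.mean_difference:+.3f} "
          f"({'significant' if row.significant else 'not significant'})")

print("\nThe truly lowered greenhouse a_max is flagged; alpha, identical in")
print("both environments, is not — the pattern this comparison is built to find.")
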