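"""Posterior-subsample ANOVA + Tukey comparison procedure."""

import numpy as np
import pytest

from mblrc.compare import (
    anova_oneway,
    compare_genotypes,
    compare_parameters,
    subsample_posterior,
    tukey_hsd,
)
from conftest import scalar_draws


def normal_posterior(mean, sd=1.0, n=2000, seed=0, name="mu.a_max[G1]"):
    rng = np.random.default_rng(seed)
    return scalar_draws(rng.normal(mean, sd, size=(2, n)), name=name)


class TestSubsample:
    def test_full_subsample_is_a_permutation(self):
        d = normal_posterior(0.0, n=100)
        out = subsample_posterior(d, "mu.a_max[G1]", n=200, rng=np.random.default_rng(1))
        np.testing.assert_array_equal(np.sort(out), np.sort(d.pooled("mu.a_max[G1]")))

    def test_reproducible_given_seed(self):
        d = normal_posterior(0.0)
        a = subsample_posterior(d, "mu.a_max[G1]", rng=np.random.default_rng(3))
        b = subsample_posterior(d, "mu.a_max[G1]", rng=np.random.default_rng(3))
        np.testing.assert_array_equal(a, b)

    def test_oversized_request_raises(self):
        d = normal_posterior(0.0, n=10)
        with pytest.raises(ValueError, match="available"):
            subsample_posterior(d, "mu.a_max[G1]", n=100)

    def test_subsample_mean_tracks_posterior_mean(self):
        # sampling-distribution check: the 3-sigma CLT bound on a mean of 50
        # draws should hold in almost every replication
        d = normal_posterior(10.0, sd=2.0, n=5000, seed=5)
        full_mean = d.pooled("mu.a_max[G1]").mean()
        full_sd = d.pooled("mu.a_max[G1]").std()
        bound = 3 * full_sd / np.sqrt(50)
        misses = sum(
            abs(subsample_posterior(d, "mu.a_max[G1]", n=50,
                                    rng=np.random.default_rng(100 + r)).mean()
                - full_mean) > bound
            for r in range(400)
        )
        assert misses / 400 < 0.05


class TestAnova:
    def test_identical_groups(self):
        res = anova_oneway([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert res.f_statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_f(self):
        # SSB = 13.5, SSW = 4 with df (1, 4): F = 13.5
        res = anova_oneway([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
        assert res.f_statistic == pytest.approx(13.5)
        assert (res.df_between, res.df_within) == (1, 4)

    def test_translation_invariance(self):
        rng = np.random.default_rng(0)
        groups = [rng.normal(size=20), rng.normal(1.0, 1.0, size=20)]
        f0 = anova_oneway(groups).f_statistic
        f1 = anova_oneway([g + 100.0 for g in groups]).f_statistic
        assert f0 == pytest.approx(f1, rel=1e-10)

    def test_degenerate_zero_within_variance(self):
        res = anova_oneway([[1.0, 1.0], [2.0, 2.0]])
        assert np.isinf(res.f_statistic) and res.p_value == 0.0
        assert res.degenerate

    def test_needs_two_groups_of_two(self):
        with pytest.raises(ValueError):
            anova_oneway([[1.0, 2.0]])
        with pytest.raises(ValueError):
            anova_oneway([[1.0, 2.0], [1.0]])


class TestTukey:
    def test_identical_groups_nothing_significant(self):
        rows = tukey_hsd([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert all(not r.significant for r in rows)

    def test_pair_count_is_choose_two(self):
        rng = np.random.default_rng(1)
        rows = tukey_hsd([rng.normal(size=10) for _ in range(3)])
        assert len(rows) == 3  # C(3,2)

    def test_extreme_separation_detected(self):
        rng = np.random.default_rng(2)
        rows = tukey_hsd([rng.normal(0, 1, 50), rng.normal(100, 1, 50)])
        assert rows[0].significant
        assert rows[0].mean_difference == pytest.approx(-100.0, abs=1.0)

    def test_adjusted_p_matches_statsmodels(self):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        rng = np.random.default_rng(3)
        groups = [rng.normal(m, 1.0, 30) for m in (0.0, 0.5, 1.5)]
        ours = tukey_hsd(groups)
        values = np.concatenate(groups)
        labels = np.repeat(["g0", "g1", "g2"], 30)
        sm = pairwise_tukeyhsd(values, labels)
        np.testing.assert_allclose(
            [r.p_adjusted for r in ours], sm.pvalues, atol=2e-3
        )


class TestCompareParameters:
    def test_identical_posteriors_not_significant(self):
        d = normal_posterior(5.0, seed=7)
        res = compare_parameters(
            {"field": d, "greenhouse": d}, "mu.a_max[G1]",
            rng=np.random.default_rng(0),
        )
        assert not res.significant

    def test_known_shift_flags_a_max_but_not_alpha(self):
        f_amax = normal_posterior(25.0, sd=1.5, seed=1)
        g_amax = normal_posterior(15.0, sd=1.5, seed=2)  # −10 shift
        f_alpha = normal_posterior(0.05, sd=0.005, seed=3, name="mu.alpha[G1]")
        g_alpha = normal_posterior(0.05, sd=0.005, seed=4, name="mu.alpha[G1]")
        res_amax = compare_parameters(
            {"field": f_amax, "greenhouse": g_amax}, "mu.a_max[G1]",
            rng=np.random.default_rng(5),
        )
        res_alpha = compare_parameters(
            {"field": f_alpha, "greenhouse": g_alpha}, "mu.alpha[G1]",
            rng=np.random.default_rng(6),
        )
        assert res_amax.significant
        assert res_amax.tukey[0].mean_difference == pytest.approx(10.0, abs=1.5)
        assert not res_alpha.significant

    def test_deterministic_given_seed(self):
        d1 = normal_posterior(5.0, seed=8)
        d2 = normal_posterior(5.2, seed=9)
        r1 = compare_parameters({"a": d1, "b": d2}, "mu.a_max[G1]",
                                rng=np.random.default_rng(11))
        r2 = compare_parameters({"a": d1, "b": d2}, "mu.a_max[G1]",
                                rng=np.random.default_rng(11))
        assert r1.anova.f_statistic == r2.anova.f_statistic
        assert [p.p_adjusted for p in r1.tukey] == [p.p_adjusted for p in r2.tukey]

    def test_needs_two_fits(self):
        with pytest.raises(ValueError):
            compare_parameters({"only": normal_posterior(0.0)}, "mu.a_max[G1]")


class TestCompareGenotypes:
    def test_tukey_rows_and_groups(self, small_fit):
        res = compare_genotypes(small_fit, "a_max", rng=np.random.default_rng(0))
        assert res.groups == small_fit.genotype_labels
        assert len(res.tukey) == 3  # C(3,2)
        assert res.subsample_size == 50
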