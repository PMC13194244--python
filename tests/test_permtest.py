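"""DKW sizing, multivariate hypergeometric resampling, p-values, corrections."""

import math

import numpy as np
import pytest
from scipy import stats

from phylohaar import (
    AbundanceSample,
    EnsembleConfig,
    TestConfig as PermConfig,
    adjust_pvalues,
    dkw_sample_size,
    mv_hypergeometric_sample,
    permutation_pvalues,
    sample_tree,
)


class TestDkw:
    def test_reference_scale_value(self):
        assert dkw_sample_size(1e-4, 0.01) == 264_915_869

    def test_epsilon_scaling(self):
        n1 = dkw_sample_size(0.02, 0.05)
        n2 = dkw_sample_size(0.01, 0.05)
        assert n2 in (4 * n1 - 3, 4 * n1 - 2, 4 * n1 - 1, 4 * n1)  # up to ceiling

    def test_closed_form_small_case(self):
        # ln(2/delta) = 2 exactly at delta = 2/e^2, so N = ceil(2 / (2 * 0.25))
        assert dkw_sample_size(0.5, 2 / math.e**2) == 4

    @pytest.mark.parametrize("eps,delta", [(0, 0.1), (-1, 0.1), (0.1, 0), (0.1, 1)])
    def test_invalid_ranges(self, eps, delta):
        with pytest.raises(ValueError):
            dkw_sample_size(eps, delta)


class TestMvHypergeometric:
    def test_draw_everything(self):
        rng = np.random.default_rng(0)
        s, c = mv_hypergeometric_sample([3, 2], 5, rng)
        assert list(s) == [3, 2] and list(c) == [0, 0]

    def test_zero_pool_category(self):
        rng = np.random.default_rng(0)
        s, _ = mv_hypergeometric_sample([5, 0, 5], 6, rng, size=100)
        assert np.all(s[:, 1] == 0)

    def test_exact_tail_probability(self):
        # pool (2,2), draw 2: P(first coordinate = 0) = C(2,0)C(2,2)/C(4,2) = 1/6
        rng = np.random.default_rng(1)
        s, _ = mv_hypergeometric_sample([2, 2], 2, rng, size=100_000)
        freq = np.bincount(s[:, 0], minlength=3) / 100_000
        expected = np.array([1 / 6, 4 / 6, 1 / 6])
        assert stats.chisquare(freq * 100_000, expected * 100_000).pvalue > 1e-3

    def test_marginal_means(self):
        rng = np.random.default_rng(2)
        pool = np.array([10, 30, 60])
        s, _ = mv_hypergeometric_sample(pool, 25, rng, size=50_000)
        expected = 25 * pool / pool.sum()
        assert np.allclose(s.mean(axis=0), expected, atol=0.15)

    def test_pool_conservation(self):
        rng = np.random.default_rng(3)
        pool = np.array([7, 5, 11, 2])
        s, c = mv_hypergeometric_sample(pool, 12, rng, size=200)
        assert np.all(s + c == pool)

    def test_out_of_range_draw(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            mv_hypergeometric_sample([1, 1], 3, rng)


class TestAdjust:
    def test_bonferroni(self):
        assert adjust_pvalues([0.001], "bonferroni", m=12)[0] == pytest.approx(0.012)
        assert adjust_pvalues([0.2], "bonferroni", m=12)[0] == pytest.approx(1.0)

    def test_bh_step_up_hand_example(self):
        # thresholds k*alpha/m = .0167, .0333, .05: all three rejected at 0.05;
        # adjusted values are max over the step-up tail of p*m/k
        adj = adjust_pvalues([0.01, 0.02, 0.04], "benjamini_hochberg")
        assert np.allclose(adj, [0.03, 0.03, 0.04])
        assert np.all(adj <= 0.05)

    def test_single_hypothesis_identity(self):
        for method in ("bonferroni", "benjamini_hochberg"):
            assert adjust_pvalues([0.03], method)[0] == pytest.approx(0.03)

    def test_adjusted_not_below_raw(self):
        rng = np.random.default_rng(0)
        p = rng.random(20)
        for method in ("bonferroni", "benjamini_hochberg"):
            assert np.all(adjust_pvalues(p, method) >= p - 1e-15)

    def test_invalid_pvalues(self):
        with pytest.raises(ValueError):
            adjust_pvalues([1.2], "bonferroni")


@pytest.fixture(scope="module")
def small_setup():
    t = sample_tree(EnsembleConfig(n=12, seed=5))
    rng = np.random.default_rng(6)
    comp = rng.dirichlet(np.ones(12))
    a = AbundanceSample(rng.multinomial(800, comp))
    b = AbundanceSample(rng.multinomial(800, comp))
    return t, a, b


class TestPermutationPvalues:
    def test_identical_samples_give_p_one(self, small_setup):
        t, a, _ = small_setup
        cfg = PermConfig(N=300, seed=0)
        df = permutation_pvalues(t, a, a, cfg)
        # observed statistics are 0; any positive resampled statistic ties or
        # exceeds, so add-one p-values are 1 wherever resampling moves at all
        positive = df[df.exceedances == 300]
        assert np.allclose(positive.p_raw, 1.0)
        assert np.all(df.component == 0.0)

    def test_degenerate_pool_single_leaf(self):
        t = sample_tree(EnsembleConfig(n=6, seed=1))
        a = AbundanceSample([50, 0, 0, 0, 0, 0])
        b = AbundanceSample([70, 0, 0, 0, 0, 0])
        df = permutation_pvalues(t, a, b, PermConfig(N=100, seed=0))
        assert np.allclose(df.p_raw, 1.0)  # every resample reproduces a' exactly
        strict = permutation_pvalues(t, a, b, PermConfig(N=100, seed=0, comparison="strict"))
        assert strict.floor_flag.all()  # the tied-at-zero hazard, flagged

    def test_reproducible_with_seed(self, small_setup):
        t, a, b = small_setup
        cfg = PermConfig(N=400, seed=123)
        df1 = permutation_pvalues(t, a, b, cfg)
        df2 = permutation_pvalues(t, a, b, cfg)
        assert df1.equals(df2)

    def test_strict_zero_exceedance_bonferroni_floor(self):
        """With no exceedances, strict mode reports 1/N and the Bonferroni
        bound m/N (the discovery-probability style of reporting)."""
        t = sample_tree(EnsembleConfig(n=8, seed=2))
        rng = np.random.default_rng(7)
        a = AbundanceSample(rng.multinomial(2000, np.ones(8) / 8))
        # gross difference: all of b on one leaf -> observed stat far in the tail
        b = AbundanceSample(np.eye(8, dtype=int)[0] * 2000)
        cfg = PermConfig(N=200, seed=1, comparison="strict", correction="bonferroni", bonferroni_m=12)
        df = permutation_pvalues(t, a, b, cfg)
        flagged = df[df.floor_flag]
        assert len(flagged) > 0
        assert np.allclose(flagged.p_raw, 1 / 200)
        assert np.allclose(flagged.p_adjusted, 12 / 200)

    def test_node_subset_and_budget(self, small_setup):
        t, a, b = small_setup
        cfg = PermConfig(N=100, seed=0)
        some = list(t.interior_nodes[:3])
        df = permutation_pvalues(t, a, b, cfg, nodes=some)
        assert set(df.node) == set(some)
        tiny = PermConfig(N=100, seed=0, max_work=10)
        with pytest.raises(ValueError, match="max_work"):
            permutation_pvalues(t, a, b, tiny)

    def test_super_uniform_under_null(self, small_setup):
        """Empirical P(p <= u) stays near-or-below u at a few thresholds."""
        t, a, b = small_setup
        from phylohaar.haar import transform

        st = transform(t)
        rng = np.random.default_rng(11)
        pvals = []
        for _ in range(150):
            comp = rng.dirichlet(np.ones(12))
            aa = AbundanceSample(rng.multinomial(800, comp))
            bb = AbundanceSample(rng.multinomial(800, comp))
            cfg = PermConfig(N=300, seed=int(rng.integers(2**31)), correction="none")
            df = permutation_pvalues(t, aa, bb, cfg, basis=st.basis, lambdas=st.diagonal)
            pvals.append(df[df.wavelet > 0].p_raw.to_numpy())
        pvals = np.concatenate(pvals)
        for u in (0.01, 0.05, 0.1):
            emp = (pvals <= u).mean()
            se = np.sqrt(u * (1 - u) / len(pvals))
            assert emp <= u + 3 * se
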