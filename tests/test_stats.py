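"""Permutation machinery, McNemar, TOST, t-test, BH-FDR."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from depictrsa import (
    PairedOutcomeTable,
    across_layer_variation_test,
    bh_fdr,
    independent_t_test,
    mantel_test,
    mcnemar_test,
    one_sided_p,
    rdm_correlation_difference_test,
    sign_permutation_test,
    tost_equivalence,
)
from depictrsa.rdm import compute_rdm
from depictrsa.stats import mantel_exact


def random_rdm(n, seed):
    rng = np.random.default_rng(seed)
    return compute_rdm(rng.standard_normal((n, n + 5)))


class TestOneSidedP:
    def test_add_one_minimum(self):
        null = np.arange(1000) / 1000.0
        assert one_sided_p(null, 2.0) == pytest.approx(1.0 / 1001.0)

    def test_observed_below_all(self):
        assert one_sided_p([1.0, 2.0, 3.0], -1.0) == 1.0

    def test_direct_count(self):
        assert one_sided_p([1, 2, 3, 4], 2.5) == pytest.approx(0.6)

    def test_empty_null_rejected(self):
        with pytest.raises(ValueError):
            one_sided_p([], 0.0)

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.floats(-5, 5), min_size=1, max_size=50), st.floats(-5, 5))
    def test_valid_range(self, null, observed):
        p = one_sided_p(null, observed)
        assert 0 < p <= 1


class TestMantel:
    def test_self_correlation_minimal_p(self):
        rdm = random_rdm(8, 0)
        res = mantel_test(rdm, rdm, n_perm=99, seed=1)
        assert res.observed == pytest.approx(1.0)
        assert res.p == pytest.approx(1.0 / 100.0)

    def test_too_few_objects(self):
        rdm = random_rdm(3, 1)
        with pytest.raises(ValueError):
            mantel_test(rdm, rdm)

    def test_reproducible_given_seed(self):
        a, b = random_rdm(7, 2), random_rdm(7, 3)
        r1 = mantel_test(a, b, n_perm=50, seed=9)
        r2 = mantel_test(a, b, n_perm=50, seed=9)
        np.testing.assert_array_equal(r1.null_sample, r2.null_sample)
        assert r1.n_perm == 50 and r1.seed == 9

    def test_monte_carlo_matches_exhaustive_small_n(self):
        for seed in range(5):
            a, b = random_rdm(4, 10 + seed), random_rdm(4, 100 + seed)
            obs, exact_p = mantel_exact(a, b)
            mc = mantel_test(a, b, n_perm=3000, seed=seed)
            assert mc.observed == pytest.approx(obs, abs=1e-12)
            assert abs(mc.p - exact_p) < 0.06

    def test_null_matches_direct_shuffle_recompute(self):
        """The vectorized null equals shuffling labels and recomputing."""
        from depictrsa.rdm import RDM
        from depictrsa.rsa import rdm_spearman

        a, b = random_rdm(6, 4), random_rdm(6, 5)
        res = mantel_test(a, b, n_perm=10, seed=7)
        rng = np.random.default_rng(7)
        for k in range(10):
            perm = rng.permutation(6)
            shuffled = RDM(a.labels, b.values[np.ix_(perm, perm)])
            assert res.null_sample[k] == pytest.approx(
                rdm_spearman(a, shuffled), abs=1e-12
            )


class TestCorrelationDifference:
    def test_identical_arguments_give_zero_and_large_p(self):
        shared, x = random_rdm(10, 6), random_rdm(10, 7)
        ps = []
        for seed in range(20):
            res = rdm_correlation_difference_test(shared, x, x, n_perm=99, seed=seed)
            assert res.observed == 0.0
            ps.append(res.p)
        assert np.median(ps) >= 0.4

    def test_swapping_negates_observed(self):
        shared, x, y = random_rdm(8, 8), random_rdm(8, 9), random_rdm(8, 10)
        r1 = rdm_correlation_difference_test(shared, x, y, n_perm=19, seed=0)
        r2 = rdm_correlation_difference_test(shared, y, x, n_perm=19, seed=0)
        assert r1.observed == pytest.approx(-r2.observed, abs=1e-12)

    def test_detects_clear_difference(self):
        shared = random_rdm(20, 11)
        y = random_rdm(20, 12)
        res = rdm_correlation_difference_test(shared, shared, y, n_perm=1000, seed=1)
        assert res.p <= 0.01


class TestAcrossLayerVariation:
    def test_constant_profile_gives_p_one(self):
        a, b = random_rdm(8, 13), random_rdm(8, 14)
        res = across_layer_variation_test([(a, b)] * 4, n_perm=99, seed=0)
        assert res.observed == pytest.approx(0.0, abs=1e-12)
        assert res.p == 1.0

    def test_requires_two_layers(self):
        a, b = random_rdm(8, 15), random_rdm(8, 16)
        with pytest.raises(ValueError):
            across_layer_variation_test([(a, b)], n_perm=10)

    def test_statistic_centered(self):
        """The statistic ignores a common offset of the per-layer rhos."""
        rhos = np.array([0.1, 0.5, 0.3])
        stat = np.sum((rhos - rhos.mean()) ** 2)
        stat_shifted = np.sum((rhos + 0.2 - (rhos + 0.2).mean()) ** 2)
        assert stat == pytest.approx(stat_shifted)


class TestSignPermutation:
    def test_all_zero_accuracies(self):
        res = sign_permutation_test(np.zeros(10), cnn_acc=0.3, n_perm=50, seed=0)
        assert res.observed == pytest.approx(-0.3)
        assert res.p == 1.0

    def test_all_ones_overwhelmingly_significant(self):
        res = sign_permutation_test(np.ones(42), cnn_acc=0.5, n_perm=1000, seed=1)
        assert res.p == pytest.approx(1.0 / 1001.0)

    def test_difference_flipping_variant(self):
        acc = np.full(20, 0.9)
        res = sign_permutation_test(acc, 0.5, n_perm=500, seed=2, flip="differences")
        assert res.observed == pytest.approx(0.4)
        assert res.p <= 0.01


class TestMcNemar:
    def test_balanced_discordance(self):
        t = PairedOutcomeTable([1, 1, 1, 0, 0, 0], [0, 0, 0, 1, 1, 1])
        chi2, p = mcnemar_test(t)
        assert chi2 == 0.0 and p == 1.0

    def test_closed_form_five_one(self):
        a = [1] * 5 + [0] * 1 + [1] * 4
        b = [0] * 5 + [1] * 1 + [1] * 4
        chi2, p = mcnemar_test(PairedOutcomeTable(a, b))
        assert chi2 == pytest.approx(16.0 / 6.0, abs=1e-12)

    def test_symmetric_in_conditions(self):
        rng = np.random.default_rng(3)
        a, b = rng.integers(0, 2, 30), rng.integers(0, 2, 30)
        c1, _ = mcnemar_test(PairedOutcomeTable(a, b))
        c2, _ = mcnemar_test(PairedOutcomeTable(b, a))
        assert c1 == pytest.approx(c2)

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

        rng = np.random.default_rng(4)
        a, b = rng.integers(0, 2, 50), rng.integers(0, 2, 50)
        t = PairedOutcomeTable(a, b)
        chi2, p = mcnemar_test(t)
        b10, b01 = t.discordant
        n11 = int(np.sum((a == 1) & (b == 1)))
        n00 = int(np.sum((a == 0) & (b == 0)))
        sm = sm_mcnemar([[n11, b10], [b01, n00]], exact=False, correction=False)
        assert chi2 == pytest.approx(float(sm.statistic), abs=1e-10)
        assert p == pytest.approx(float(sm.pvalue), abs=1e-10)

    def test_no_discordance_is_error(self):
        with pytest.raises(ValueError, match="undefined"):
            mcnemar_test(PairedOutcomeTable([1, 1, 0], [1, 1, 0]))


class TestTost:
    def test_identical_samples_equivalent(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0.9, 0.05, 42)
        p, decision = tost_equivalence(x, x + rng.normal(0, 1e-6, 42), (-0.05, 0.05))
        assert p < 0.001 and decision

    def test_mean_at_bound_p_half(self):
        rng = np.random.default_rng(6)
        noise = rng.normal(0, 1.0, 5000)
        x = noise - noise.mean() + 0.05  # paired mean difference exactly 0.05
        y = np.zeros(5000)
        p, _ = tost_equivalence(x, y, (-0.05, 0.05))
        assert p == pytest.approx(0.5, abs=0.05)

    def test_zero_variance_inside_and_outside(self):
        x = np.full(10, 0.5)
        p_in, dec_in = tost_equivalence(x, x - 0.01, (-0.05, 0.05))
        p_out, dec_out = tost_equivalence(x, x - 0.2, (-0.05, 0.05))
        assert (p_in, dec_in) == (0.0, True)
        assert (p_out, dec_out) == (1.0, False)

    def test_shrinking_bounds_never_decreases_p(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0.02, 0.1, 40)
        y = rng.normal(0.0, 0.1, 40)
        bounds = [0.2, 0.1, 0.05, 0.03]
        ps = [tost_equivalence(x, y, (-b, b))[0] for b in bounds]
        assert all(p2 >= p1 - 1e-12 for p1, p2 in zip(ps, ps[1:]))


class TestIndependentT:
    def test_identical_samples(self):
        x = np.array([1.0, 2.0, 3.0])
        t, p, df = independent_t_test(x, x)
        assert t == 0.0 and p == 1.0 and df == 4

    def test_closed_form_pooled_variance(self):
        t, p, df = independent_t_test([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.674, abs=1e-3)
        assert df == 4
        # closed form: pooled var 1, se = sqrt(2/3)
        assert t == pytest.approx(-3.0 / np.sqrt(2.0 / 3.0), abs=1e-12)

    def test_scale_invariant(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(0, 1, 10), rng.normal(0.5, 1, 12)
        t1, _, _ = independent_t_test(x, y)
        t2, _, _ = independent_t_test(x * 3.7, y * 3.7)
        assert t1 == pytest.approx(t2, abs=1e-10)


class TestBhFdr:
    def test_closed_form_examples(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04], atol=1e-12
        )
        np.testing.assert_allclose(bh_fdr([0.001, 0.5]), [0.002, 0.5], atol=1e-12)

    def test_equal_inputs_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.2] * 5), [0.2] * 5, atol=1e-12)

    def test_matches_manual_step_up(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(0, 1, 17)
        # independent step-up oracle
        order = np.argsort(p)
        m = len(p)
        q_sorted = np.minimum.accumulate(
            (p[order] * m / np.arange(1, m + 1))[::-1]
        )[::-1]
        expected = np.empty(m)
        expected[order] = np.clip(q_sorted, 0, 1)
        np.testing.assert_allclose(bh_fdr(p), expected, atol=1e-12)

    def test_monotone_in_inputs(self):
        rng = np.random.default_rng(10)
        p = np.sort(rng.uniform(0, 1, 12))
        q = bh_fdr(p)
        assert np.all(np.diff(q) >= -1e-12)

    def test_invalid_input_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.1, 1.5])
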