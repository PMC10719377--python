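"""Statistical kernels against brute-force oracles and closed forms."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from pdmg.io_formats import CountMatrix
from pdmg.stats import (
    bh_fdr,
    de_table,
    hypergeom_test,
    nb_lrt_test,
    spearman_corr,
    wilcoxon_rank_sum,
)


def exact_wilcoxon_oracle(x, y):
    """Full enumeration of the permutation distribution of the rank sum."""
    pooled = np.concatenate([x, y])
    n, n_x = len(pooled), len(x)
    ranks = scipy.stats.rankdata(pooled)
    base = n_x * (n_x + 1) / 2
    obs = ranks[:n_x].sum() - base
    us = np.array(
        [ranks[list(c)].sum() - base for c in itertools.combinations(range(n), n_x)]
    )
    lo = np.mean(us <= obs + 1e-9)
    hi = np.mean(us >= obs - 1e-9)
    return obs, min(1.0, 2 * min(lo, hi))


class TestWilcoxon:
    def test_separated_pairs(self):
        u, p = wilcoxon_rank_sum([1, 2], [3, 4], mode="exact")
        assert u == 0
        assert p == pytest.approx(1 / 3)

    def test_identical_multisets_give_half_u(self, rng):
        x = rng.normal(size=6)
        u, _ = wilcoxon_rank_sum(x, x, mode="approx")
        assert u == pytest.approx(len(x) ** 2 / 2)

    def test_exact_path_equals_enumeration_oracle_with_ties(self, rng):
        for _ in range(200):
            n_x = int(rng.integers(1, 9))
            n_y = int(rng.integers(1, 11 - n_x))
            x = rng.integers(0, 5, n_x).astype(float)
            y = rng.integers(0, 5, n_y).astype(float)
            u, p = wilcoxon_rank_sum(x, y, mode="exact")
            u_ref, p_ref = exact_wilcoxon_oracle(x, y)
            assert u == pytest.approx(u_ref)
            assert p == pytest.approx(p_ref, abs=1e-12)

    def test_approx_close_to_exact_at_moderate_n(self, rng):
        x = rng.normal(0.0, 1.0, 7)
        y = rng.normal(0.8, 1.0, 7)
        _, p_apx = wilcoxon_rank_sum(x, y, mode="approx")
        _, p_ex = wilcoxon_rank_sum(x, y, mode="exact")
        assert p_apx == pytest.approx(p_ex, rel=0.25)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestNbLrt:
    def test_identical_groups_null_identity(self):
        lrt, p = nb_lrt_test([5, 6, 7], [5, 6, 7], dispersion=0.1)
        assert lrt == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_all_zero_gene(self):
        lrt, p = nb_lrt_test([0, 0], [0, 0], dispersion=0.1)
        assert (lrt, p) == (0.0, 1.0)

    def test_poisson_limit(self):
        x, y = np.array([10, 12, 8]), np.array([20, 22, 18])
        lrt_nb, _ = nb_lrt_test(x, y, dispersion=1e-8)
        # closed-form Poisson LRT on the same data

        def pois_ll(v, lam):
            return np.sum(v * np.log(lam) - lam)

        both = np.concatenate([x, y])
        lrt_pois = 2 * (
            pois_ll(x, x.mean()) + pois_ll(y, y.mean()) - pois_ll(both, both.mean())
        )
        assert lrt_nb == pytest.approx(lrt_pois, rel=1e-5)

    def test_constant_offset_shift_is_absorbed(self):
        # shifting every offset by a constant re-parameterizes the mean and
        # leaves the likelihood ratio unchanged
        x, y = np.array([10, 12, 8]), np.array([30, 28, 33])
        lrt1, p1 = nb_lrt_test(x, y, offsets=np.zeros(6), dispersion=0.1)
        lrt2, p2 = nb_lrt_test(x, y, offsets=np.full(6, 3.7), dispersion=0.1)
        assert lrt1 == pytest.approx(lrt2, rel=1e-8)
        assert p1 == pytest.approx(p2, rel=1e-8)

    def test_null_pvalues_approximately_uniform(self, rng):
        phi, mu, n = 0.1, 50.0, 5
        pvals = []
        for _ in range(400):
            lam_x = rng.gamma(1 / phi, mu * phi, n)
            lam_y = rng.gamma(1 / phi, mu * phi, n)
            _, p = nb_lrt_test(rng.poisson(lam_x), rng.poisson(lam_y), dispersion=phi)
            pvals.append(p)
        ks = scipy.stats.kstest(pvals, "uniform").statistic
        assert ks < 0.08


class TestBhFdr:
    def test_hand_computed_example(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_constant_pvalues_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.2, 0.2, 0.2]), 0.2)

    def test_q_at_least_p_and_monotone(self, rng):
        p = rng.uniform(size=100)
        q = bh_fdr(p)
        assert np.all(q >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40), st.integers(0, 1000))
    def test_permutation_equivariance_and_oracle_agreement(self, pvals, seed):
        from statsmodels.stats.multitest import multipletests

        p = np.asarray(pvals)
        q = bh_fdr(p)
        perm = np.random.default_rng(seed).permutation(len(p))
        np.testing.assert_allclose(bh_fdr(p[perm]), q[perm], atol=1e-12)
        _, q_ref, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(q, q_ref, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestHypergeom:
    def test_complete_overlap_enumeration(self):
        assert hypergeom_test(5, 5, 5, 10) == pytest.approx(1 / 252, rel=1e-12)

    def test_zero_overlap_is_one(self):
        assert hypergeom_test(0, 5, 5, 10) == 1.0

    def test_matches_pmf_summation_oracle(self, rng):
        from math import comb

        for _ in range(100):
            N = int(rng.integers(2, 41))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            k = int(rng.integers(max(0, K + n - N), min(K, n) + 1))
            brute = sum(
                comb(K, j) * comb(N - K, n - j)
                for j in range(k, min(K, n) + 1)
                if n - j <= N - K
            ) / comb(N, n)
            assert hypergeom_test(k, K, n, N) == pytest.approx(brute, abs=1e-12)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_test(6, 5, 5, 10)


class TestSpearman:
    def test_monotone_transform_gives_one(self):
        a = np.arange(1.0, 9.0)
        assert spearman_corr(a, a**2) == pytest.approx(1.0)
        assert spearman_corr(a, -a) == pytest.approx(-1.0)

    def test_hand_ranked_example(self):
        # Sum d^2 = 4 -> rho = 1 - 6*4/(4*15) = 0.6
        assert spearman_corr([1, 2, 3, 4], [2, 1, 4, 3]) == pytest.approx(0.6)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_corr([1, 1, 1], [1, 2, 3])


class TestDeTable:
    def _null_matrix(self, rng, n_genes=300, n=12, mu=200.0, phi=0.05):
        lam = rng.gamma(1 / phi, mu * phi, size=(n_genes, n))
        values = rng.poisson(lam)
        genes = [f"g{i}" for i in range(n_genes)]
        cols = [f"c{j}" for j in range(n)]
        return CountMatrix(values, genes, cols), {
            c: ("x" if j < n // 2 else "y") for j, c in enumerate(cols)
        }

    def test_null_data_false_positive_rate_near_alpha(self, rng):
        m, groups = self._null_matrix(rng)
        tab = de_table(m, groups, method="nb_lrt", dispersion=0.05)
        frac_raw = float((tab.table["p"] < 0.05).mean())
        assert 0.02 <= frac_raw <= 0.09
        assert len(tab.significant(0.05)) <= 5  # BH keeps the null clean

    def test_planted_signature_recovery(self):
        from pdmg.synthetic_data import gen_bulk_counts, make_truth

        # 40 planted effects in a 300-gene focused comparison: at 6v6 and
        # phi = 0.1 the planted effect sits ~3.8 sigma out, and the BH
        # threshold at this prevalence leaves recall/precision headroom
        truth = make_truth({"seed": 5, "n_signature": 40, "n_genes": 300})
        m, groups = gen_bulk_counts(truth, n_per_group=6, depth=1e6)
        tab = de_table(m, groups, method="nb_lrt", disease_group="disease")
        called = set(tab.significant(0.05).index)
        planted = {g for g, _ in truth.signature_genes}
        recall = len(called & planted) / len(planted)
        precision = len(called & planted) / max(len(called), 1)
        assert recall >= 0.8
        assert precision >= 0.9
        # recovered directions match the planted ones
        for g, d in truth.signature_genes:
            if g in called:
                assert tab.table.loc[g, "direction"] == d

    def test_wilcoxon_path_on_cells(self, small_truth):
        from pdmg.synthetic_data import gen_sn_counts

        sn, meta = gen_sn_counts(
            small_truth, donors_per_group=2, cells_per_donor=100
        )
        mg = meta.index[meta["cell_type"] == "microglia"]
        sub = sn.subset_columns(list(mg))
        tab = de_table(
            sub,
            meta.loc[mg, "condition"].to_dict(),
            method="wilcoxon",
            disease_group="disease",
            min_prop=0.1,
        )
        assert (tab.table["q"] >= tab.table["p"] - 1e-12).all()
        planted = {g for g, _ in small_truth.signature_genes}
        called = set(tab.significant(0.05).index)
        assert len(called & planted) >= 0.5 * len(planted)

    def test_empty_matrix_gives_empty_table(self):
        m = CountMatrix(np.zeros((0, 4), dtype=int), [], ["a", "b", "c", "d"])
        tab = de_table(m, {"a": "x", "b": "x", "c": "y", "d": "y"})
        assert len(tab) == 0

    def test_nb_lrt_needs_two_per_group(self):
        m = CountMatrix(np.array([[1, 2, 3]]), ["g"], ["a", "b", "c"])
        with pytest.raises(ValueError, match="2 columns per group"):
            de_table(m, {"a": "x", "b": "y", "c": "y"}, method="nb_lrt")
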