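import itertools
import math

import numpy as np
import pytest
import scipy.stats as st

from hifbind.set_enrichment import (
    bh_fdr,
    gsea_es,
    gsea_permutation,
    hypergeom_upper_tail,
    ora,
)


def enumerate_upper_tail(k, K, n, N):
    """Exhaustive combinatorial oracle: count draws with >= k successes."""
    hits = 0
    total = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if sum(1 for x in draw if x < K) >= k:
            hits += 1
    return hits / total


def brute_running_sum(genes, scores, gene_set, w=1.0):
    """Independent cumulative-sum GSEA implementation."""
    hits = [g in gene_set for g in genes]
    nh = sum(hits)
    hit_total = sum(abs(s) ** w for s, h in zip(scores, hits) if h)
    run, best = 0.0, 0.0
    profile = []
    for s, h in zip(scores, hits):
        if h:
            run += (abs(s) ** w / hit_total) if hit_total > 0 else 1.0 / nh
        else:
            run -= 1.0 / (len(genes) - nh)
        profile.append(run)
        if abs(run) > abs(best):
            best = run
    return best, profile


class TestHypergeom:
    def test_k_zero_is_one(self):
        assert hypergeom_upper_tail(0, 5, 4, 10) == 1.0

    def test_small_exhaustive_enumeration(self):
        # full sweep over a representative small grid
        for N in (4, 7, 10):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(min(K, n) + 1):
                        expected = enumerate_upper_tail(k, K, n, N)
                        got = hypergeom_upper_tail(k, K, n, N)
                        assert got == pytest.approx(expected, abs=1e-12), (k, K, n, N)

    def test_product_form_closed_expression(self):
        # k = n = K << N: P = prod_{i<k} (K - i) / (N - i)
        k, K, n, N = 4, 4, 4, 5000
        closed = math.prod((K - i) / (N - i) for i in range(k))
        assert hypergeom_upper_tail(k, K, n, N) == pytest.approx(closed, rel=1e-12)

    def test_matches_scipy_sf_on_random_configs(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            N = int(rng.integers(2, 5000))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            k = int(rng.integers(0, min(K, n) + 1))
            expected = float(st.hypergeom.sf(k - 1, N, K, n))
            assert hypergeom_upper_tail(k, K, n, N) == pytest.approx(expected, rel=1e-9, abs=1e-300)

    def test_decreasing_in_k_and_masses_sum_to_one(self):
        K, n, N = 20, 30, 100
        tails = [hypergeom_upper_tail(k, K, n, N) for k in range(min(K, n) + 1)]
        assert all(a >= b for a, b in zip(tails, tails[1:]))
        masses = [st.hypergeom.pmf(k, N, K, n) for k in range(min(K, n) + 1)]
        assert sum(masses) == pytest.approx(1.0, abs=1e-9)

    def test_impossible_configuration_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_upper_tail(5, 3, 4, 10)


class TestBhFdr:
    def test_single_p_is_identity(self):
        assert bh_fdr([0.03]) == pytest.approx([0.03])

    def test_all_equal_stay_equal(self):
        q = bh_fdr([0.2] * 7)
        assert np.allclose(q, 0.2)

    def test_matches_sorted_formula_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(1000):
            p = rng.uniform(1e-8, 1.0, size=int(rng.integers(1, 50)))
            q = bh_fdr(p)
            order = np.argsort(p)
            m = p.size
            ranked = p[order] * m / np.arange(1, m + 1)
            expected_sorted = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1)
            assert np.allclose(np.sort(q), np.sort(expected_sorted))
            assert np.allclose(q[order], expected_sorted)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(2)
        p = rng.uniform(0.0001, 1, 200)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(bh_fdr(p), q_sm)

    def test_never_more_discoveries_than_raw(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(0.0001, 1, 500) ** 2
        assert np.sum(bh_fdr(p) < 0.05) <= np.sum(p < 0.05)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 0.0])


class TestOra:
    def test_degenerate_full_universe_query(self):
        universe = {f"g{i}" for i in range(10)}
        results = ora(universe, {"all": universe}, universe, 0.01)
        (r,) = results
        assert r.p == 1.0 and r.k == r.K == r.n == r.N == 10

    def test_planted_enrichment_ranks_first(self):
        rng = np.random.default_rng(7)
        universe = {f"g{i}" for i in range(1000)}
        planted = {f"g{i}" for i in range(50)}
        query = {g for g in planted if rng.random() < 0.8} | {
            f"g{i}" for i in range(50, 1000) if rng.random() < 0.05
        }
        collection = {"planted": planted}
        for j in range(9):
            collection[f"rand{j}"] = set(
                rng.choice(sorted(universe), size=50, replace=False)
            )
        results = ora(query, collection, universe)
        assert results[0].set_name == "planted" and results[0].enriched

    def test_enrichment_threshold_is_strict(self):
        universe = {f"g{i}" for i in range(20)}
        results = ora({"g0"}, {"s": {"g0"}}, universe, fdr_threshold=0.05)
        (r,) = results
        assert r.p == pytest.approx(1 / 20)
        assert r.enriched == (r.q < 0.05)

    def test_query_outside_universe_dropped_and_empty_errors(self):
        universe = {"g1", "g2"}
        with pytest.raises(ValueError):
            ora({"zzz"}, {"s": {"g1"}}, universe)


class TestGseaEs:
    def test_singleton_at_rank_one_is_one(self):
        genes = [f"g{i}" for i in range(10)]
        res = gsea_es(genes, np.linspace(5, 0.5, 10), {"g0"})
        assert res.es == pytest.approx(1.0)

    def test_singleton_at_last_rank_descends_to_minus_one(self):
        # n-1 misses of -1/(n-1) each take the profile to -1 just before the
        # final hit restores it to 0; the signed extremum is therefore -1
        # (value frozen from the hand-rolled cumulative-sum oracle below)
        n = 10
        genes = [f"g{i}" for i in range(n)]
        scores = np.linspace(5, 0.5, n)
        res = gsea_es(genes, scores, {f"g{n - 1}"})
        es_oracle, profile_oracle = brute_running_sum(genes, scores, {f"g{n - 1}"})
        assert es_oracle == pytest.approx(-1.0)
        assert res.es == pytest.approx(es_oracle)
        assert res.profile[-1] == pytest.approx(0.0)
        assert np.allclose(res.profile, profile_oracle)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 20
        genes = [f"g{i}" for i in range(n)]
        scores = np.sort(rng.normal(0, 2, n))[::-1]
        gene_set = set(rng.choice(genes, size=5, replace=False))
        res = gsea_es(genes, scores, gene_set)
        es_oracle, profile_oracle = brute_running_sum(genes, scores, gene_set)
        assert res.es == pytest.approx(es_oracle, abs=1e-12)
        assert np.allclose(res.profile, profile_oracle)

    def test_scale_invariance_of_scores(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(30)]
        scores = np.sort(rng.lognormal(0, 1, 30))[::-1]
        gene_set = set(genes[2:8])
        a = gsea_es(genes, scores, gene_set).es
        b = gsea_es(genes, scores * 37.5, gene_set).es
        assert a == pytest.approx(b, rel=1e-12)

    def test_disjoint_or_total_set_rejected(self):
        genes = ["g0", "g1", "g2"]
        with pytest.raises(ValueError):
            gsea_es(genes, [3, 2, 1], {"zzz"})
        with pytest.raises(ValueError):
            gsea_es(genes, [3, 2, 1], set(genes))


class TestGseaPermutation:
    def test_fixed_seed_is_reproducible(self):
        rng = np.random.default_rng(6)
        genes = [f"g{i}" for i in range(50)]
        scores = np.sort(rng.normal(0, 1, 50))[::-1]
        gene_set = set(genes[::7])
        a = gsea_permutation(genes, scores, gene_set, 100, seed=42)
        b = gsea_permutation(genes, scores, gene_set, 100, seed=42)
        assert a.es == b.es and a.p_perm == b.p_perm and a.nes == b.nes

    def test_planted_front_loading_is_significant(self):
        rng = np.random.default_rng(8)
        n = 300
        genes = [f"g{i}" for i in range(n)]
        scores = np.sort(rng.lognormal(0, 1, n))[::-1]
        gene_set = set(genes[:40])  # concentrated at the top
        res = gsea_permutation(genes, scores, gene_set, 1000, seed=9)
        assert res.es > 0 and res.p_perm <= 0.01 and res.nes > 1

    def test_n_perm_minimum_enforced(self):
        with pytest.raises(ValueError):
            gsea_permutation(["a", "b"], [2, 1], {"a"}, n_perm=10, seed=1)
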