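import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from mina import MinaError, SeedSet, annotation_enrichment, enrichment_score, permutation_null
from mina.network_score import NetworkScore

from conftest import build_net


class TestEnrichmentScore:
    def test_one_in_a_hundred_scores_two(self):
        # a 1-gene network holding the single seed of a 100-gene universe
        # arises by chance with probability exactly 1/100
        s = enrichment_score(n_network=1, k_seeds_in=1, N_universe=100, K_seeds_total=1)
        assert s.p_enrichment == pytest.approx(0.01, abs=1e-15)
        assert s.score == pytest.approx(2.0, abs=1e-12)

    def test_zero_seeds_scores_zero(self):
        s = enrichment_score(10, 0, 1000, 9)
        assert s.p_enrichment == 1.0
        assert s.score == 0.0

    def test_all_seeds_small_universe_matches_enumeration(self):
        # N=10, K=3, n=3, k=3: enumerate all C(10,3)=120 subsets
        hits = sum(
            1
            for sub in itertools.combinations(range(10), 3)
            if set(sub) == {0, 1, 2}
        )
        total = math.comb(10, 3)
        s = enrichment_score(3, 3, 10, 3)
        assert s.p_enrichment == pytest.approx(hits / total, rel=1e-12)
        assert s.score == pytest.approx(math.log10(120), abs=1e-9)

    def test_bounds_enforced(self):
        with pytest.raises(MinaError):
            enrichment_score(5, 6, 100, 9)
        with pytest.raises(MinaError):
            enrichment_score(101, 1, 100, 9)

    @given(
        k=st.integers(0, 6),
        n=st.integers(6, 20),
        K=st.integers(6, 10),
        N=st.integers(30, 80),
    )
    @settings(max_examples=60, deadline=None)
    def test_monotone_in_seeds_observed(self, k, n, K, N):
        p_k = enrichment_score(n, k, N, K).p_enrichment
        p_k1 = enrichment_score(n, k + 1, N, K).p_enrichment if k + 1 <= min(n, K) else 0
        assert p_k1 <= p_k + 1e-12

    def test_score_is_log10_of_p(self):
        s = NetworkScore.from_p(1e-26)
        assert s.score == pytest.approx(26.0, abs=1e-12)

    def test_agrees_with_monte_carlo(self, rng):
        # analytic upper tail vs direct subset sampling on a small instance
        N, K, n, k = 40, 6, 10, 3
        draws = rng.hypergeometric(K, N - K, n, size=100_000)
        mc = np.mean(draws >= k)
        se = math.sqrt(mc * (1 - mc) / draws.size)
        analytic = enrichment_score(n, k, N, K).p_enrichment
        assert abs(analytic - mc) < 3 * se


class TestPermutationNull:
    @pytest.fixture
    def chain_net(self):
        return build_net([(f"N{i}", f"N{i+1}") for i in range(19)])

    def test_addone_rule_extremes(self, chain_net):
        null = permutation_null(
            chain_net, seeds=SeedSet(("N0", "N19")), n_permutations=99,
            matching="uniform", rng_seed=3, observed_score=np.inf,
        )
        assert null.p_empirical == pytest.approx(1 / 100)
        null = permutation_null(
            chain_net, seeds=SeedSet(("N0", "N19")), n_permutations=99,
            matching="uniform", rng_seed=3, observed_score=-1.0,
        )
        assert null.p_empirical == 1.0

    def test_reproducible_given_rng_seed(self, chain_net):
        a = permutation_null(chain_net, seeds=SeedSet(("N0", "N10")),
                             n_permutations=20, matching="uniform", rng_seed=7)
        b = permutation_null(chain_net, seeds=SeedSet(("N0", "N10")),
                             n_permutations=20, matching="uniform", rng_seed=7)
        assert np.array_equal(a.scores, b.scores)
        assert a.p_empirical == b.p_empirical

    def test_seed_count_exceeding_nodes_rejected(self, chain_net):
        with pytest.raises(MinaError):
            permutation_null(chain_net, seed_count=100, n_permutations=5,
                             matching="uniform", rng_seed=1, observed_score=1.0)

    def test_degree_matching_draws_similar_degrees(self):
        # hub-and-spoke: degree-matched nulls for leaf seeds never draw the hub
        edges = [("HUB", f"L{i:02d}") for i in range(30)]
        net = build_net(edges)
        null = permutation_null(
            net, seeds=SeedSet(("L00", "L01", "L02")), n_permutations=30,
            matching="degree_matched", rng_seed=5, observed_score=1.0,
        )
        assert null.n_permutations == 30
        # with 30 degree-1 leaves and one degree-30 hub, every matched draw
        # stays in the leaf decile, so all permuted scores are finite and equal
        assert len(set(np.round(null.scores, 9))) == 1

    def test_empirical_p_conservatively_valid(self):
        """P(p_empirical <= t) <= t under the null (super-uniformity).

        The score is a coarsely discrete statistic, so the tie-inclusive
        add-one estimator is conservative rather than exactly uniform;
        validity is the property inference relies on.
        """
        from mina import ShortestPathCache
        from mina.synthetic import SyntheticSpec, make_interactome

        spec = SyntheticSpec(n_genes=150, rng_seed=11)
        net, _ = make_interactome(spec)
        direct = net.direct_subgraph()
        cache = ShortestPathCache(direct.graph)
        nodes = sorted(direct.nodes)
        rng = np.random.default_rng(99)
        pvals = []
        for _ in range(60):
            drawn = [str(g) for g in rng.choice(nodes, size=5, replace=False)]
            null = permutation_null(
                direct, seeds=SeedSet(tuple(drawn)), n_permutations=39,
                matching="uniform", rng_seed=int(rng.integers(2**31)),
                paths=cache,
            )
            pvals.append(null.p_empirical)
        pvals = np.array(pvals)
        for t in (0.05, 0.1, 0.25, 0.5):
            # binomial slack: 3 standard errors above t
            slack = 3 * math.sqrt(t * (1 - t) / len(pvals))
            assert np.mean(pvals <= t) <= t + slack


class TestAnnotationEnrichment:
    def test_perfect_overlap_near_minimal_p(self):
        universe = {f"G{i}" for i in range(1000)}
        gene_set = {"G1", "G2", "G3", "G4", "G5"}
        table = annotation_enrichment(gene_set, {"term": set(gene_set)}, universe)
        # hypergeometric point mass of a perfect 5/5 overlap
        expected = 1 / math.comb(1000, 5) * math.comb(5, 5) * math.comb(995, 0)
        assert table.loc[0, "p_fisher"] == pytest.approx(expected, rel=1e-6)

    def test_disjoint_term_p_one(self):
        universe = {f"G{i}" for i in range(50)}
        table = annotation_enrichment({"G1", "G2"}, {"t": {"G40", "G41"}}, universe)
        assert table.loc[0, "p_fisher"] == pytest.approx(1.0)

    def test_matches_hypergeometric_tail_summation(self):
        # 2x2 table (10,5;20,965): sum the tail terms directly
        a, b, c, d = 10, 5, 20, 965
        N = a + b + c + d
        K = a + c  # term size
        n = a + b  # gene-set size
        tail = sum(
            math.comb(K, i) * math.comb(N - K, n - i) / math.comb(N, n)
            for i in range(a, min(K, n) + 1)
        )
        universe = {f"G{i}" for i in range(N)}
        term = {f"G{i}" for i in range(K)}
        gene_set = {f"G{i}" for i in range(a)} | {f"G{i}" for i in range(K, K + b)}
        table = annotation_enrichment(gene_set, {"t": term}, universe)
        assert table.loc[0, "p_fisher"] == pytest.approx(tail, rel=1e-9)

    def test_empty_universe_rejected(self):
        with pytest.raises(MinaError, match="empty universe"):
            annotation_enrichment(set(), {}, set())

    def test_bh_column_monotone_transform(self):
        universe = {f"G{i}" for i in range(100)}
        annotation = {
            "a": {f"G{i}" for i in range(10)},
            "b": {f"G{i}" for i in range(40, 80)},
            "c": {f"G{i}" for i in range(5)},
        }
        table = annotation_enrichment({"G1", "G2", "G3"}, annotation, universe)
        assert (table["q_bh"] >= table["p_fisher"] - 1e-12).all()
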