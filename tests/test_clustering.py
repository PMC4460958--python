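import itertools
import math

import numpy as np
import pytest
from scipy.cluster.hierarchy import linkage as scipy_linkage
from scipy.spatial.distance import squareform

import drugrepo as dr
from drugrepo.clustering import enrichment_table


# --- independent oracles -------------------------------------------------

def oracle_agglomerate(D, method):
    """Brute-force agglomeration recomputing every inter-cluster distance
    from the ORIGINAL matrix by definition (no Lance-Williams updates)."""
    D = np.asarray(D, float)
    n = D.shape[0]
    clusters = {i: frozenset([i]) for i in range(n)}
    merges = []
    for step in range(n - 1):
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            pts = [D[i, j] for i in clusters[a] for j in clusters[b]]
            if method == "single":
                d = min(pts)
            elif method == "complete":
                d = max(pts)
            else:
                d = sum(pts) / len(pts)
            if best is None or (d, a, b) < best:
                best = (d, a, b)
        d, a, b = best
        new = n + step
        clusters[new] = clusters[a] | clusters[b]
        merges.append((a, b, d, len(clusters[new])))
        del clusters[a], clusters[b]
    return merges


def oracle_hypergeom_tail(x, n_c, K, N):
    """P[X >= x] by exhaustive enumeration of all C(N, n_c) draws."""
    hits = total = 0
    for draw in itertools.combinations(range(N), n_c):
        total += 1
        if sum(1 for i in draw if i < K) >= x:
            hits += 1
    return hits / total


# --- pairwise distances --------------------------------------------------

class TestPairwiseDistance:
    def test_euclidean_345_triangle(self):
        D = dr.pairwise_distance(np.array([[0.0, 0.0], [3.0, 4.0]]), "euclidean")
        assert D[0, 1] == pytest.approx(5.0)

    def test_cosine_orthogonal(self):
        D = dr.pairwise_distance(np.array([[1.0, 0.0], [0.0, 1.0]]), "cosine")
        assert D[0, 1] == pytest.approx(1.0)

    def test_cityblock_example(self):
        D = dr.pairwise_distance(np.array([[1.0, 2.0], [4.0, 0.0]]), "cityblock")
        assert D[0, 1] == pytest.approx(5.0)

    def test_symmetric_zero_diagonal(self, rng):
        U = rng.normal(size=(7, 3))
        for met in ("euclidean", "cosine", "cityblock", "mahalanobis"):
            D = dr.pairwise_distance(U, met)
            assert np.allclose(D, D.T)
            assert np.allclose(np.diag(D), 0.0)

    def test_cosine_zero_norm_names_drug(self):
        U = np.array([[1.0, 0.0], [0.0, 0.0]])
        with pytest.raises(ValueError, match="drugB"):
            dr.pairwise_distance(U, "cosine", ids=["drugA", "drugB"])

    def test_unknown_metric(self):
        with pytest.raises(ValueError):
            dr.pairwise_distance(np.eye(2), "hamming")


# --- agglomeration -------------------------------------------------------

class TestAgglomerate:
    def test_two_points_single_merge(self):
        D = np.array([[0.0, 2.5], [2.5, 0.0]])
        den = dr.agglomerate(D, "single", ["a", "b"])
        assert den.merges == [(0, 1, 2.5, 2)]

    def test_three_collinear_points_single_linkage(self):
        pts = np.array([[0.0], [1.0], [10.0]])
        D = dr.pairwise_distance(pts, "euclidean")
        den = dr.agglomerate(D, "single")
        heights = [m[2] for m in den.merges]
        assert heights == pytest.approx([1.0, 9.0])

    @pytest.mark.parametrize("method", ["single", "complete", "average"])
    @pytest.mark.parametrize("n", [4, 7, 10, 12])
    def test_matches_bruteforce_oracle(self, method, n, rng):
        U = rng.normal(size=(n, 3))
        D = dr.pairwise_distance(U, "euclidean")
        den = dr.agglomerate(D, method)
        expected = oracle_agglomerate(D, method)
        for (a, b, h, s), (ea, eb, eh, es) in zip(den.merges, expected):
            assert (a, b, s) == (ea, eb, es)
            assert h == pytest.approx(eh, abs=1e-10)

    @pytest.mark.parametrize("method", ["single", "complete", "average"])
    def test_matches_scipy_on_tie_free_data(self, method, rng):
        # cross-check against an established implementation where the
        # tie rule cannot matter (generic continuous distances)
        U = rng.normal(size=(15, 4))
        D = dr.pairwise_distance(U, "euclidean")
        den = dr.agglomerate(D, method)
        Z = scipy_linkage(squareform(D, checks=False), method=method)
        np.testing.assert_allclose(
            den.to_linkage_matrix()[:, 2], Z[:, 2], atol=1e-10
        )

    def test_heights_non_decreasing_all_linkages(self, rng):
        U = rng.normal(size=(10, 3))
        D = dr.pairwise_distance(U, "cityblock")
        for method in ("single", "complete", "average"):
            h = [m[2] for m in dr.agglomerate(D, method).merges]
            assert all(a <= b + 1e-12 for a, b in zip(h, h[1:]))

    def test_tie_break_lowest_pair(self):
        # equilateral configuration: every pairwise distance equal
        D = np.ones((3, 3)) - np.eye(3)
        den = dr.agglomerate(D, "average")
        assert den.merges[0][:2] == (0, 1)

    def test_singleton_input_rejected(self):
        with pytest.raises(ValueError):
            dr.agglomerate(np.zeros((1, 1)), "average")

    def test_newick_export_parses(self, rng):
        import io as _io
        from Bio import Phylo

        U = rng.normal(size=(6, 2))
        den = dr.agglomerate(dr.pairwise_distance(U, "euclidean"), "average",
                             [f"d{i}" for i in range(6)])
        tree = Phylo.read(_io.StringIO(den.to_newick()), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == [f"d{i}" for i in range(6)]


# --- hypergeometric tail -------------------------------------------------

class TestHypergeomTail:
    def test_x_zero_is_one(self):
        assert dr.hypergeom_tail(0, 5, 6, 20) == 1.0

    def test_degenerate_universe(self):
        assert dr.hypergeom_tail(4, 4, 4, 4) == 1.0

    def test_worked_example(self):
        # (C(6,4)C(14,1) + C(6,5)C(14,0)) / C(20,5)
        expected = (math.comb(6, 4) * math.comb(14, 1) + math.comb(6, 5)) / math.comb(20, 5)
        assert dr.hypergeom_tail(4, 5, 6, 20) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.013932, abs=5e-7)

    @pytest.mark.parametrize("N", [6, 9, 12])
    def test_matches_enumeration_oracle(self, N):
        for K in range(N + 1):
            for n_c in range(N + 1):
                for x in range(min(n_c, K) + 1):
                    assert dr.hypergeom_tail(x, n_c, K, N) == pytest.approx(
                        oracle_hypergeom_tail(x, n_c, K, N), abs=1e-12
                    )

    def test_inconsistent_arguments(self):
        with pytest.raises(ValueError):
            dr.hypergeom_tail(3, 2, 5, 10)
        with pytest.raises(ValueError):
            dr.hypergeom_tail(1, 2, 11, 10)


# --- enrichment over the dendrogram -------------------------------------

def packed_fixture(rng):
    """20 leaves; 6 known; 5-point tight cluster holding 4 knowns."""
    pts = rng.uniform(10, 20, size=(20, 2))
    pts[:5] = rng.normal(scale=0.01, size=(5, 2))  # tight cluster at origin
    ids = [f"d{i:02d}" for i in range(20)]
    known = {"d00", "d01", "d02", "d03", "d15", "d16"}
    D = dr.pairwise_distance(pts, "euclidean")
    return dr.agglomerate(D, "average", ids), known


class TestEnrichedClusters:
    def test_saturated_universe_no_hits(self, rng):
        U = rng.normal(size=(8, 2))
        den = dr.agglomerate(dr.pairwise_distance(U, "euclidean"), "average",
                             [f"d{i}" for i in range(8)])
        assert dr.enriched_clusters(den, {f"d{i}" for i in range(8)}) == []

    def test_packed_known_cluster_found(self, rng):
        # scanning candidate clusters of 5-10 drugs: the tight 5-cluster
        # holding 4 of the 6 knowns is the one significant node
        den, known = packed_fixture(rng)
        results = dr.enriched_clusters(den, known, alpha=0.05, min_size=5, max_size=10)
        assert len(results) == 1
        best = results[0]
        assert set(best.members) == {"d00", "d01", "d02", "d03", "d04"}
        assert best.x == 4 and best.n_c == 5
        assert best.p_value == pytest.approx(0.013932, abs=5e-7)
        assert best.q_value <= 0.05

    def test_min_size_beyond_n_gives_empty(self, rng):
        den, known = packed_fixture(rng)
        assert dr.enriched_clusters(den, known, min_size=50) == []

    def test_empty_known_set_errors(self, rng):
        den, _ = packed_fixture(rng)
        with pytest.raises(ValueError):
            dr.enriched_clusters(den, set())

    def test_unknown_leaf_in_known_set_errors(self, rng):
        den, _ = packed_fixture(rng)
        with pytest.raises(ValueError, match="absent"):
            dr.enriched_clusters(den, {"not-a-leaf"})

    def test_collapse_keeps_most_significant_of_nested(self, rng):
        den, known = packed_fixture(rng)
        results = dr.enriched_clusters(den, known, alpha=0.05)
        for a, b in itertools.combinations(results, 2):
            assert not (set(a.members) <= set(b.members)
                        or set(b.members) <= set(a.members))

    def test_table_columns(self, rng):
        den, known = packed_fixture(rng)
        df = enrichment_table(dr.enriched_clusters(den, known))
        assert list(df.columns) == ["node_id", "members", "x", "n_c", "K", "N", "p", "q"]


# --- consensus -----------------------------------------------------------

class TestConsensusHits:
    def test_identical_sets(self):
        s = {"a", "b"}
        assert dr.consensus_hits([s, set(s), set(s)], {"a", "b"}) == s

    def test_three_way_intersection(self):
        out = dr.consensus_hits([{"a", "b", "c"}, {"b", "c", "d"}, {"b", "c", "e"}],
                                {"a", "b", "c", "d", "e"})
        assert out == {"b", "c"}

    def test_empty_input_absorbs(self):
        assert dr.consensus_hits([{"a"}, set(), {"a"}], {"a"}) == set()

    def test_subset_of_every_input_and_order_invariant(self, rng):
        pool = [f"d{i}" for i in range(10)]
        sets = [set(rng.choice(pool, size=6, replace=False)) for _ in range(3)]
        uni = set(pool[:8])
        out = dr.consensus_hits(sets, uni)
        assert all(out <= s for s in sets) and out <= uni
        assert out == dr.consensus_hits(sets[::-1], uni)

    def test_universe_restriction(self):
        assert dr.consensus_hits([{"a", "b"}, {"a", "b"}], {"b"}) == {"b"}
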