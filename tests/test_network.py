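"""Equivalent-network sampling, Pearson matrices and spanning trees."""

import itertools

import numpy as np
import pandas as pd
import pytest

from snpsig import (
    extreme_separation_cohort,
    max_spanning_tree,
    pearson_matrix,
    sample_networks,
)
from snpsig.network import weighted_sample_without_replacement

from conftest import labels_for


def naive_pearson(X):
    """Textbook two-pass covariance/correlation."""
    n, m = X.shape
    out = np.empty((m, m))
    for a in range(m):
        for b in range(m):
            xa, xb = X[:, a], X[:, b]
            ca, cb = xa - xa.mean(), xb - xb.mean()
            out[a, b] = (ca * cb).sum() / np.sqrt((ca**2).sum() * (cb**2).sum())
    return out


def brute_force_best_tree(corr, maximize=True):
    """Enumerate every spanning tree of the complete graph; return best |r| sum."""
    ids = list(corr.columns)
    n = len(ids)
    all_edges = [(a, b) for a in range(n) for b in range(a + 1, n)]
    best = None
    for subset in itertools.combinations(all_edges, n - 1):
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                x = parent[x]
            return x

        acyclic = True
        for a, b in subset:
            ra, rb = find(a), find(b)
            if ra == rb:
                acyclic = False
                break
            parent[ra] = rb
        if not acyclic:
            continue
        w = sum(abs(corr.iloc[a, b]) for a, b in subset)
        if best is None or (w > best if maximize else w < best):
            best = w
    return best


class TestPearsonMatrix:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(1)
        X = rng.integers(1, 4, size=(20, 3)).astype(float)
        r = pearson_matrix(X)
        np.testing.assert_allclose(np.diag(r), 1.0)

    def test_code_reflection_is_perfectly_anticorrelated(self):
        col = np.array([1, 2, 3, 1, 3, 2, 1], dtype=float)
        X = np.column_stack([col, 4 - col])
        assert pearson_matrix(X).iloc[0, 1] == pytest.approx(-1.0)

    def test_matches_two_pass_oracle(self):
        rng = np.random.default_rng(2)
        X = rng.integers(1, 4, size=(25, 5)).astype(float)
        np.testing.assert_allclose(
            pearson_matrix(X).to_numpy(), naive_pearson(X), rtol=1e-12, atol=1e-12
        )

    def test_zero_variance_snp_named_in_error(self):
        X = np.column_stack([np.ones(6), np.arange(6, dtype=float)])
        with pytest.raises(ValueError, match="x0"):
            pearson_matrix(X)


class TestMaxSpanningTree:
    def test_three_node_hand_case(self):
        corr = pd.DataFrame(
            [[1.0, 0.9, 0.2], [0.9, 1.0, 0.5], [0.2, 0.5, 1.0]],
            index=list("ABC"), columns=list("ABC"),
        )
        tree = max_spanning_tree(corr)
        edges = {frozenset((a, b)) for a, b, _ in tree.edges}
        assert edges == {frozenset("AB"), frozenset("BC")}
        assert tree.total_weight == pytest.approx(1.4)

    def test_tree_shape_invariants(self):
        rng = np.random.default_rng(3)
        X = rng.integers(1, 4, size=(30, 7)).astype(float)
        tree = max_spanning_tree(pearson_matrix(X))
        assert len(tree.edges) == 6
        # connectivity: union-find over the edges reaches every node
        comp = {n: n for n in tree.nodes}

        def find(x):
            while comp[x] != x:
                x = comp[x]
            return x

        for a, b, _ in tree.edges:
            comp[find(a)] = find(b)
        assert len({find(n) for n in tree.nodes}) == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_optimal_against_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(4, 7))
        X = rng.normal(size=(15, n))
        corr = pd.DataFrame(np.corrcoef(X, rowvar=False),
                            index=[f"s{j}" for j in range(n)],
                            columns=[f"s{j}" for j in range(n)])
        tree = max_spanning_tree(corr)
        assert tree.total_weight == pytest.approx(brute_force_best_tree(corr))

    def test_agrees_with_networkx(self):
        import networkx as nx

        rng = np.random.default_rng(4)
        X = rng.normal(size=(40, 8))
        corr = pd.DataFrame(np.corrcoef(X, rowvar=False),
                            index=[f"s{j}" for j in range(8)],
                            columns=[f"s{j}" for j in range(8)])
        tree = max_spanning_tree(corr)
        g = nx.Graph()
        for a in range(8):
            for b in range(a + 1, 8):
                g.add_edge(f"s{a}", f"s{b}", weight=abs(corr.iloc[a, b]))
        ref = nx.maximum_spanning_tree(g)
        ref_weight = sum(d["weight"] for _, _, d in ref.edges(data=True))
        assert tree.total_weight == pytest.approx(ref_weight)

    def test_minimum_variant_and_small_graphs(self):
        corr = pd.DataFrame([[1.0, 0.3], [0.3, 1.0]], index=list("ab"),
                            columns=list("ab"))
        assert max_spanning_tree(corr, minimum=True).total_weight == pytest.approx(0.3)
        with pytest.raises(ValueError, match="2 nodes"):
            max_spanning_tree(corr.iloc[:1, :1])


class TestWeightedSampling:
    def test_inclusion_probability_matches_enumeration(self):
        """Empirical inclusion frequencies converge to the exact successive-
        sampling inclusion probabilities (enumerated over ordered draws)."""
        w = np.array([5.0, 3.0, 1.0, 1.0, 0.5, 0.5])
        size = 2
        # exact inclusion probabilities by enumerating ordered pairs
        incl = np.zeros(len(w))
        W = w.sum()
        for i in range(len(w)):
            for j in range(len(w)):
                if i == j:
                    continue
                p = (w[i] / W) * (w[j] / (W - w[i]))
                incl[i] += p
                incl[j] += p
        rng = np.random.default_rng(5)
        draws = 20000
        counts = np.zeros(len(w))
        for _ in range(draws):
            counts[weighted_sample_without_replacement(w, size, rng)] += 1
        freq = counts / draws
        se = np.sqrt(incl * (1 - incl) / draws)
        assert (np.abs(freq - incl) < 5 * se + 1e-3).all()

    def test_oversampling_rejected(self):
        with pytest.raises(ValueError, match="more items"):
            weighted_sample_without_replacement(np.ones(3), 4, np.random.default_rng(0))


class TestSampleNetworks:
    @pytest.fixture()
    def cohort(self):
        m, y, _ = extreme_separation_cohort(20, 10, 40, 4, seed=6)
        from snpsig import select_discriminatory, snp_statistics

        ranked = select_discriminatory(snp_statistics(m, y), tail_fraction=0.5,
                                       fr_min=0.0)
        return m, y, ranked

    def test_single_sample_posterior_is_indicator(self, cohort):
        m, y, ranked = cohort
        post = sample_networks(m, y, ranked, network_size=3, n_samples=1, seed=7)
        freq = post.posterior_frequency
        members = set(post.sampled_networks[0][0])
        assert all(freq[s] == (1.0 if s in members else 0.0) for s in freq.index)

    def test_dominant_weight_snp_is_always_retained(self):
        """A SNP whose FR weight dominates by >1e4 appears in essentially
        every sampled network, so its posterior frequency is 1."""
        rng = np.random.default_rng(8)
        X = rng.integers(1, 4, size=(30, 6)).astype(float)
        labels = labels_for(18, 12).labels
        pool = pd.DataFrame({
            "snp_id": [f"x{j}" for j in range(6)],
            "fisher_ratio": [1e6, 10.0, 5.0, 2.0, 1.0, 0.5],
        })
        post = sample_networks(X, labels, pool, network_size=2, n_samples=50, seed=8)
        assert post.posterior_frequency["x0"] == 1.0

    def test_equal_weights_sample_uniformly(self):
        """With all FRs equal, per-SNP sampling frequency over all sampled
        networks is uniform within multinomial bounds."""
        rng = np.random.default_rng(9)
        n_pool, size, n_samples = 8, 2, 2000
        X = rng.integers(1, 4, size=(20, n_pool)).astype(float)
        labels = labels_for(12, 8).labels
        pool = pd.DataFrame({"snp_id": [f"x{j}" for j in range(n_pool)],
                             "fisher_ratio": np.ones(n_pool)})
        post = sample_networks(X, labels, pool, network_size=size,
                               n_samples=n_samples, threshold_offset=1.0, seed=9)
        counts = np.zeros(n_pool)
        for net, _ in post.sampled_networks:
            for s in net:
                counts[int(s[1:])] += 1
        p = size / n_pool
        se = np.sqrt(p * (1 - p) / n_samples)
        assert (np.abs(counts / n_samples - p) < 4.5 * se).all()

    def test_retained_networks_meet_threshold(self, cohort):
        m, y, ranked = cohort
        post = sample_networks(m, y, ranked, network_size=3, n_samples=30, seed=10)
        best = max(acc for _, acc in post.sampled_networks)
        assert all(acc >= best - 0.02 for _, acc in post.retained_networks)
        assert post.retained_networks  # the best network is always retained

    def test_seed_determinism(self, cohort):
        m, y, ranked = cohort
        a = sample_networks(m, y, ranked, network_size=3, n_samples=20, seed=11)
        b = sample_networks(m, y, ranked, network_size=3, n_samples=20, seed=11)
        assert a.sampled_networks == b.sampled_networks
        pd.testing.assert_series_equal(a.posterior_frequency, b.posterior_frequency)
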