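"""Equivalent predictive networks and the signature correlation tree.

Two complementary views of how interchangeable the discriminatory SNPs are:

* **Random network sampling** — candidate networks (SNP subsets of fixed
  size) are drawn without replacement with per-SNP prior weight proportional
  to Fisher's ratio, so the most discriminatory SNPs are sampled
  preferentially. Each network is scored by LOOCV accuracy; networks within a
  tolerance of the best sampled accuracy are retained, and each SNP's
  *posterior sampling frequency* is the fraction of retained networks that
  contain it. SNPs with high posterior frequency are near-indispensable;
  interchangeable SNPs dilute each other's frequency.
* **Correlation tree** — the maximum spanning tree of the complete graph on
  the signature SNPs with edges weighted by the absolute Pearson correlation
  of their code vectors. Strong dependence of either sign makes an edge; low
  edge weights throughout indicate nearly independent predictors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import ClassifierSpec
from .containers import GenotypeMatrix
from .signature import _to_xy, loocv_accuracy

__all__ = [
    "NetworkPosterior",
    "CorrelationTree",
    "weighted_sample_without_replacement",
    "sample_networks",
    "pearson_matrix",
    "max_spanning_tree",
]


@dataclass(frozen=True)
class NetworkPosterior:
    """Sampled networks, the retained high-accuracy subset, and per-SNP frequencies."""

    sampled_networks: list = field(repr=False)  # (tuple of snp ids, accuracy)
    retained_networks: list = field(repr=False)
    posterior_frequency: pd.Series = field(repr=False)  # index: snp id
    threshold: float
    n_samples: int
    seed: int


@dataclass(frozen=True)
class CorrelationTree:
    """A spanning tree over SNPs; edges carry the signed Pearson r."""

    nodes: tuple
    edges: tuple  # (snp_a, snp_b, pearson_r), snp_a < snp_b
    total_weight: float  # sum of |r| over edges


def weighted_sample_without_replacement(
    weights: np.ndarray, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Successive weighted sampling without replacement (indices).

    Items are drawn one at a time with probability proportional to their
    weight among the items not yet drawn.
    """
    weights = np.asarray(weights, dtype=float)
    if size > len(weights):
        raise ValueError("cannot sample more items than available")
    if (weights <= 0).any():
        raise ValueError("weights must be strictly positive")
    remaining = weights.copy()
    chosen = np.empty(size, dtype=np.intp)
    for t in range(size):
        p = remaining / remaining.sum()
        j = rng.choice(len(weights), p=p)
        chosen[t] = j
        remaining[j] = 0.0
    return chosen


def _fr_weights(fr: np.ndarray) -> np.ndarray:
    """Sampling weights proportional to FR; the sentinel gets 10x the max finite FR."""
    fr = np.asarray(fr, dtype=float)
    w = fr.copy()
    inf = np.isinf(w)
    if inf.any():
        finite = w[~inf]
        top = finite.max() if finite.size and finite.max() > 0 else 1.0
        w[inf] = top * 10.0
    if (w <= 0).any():
        # zero-FR SNPs are never preferentially sampled but stay reachable
        tiny = w[w > 0].min() * 1e-6 if (w > 0).any() else 1.0
        w[w <= 0] = tiny
    return w


def sample_networks(
    m,
    y,
    pool: pd.DataFrame,
    network_size: int,
    n_samples: int,
    threshold_offset: float = 0.02,
    spec: ClassifierSpec | None = None,
    seed: int = 0,
) -> NetworkPosterior:
    """Sample SNP networks with FR-proportional priors and score them by LOOCV.

    ``pool`` is a ranked statistics table (``snp_id``/``fisher_ratio``
    columns). Networks with accuracy at or above ``best - threshold_offset``
    are retained. The result is a pure function of ``seed``.
    """
    spec = spec or ClassifierSpec()
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if pool.empty:
        raise ValueError("SNP pool is empty")
    snp_ids = list(pool["snp_id"])
    if not (1 <= network_size <= len(snp_ids)):
        raise ValueError(f"network_size must lie in [1, {len(snp_ids)}]")
    weights = _fr_weights(pool["fisher_ratio"].to_numpy())

    X, labels = _to_xy(m, y, snp_ids)
    rng = np.random.default_rng(seed)
    sampled = []
    for _ in range(n_samples):
        idx = weighted_sample_without_replacement(weights, network_size, rng)
        rep = loocv_accuracy(X[:, idx], labels, spec=spec)
        sampled.append((tuple(snp_ids[j] for j in idx), rep.accuracy))

    best = max(acc for _, acc in sampled)
    threshold = best - threshold_offset
    retained = [(net, acc) for net, acc in sampled if acc >= threshold]
    counts = {s: 0 for s in snp_ids}
    for net, _ in retained:
        for s in net:
            counts[s] += 1
    freq = pd.Series(
        {s: counts[s] / len(retained) for s in snp_ids}, name="posterior_frequency"
    )
    return NetworkPosterior(
        sampled_networks=sampled,
        retained_networks=retained,
        posterior_frequency=freq,
        threshold=float(threshold),
        n_samples=n_samples,
        seed=seed,
    )


def pearson_matrix(m, subset=None) -> pd.DataFrame:
    """Pearson correlation of SNP code vectors across all samples.

    Every SNP in the subset must vary across samples (zero-variance columns
    have no defined correlation and raise, naming the SNP).
    """
    if isinstance(m, GenotypeMatrix):
        ids = list(subset) if subset is not None else list(m.snp_ids)
        X = np.asarray(m.codes, dtype=float)[:, m.snp_index(ids)]
    else:
        X = np.asarray(m, dtype=float)
        if subset is not None:
            X = X[:, np.asarray(subset, dtype=np.intp)]
        ids = [f"x{j}" for j in range(X.shape[1])]
    sd = X.std(axis=0)
    for j, s in enumerate(sd):
        if s == 0:
            raise ValueError(f"SNP {ids[j]!r} has zero variance; Pearson r undefined")
    r = np.corrcoef(X, rowvar=False)
    r = np.atleast_2d(r)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=ids, columns=ids)


def max_spanning_tree(corr: pd.DataFrame, minimum: bool = False) -> CorrelationTree:
    """Spanning tree extremizing the total absolute Pearson correlation.

    Kruskal's greedy algorithm on edge weight |r|, maximizing by default
    (``minimum=True`` gives the minimum variant). Ties between equal-weight
    edges break deterministically by the lexicographic (snp_a, snp_b) pair.
    The signed r is reported on each edge.
    """
    ids = [str(c) for c in corr.columns]
    n = len(ids)
    if n < 2:
        raise ValueError("spanning tree needs at least 2 nodes")
    r = corr.to_numpy()
    edges = []
    for a in range(n):
        for b in range(a + 1, n):
            ia, ib = sorted((ids[a], ids[b]))
            edges.append((abs(r[a, b]), ia, ib, r[a, b]))
    edges.sort(key=lambda e: ((e[0] if minimum else -e[0]), e[1], e[2]))

    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    chosen = []
    total = 0.0
    for w, a, b, signed in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
            chosen.append((a, b, float(signed)))
            total += w
            if len(chosen) == n - 1:
                break
    return CorrelationTree(nodes=tuple(ids), edges=tuple(chosen), total_weight=float(total))


def tree_to_networkx(tree: CorrelationTree):
    """Export a CorrelationTree as a networkx Graph (e.g. for GraphML output)."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(tree.nodes)
    for a, b, rr in tree.edges:
        g.add_edge(a, b, pearson_r=rr, weight=abs(rr))
    return g
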