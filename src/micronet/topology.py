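"""Topology of signed interaction networks and group comparison.

Per-node degree (number of significant links) and strength (sum of
absolute link weights) identify hub taxa (top 10% by degree); global
transitivity measures how often connected triples close into
triangles.  Observed topology is calibrated against a degree-preserving
rewiring null ensemble, and group differences are assessed with a
label-permutation test that rebuilds both networks from scratch for
every permutation.
"""

from __future__ import annotations

import logging
import math
import threading
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import networkx as nx
import numpy as np

from .core import AbundanceTable, relative_abundance
from .network import DEFAULT_ALPHA, SignedNetwork, spearman_matrix, threshold_network

logger = logging.getLogger(__name__)

__all__ = [
    "TopologySummary",
    "NullEnsemble",
    "degree_strength",
    "mean_interactions",
    "hubs",
    "transitivity",
    "summarize",
    "rewire_null",
    "compare_groups",
    "is_isomorphic",
]


@dataclass
class TopologySummary:
    taxon_ids: list[str]
    degree: np.ndarray
    strength: np.ndarray
    mean_interactions: float
    transitivity: float
    hub_set: list[str]


@dataclass
class NullEnsemble:
    """Observed statistic vs a randomized-network null distribution."""

    statistic: str
    observed: float
    null_values: np.ndarray
    swap_failed: bool = False

    @property
    def n_replicates(self) -> int:
        return self.null_values.size

    @property
    def z_score(self) -> float:
        sd = self.null_values.std(ddof=1) if self.n_replicates > 1 else 0.0
        if sd == 0:
            return 0.0 if self.observed == self.null_values.mean() else math.inf
        return float((self.observed - self.null_values.mean()) / sd)

    @property
    def p_value(self) -> float:
        """Empirical upper-tail p with +1 correction."""
        n = self.n_replicates
        return float((1 + np.sum(self.null_values >= self.observed)) / (n + 1))


def degree_strength(net: SignedNetwork) -> tuple[np.ndarray, np.ndarray]:
    """Per-node degree (count of nonzero weights) and strength (sum |w|)."""
    w = net.weights
    degree = (w != 0).sum(axis=1).astype(int)
    strength = np.abs(w).sum(axis=1)
    return degree, strength


def mean_interactions(net: SignedNetwork) -> float:
    """Average number of links per node, 2E/N."""
    n = net.n_nodes
    if n < 1:
        raise ValueError("network has no nodes")
    return 2.0 * net.n_edges / n


def hubs(net: SignedNetwork, fraction: float = 0.10) -> list[str]:
    """Top ``ceil(fraction * N)`` nodes by degree.

    Ties at the cutoff are broken by strength, then lexicographically
    by node id, so the hub set is deterministic and always has exactly
    ``ceil(fraction * N)`` members.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    degree, strength = degree_strength(net)
    k = math.ceil(fraction * net.n_nodes)
    order = sorted(
        range(net.n_nodes),
        key=lambda i: (-degree[i], -strength[i], net.taxon_ids[i]),
    )
    return [net.taxon_ids[i] for i in order[:k]]


def _binary_graph(net: SignedNetwork) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(net.taxon_ids)
    for a, b, w in net.edges():
        g.add_edge(a, b, weight=w, sign="+" if w > 0 else "-")
    return g


def transitivity(net: SignedNetwork) -> float:
    """Global clustering coefficient 3*triangles / connected triples.

    Computed on the binarized graph of the given view; edge signs are
    ignored within the view.  Returns 0 when no triples exist.
    """
    return float(nx.transitivity(_binary_graph(net)))


def summarize(net: SignedNetwork, hub_fraction: float = 0.10) -> TopologySummary:
    degree, strength = degree_strength(net)
    return TopologySummary(
        taxon_ids=list(net.taxon_ids),
        degree=degree,
        strength=strength,
        mean_interactions=mean_interactions(net),
        transitivity=transitivity(net),
        hub_set=hubs(net, hub_fraction),
    )


def _double_edge_swap(
    edges: list[tuple[int, int]],
    n_nodes: int,
    rng: np.random.Generator,
    n_swaps: int,
    max_tries: int,
) -> tuple[list[tuple[int, int]], int]:
    """Degree-preserving rewiring: swap (a,b),(c,d) -> (a,d),(c,b)."""
    edge_set = {frozenset(e) for e in edges}
    edges = [tuple(e) for e in edges]
    done = 0
    tries = 0
    m = len(edges)
    while done < n_swaps and tries < max_tries:
        tries += 1
        i, j = rng.integers(0, m, size=2)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if rng.random() < 0.5:
            c, d = d, c
        # new edges (a, d) and (c, b)
        if len({a, b, c, d}) < 4:
            continue
        e1, e2 = frozenset((a, d)), frozenset((c, b))
        if e1 in edge_set or e2 in edge_set:
            continue
        edge_set.discard(frozenset((a, b)))
        edge_set.discard(frozenset((c, d)))
        edge_set.add(e1)
        edge_set.add(e2)
        edges[i] = (a, d)
        edges[j] = (c, b)
        done += 1
    return edges, done


def rewire_null(
    net: SignedNetwork,
    statistics: Mapping[str, Callable[[SignedNetwork], float]] | None = None,
    n: int = 1000,
    seed: int | None = None,
) -> dict[str, NullEnsemble]:
    """Degree-preserving rewiring null for network-level statistics.

    Each replicate applies ``10 * E`` successful double-edge swaps to
    the binarized edge set (preserving every node's degree exactly) and
    re-assigns the original multiset of signed weights to the rewired
    edges in shuffled order.  Graphs admitting no swap (e.g. stars)
    yield replicates equal to the original, flagged on the result.
    """
    if statistics is None:
        statistics = {"transitivity": transitivity, "mean_strength": _mean_strength}
    m = net.n_edges
    if m < 2:
        raise ValueError("need at least 2 edges to rewire")
    rng = np.random.default_rng(seed)
    id_of = {t: i for i, t in enumerate(net.taxon_ids)}
    base_edges = [(id_of[a], id_of[b]) for a, b, _ in net.edges()]
    base_weights = np.array([w for _, _, w in net.edges()])

    observed = {name: fn(net) for name, fn in statistics.items()}
    nulls = {name: np.empty(n) for name in statistics}
    any_failed = False
    for r in range(n):
        new_edges, n_done = _double_edge_swap(
            base_edges, net.n_nodes, rng, n_swaps=10 * m, max_tries=100 * m
        )
        if n_done == 0:
            any_failed = True
        w = np.zeros_like(net.weights)
        perm = rng.permutation(m)
        for (i, j), wt in zip(new_edges, base_weights[perm]):
            w[i, j] = w[j, i] = wt
        replicate = SignedNetwork(list(net.taxon_ids), w, alpha=net.alpha)
        for name, fn in statistics.items():
            nulls[name][r] = fn(replicate)
    if any_failed:
        logger.warning("no valid double-edge swap found; null replicates equal the original network")
    return {
        name: NullEnsemble(
            statistic=name,
            observed=observed[name],
            null_values=nulls[name],
            swap_failed=any_failed,
        )
        for name in statistics
    }


def _mean_strength(net: SignedNetwork) -> float:
    return float(degree_strength(net)[1].mean())


def build_group_network(
    table: AbundanceTable,
    group: str,
    core_taxa: Sequence[str],
    alpha: float = DEFAULT_ALPHA,
) -> SignedNetwork:
    """Relative abundance on the group's samples -> Spearman -> threshold."""
    sub = table.subset_samples(table.samples_in_group(group))
    rel = relative_abundance(sub, list(core_taxa))
    return threshold_network(spearman_matrix(rel), alpha=alpha)


@dataclass
class GroupComparison:
    statistic: str
    observed_a: float
    observed_b: float
    observed_diff: float
    p_value: float
    p_adjusted: float
    n_perm: int


def compare_groups(
    table_a: AbundanceTable,
    table_b: AbundanceTable,
    core_taxa: Sequence[str],
    statistics: Mapping[str, Callable[[SignedNetwork], float]],
    n_perm: int = 1000,
    alpha: float = DEFAULT_ALPHA,
    seed: int | None = None,
) -> dict[str, GroupComparison]:
    """Permutation test for differences in network statistics.

    Group labels are shuffled across the pooled samples; both networks
    are rebuilt from scratch (relative abundance over the shared core,
    Spearman matrix, thresholding at ``alpha``) for every permutation,
    and the observed between-group difference of each statistic is
    compared with its permutation distribution (two-sided, +1
    corrected).  P-values are Bonferroni-adjusted over the number of
    statistics tested.
    """
    if n_perm < 100:
        logger.warning("n_perm=%d gives limited p-value resolution", n_perm)
    n_a, n_b = table_a.n_samples, table_b.n_samples
    if n_a < 4 or n_b < 4:
        raise ValueError("each group needs at least 4 samples")
    rng = np.random.default_rng(seed)

    def nets_for(counts_a, counts_b):
        rel_a = counts_a.loc[list(core_taxa)].astype(float).div(counts_a.sum(axis=0), axis=1)
        rel_b = counts_b.loc[list(core_taxa)].astype(float).div(counts_b.sum(axis=0), axis=1)
        net_a = threshold_network(spearman_matrix(rel_a), alpha=alpha)
        net_b = threshold_network(spearman_matrix(rel_b), alpha=alpha)
        return net_a, net_b

    net_a, net_b = nets_for(table_a.counts, table_b.counts)
    obs = {
        name: (fn(net_a), fn(net_b)) for name, fn in statistics.items()
    }

    pooled = table_a.counts.join(table_b.counts, how="outer").fillna(0).astype(np.int64)
    pooled = pooled.loc[
        [t for t in pooled.index if t in set(table_a.taxon_ids) | set(table_b.taxon_ids)]
    ]
    sample_ids = list(table_a.sample_ids) + list(table_b.sample_ids)
    null_diffs = {name: np.empty(n_perm) for name in statistics}
    for r in range(n_perm):
        perm = rng.permutation(len(sample_ids))
        ids_a = [sample_ids[i] for i in perm[:n_a]]
        ids_b = [sample_ids[i] for i in perm[n_a:]]
        pa, pb = nets_for(pooled[ids_a], pooled[ids_b])
        for name, fn in statistics.items():
            null_diffs[name][r] = fn(pa) - fn(pb)

    k = len(statistics)
    out = {}
    for name in statistics:
        oa, ob = obs[name]
        d = oa - ob
        p = float((1 + np.sum(np.abs(null_diffs[name]) >= abs(d) - 1e-15)) / (n_perm + 1))
        out[name] = GroupComparison(
            statistic=name,
            observed_a=oa,
            observed_b=ob,
            observed_diff=d,
            p_value=p,
            p_adjusted=min(1.0, p * k),
            n_perm=n_perm,
        )
    return out


def is_isomorphic(
    net_a: SignedNetwork, net_b: SignedNetwork, timeout: float | None = None
) -> bool | None:
    """Exact graph isomorphism of the binarized networks.

    Uses a degree-sequence pre-filter, then exact backtracking (VF2).
    With ``timeout`` (seconds), an unfinished search returns ``None``
    (inconclusive), distinct from ``False``.
    """
    ga, gb = _binary_graph(net_a), _binary_graph(net_b)
    if ga.number_of_nodes() != gb.number_of_nodes():
        return False
    if sorted(d for _, d in ga.degree()) != sorted(d for _, d in gb.degree()):
        return False
    if timeout is None:
        return bool(nx.is_isomorphic(ga, gb))
    result: list[bool] = []
    worker = threading.Thread(
        target=lambda: result.append(bool(nx.is_isomorphic(ga, gb))), daemon=True
    )
    worker.start()
    worker.join(timeout)
    if worker.is_alive():
        return None
    return result[0]
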