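"""Partitioning of the mapped module network.

Three algorithms, run on the same weighted graph so their partitions are
comparable:

* ``mcl`` — Markov clustering: simulate random-walk flow by alternating
  expansion (matrix power) and inflation (elementwise power + column
  renormalization) on the column-stochastic transition matrix until the
  flow stabilizes; clusters are read off the attractor structure.
* ``fn_cluster`` — agglomerative greedy modularity maximization
  (Newman-style fast greedy merging of community pairs by best delta-Q).
* ``spectral_cluster`` — normalized-Laplacian spectral clustering with the
  weighted adjacency as a precomputed affinity and deterministic
  discretization for label assignment.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
from networkx.algorithms.community import greedy_modularity_communities
from sklearn.cluster import SpectralClustering

from .containers import Partition, ValidationError


def _sorted_nodes(net: nx.Graph) -> list:
    return sorted(net.nodes)


def _adjacency(net: nx.Graph, nodes: list, weighted: bool = True) -> np.ndarray:
    a = nx.to_numpy_array(net, nodelist=nodes, weight="weight" if weighted else None)
    return a


# ----------------------------------------------------------------------- MCL

def mcl(net: nx.Graph, inflation: float = 1.2, expansion: int = 2,
        prune_threshold: float = 1e-5, max_iter: int = 200,
        tol: float = 1e-6, weighted: bool = True) -> Partition:
    """Markov clustering of the weighted graph.

    Self-loops are added with weight equal to the node's maximum incident
    edge weight (1 for isolated nodes) before column normalization. A node
    whose column is attracted to several attractor systems is assigned to
    the lowest cluster id.
    """
    if inflation <= 1:
        raise ValidationError("inflation must exceed 1")
    if expansion < 2 or int(expansion) != expansion:
        raise ValidationError("expansion must be an integer >= 2")
    nodes = _sorted_nodes(net)
    n = len(nodes)
    if n == 0:
        raise ValidationError("empty graph")
    m = _adjacency(net, nodes, weighted)
    loop = np.where(m.max(axis=1) > 0, m.max(axis=1), 1.0)
    np.fill_diagonal(m, loop)
    m = m / m.sum(axis=0, keepdims=True)

    converged = False
    for _ in range(max_iter):
        prev = m
        m = np.linalg.matrix_power(m, int(expansion))
        m = m ** inflation
        m /= m.sum(axis=0, keepdims=True)
        m[m < prune_threshold] = 0.0
        col = m.sum(axis=0, keepdims=True)
        col[col == 0] = 1.0
        m /= col
        if np.abs(m - prev).max() < tol:
            converged = True
            break
    if not converged:
        warnings.warn("MCL did not converge within max_iter; interpreting "
                      "the current flow matrix")

    # attractors: rows with positive diagonal flow; each attractor row's
    # support is one (part of a) cluster, overlapping supports merge
    support_eps = prune_threshold
    attractors = [i for i in range(n) if m[i, i] > support_eps]
    cluster_of = {}
    next_id = 1
    for i in attractors:
        members = set(np.flatnonzero(m[i] > support_eps))
        members.add(i)
        hit = sorted({cluster_of[j] for j in members if j in cluster_of})
        cid = hit[0] if hit else next_id
        if not hit:
            next_id += 1
        for j in members:
            cluster_of.setdefault(j, cid)
        if len(hit) > 1:  # merge overlapping attractor systems
            merged = set(hit[1:])
            cluster_of = {j: (hit[0] if c in merged else c)
                          for j, c in cluster_of.items()}
    for i in range(n):  # orphans (fully pruned columns) become singletons
        if i not in cluster_of:
            cluster_of[i] = next_id
            next_id += 1
    assignment = {nodes[i]: cluster_of[i] for i in range(n)}
    return Partition(_order_by_size(assignment), algorithm="mcl",
                     params={"inflation": inflation, "expansion": expansion},
                     converged=converged)


# ----------------------------------------------------- greedy modularity (FN)

def fn_cluster(net: nx.Graph, weighted: bool = True) -> Partition:
    """Greedy agglomerative modularity maximization: repeatedly merge the
    community pair with the largest modularity gain, return the partition
    at maximum Q."""
    if net.number_of_nodes() == 0:
        raise ValidationError("empty graph")
    if net.number_of_edges() == 0:
        warnings.warn("edgeless graph: every node is its own cluster (Q=0)")
        assignment = {node: i + 1 for i, node in enumerate(_sorted_nodes(net))}
        return Partition(assignment, algorithm="fn")
    communities = greedy_modularity_communities(
        net, weight="weight" if weighted else None)
    assignment = {node: cid for cid, comm in enumerate(communities, start=1)
                  for node in comm}
    return Partition(_order_by_size(assignment), algorithm="fn")


# ------------------------------------------------------------------ spectral

def spectral_cluster(net: nx.Graph, k: int, seed: int = 0,
                     weighted: bool = True) -> Partition:
    """Spectral clustering on the weighted adjacency as precomputed
    affinity with deterministic ("discretize") label assignment.

    A disconnected graph is clustered per connected component with ``k``
    apportioned across components by size (largest remainder, at least one
    cluster each).
    """
    n = net.number_of_nodes()
    if n == 0:
        raise ValidationError("empty graph")
    if k > n:
        raise ValidationError(f"k={k} exceeds node count {n}")
    if k < 2:
        raise ValidationError("k must be >= 2")
    comps = sorted(nx.connected_components(net), key=lambda c: (-len(c), min(c)))
    shares = _apportion(k, [len(c) for c in comps])
    assignment: dict = {}
    offset = 0
    for comp, k_c in zip(comps, shares):
        nodes = sorted(comp)
        if k_c >= len(nodes):
            labels = list(range(len(nodes)))
        elif k_c == 1 or len(nodes) < 3:
            labels = [0] * len(nodes)
        else:
            aff = _adjacency(net.subgraph(nodes), nodes, weighted)
            model = SpectralClustering(n_clusters=k_c, affinity="precomputed",
                                       assign_labels="discretize",
                                       random_state=seed)
            labels = model.fit_predict(aff)
        for node, lab in zip(nodes, labels):
            assignment[node] = offset + int(lab) + 1
        offset += int(max(labels)) + 1
    return Partition(_order_by_size(assignment), algorithm="spectral",
                     params={"k": k, "seed": seed})


def _apportion(k: int, sizes: list[int]) -> list[int]:
    """Largest-remainder split of k clusters over components, >=1 each."""
    total = sum(sizes)
    quotas = [k * s / total for s in sizes]
    shares = [max(1, int(q)) for q in quotas]
    while sum(shares) < k:
        rema = [(q - s, -i) for i, (q, s) in enumerate(zip(quotas, shares))]
        i = -max(rema)[1]
        shares[i] += 1
    return [min(s, size) for s, size in zip(shares, sizes)]


def _order_by_size(assignment: dict) -> dict:
    """Relabel clusters 1..K by decreasing size, ties by smallest member."""
    groups: dict = {}
    for node, cid in assignment.items():
        groups.setdefault(cid, []).append(node)
    order = sorted(groups, key=lambda c: (-len(groups[c]), min(groups[c])))
    remap = {old: new for new, old in enumerate(order, start=1)}
    return {node: remap[cid] for node, cid in assignment.items()}
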