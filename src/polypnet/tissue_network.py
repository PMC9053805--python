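"""Tissue-specific functional interaction network construction and the
mapping of selected co-expression module genes onto it.

The raw functional network keeps an edge only when its functional-similarity
weight exceeds ``min_weight`` (default 0.1 — the lowest-similarity band is
discarded), keeps only nodes on the tissue-expressed gene list, and drops
isolated nodes. Downstream analysis continues on the largest connected
component. Module genes are mapped as the induced (order-0) subgraph: only
genes directly adjacent to another module gene survive; one-hop neighbor
expansion is available but off by default.
"""

from __future__ import annotations

import networkx as nx

from .containers import ValidationError, check_weighted_network


def filter_network(net: nx.Graph, min_weight: float = 0.1,
                   tissue_genes: set | None = None) -> nx.Graph:
    """Drop edges with weight <= ``min_weight``, then nodes outside
    ``tissue_genes`` (with incident edges), then isolated nodes."""
    if not 0 <= min_weight < 1:
        raise ValidationError("min_weight must lie in [0,1)")
    check_weighted_network(net)
    out = nx.Graph()
    keep = None if tissue_genes is None else set(tissue_genes)
    for u, v, data in net.edges(data=True):
        if data["weight"] <= min_weight:
            continue
        if keep is not None and (u not in keep or v not in keep):
            continue
        out.add_edge(u, v, weight=data["weight"])
    if out.number_of_nodes() == 0:
        raise ValidationError("network empty after weight/tissue filtering")
    return out


def largest_component(net: nx.Graph) -> nx.Graph:
    """Subgraph on the largest connected component; ties broken by the
    smallest lexicographic node id in the component."""
    if net.number_of_nodes() == 0:
        raise ValidationError("empty network")
    comps = sorted(nx.connected_components(net),
                   key=lambda c: (-len(c), min(c)))
    return net.subgraph(comps[0]).copy()


def component_count(net: nx.Graph) -> int:
    return nx.number_connected_components(net)


def induced_submodule(net: nx.Graph, module_genes: set,
                      expand_neighbors: bool = False) -> nx.Graph:
    """Subgraph induced on ``module_genes`` with isolated nodes dropped,
    so only genes directly connected to another kept gene remain.

    ``expand_neighbors=True`` first grows the gene set by one network hop
    (order-1 ego expansion) before inducing.
    """
    if not module_genes:
        raise ValidationError("module gene set is empty")
    present = set(module_genes) & set(net.nodes)
    if not present:
        raise ValidationError("no module gene occurs in the network")
    if expand_neighbors:
        present = present | {nbr for g in present for nbr in net.neighbors(g)}
    sub = net.subgraph(present).copy()
    sub.remove_nodes_from([n for n, d in sub.degree() if d == 0])
    if sub.number_of_nodes() == 0:
        raise ValidationError("no module genes are directly connected in the network")
    return sub
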