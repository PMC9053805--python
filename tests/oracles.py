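"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately avoid the library code paths they check: modularity by an
explicit double loop over ordered node pairs, silhouette from BFS hop
distances, BHI by ordered-pair enumeration, Wang S-values by recursive
ancestor-path enumeration, the hypergeometric tail from binomial
coefficients, and BH by the literal step-up definition.
"""

import math

import networkx as nx
import numpy as np


def modularity_oracle(graph: nx.Graph, assignment: dict) -> float:
    nodes = sorted(graph.nodes)
    a = nx.to_numpy_array(graph, nodelist=nodes, weight=None)
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    two_m = k.sum()
    q = 0.0
    for i in range(len(nodes)):
        for j in range(len(nodes)):
            if assignment[nodes[i]] == assignment[nodes[j]]:
                q += a[i, j] - k[i] * k[j] / two_m
    return q / two_m


def bfs_hops(graph: nx.Graph, source):
    dist = {source: 0}
    frontier = [source]
    while frontier:
        nxt = []
        for node in frontier:
            for nbr in graph.neighbors(node):
                if nbr not in dist:
                    dist[nbr] = dist[node] + 1
                    nxt.append(nbr)
        frontier = nxt
    return dist


def silhouette_oracle(graph: nx.Graph, assignment: dict):
    nodes = sorted(graph.nodes)
    n = len(nodes)
    dist = {}
    for u in nodes:
        hops = bfs_hops(graph, u)
        for v in nodes:
            dist[u, v] = hops.get(v, n)
    scores = []
    for u in nodes:
        own = [v for v in nodes if v != u and assignment[v] == assignment[u]]
        if not own:
            scores.append(0.0)
            continue
        a = sum(dist[u, v] for v in own) / len(own)
        b = min(sum(dist[u, v] for v in nodes if assignment[v] == c)
                / sum(1 for v in nodes if assignment[v] == c)
                for c in set(assignment.values()) if c != assignment[u])
        scores.append((b - a) / max(a, b))
    return sum(scores) / len(scores), dict(zip(nodes, scores))


def bhi_oracle(assignment: dict, gene_classes: dict) -> float:
    clusters = {}
    for gene, cid in assignment.items():
        clusters.setdefault(cid, []).append(gene)
    vals = []
    for members in clusters.values():
        annotated = [g for g in members if gene_classes.get(g)]
        if len(annotated) < 2:
            continue
        total = 0
        for gi in annotated:
            for gj in annotated:
                if gi != gj and gene_classes[gi] & gene_classes[gj]:
                    total += 1
        vals.append(total / (len(annotated) * (len(annotated) - 1)))
    return sum(vals) / len(vals)


def wang_svalues_oracle(dag: nx.DiGraph, term: str,
                        weights=None) -> dict:
    """S-values by exhaustive enumeration of all upward paths."""
    weights = weights or {"is_a": 0.8, "part_of": 0.6}
    s = {}

    def walk(node, value):
        if value > s.get(node, 0.0):
            s[node] = value
        for parent in dag.successors(node):
            rel = dag.edges[node, parent]["relation"]
            walk(parent, value * weights[rel])

    walk(term, 1.0)
    return s


def wang_term_sim_oracle(dag: nx.DiGraph, a: str, b: str) -> float:
    sa = wang_svalues_oracle(dag, a)
    sb = wang_svalues_oracle(dag, b)
    common = set(sa) & set(sb)
    if not common:
        return 0.0
    return (sum(sa[t] + sb[t] for t in common)
            / (sum(sa.values()) + sum(sb.values())))


def wang_gene_sim_oracle(dag: nx.DiGraph, terms_a, terms_b) -> float:
    terms_a, terms_b = sorted(set(terms_a)), sorted(set(terms_b))
    best_a = [max(wang_term_sim_oracle(dag, t, s) for s in terms_b)
              for t in terms_a]
    best_b = [max(wang_term_sim_oracle(dag, t, s) for s in terms_a)
              for t in terms_b]
    return (sum(best_a) + sum(best_b)) / (len(terms_a) + len(terms_b))


def hypergeom_tail_oracle(overlap: int, universe: int, set_size: int,
                          query: int) -> float:
    """P(X >= overlap) by direct summation of binomial coefficients."""
    total = 0
    for x in range(overlap, min(set_size, query) + 1):
        total += math.comb(set_size, x) * math.comb(universe - set_size,
                                                    query - x)
    return total / math.comb(universe, query)


def bh_oracle(p):
    """Literal BH step-up: adjusted p_(i) = min over j>=i of p_(j) m / j."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adjusted[i] = running
    return adjusted


def random_dag(rng, n_terms: int = 12, n_roots: int = 1) -> nx.DiGraph:
    """Random layered DAG with mixed relations."""
    dag = nx.DiGraph()
    terms = [f"t{i}" for i in range(n_terms)]
    for i, term in enumerate(terms):
        dag.add_node(term, namespace="BP")
        if i < n_roots:
            continue
        n_parents = 1 + int(rng.random() < 0.3)
        parents = rng.choice(i, size=min(n_parents, i), replace=False)
        for p in np.atleast_1d(parents):
            rel = "is_a" if rng.random() < 0.8 else "part_of"
            dag.add_edge(term, terms[int(p)], relation=rel)
    return dag
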