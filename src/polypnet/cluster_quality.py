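"""Internal and biological scoring of network partitions.

* Modularity Q: excess of intra-cluster edges over the degree-preserving
  random expectation, summed over all ordered node pairs (A_ii = 0). Binary
  adjacency by default for scoring parity; a weighted variant is available.
* Silhouette S(u): mean over nodes of (b-a)/max(a,b) with unweighted
  shortest-path hop distance; disconnected pairs get distance n (the node
  count) and singleton clusters score 0.
* BHI: probability that two annotated genes of the same cluster share at
  least one functional class, averaged over clusters with >=2 annotated
  genes.
* Wang semantic similarity: DAG-topology term similarity with relation
  weights 0.8 (is_a) / 0.6 (part_of), aggregated gene-to-gene by
  best-match average, per ontology namespace (BP, MF).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import networkx as nx
import numpy as np
import pandas as pd

from .containers import Partition, ValidationError

WANG_RELATION_WEIGHTS = {"is_a": 0.8, "part_of": 0.6}


# ---------------------------------------------------------------- modularity

def modularity(net: nx.Graph, part: Partition, weighted: bool = False) -> float:
    """Q = (1/2m) sum_ij (A_ij - k_i k_j / 2m) delta(c_i, c_j)."""
    if not part.covers(net):
        raise ValidationError("partition does not cover the graph's nodes")
    weight = "weight" if weighted else None
    two_m = sum(d for _, d in net.degree(weight=weight))
    if two_m == 0:
        raise ValidationError("graph has no edges")
    q = 0.0
    degree = dict(net.degree(weight=weight))
    for members in part.clusters().values():
        member_set = set(members)
        internal = sum(data.get("weight", 1.0) if weighted else 1.0
                       for u, v, data in net.edges(members, data=True)
                       if v in member_set and u in member_set)
        total_degree = sum(degree[u] for u in members)
        q += 2.0 * internal / two_m - (total_degree / two_m) ** 2
    return q


# ---------------------------------------------------------------- silhouette

def hop_distance_matrix(net: nx.Graph, nodes: list) -> np.ndarray:
    """Unweighted shortest-path lengths; disconnected pairs set to n."""
    n = len(nodes)
    index = {node: i for i, node in enumerate(nodes)}
    dist = np.full((n, n), float(n))
    np.fill_diagonal(dist, 0.0)
    for source, lengths in nx.all_pairs_shortest_path_length(net):
        i = index[source]
        for target, d in lengths.items():
            dist[i, index[target]] = float(d)
    return dist


def silhouette_index(net: nx.Graph, part: Partition,
                     distance: np.ndarray | None = None):
    """Returns (S(u), per-node S(i) series). ``distance`` may supply an
    alternative precomputed matrix (e.g. 1-TOM) over sorted nodes."""
    if not part.covers(net):
        raise ValidationError("partition does not cover the graph's nodes")
    if part.n_clusters < 2:
        raise ValidationError("silhouette requires >=2 clusters")
    nodes = sorted(net.nodes)
    dist = hop_distance_matrix(net, nodes) if distance is None else distance
    labels = np.array([part.assignment[node] for node in nodes])
    s = np.zeros(len(nodes))
    for i in range(len(nodes)):
        own = labels == labels[i]
        own[i] = False
        if not own.any():  # singleton convention
            s[i] = 0.0
            continue
        a = dist[i, own].mean()
        b = min(dist[i, labels == other].mean()
                for other in set(labels) if other != labels[i])
        s[i] = (b - a) / max(a, b)
    return float(s.mean()), pd.Series(s, index=nodes)


# ----------------------------------------------------------------------- BHI

def bhi(part: Partition, gene_classes: dict) -> float:
    """Biological Homogeneity Index over clusters with >=2 annotated genes;
    genes without any functional class are excluded."""
    scores = []
    for members in part.clusters().values():
        annotated = [g for g in members if gene_classes.get(g)]
        n_k = len(annotated)
        if n_k < 2:
            continue
        hits = sum(1 for i in range(n_k) for j in range(n_k) if i != j
                   and gene_classes[annotated[i]] & gene_classes[annotated[j]])
        scores.append(hits / (n_k * (n_k - 1)))
    if not scores:
        raise ValidationError("no cluster has >=2 annotated genes")
    return float(np.mean(scores))


# ----------------------------------------------------------------- Wang sim

class WangSimilarity:
    """Wang DAG-based semantic similarity with cached term S-values.

    ``annotations`` maps namespace -> gene -> term set; term namespaces are
    read from the DAG's node attributes when restricting a computation.
    """

    def __init__(self, dag: nx.DiGraph,
                 relation_weights: dict | None = None) -> None:
        if not nx.is_directed_acyclic_graph(dag):
            raise ValidationError("ontology must be acyclic")
        self.dag = dag
        self.weights = dict(relation_weights or WANG_RELATION_WEIGHTS)
        self._svalues = lru_cache(maxsize=None)(self._svalues_uncached)
        self._term_sim = lru_cache(maxsize=None)(self._term_sim_uncached)

    def _svalues_uncached(self, term: str) -> tuple:
        if term not in self.dag:
            raise ValidationError(f"term {term!r} not in the ontology")
        # max-product propagation upward; relation weights < 1 make this a
        # Dijkstra-style relaxation over the ancestor closure
        s = {term: 1.0}
        import heapq
        heap = [(-1.0, term)]
        while heap:
            neg, t = heapq.heappop(heap)
            if -neg < s.get(t, 0.0):
                continue
            for parent in self.dag.successors(t):
                rel = self.dag.edges[t, parent].get("relation", "is_a")
                w = self.weights.get(rel)
                if w is None:
                    raise ValidationError(f"unknown relation {rel!r}")
                cand = -neg * w
                if cand > s.get(parent, 0.0):
                    s[parent] = cand
                    heapq.heappush(heap, (-cand, parent))
        return tuple(sorted(s.items()))

    def term_similarity(self, a: str, b: str) -> float:
        if a > b:
            a, b = b, a
        return self._term_sim(a, b)

    def _term_sim_uncached(self, a: str, b: str) -> float:
        sa, sb = dict(self._svalues(a)), dict(self._svalues(b))
        common = set(sa) & set(sb)
        if not common:
            return 0.0
        return sum(sa[t] + sb[t] for t in common) / (sum(sa.values()) + sum(sb.values()))

    def gene_similarity(self, terms_a, terms_b) -> float:
        """Best-match average between two term sets."""
        terms_a, terms_b = sorted(set(terms_a)), sorted(set(terms_b))
        if not terms_a or not terms_b:
            raise ValidationError("gene without annotations in this namespace")
        best_a = [max(self.term_similarity(t, s) for s in terms_b) for t in terms_a]
        best_b = [max(self.term_similarity(t, s) for s in terms_a) for t in terms_b]
        return (sum(best_a) + sum(best_b)) / (len(terms_a) + len(terms_b))


def wang_similarity(dag: nx.DiGraph, annotations: dict, gene_a: str,
                    gene_b: str, namespace: str = "BP") -> float:
    """Wang similarity of two genes within one namespace; errors if either
    gene carries no annotation there."""
    per_gene = annotations.get(namespace, {})
    if gene_a not in per_gene or gene_b not in per_gene:
        raise ValidationError("both genes must be annotated in the namespace")
    return WangSimilarity(dag).gene_similarity(per_gene[gene_a], per_gene[gene_b])


def mean_pairwise_wang(calc: WangSimilarity, genes, per_gene: dict) -> float:
    """Mean best-match-average similarity over unordered annotated pairs;
    NaN when fewer than two genes are annotated."""
    annotated = [g for g in genes if per_gene.get(g)]
    if len(annotated) < 2:
        return float("nan")
    sims = [calc.gene_similarity(per_gene[a], per_gene[b])
            for i, a in enumerate(annotated) for b in annotated[i + 1:]]
    return float(np.mean(sims))


# -------------------------------------------------------------------- report

@dataclass
class MetricReport:
    algorithm: str
    q: float
    silhouette: float
    per_cluster: pd.DataFrame  # cluster, size, n_annotated, bhi, wang_bp,
    #                            wang_mf, n_down, n_up


def evaluate_partition(net: nx.Graph, part: Partition, dag: nx.DiGraph,
                       annotations: dict, up_genes: set, down_genes: set,
                       gene_classes: dict | None = None) -> MetricReport:
    """Partition-level Q and S(u) plus per-submodule biological scores and
    up/down DEG counts. ``gene_classes`` (for BHI) defaults to the pooled
    annotation terms of each gene."""
    if gene_classes is None:
        gene_classes = {}
        for per_gene in annotations.values():
            for gene, terms in per_gene.items():
                gene_classes.setdefault(gene, set()).update(terms)
    calc = WangSimilarity(dag)
    q = modularity(net, part)
    s_u = silhouette_index(net, part)[0] if part.n_clusters >= 2 else float("nan")
    rows = []
    for cid, members in part.clusters().items():
        annotated = [g for g in members if gene_classes.get(g)]
        single = Partition({g: 1 for g in members})
        try:
            cluster_bhi = bhi(single, gene_classes)
        except ValidationError:
            cluster_bhi = float("nan")
        rows.append({
            "cluster": cid,
            "size": len(members),
            "n_annotated": len(annotated),
            "bhi": cluster_bhi,
            "wang_bp": mean_pairwise_wang(calc, members, annotations.get("BP", {})),
            "wang_mf": mean_pairwise_wang(calc, members, annotations.get("MF", {})),
            "n_down": len(set(members) & set(down_genes)),
            "n_up": len(set(members) & set(up_genes)),
        })
    return MetricReport(algorithm=part.algorithm, q=q, silhouette=s_u,
                        per_cluster=pd.DataFrame(rows).set_index("cluster"))
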