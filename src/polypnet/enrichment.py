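"""Over-representation analysis of submodule genes and the term-gene graph.

The test is the one-sided hypergeometric tail P(X >= overlap) against the
analysis universe (by default the genes on the expression matrix, not the
whole genome), with Benjamini-Hochberg adjustment within each collection;
terms with FDR <= 0.05 (inclusive, as distinct from the strict DEG cut)
are significant. The enriched-term / gene relationships are exported as a
bipartite node-link graph with DEG directions on the gene nodes.
"""

from __future__ import annotations

import networkx as nx
import pandas as pd
from scipy import stats

from .containers import ValidationError
from .diff_expression import benjamini_hochberg


def ora(query: set, collections: dict, universe: set,
        fdr_threshold: float = 0.05) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` against gene-set
    ``collections``: either {name: (description, members)} (single
    collection) or {collection: {name: (description, members)}}.

    Returns a table with one row per set: overlap, sizes, p, fdr,
    significant (fdr <= threshold); BH runs within each collection.
    """
    if not query:
        raise ValidationError("empty query gene set")
    if not universe:
        raise ValidationError("empty universe")
    stray = set(query) - set(universe)
    if stray:
        raise ValidationError(f"query genes outside universe: {sorted(stray)[:5]}")
    if collections and isinstance(next(iter(collections.values())), tuple):
        collections = {"sets": collections}

    frames = []
    n_universe = len(universe)
    n_query = len(query)
    for coll_name, sets in collections.items():
        rows = []
        for name, (description, members) in sorted(sets.items()):
            members = set(members) & set(universe)
            if not members:
                continue
            overlap = sorted(query & members)
            # P(X >= k) with population N, successes K, draws n
            p = float(stats.hypergeom.sf(len(overlap) - 1, n_universe,
                                         len(members), n_query))
            rows.append({"term": name, "name": description,
                         "collection": coll_name,
                         "overlap_genes": overlap, "overlap": len(overlap),
                         "set_size": len(members), "query_size": n_query,
                         "universe_size": n_universe, "p": min(p, 1.0)})
        if rows:
            frame = pd.DataFrame(rows)
            frame["fdr"] = benjamini_hochberg(frame["p"].to_numpy())
            frames.append(frame)
    if not frames:
        raise ValidationError("no gene set intersects the universe")
    table = pd.concat(frames, ignore_index=True)
    table["significant"] = table["fdr"] <= fdr_threshold
    return table.sort_values(["collection", "fdr", "term"]).reset_index(drop=True)


def term_gene_graph(enrichment: pd.DataFrame,
                    directions: pd.Series) -> nx.Graph:
    """Bipartite graph of significant terms and their overlap genes; gene
    nodes carry an up/down/ns ``direction`` attribute."""
    significant = enrichment[enrichment["significant"]]
    if significant.empty:
        raise ValidationError("no significant term to draw")
    graph = nx.Graph()
    for row in significant.itertuples(index=False):
        graph.add_node(row.term, kind="term", collection=row.collection,
                       fdr=float(row.fdr))
        for gene in row.overlap_genes:
            direction = directions.get(gene, "ns") if directions is not None else "ns"
            graph.add_node(gene, kind="gene", direction=direction)
            graph.add_edge(row.term, gene)
    return graph


def graph_to_node_link(graph: nx.Graph) -> dict:
    return {
        "nodes": [{"id": n, **graph.nodes[n]} for n in sorted(graph.nodes)],
        "links": [{"source": min(u, v), "target": max(u, v)}
                  for u, v in sorted((min(u, v), max(u, v))
                                     for u, v in graph.edges)],
    }


def graph_to_dot(graph: nx.Graph) -> str:
    """Minimal DOT export: term nodes boxed, gene nodes colored by
    direction (up=red, down=green)."""
    colors = {"up": "red", "down": "green", "ns": "gray"}
    lines = ["graph term_gene {"]
    for node in sorted(graph.nodes):
        attrs = graph.nodes[node]
        if attrs.get("kind") == "term":
            lines.append(f'  "{node}" [shape=box];')
        else:
            color = colors.get(attrs.get("direction", "ns"), "gray")
            lines.append(f'  "{node}" [shape=ellipse, color={color}];')
    for u, v in sorted((min(u, v), max(u, v)) for u, v in graph.edges):
        lines.append(f'  "{u}" -- "{v}";')
    lines.append("}")
    return "\n".join(lines)
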