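"""Readers and writers for the plain-text interchange formats.

All tabular formats are TSV. Networks travel as three-column edge lists
(gene_a, gene_b, weight); ontologies as (child_term, parent_term, relation)
plus a (gene_id, term_id[, namespace]) annotation table; gene-set collections
as standard GMT (name, description, tab-separated members).
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd

from .containers import (
    ExpressionMatrix,
    ProbeMatrix,
    SampleMetadata,
    ValidationError,
    check_weighted_network,
)

NA_TOKEN = "NA"


# ---------------------------------------------------------------- expression

def read_metadata(path) -> SampleMetadata:
    table = pd.read_csv(path, sep="\t", index_col="sample_id", dtype=str)
    return SampleMetadata(table)


def write_metadata(meta: SampleMetadata, path) -> None:
    meta.table.to_csv(path, sep="\t", index_label="sample_id")


def read_probe_matrix(values_path, annotation_path, metadata_path) -> ProbeMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    ann = pd.read_csv(annotation_path, sep="\t", dtype=str,
                      keep_default_na=False)
    probe_to_gene = ann.set_index("probe_id")["gene_id"].replace(NA_TOKEN, pd.NA)
    return ProbeMatrix(values, probe_to_gene, read_metadata(metadata_path))


def write_probe_matrix(pm: ProbeMatrix, values_path, annotation_path) -> None:
    pm.values.to_csv(values_path, sep="\t", index_label="probe_id", float_format="%.6f")
    ann = pm.probe_to_gene.fillna(NA_TOKEN)
    ann.rename("gene_id").to_csv(annotation_path, sep="\t", index_label="probe_id")


def read_expression(values_path, metadata_path) -> ExpressionMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    return ExpressionMatrix(values, read_metadata(metadata_path))


def write_expression(em: ExpressionMatrix, path) -> None:
    em.values.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6f")


# ------------------------------------------------------------------ networks

def read_edge_list(path) -> nx.Graph:
    table = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    graph = nx.Graph()
    for a, b, w in table[["gene_a", "gene_b", "weight"]].itertuples(index=False):
        graph.add_edge(a, b, weight=float(w))
    return check_weighted_network(graph)


def write_edge_list(graph: nx.Graph, path) -> None:
    rows = sorted((min(u, v), max(u, v), d["weight"])
                  for u, v, d in graph.edges(data=True))
    table = pd.DataFrame(rows, columns=["gene_a", "gene_b", "weight"])
    table.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_gene_list(path) -> set[str]:
    lines = Path(path).read_text().splitlines()
    return {line.strip() for line in lines if line.strip()}


def write_gene_list(genes, path) -> None:
    Path(path).write_text("\n".join(sorted(genes)) + "\n")


def read_partition(path) -> dict:
    table = pd.read_csv(path, sep="\t", dtype={"node": str})
    return dict(zip(table["node"], table["cluster"].astype(int)))


def write_partition(assignment: dict, path) -> None:
    table = pd.DataFrame(sorted(assignment.items()), columns=["node", "cluster"])
    table.to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------------ ontology

def read_ontology(path) -> nx.DiGraph:
    """Child -> parent DAG with a ``relation`` attribute per edge and a
    ``namespace`` attribute per term (carried on the node)."""
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    dag = nx.DiGraph()
    for row in table.itertuples(index=False):
        dag.add_node(row.child_term, namespace=row.namespace)
        if row.parent_term != NA_TOKEN:
            dag.add_node(row.parent_term, namespace=row.namespace)
            dag.add_edge(row.child_term, row.parent_term, relation=row.relation)
    if not nx.is_directed_acyclic_graph(dag):
        raise ValidationError("ontology file contains a cycle")
    return dag


def write_ontology(dag: nx.DiGraph, path) -> None:
    rows = []
    for term in sorted(dag.nodes):
        ns = dag.nodes[term].get("namespace", "BP")
        parents = list(dag.successors(term))
        if not parents:
            rows.append((term, NA_TOKEN, NA_TOKEN, ns))
        for parent in sorted(parents):
            rows.append((term, parent, dag.edges[term, parent]["relation"], ns))
    pd.DataFrame(rows, columns=["child_term", "parent_term", "relation", "namespace"]) \
        .to_csv(path, sep="\t", index=False)


def read_annotations(path) -> dict:
    """gene -> set of term ids (all namespaces pooled; the DAG knows the
    namespace of each term)."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    out: dict = {}
    for gene, term in table[["gene_id", "term_id"]].itertuples(index=False):
        out.setdefault(gene, set()).add(term)
    return out


def write_annotations(annotations: dict, path) -> None:
    rows = [(g, t) for g in sorted(annotations) for t in sorted(annotations[g])]
    pd.DataFrame(rows, columns=["gene_id", "term_id"]).to_csv(path, sep="\t", index=False)


# ----------------------------------------------------------------------- GMT

def read_gmt(path) -> dict:
    """name -> (description, member set)."""
    sets: dict = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValidationError(f"malformed GMT line: {line[:60]!r}")
        name, description, members = parts[0], parts[1], parts[2:]
        sets[name] = (description, {m for m in members if m})
    return sets


def write_gmt(sets: dict, path) -> None:
    lines = []
    for name in sorted(sets):
        description, members = sets[name]
        lines.append("\t".join([name, description, *sorted(members)]))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------- JSON

def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonable))


def read_json(path):
    return json.loads(Path(path).read_text())


def _jsonable(obj):
    import numpy as np

    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
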