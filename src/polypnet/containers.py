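"""Core in-memory containers shared across pipeline stages.

Expression data travels as a genes x samples :class:`~pandas.DataFrame` of
log2 intensities together with per-sample metadata (phenotype, batch).
Networks are :class:`networkx.Graph` objects with a ``weight`` attribute on
every edge; partitions are plain ``node -> cluster id`` mappings wrapped with
provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

PHENOTYPES = ("normal", "polyp")
#: phenotype coding used everywhere downstream: normal=0, polyp=1
PHENOTYPE_CODE = {"normal": 0, "polyp": 1}


class ValidationError(ValueError):
    """An input violated a structural precondition."""


@dataclass
class SampleMetadata:
    """Per-sample annotations: phenotype in {normal, polyp} and batch label."""

    table: pd.DataFrame  # index: sample_id; columns: phenotype, batch

    def __post_init__(self) -> None:
        required = {"phenotype", "batch"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"metadata missing columns: {sorted(missing)}")
        bad = set(self.table["phenotype"]) - set(PHENOTYPES)
        if bad:
            raise ValidationError(f"unknown phenotypes: {sorted(bad)}")
        if self.table["batch"].isna().any() or self.table["phenotype"].isna().any():
            raise ValidationError("metadata contains missing phenotype/batch values")
        if self.table.index.duplicated().any():
            raise ValidationError("duplicate sample ids in metadata")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def phenotype_code(self) -> pd.Series:
        """Numeric phenotype: normal=0, polyp=1."""
        return self.table["phenotype"].map(PHENOTYPE_CODE).astype(float)

    def subset(self, sample_ids) -> "SampleMetadata":
        return SampleMetadata(self.table.loc[list(sample_ids)].copy())


@dataclass
class ProbeMatrix:
    """Probe-level log2 matrix with a probe -> gene annotation map.

    ``probe_to_gene`` may contain NA for unannotated probes; those rows are
    removed during aggregation.
    """

    values: pd.DataFrame  # probes x samples
    probe_to_gene: pd.Series  # index: probe_id, values: gene_id or NA
    metadata: SampleMetadata

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValidationError("duplicate probe ids")
        unknown = set(self.values.columns) - set(self.metadata.sample_ids)
        if unknown:
            raise ValidationError(f"samples absent from metadata: {sorted(unknown)[:5]}")
        missing_probes = set(self.values.index) - set(self.probe_to_gene.index)
        if missing_probes:
            raise ValidationError(
                f"probes without annotation rows: {sorted(missing_probes)[:5]}"
            )


@dataclass
class ExpressionMatrix:
    """Gene-level log2 expression (genes x samples) plus sample metadata."""

    values: pd.DataFrame
    metadata: SampleMetadata

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValidationError("duplicate gene ids")
        if list(self.values.columns) != self.metadata.sample_ids:
            # column order must match the metadata order exactly
            if set(self.values.columns) == set(self.metadata.sample_ids):
                self.values = self.values[self.metadata.sample_ids]
            else:
                raise ValidationError("expression columns do not match metadata samples")
        if not all(pd.api.types.is_float_dtype(d) or pd.api.types.is_integer_dtype(d)
                   for d in self.values.dtypes):
            raise ValidationError("expression values must be numeric")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes) -> "ExpressionMatrix":
        keep = [g for g in self.values.index if g in set(genes)]
        return ExpressionMatrix(self.values.loc[keep].copy(), self.metadata)


@dataclass
class Partition:
    """Node -> dense 1..K cluster assignment with provenance."""

    assignment: dict
    algorithm: str = ""
    params: dict = field(default_factory=dict)
    converged: bool = True

    def __post_init__(self) -> None:
        self.assignment = dict(self.assignment)
        ids = sorted(set(self.assignment.values()))
        if ids and ids != list(range(1, len(ids) + 1)):
            remap = {c: i + 1 for i, c in enumerate(ids)}
            self.assignment = {n: remap[c] for n, c in self.assignment.items()}

    @property
    def n_clusters(self) -> int:
        return len(set(self.assignment.values()))

    def clusters(self) -> dict:
        """cluster id -> sorted member list."""
        out: dict = {}
        for node, cid in self.assignment.items():
            out.setdefault(cid, []).append(node)
        return {cid: sorted(members) for cid, members in sorted(out.items())}

    def covers(self, graph: nx.Graph) -> bool:
        return set(self.assignment) == set(graph.nodes)


def check_weighted_network(graph: nx.Graph) -> nx.Graph:
    """Validate the functional-network contract: undirected simple graph,
    no self-loops, every edge weight in (0, 1]."""
    if graph.is_directed() or graph.is_multigraph():
        raise ValidationError("network must be a simple undirected graph")
    for u, v, data in graph.edges(data=True):
        if u == v:
            raise ValidationError(f"self-loop at {u}")
        w = data.get("weight")
        if w is None or not (0 < w <= 1):
            raise ValidationError(f"edge ({u},{v}) weight {w!r} outside (0,1]")
    return graph
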