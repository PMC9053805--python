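"""Ground-truthed synthetic inputs for the whole pipeline.

The generator emulates the statistical structure the analysis assumes:

* a multi-batch log2-intensity cohort (normal vs polyp) built from a
  latent-factor model — each planted co-expression module has one factor per
  sample whose correlation with the phenotype is controlled directly
  (``eigen_effect``), per-gene loadings, planted differential-expression
  shifts, and ComBat-style additive/multiplicative batch effects;
* probe-level replication on top of the gene values (1..k probes per gene,
  a configurable fraction left unannotated) to exercise the median
  aggregation and NA-drop rules;
* a planted-partition weighted functional network whose first communities
  coincide with the planted expression modules;
* a small two-namespace (BP/MF) ontology DAG whose branches concentrate on
  the planted communities, with gene annotations and derived GMT gene sets;
* a compound-target-action table seeded with correct and decoy action types.

Everything is driven by one integer seed; fixed per-artifact offsets keep the
individual generators independently reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import io
from .containers import (
    PHENOTYPE_CODE,
    ExpressionMatrix,
    ProbeMatrix,
    SampleMetadata,
    ValidationError,
)

NAMESPACES = ("BP", "MF")

# substream offsets applied to SimConfig.seed so each artifact has its own
# reproducible stream
_OFFSET = {"cohort": 0, "network": 1, "ontology": 2, "tissue": 3, "compounds": 4}


# ------------------------------------------------------------------- configs

@dataclass
class PlantedModule:
    """A co-expressed gene module with a phenotype-linked latent factor."""

    name: str
    member_genes: list[str]
    eigen_effect: float = 0.6           # |cor(factor, phenotype)| target
    trait_direction: int = -1           # -1: factor lower in polyp samples
    loading_range: tuple[float, float] = (0.7, 1.0)
    de_genes: dict[str, float] = field(default_factory=dict)  # gene -> extra log2FC

    def validate(self) -> None:
        if not 0 <= self.eigen_effect <= 1:
            raise ValidationError(f"module {self.name}: eigen_effect outside [0,1]")
        if self.trait_direction not in (-1, 1):
            raise ValidationError(f"module {self.name}: trait_direction must be +-1")
        extra = set(self.de_genes) - set(self.member_genes)
        if extra:
            raise ValidationError(
                f"module {self.name}: de_genes outside member set: {sorted(extra)[:5]}"
            )


@dataclass
class PlantedNetworkConfig:
    """Planted-partition graph settings; module genes become the first
    communities, remaining genes are chunked into background communities."""

    p_within: float = 0.3
    p_between: float = 0.02
    background_community_size: int = 50
    weight_within: tuple[float, float] = (0.5, 1.0)
    weight_between: tuple[float, float] = (0.05, 0.5)

    def validate(self) -> None:
        for p in (self.p_within, self.p_between):
            if not 0 <= p <= 1:
                raise ValidationError("edge probabilities must lie in [0,1]")
        if self.p_within <= self.p_between:
            raise ValidationError("p_within must exceed p_between")
        if self.background_community_size < 2:
            raise ValidationError("background communities need >=2 nodes")


@dataclass
class PlantedOntologyConfig:
    """Layered DAG: one branch term per community under each namespace root,
    ``terms_per_branch`` leaves per branch."""

    terms_per_branch: int = 3
    frac_is_a: float = 0.8
    p_in_branch: float = 0.85   # community gene annotated inside its own branch
    annotate_frac: float = 0.9

    def validate(self) -> None:
        if self.terms_per_branch < 1:
            raise ValidationError("terms_per_branch must be >=1")
        for p in (self.frac_is_a, self.p_in_branch, self.annotate_frac):
            if not 0 <= p <= 1:
                raise ValidationError("ontology fractions must lie in [0,1]")


@dataclass
class SimConfig:
    n_genes: int = 2000
    probe_count_weights: dict[int, float] = field(
        default_factory=lambda: {1: 0.5, 2: 0.3, 3: 0.2})
    n_samples_per_batch: list[int] = field(default_factory=lambda: [40, 40, 40])
    phenotype_balance: float = 0.5      # fraction of polyp samples per batch
    modules: list[PlantedModule] = field(default_factory=list)
    batch_shift_sd: float = 0.8         # additive batch effect, log2 units
    batch_scale_sd: float = 0.2         # sd of log multiplicative noise scale
    noise_sd: float = 0.5               # residual gene noise, log2 units
    probe_noise_sd: float = 0.1
    frac_unannotated_probes: float = 0.05
    baseline_range: tuple[float, float] = (6.0, 12.0)
    tissue_background_frac: float = 0.9  # background genes kept on tissue list
    network: PlantedNetworkConfig = field(default_factory=PlantedNetworkConfig)
    ontology: PlantedOntologyConfig = field(default_factory=PlantedOntologyConfig)
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1 or not self.n_samples_per_batch:
            raise ValidationError("n_genes and n_samples_per_batch must be positive")
        if any(n < 1 for n in self.n_samples_per_batch):
            raise ValidationError("every batch needs >=1 sample")
        if not 0 <= self.phenotype_balance <= 1:
            raise ValidationError("phenotype_balance must lie in [0,1]")
        if abs(sum(self.probe_count_weights.values()) - 1) > 1e-9:
            raise ValidationError("probe_count_weights must sum to 1")
        universe = set(self.gene_ids())
        seen: set[str] = set()
        for module in self.modules:
            module.validate()
            members = set(module.member_genes)
            if members - universe:
                raise ValidationError(
                    f"module {module.name}: members outside gene universe")
            if members & seen:
                raise ValidationError("module member sets must be disjoint")
            seen |= members
        self.network.validate()
        self.ontology.validate()

    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"g{i:0{width}d}" for i in range(1, self.n_genes + 1)]

    @property
    def n_samples(self) -> int:
        return int(sum(self.n_samples_per_batch))


@dataclass
class PlantedTruth:
    """Ground truth emitted next to the simulated data."""

    module_of_gene: dict[str, str]        # only genes inside planted modules
    community_of_gene: dict[str, int]     # every gene, dense ids from 1
    true_log2fc: dict[str, float]         # expected polyp - normal, log2
    de_direction: dict[str, str]          # planted DE genes -> up/down
    tissue_genes: set[str] = field(default_factory=set)
    batch_params: dict = field(default_factory=dict)

    def biomarker_genes(self, annotated: set[str]) -> set[str]:
        """Planted DE genes that sit in a phenotype-linked module, in a
        planted network community, and carry an annotation."""
        return {g for g in self.de_direction
                if g in self.module_of_gene and g in self.community_of_gene
                and g in annotated}

    def to_json(self) -> dict:
        return {
            "module_of_gene": self.module_of_gene,
            "community_of_gene": self.community_of_gene,
            "true_log2fc": {g: round(v, 6) for g, v in self.true_log2fc.items()},
            "de_direction": self.de_direction,
            "tissue_genes": sorted(self.tissue_genes),
            "batch_params": self.batch_params,
        }


# ----------------------------------------------------------------- reference

def reference_config(seed: int = 7, n_genes: int = 2000,
                     module_size: int = 50, n_de: int = 15,
                     eigen_effect: float = 0.6,
                     n_samples_per_batch: tuple[int, ...] = (40, 40, 40),
                     de_effect: float = 1.5) -> SimConfig:
    """The reference study conditions: two phenotype-linked modules of 50
    genes in a 2000-gene, three-batch cohort of 120 samples.

    Most planted DE genes move down in polyp (mirroring the down-shifted
    chemokine profile the pipeline is meant to find); one gene per module is
    planted up to exercise direction bookkeeping.
    """
    width = len(str(n_genes))
    ids = [f"g{i:0{width}d}" for i in range(1, n_genes + 1)]
    modules = []
    for m in range(2):
        members = ids[m * module_size:(m + 1) * module_size]
        de = {g: -de_effect for g in members[:n_de]}
        # one up-regulated gene per module; the shift must overcome the
        # module factor's downward pull (~ -1.2 x loading) to net > +1
        de[members[0]] = +de_effect + 1.0
        modules.append(PlantedModule(
            name=f"mod{m + 1}", member_genes=members,
            eigen_effect=eigen_effect, trait_direction=-1, de_genes=de))
    return SimConfig(n_genes=n_genes, modules=modules,
                     n_samples_per_batch=list(n_samples_per_batch), seed=seed)


# -------------------------------------------------------------------- cohort

def _sample_layout(config: SimConfig):
    """Sample ids, phenotypes and batch labels; polyp counts are fixed per
    batch (round(balance * n)) so the design is balanced across batches."""
    rows = []
    for b, n in enumerate(config.n_samples_per_batch, start=1):
        n_polyp = int(round(config.phenotype_balance * n))
        phenos = ["polyp"] * n_polyp + ["normal"] * (n - n_polyp)
        for i, ph in enumerate(phenos, start=1):
            rows.append((f"b{b}s{i:03d}", ph, f"batch{b}"))
    table = pd.DataFrame(rows, columns=["sample_id", "phenotype", "batch"])
    return SampleMetadata(table.set_index("sample_id"))


def simulate_cohort(config: SimConfig):
    """Draw the probe-level cohort.

    Gene value = baseline + loading x module factor + DE shift(phenotype)
    + batch shift + batch scale x noise; each probe adds independent probe
    noise. Returns ``(probe_matrix, metadata, truth)``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + _OFFSET["cohort"])
    meta = _sample_layout(config)
    genes = config.gene_ids()
    gene_index = {g: i for i, g in enumerate(genes)}
    n_genes, n_samples = len(genes), len(meta.sample_ids)

    y = meta.phenotype_code.to_numpy()
    if y.std() == 0:
        z = np.zeros_like(y)
    else:
        z = (y - y.mean()) / y.std()
    delta_z = 0.0 if y.std() == 0 else 1.0 / np.sqrt(y.mean() * (1 - y.mean()))

    baseline = rng.uniform(*config.baseline_range, size=n_genes)
    values = np.tile(baseline[:, None], (1, n_samples))

    module_of_gene: dict[str, str] = {}
    true_lfc = dict.fromkeys(genes, 0.0)
    de_direction: dict[str, str] = {}
    for module in config.modules:
        e = module.eigen_effect
        factor = module.trait_direction * e * z \
            + np.sqrt(max(0.0, 1 - e * e)) * rng.standard_normal(n_samples)
        loadings = rng.uniform(*module.loading_range, size=len(module.member_genes))
        for gene, loading in zip(module.member_genes, loadings):
            gi = gene_index[gene]
            values[gi] += loading * factor
            module_of_gene[gene] = module.name
            true_lfc[gene] += loading * module.trait_direction * e * delta_z
        for gene, fc in module.de_genes.items():
            values[gene_index[gene]] += fc * y
            true_lfc[gene] += fc
            de_direction[gene] = "up" if true_lfc[gene] > 0 else "down"

    batch_params: dict = {}
    batches = meta.table["batch"].to_numpy()
    for batch in dict.fromkeys(batches):  # preserves batch order
        cols = np.flatnonzero(batches == batch)
        shift = rng.normal(0.0, config.batch_shift_sd, size=n_genes) \
            if config.batch_shift_sd > 0 else np.zeros(n_genes)
        scale = np.exp(rng.normal(0.0, config.batch_scale_sd, size=n_genes)) \
            if config.batch_scale_sd > 0 else np.ones(n_genes)
        noise = rng.normal(0.0, config.noise_sd, size=(n_genes, len(cols)))
        values[:, cols] += shift[:, None] + scale[:, None] * noise
        batch_params[batch] = {"shift_sd": float(shift.std()),
                               "scale_sd": float(np.log(scale).std())}

    truth = PlantedTruth(module_of_gene=module_of_gene,
                         community_of_gene={},
                         true_log2fc=true_lfc,
                         de_direction=de_direction,
                         batch_params=batch_params)

    # probe replication on top of the gene values
    counts = np.array(sorted(config.probe_count_weights))
    probs = np.array([config.probe_count_weights[c] for c in counts], dtype=float)
    per_gene = rng.choice(counts, size=n_genes, p=probs)
    probe_rows, probe_ids, probe_genes = [], [], []
    k = 0
    for gi, gene in enumerate(genes):
        for _ in range(int(per_gene[gi])):
            k += 1
            probe_ids.append(f"p{k:06d}")
            probe_genes.append(gene)
            probe_rows.append(values[gi] + rng.normal(0, config.probe_noise_sd,
                                                      size=n_samples))
    n_na = int(round(config.frac_unannotated_probes * len(probe_ids)))
    for _ in range(n_na):
        k += 1
        probe_ids.append(f"p{k:06d}")
        probe_genes.append(None)
        probe_rows.append(rng.uniform(*config.baseline_range)
                          + rng.normal(0, config.noise_sd, size=n_samples))

    pm = ProbeMatrix(
        values=pd.DataFrame(np.vstack(probe_rows), index=probe_ids,
                            columns=meta.sample_ids),
        probe_to_gene=pd.Series(probe_genes, index=probe_ids, dtype="object"),
        metadata=meta)
    return pm, meta, truth


def simulate_validation_cohort(config: SimConfig, n_samples: int = 60,
                               seed_offset: int = 1000):
    """An independent single-batch cohort with the same planted modules and
    DE effects but no batch structure — validation sets are analyzed on
    their own and never batch-corrected."""
    cfg = dataclasses.replace(
        config,
        n_samples_per_batch=[n_samples],
        batch_shift_sd=0.0, batch_scale_sd=0.0,
        seed=config.seed + seed_offset)
    return simulate_cohort(cfg)


# ------------------------------------------------------------------- network

def planted_partition_graph(community_nodes: list[list[str]],
                            p_within: float, p_between: float,
                            weight_within=(0.5, 1.0), weight_between=(0.05, 0.5),
                            rng=None) -> nx.Graph:
    """Weighted planted-partition graph over explicit community node lists."""
    if p_within <= p_between:
        raise ValidationError("p_within must exceed p_between")
    rng = np.random.default_rng(rng)
    graph = nx.Graph()
    for nodes in community_nodes:
        graph.add_nodes_from(nodes)
    for a, comm_a in enumerate(community_nodes):
        for b in range(a, len(community_nodes)):
            comm_b = community_nodes[b]
            if a == b:
                pairs = [(comm_a[i], comm_a[j])
                         for i in range(len(comm_a)) for j in range(i + 1, len(comm_a))]
                p, wlo, whi = p_within, *weight_within
            else:
                pairs = [(u, v) for u in comm_a for v in comm_b]
                p, wlo, whi = p_between, *weight_between
            if not pairs:
                continue
            hits = rng.random(len(pairs)) < p
            weights = rng.uniform(wlo, whi, size=len(pairs))
            for (u, v), hit, w in zip(pairs, hits, weights):
                if hit:
                    graph.add_edge(u, v, weight=float(w))
    return graph


def _communities(config: SimConfig) -> list[list[str]]:
    in_module = {g for m in config.modules for g in m.member_genes}
    comms = [list(m.member_genes) for m in config.modules]
    background = [g for g in config.gene_ids() if g not in in_module]
    size = config.network.background_community_size
    comms += [background[i:i + size] for i in range(0, len(background), size)]
    return [c for c in comms if c]


def simulate_network(config: SimConfig, truth: PlantedTruth) -> nx.Graph:
    """Planted-partition functional network; fills ``truth.community_of_gene``
    (module communities first, then background chunks)."""
    config.validate()
    net = config.network
    comms = _communities(config)
    rng = np.random.default_rng(config.seed + _OFFSET["network"])
    graph = planted_partition_graph(comms, net.p_within, net.p_between,
                                    net.weight_within, net.weight_between, rng)
    truth.community_of_gene = {g: cid for cid, nodes in enumerate(comms, start=1)
                               for g in nodes}
    return graph


def simulate_tissue_genes(config: SimConfig, truth: PlantedTruth) -> set[str]:
    """Colon-tissue-expressed gene list: every module gene plus a random
    fraction of the background (the rest get filtered out downstream)."""
    rng = np.random.default_rng(config.seed + _OFFSET["tissue"])
    in_module = {g for m in config.modules for g in m.member_genes}
    tissue = set(in_module)
    for gene in config.gene_ids():
        if gene not in in_module and rng.random() < config.tissue_background_frac:
            tissue.add(gene)
    truth.tissue_genes = tissue
    return tissue


# ------------------------------------------------------------------ ontology

def simulate_ontology(config: SimConfig, truth: PlantedTruth):
    """Layered BP/MF DAG whose branches track the planted communities.

    Each community owns one branch term per namespace with a few leaf terms
    under it; community genes annotate mostly inside their own branch (to a
    leaf and to the branch term, so genes of one community share a
    functional class). Returns ``(dag, annotations)`` where annotations map
    ``namespace -> gene -> term set``.
    """
    config.validate()
    if not truth.community_of_gene:
        raise ValidationError("simulate_network must run before simulate_ontology")
    onto = config.ontology
    rng = np.random.default_rng(config.seed + _OFFSET["ontology"])
    comm_ids = sorted(set(truth.community_of_gene.values()))

    dag = nx.DiGraph()
    branches: dict[str, dict[int, str]] = {}
    leaves: dict[str, dict[int, list[str]]] = {}
    for ns in NAMESPACES:
        root = f"{ns}:root"
        dag.add_node(root, namespace=ns)
        branches[ns], leaves[ns] = {}, {}
        for cid in comm_ids:
            branch = f"{ns}:c{cid:02d}"
            rel = "is_a" if rng.random() < onto.frac_is_a else "part_of"
            dag.add_node(branch, namespace=ns)
            dag.add_edge(branch, root, relation=rel)
            branches[ns][cid] = branch
            leaves[ns][cid] = []
            for j in range(1, onto.terms_per_branch + 1):
                leaf = f"{ns}:c{cid:02d}t{j}"
                rel = "is_a" if rng.random() < onto.frac_is_a else "part_of"
                dag.add_node(leaf, namespace=ns)
                dag.add_edge(leaf, branch, relation=rel)
                leaves[ns][cid].append(leaf)
    assert nx.is_directed_acyclic_graph(dag)

    annotations: dict[str, dict[str, set[str]]] = {ns: {} for ns in NAMESPACES}
    for gene in config.gene_ids():
        cid = truth.community_of_gene[gene]
        for ns in NAMESPACES:
            if rng.random() >= onto.annotate_frac:
                continue
            if rng.random() < onto.p_in_branch or len(comm_ids) == 1:
                target = cid
            else:
                others = [c for c in comm_ids if c != cid]
                target = others[int(rng.integers(len(others)))]
            leaf = leaves[ns][target][int(rng.integers(onto.terms_per_branch))]
            annotations[ns][gene] = {leaf, branches[ns][target]}
    return dag, annotations


def annotation_classes(annotations: dict) -> dict[str, set[str]]:
    """Invert gene->terms (all namespaces pooled) into the functional class
    map consumed by the homogeneity index: term -> gene set."""
    classes: dict[str, set[str]] = {}
    for per_gene in annotations.values():
        for gene, terms in per_gene.items():
            for term in terms:
                classes.setdefault(term, set()).add(gene)
    return classes


def gene_sets_from_annotations(annotations: dict, min_size: int = 3) -> dict:
    """GMT-style collection: one gene set per ontology term."""
    out = {}
    for term, members in annotation_classes(annotations).items():
        if len(members) >= min_size:
            out[term] = (f"synthetic term {term}", set(members))
    return out


# ----------------------------------------------------------------- compounds

_INHIBITORY = ["inhibitor", "antagonist", "blocker"]
_ACTIVATING = ["agonist", "activator"]


def simulate_compounds(config: SimConfig, truth: PlantedTruth) -> pd.DataFrame:
    """Compound-target-action table: each planted DE gene gets one compound
    whose action type matches its direction (inhibitory for up, activating
    for down) and, with probability 1/2, a decoy with the opposite class."""
    rng = np.random.default_rng(config.seed + _OFFSET["compounds"])
    rows = []
    for i, (gene, direction) in enumerate(sorted(truth.de_direction.items()), 1):
        good = _INHIBITORY if direction == "up" else _ACTIVATING
        bad = _ACTIVATING if direction == "up" else _INHIBITORY
        rows.append((f"cmpd{i:03d}a", gene,
                     good[int(rng.integers(len(good)))], "matched action"))
        if rng.random() < 0.5:
            rows.append((f"cmpd{i:03d}b", gene,
                         bad[int(rng.integers(len(bad)))], "decoy action"))
    return pd.DataFrame(rows, columns=["compound", "target", "action", "description"])


# -------------------------------------------------------------------- driver

def write_all(config: SimConfig, outdir) -> PlantedTruth:
    """Generate every artifact and write the plain-text files the pipeline
    reads; returns the planted truth (also written as JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pm, meta, truth = simulate_cohort(config)
    io.write_probe_matrix(pm, outdir / "probes.tsv", outdir / "probe_annotation.tsv")
    io.write_metadata(meta, outdir / "metadata.tsv")
    graph = simulate_network(config, truth)
    io.write_edge_list(graph, outdir / "network.tsv")
    tissue = simulate_tissue_genes(config, truth)
    io.write_gene_list(tissue, outdir / "tissue_genes.txt")
    dag, annotations = simulate_ontology(config, truth)
    io.write_ontology(dag, outdir / "ontology.tsv")
    flat = {}
    for per_gene in annotations.values():
        for gene, terms in per_gene.items():
            flat.setdefault(gene, set()).update(terms)
    io.write_annotations(flat, outdir / "annotations.tsv")
    io.write_gmt(gene_sets_from_annotations(annotations), outdir / "gene_sets.gmt")
    compounds = simulate_compounds(config, truth)
    compounds.to_csv(outdir / "compounds.tsv", sep="\t", index=False)
    vpm, vmeta, _ = simulate_validation_cohort(config)
    io.write_probe_matrix(vpm, outdir / "validation_probes.tsv",
                          outdir / "validation_probe_annotation.tsv")
    io.write_metadata(vmeta, outdir / "validation_metadata.tsv")
    io.write_json(truth.to_json(), outdir / "truth.json")
    return truth
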