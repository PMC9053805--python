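"""End-to-end orchestration: preprocess -> co-expression modules -> tissue
network mapping -> clustering x3 -> metric evaluation -> differential
expression -> enrichment -> independent validation -> biomarker report.

One :class:`PipelineConfig` (usually loaded from YAML) holds every input
path and stage parameter; a single seed is fanned out to the stages that
need randomness. Every run writes its artifacts plus a manifest of input
hashes, parameters and output hashes, so reruns with identical inputs are
byte-comparable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io
from .cluster_quality import MetricReport, evaluate_partition
from .coexpression import run_wgcna
from .containers import ExpressionMatrix, ValidationError
from .diff_expression import differential_expression, direction_of, select_degs
from .enrichment import graph_to_dot, graph_to_node_link, ora, term_gene_graph
from .graph_clustering import fn_cluster, mcl, spectral_cluster
from .preprocess import combat_adjust, drop_unannotated_and_aggregate
from .reporting import (concordance_summary, drug_action_filter,
                        select_submodules, validate_overlap)
from .tissue_network import filter_network, induced_submodule, largest_component

log = logging.getLogger("polypnet")


@dataclass
class PipelineConfig:
    # inputs
    probes: str = ""
    probe_annotation: str = ""
    metadata: str = ""
    network: str = ""
    tissue_genes: str = ""
    ontology: str = ""
    annotations: str = ""
    gene_sets: dict = field(default_factory=dict)   # collection name -> GMT path
    compounds: str | None = None
    validation: list = field(default_factory=list)  # [{name, probes, probe_annotation, metadata}]
    outdir: str = "results"
    # stage parameters (defaults are the published operating points)
    batch_correction: bool = True
    power: int | None = None          # None: auto-select by scale-free fit
    r2_cut: float = 0.8
    cut_height: float = 0.95
    min_module_size: int = 30
    merge_height: float = 0.25        # eigengene correlation 0.75
    trait_r: float = 0.3
    min_weight: float = 0.1
    mcl_inflation: float = 1.2
    mcl_expansion: int = 2
    spectral_k: int | None = None     # None: match the MCL cluster count
    fc_threshold: float = 1.0
    fdr_threshold: float = 0.05
    enrich_fdr: float = 0.05
    submodule_min_size: int = 10
    top_n: int = 3
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def required_inputs(self) -> list[str]:
        paths = [self.probes, self.probe_annotation, self.metadata,
                 self.network, self.tissue_genes, self.ontology,
                 self.annotations, *self.gene_sets.values()]
        if self.compounds:
            paths.append(self.compounds)
        for cohort in self.validation:
            paths += [cohort["probes"], cohort["probe_annotation"],
                      cohort["metadata"]]
        return paths


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _stage(name):
    log.info("stage: %s", name)
    return time.time()


def run_all(config: PipelineConfig) -> dict:
    """Execute every stage in order and write the report bundle; returns a
    dict with the in-memory results of each stage."""
    for path in config.required_inputs():
        if not Path(path).exists():
            raise ValidationError(f"missing input file: {path}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "parameters": {k: v for k, v in vars(config).items()
                       if k not in ("validation", "gene_sets")},
        "inputs": {p: _sha256(p) for p in config.required_inputs()},
        "stages": {},
    }

    # ---- preprocess ------------------------------------------------------
    t0 = _stage("preprocess")
    pm = io.read_probe_matrix(config.probes, config.probe_annotation,
                              config.metadata)
    em = drop_unannotated_and_aggregate(pm)
    n_batches = em.metadata.table["batch"].nunique()
    if config.batch_correction and n_batches >= 2:
        em = combat_adjust(em)
    io.write_expression(em, outdir / "expression.tsv")
    manifest["stages"]["preprocess"] = {
        "seconds": round(time.time() - t0, 2),
        "genes": len(em.genes), "samples": em.n_samples,
        "batches": int(n_batches)}

    # ---- co-expression ---------------------------------------------------
    t0 = _stage("wgcna")
    coex = run_wgcna(em, power=config.power, r2_cut=config.r2_cut,
                     cut_height=config.cut_height,
                     min_module_size=config.min_module_size,
                     merge_height=config.merge_height,
                     r_threshold=config.trait_r)
    coex.labels.rename("module").to_csv(outdir / "module_labels.tsv", sep="\t",
                                        index_label="gene_id")
    coex.module_trait.to_csv(outdir / "module_trait.tsv", sep="\t")
    selected_genes = sorted(coex.labels.index[coex.labels.isin(coex.selected)])
    io.write_gene_list(selected_genes, outdir / "selected_module_genes.txt")
    manifest["stages"]["wgcna"] = {
        "seconds": round(time.time() - t0, 2), "power": coex.power,
        "modules": int(coex.labels.max()),
        "selected_modules": list(map(int, coex.selected)),
        "selected_genes": len(selected_genes)}
    if not selected_genes:
        raise ValidationError("no phenotype-linked module passed |r| > "
                              f"{config.trait_r}")

    # ---- tissue network mapping -----------------------------------------
    t0 = _stage("map-network")
    fin = filter_network(io.read_edge_list(config.network),
                         min_weight=config.min_weight,
                         tissue_genes=io.read_gene_list(config.tissue_genes))
    fin = largest_component(fin)
    mapped = induced_submodule(fin, set(selected_genes))
    io.write_edge_list(mapped, outdir / "mapped_network.tsv")
    manifest["stages"]["map_network"] = {
        "seconds": round(time.time() - t0, 2),
        "fin_nodes": fin.number_of_nodes(), "fin_edges": fin.number_of_edges(),
        "mapped_nodes": mapped.number_of_nodes(),
        "mapped_edges": mapped.number_of_edges()}

    # ---- clustering ------------------------------------------------------
    t0 = _stage("cluster")
    partitions = {}
    partitions["mcl"] = mcl(mapped, inflation=config.mcl_inflation,
                            expansion=config.mcl_expansion)
    partitions["fn"] = fn_cluster(mapped)
    k = config.spectral_k or max(2, partitions["mcl"].n_clusters)
    partitions["spectral"] = spectral_cluster(mapped, k=k, seed=config.seed)
    for name, part in partitions.items():
        io.write_partition(part.assignment, outdir / f"partition_{name}.tsv")
    manifest["stages"]["cluster"] = {
        "seconds": round(time.time() - t0, 2),
        "clusters": {name: part.n_clusters for name, part in partitions.items()}}

    # ---- differential expression ----------------------------------------
    t0 = _stage("dge")
    deg_table = differential_expression(em)
    deg_table.to_csv(outdir / "deg_table.tsv", sep="\t", index_label="gene_id")
    up, down, _ = select_degs(deg_table, config.fc_threshold,
                              config.fdr_threshold)
    directions = direction_of(deg_table, config.fc_threshold,
                              config.fdr_threshold)
    manifest["stages"]["dge"] = {"seconds": round(time.time() - t0, 2),
                                 "up": len(up), "down": len(down)}

    # ---- evaluation ------------------------------------------------------
    t0 = _stage("evaluate")
    dag = io.read_ontology(config.ontology)
    flat_annotations = io.read_annotations(config.annotations)
    per_ns = _split_by_namespace(dag, flat_annotations)
    reports: list[MetricReport] = []
    for name, part in partitions.items():
        report = evaluate_partition(mapped, part, dag, per_ns, up, down)
        report.per_cluster.to_csv(outdir / f"metrics_{name}.tsv", sep="\t")
        reports.append(report)
    manifest["stages"]["evaluate"] = {
        "seconds": round(time.time() - t0, 2),
        "q": {r.algorithm: round(r.q, 4) for r in reports},
        "silhouette": {r.algorithm: round(r.silhouette, 4) for r in reports}}

    # ---- submodule selection + enrichment -------------------------------
    t0 = _stage("enrich")
    ranked = select_submodules(reports, min_size=config.submodule_min_size,
                               top_n=config.top_n)
    ranked.to_csv(outdir / "ranked_submodules.tsv", sep="\t", index=False)
    collections = {name: io.read_gmt(path)
                   for name, path in config.gene_sets.items()}
    universe = set(em.genes)
    training_sets: dict = {}
    enrichment_frames = []
    for row in ranked.itertuples(index=False):
        sid = f"{row.algorithm}:{row.cluster}"
        members = set(partitions[row.algorithm].clusters()[row.cluster])
        training_sets[sid] = {"up": up & members, "down": down & members,
                              "genes": members}
        if collections:
            enr = ora(members & universe, collections, universe,
                      fdr_threshold=config.enrich_fdr)
            enr.insert(0, "submodule", sid)
            enrichment_frames.append(enr)
    if enrichment_frames:
        enrichment = pd.concat(enrichment_frames, ignore_index=True)
        enrichment.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        if enrichment["significant"].any():
            graph = term_gene_graph(enrichment, directions)
            io.write_json(graph_to_node_link(graph),
                          outdir / "term_gene_graph.json")
            (outdir / "term_gene_graph.dot").write_text(graph_to_dot(graph))
    manifest["stages"]["enrich"] = {
        "seconds": round(time.time() - t0, 2),
        "selected_submodules": sorted(training_sets)}

    # ---- independent validation -----------------------------------------
    t0 = _stage("validate")
    validation_degs = {}
    for cohort in config.validation:
        vpm = io.read_probe_matrix(cohort["probes"], cohort["probe_annotation"],
                                   cohort["metadata"])
        vem = drop_unannotated_and_aggregate(vpm)  # never batch-corrected
        vtable = differential_expression(vem)
        vtable.to_csv(outdir / f"deg_{cohort['name']}.tsv", sep="\t",
                      index_label="gene_id")
        vup, vdown, _ = select_degs(vtable, config.fc_threshold,
                                    config.fdr_threshold)
        validation_degs[cohort["name"]] = {"up": vup, "down": vdown}
    records = validate_overlap(
        {sid: {"up": sets["up"], "down": sets["down"]}
         for sid, sets in training_sets.items()},
        validation_degs) if validation_degs else []
    io.write_json([r.to_json() for r in records], outdir / "biomarkers.json")
    if records:
        concordance_summary(records).to_csv(outdir / "concordance.tsv",
                                            sep="\t", index=False)
    manifest["stages"]["validate"] = {
        "seconds": round(time.time() - t0, 2),
        "biomarkers": len(records),
        "concordant": sum(1 for r in records if r.concordant)}

    # ---- compound filtering ---------------------------------------------
    candidates = pd.DataFrame()
    if config.compounds and records:
        compounds = pd.read_csv(config.compounds, sep="\t", dtype=str)
        candidates = drug_action_filter(records, compounds)
        candidates.to_csv(outdir / "drug_candidates.tsv", sep="\t", index=False)
        manifest["stages"]["drugs"] = {"candidates": len(candidates)}

    manifest["outputs"] = {p.name: _sha256(p) for p in sorted(outdir.iterdir())
                           if p.name != "manifest.json" and p.is_file()}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     sort_keys=True))
    return {"expression": em, "coexpression": coex, "network": mapped,
            "partitions": partitions, "reports": reports, "ranked": ranked,
            "deg_table": deg_table, "up": up, "down": down,
            "training_sets": training_sets, "records": records,
            "validation_degs": validation_degs, "drug_candidates": candidates,
            "manifest": manifest}


def _split_by_namespace(dag, flat_annotations: dict) -> dict:
    """Regroup a flat gene->terms map into namespace -> gene -> terms using
    the DAG's node namespaces."""
    ns_of = {t: dag.nodes[t].get("namespace", "BP") for t in dag.nodes}
    out: dict = {}
    for gene, terms in flat_annotations.items():
        for term in terms:
            ns = ns_of.get(term)
            if ns is None:
                raise ValidationError(f"annotated term {term!r} not in ontology")
            out.setdefault(ns, {}).setdefault(gene, set()).add(term)
    return out
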