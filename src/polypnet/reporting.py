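"""Submodule selection, independent-cohort validation, and compound
action-type filtering.

Submodules are ranked by the mean of min-max-normalized biological scores
(BHI, Wang-BP, Wang-MF) among submodules that are large enough and contain
at least one DEG — an explicit, reproducible version of picking the rows
with the highest biological evaluation criteria. Biomarkers are the DEGs of
the selected submodules; they validate when an independently analyzed
cohort reproduces their direction. Compounds are kept when their action
class opposes the biomarker's expression change (inhibitory classes for
up-regulated targets, activating classes for down-regulated ones).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cluster_quality import MetricReport

#: controlled action vocabulary with synonyms, editable by callers
ACTION_CLASSES = {
    "inhibitory": {"inhibitor", "antagonist", "blocker"},
    "activating": {"agonist", "activator"},
}


@dataclass
class BiomarkerRecord:
    gene: str
    submodule: str                      # "<algorithm>:<cluster id>"
    training_direction: str             # up / down
    validation_direction: dict = field(default_factory=dict)  # cohort -> label
    enriched_terms: list = field(default_factory=list)
    concordant: bool = False

    def to_json(self) -> dict:
        return {"gene": self.gene, "submodule": self.submodule,
                "training_direction": self.training_direction,
                "validation_direction": dict(self.validation_direction),
                "enriched_terms": list(self.enriched_terms),
                "concordant": self.concordant}


def select_submodules(reports: list[MetricReport], min_size: int = 10,
                      top_n: int = 3) -> pd.DataFrame:
    """Rank submodules across all partitions by the mean of
    min-max-normalized (bhi, wang_bp, wang_mf); submodules smaller than
    ``min_size`` or without any DEG are excluded. Returns the top ``top_n``
    rows with the full score breakdown."""
    if not reports:
        raise ValueError("no metric reports supplied")
    frames = []
    for report in reports:
        frame = report.per_cluster.reset_index()
        frame.insert(0, "algorithm", report.algorithm)
        frames.append(frame)
    table = pd.concat(frames, ignore_index=True)
    table["n_deg"] = table["n_up"] + table["n_down"]
    eligible = table[(table["size"] >= min_size) & (table["n_deg"] > 0)].copy()
    if eligible.empty:
        warnings.warn("no submodule passes the size/DEG eligibility rule")
        return eligible.assign(score=pd.Series(dtype=float))
    for metric in ("bhi", "wang_bp", "wang_mf"):
        col = eligible[metric].astype(float)
        span = col.max() - col.min()
        eligible[f"{metric}_norm"] = 0.5 if span == 0 or not np.isfinite(span) \
            else (col - col.min()) / span
    eligible["score"] = eligible[[f"{m}_norm" for m in
                                  ("bhi", "wang_bp", "wang_mf")]].mean(axis=1)
    eligible = eligible.sort_values(["score", "algorithm", "cluster"],
                                    ascending=[False, True, True])
    return eligible.head(top_n).reset_index(drop=True)


def validate_overlap(training: dict, validation_degs: dict) -> list[BiomarkerRecord]:
    """Compare training submodule DEGs against per-cohort validation DEGs.

    ``training`` maps submodule id -> {"up": genes, "down": genes};
    ``validation_degs`` maps cohort name -> {"up": genes, "down": genes}
    (each cohort analyzed independently — never merged or batch-corrected
    with the training data). A biomarker is concordant when at least one
    cohort reproduces its training direction.
    """
    for cohort, cohort_sets in validation_degs.items():
        if not cohort_sets.get("up") and not cohort_sets.get("down"):
            warnings.warn(f"validation cohort {cohort} has no DEGs")
    records: list[BiomarkerRecord] = []
    for submodule in sorted(training):
        for direction in ("down", "up"):
            for gene in sorted(training[submodule].get(direction, ())):
                record = BiomarkerRecord(gene=gene, submodule=submodule,
                                         training_direction=direction)
                for cohort in sorted(validation_degs):
                    cohort_sets = validation_degs[cohort]
                    if gene in cohort_sets.get("up", ()):
                        label = "up"
                    elif gene in cohort_sets.get("down", ()):
                        label = "down"
                    else:
                        label = "absent"
                    record.validation_direction[cohort] = label
                record.concordant = direction in record.validation_direction.values()
                records.append(record)
    return records


def concordance_summary(records: list[BiomarkerRecord]) -> pd.DataFrame:
    """Concordant up/down counts per (submodule, cohort)."""
    rows = []
    cohorts = sorted({c for r in records for c in r.validation_direction})
    for submodule in sorted({r.submodule for r in records}):
        for cohort in cohorts:
            subset = [r for r in records if r.submodule == submodule]
            rows.append({
                "submodule": submodule, "cohort": cohort,
                "concordant_down": sum(
                    1 for r in subset if r.training_direction == "down"
                    and r.validation_direction.get(cohort) == "down"),
                "concordant_up": sum(
                    1 for r in subset if r.training_direction == "up"
                    and r.validation_direction.get(cohort) == "up"),
            })
    return pd.DataFrame(rows)


def drug_action_filter(biomarkers: list[BiomarkerRecord],
                       compounds: pd.DataFrame,
                       action_classes: dict | None = None,
                       require_concordant: bool = True) -> pd.DataFrame:
    """Keep compounds whose action class opposes the biomarker's change:
    inhibitory actions for up-regulated targets, activating actions for
    down-regulated ones. Rows with unknown action types are skipped with a
    warning."""
    classes = action_classes or ACTION_CLASSES
    known = {a for members in classes.values() for a in members}
    direction_of = {}
    for record in biomarkers:
        if require_concordant and not record.concordant:
            continue
        direction_of[record.gene] = record.training_direction
    wanted_class = {"up": "inhibitory", "down": "activating"}
    rows = []
    for row in compounds.itertuples(index=False):
        action = str(row.action).strip().lower()
        if action not in known:
            warnings.warn(f"unknown action type {row.action!r}; row skipped")
            continue
        direction = direction_of.get(row.target)
        if direction is None:
            continue
        if action in classes[wanted_class[direction]]:
            rows.append({"target": row.target, "expression": direction,
                         "compound": row.compound, "action": row.action,
                         "description": getattr(row, "description", "")})
    return pd.DataFrame(rows, columns=["target", "expression", "compound",
                                       "action", "description"])
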