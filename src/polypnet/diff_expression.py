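"""Per-gene differential expression between normal and polyp samples.

Two-sample t-test (equal-variance Student by default, Welch optional) on
the log2 matrix; log2 fold change is the polyp-minus-normal difference of
group means (the data are already log2, so |log2FC| > 1 means a 2-fold
change); Benjamini-Hochberg adjustment across all genes. DEG selection uses
strict inequalities: |log2FC| > fc_threshold and FDR < fdr_threshold.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, ValidationError


def differential_expression(em: ExpressionMatrix,
                            welch: bool = False) -> pd.DataFrame:
    """DEG table: gene id index with log2fc, t, p, fdr columns.

    Genes with zero pooled variance get p = 1 (flagged with a warning)
    rather than failing the whole cohort.
    """
    code = em.metadata.phenotype_code.to_numpy()
    x = em.values.to_numpy(dtype=float)
    polyp = x[:, code == 1]
    normal = x[:, code == 0]
    if polyp.shape[1] < 2 or normal.shape[1] < 2:
        raise ValidationError("each phenotype group needs >=2 samples")

    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(polyp, normal, axis=1, equal_var=not welch)
    log2fc = polyp.mean(axis=1) - normal.mean(axis=1)
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} gene(s) with zero variance; "
                      "p set to 1")
        p = np.where(degenerate, 1.0, p)
        t = np.where(np.isfinite(t), t, 0.0)
    fdr = benjamini_hochberg(p)
    return pd.DataFrame({"log2fc": log2fc, "t": t, "p": p, "fdr": fdr},
                        index=em.values.index)


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values."""
    return multipletests(np.asarray(p, dtype=float), method="fdr_bh")[1]


def select_degs(table: pd.DataFrame, fc_threshold: float = 1.0,
                fdr_threshold: float = 0.05,
                module_genes: dict | None = None):
    """Split the DEG table into up/down gene sets with strict thresholds;
    optionally intersect with per-submodule gene sets.

    Returns ``(up, down, per_module)`` where ``per_module`` maps submodule
    id -> {"up": set, "down": set} for ``module_genes`` given as
    submodule id -> gene set.
    """
    if fc_threshold <= 0 or fdr_threshold <= 0:
        raise ValidationError("thresholds must be positive")
    sig = table["fdr"] < fdr_threshold
    up = set(table.index[sig & (table["log2fc"] > fc_threshold)])
    down = set(table.index[sig & (table["log2fc"] < -fc_threshold)])
    per_module = None
    if module_genes is not None:
        per_module = {mid: {"up": up & set(genes), "down": down & set(genes)}
                      for mid, genes in module_genes.items()}
    return up, down, per_module


def direction_of(table: pd.DataFrame, fc_threshold: float = 1.0,
                 fdr_threshold: float = 0.05) -> pd.Series:
    """Per-gene direction label: up / down / ns."""
    up, down, _ = select_degs(table, fc_threshold, fdr_threshold)
    out = pd.Series("ns", index=table.index, dtype=object)
    out[list(up)] = "up"
    out[list(down)] = "down"
    return out
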