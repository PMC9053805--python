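"""Weighted co-expression module detection.

Pipeline: pick a soft-threshold power by the scale-free topology criterion,
raise |Pearson correlation| to that power to get an unsigned adjacency,
transform to the topological overlap matrix (TOM), cluster genes by
average-linkage on 1-TOM with a static height cut, summarize modules by
eigengenes (first principal component), merge modules whose eigengenes are
closely correlated, and keep modules whose eigengene correlates with the
phenotype beyond a threshold.

The static height cut plus minimum module size is a documented
simplification of adaptive dendrogram cutting; the eigengene merge step
(default height 0.25, i.e. correlation 0.75) absorbs the over-splitting the
static cut can produce.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .containers import ExpressionMatrix, SampleMetadata, ValidationError

UNASSIGNED = 0  # label for genes outside every module ("grey")


@dataclass
class PowerSelection:
    candidates: list[int]
    fit_r2: list[float]          # signed scale-free fit index per candidate
    mean_connectivity: list[float]
    power: int                   # chosen beta
    reached_cut: bool


@dataclass
class CoexpressionResult:
    power: int
    tom: pd.DataFrame
    labels: pd.Series                  # gene -> module label (0 = unassigned)
    eigengenes: pd.DataFrame           # module x sample
    module_trait: pd.DataFrame         # per-module r, p vs phenotype
    selected: list[int] = field(default_factory=list)


def _correlation(em: ExpressionMatrix) -> np.ndarray:
    x = em.values.to_numpy(dtype=float)
    sd = x.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValidationError(
            f"constant genes (correlation undefined): {[em.genes[i] for i in bad[:10]]}")
    cor = np.corrcoef(x)
    if not np.isfinite(cor).all():
        raise ValidationError("non-finite correlations")
    return cor


def pick_soft_threshold(em: ExpressionMatrix,
                        candidates=(1, 2, 3, 4, 5, 6, 7, 8, 10, 12, 14, 16, 18, 20),
                        r2_cut: float = 0.8, n_bins: int = 10) -> PowerSelection:
    """Scale-free topology criterion: for each candidate power, regress
    log10 p(k) on log10 k over connectivity bins; the fit index is R^2
    signed positive only when the slope is negative (decaying degree
    distribution). Chosen power = smallest candidate reaching ``r2_cut``,
    else the best-fitting candidate (with a warning)."""
    if em.n_samples < 3 or len(em.genes) < 10:
        raise ValidationError("need >=3 samples and >=10 genes")
    acor = np.abs(_correlation(em))
    np.fill_diagonal(acor, 0.0)
    fit, mean_k = [], []
    for beta in candidates:
        k = (acor ** beta).sum(axis=1)
        mean_k.append(float(k.mean()))
        fit.append(_scale_free_fit(k, n_bins))
    reached = [i for i, r2 in enumerate(fit) if r2 >= r2_cut]
    if reached:
        idx, ok = reached[0], True
    else:
        idx, ok = int(np.argmax(fit)), False
        warnings.warn("no candidate power reached the scale-free fit cut; "
                      f"using best fit beta={candidates[idx]}")
    return PowerSelection(list(candidates), fit, mean_k, int(candidates[idx]), ok)


def _scale_free_fit(k: np.ndarray, n_bins: int) -> float:
    k = k[k > 0]
    if k.size < n_bins or np.ptp(k) == 0:
        return 0.0
    edges = np.linspace(k.min(), k.max() * (1 + 1e-12), n_bins + 1)
    which = np.digitize(k, edges) - 1
    logk, logp = [], []
    for b in range(n_bins):
        members = k[which == b]
        if members.size == 0:
            continue
        logk.append(np.log10(members.mean()))
        logp.append(np.log10(members.size / k.size))
    if len(logk) < 3 or np.ptp(logk) == 0:
        return 0.0
    slope, _, r, _, _ = stats.linregress(logk, logp)
    return float(r * r if slope < 0 else -r * r)


def tom_from_expression(em: ExpressionMatrix, beta: int) -> pd.DataFrame:
    """Topological overlap of the unsigned adjacency a_ij = |cor|^beta:
    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)."""
    if beta < 1:
        raise ValidationError("beta must be >= 1")
    acor = np.abs(_correlation(em))
    adj = acor ** beta
    np.fill_diagonal(adj, 0.0)
    return pd.DataFrame(tom_from_adjacency(adj), index=em.genes, columns=em.genes)


def tom_from_adjacency(adj: np.ndarray) -> np.ndarray:
    """TOM of a hollow symmetric adjacency with entries in [0,1]."""
    k = adj.sum(axis=1)
    shared = adj @ adj
    denom = np.minimum.outer(k, k) + 1.0 - adj
    tom = (shared + adj) / denom
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def detect_modules(tom: pd.DataFrame, min_module_size: int = 30,
                   cut_height: float = 0.95) -> pd.Series:
    """Average-linkage clustering of 1-TOM, static cut at ``cut_height``;
    branches below ``min_module_size`` genes are relabelled unassigned (0);
    surviving modules are numbered 1.. by decreasing size."""
    if min_module_size < 2:
        raise ValidationError("min_module_size must be >= 2")
    genes = list(tom.index)
    diss = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(diss, 0.0)
    tree = linkage(squareform(diss, checks=False), method="average")
    raw = fcluster(tree, t=cut_height, criterion="distance")
    return relabel_by_size(pd.Series(raw, index=genes), min_module_size)


def relabel_by_size(labels: pd.Series, min_size: int = 1) -> pd.Series:
    """Renumber cluster labels 1.. by decreasing size (ties: smallest member
    id first); clusters below ``min_size`` become unassigned."""
    out = pd.Series(UNASSIGNED, index=labels.index, dtype=int)
    groups = [(members.size, min(members.index), lab)
              for lab, members in labels.groupby(labels) if members.size >= min_size]
    groups.sort(key=lambda g: (-g[0], g[1]))
    for new, (_, _, lab) in enumerate(groups, start=1):
        out[labels == lab] = new
    return out


def module_eigengenes(em: ExpressionMatrix, labels: pd.Series) -> pd.DataFrame:
    """First principal component per module over gene-standardized rows,
    sign-oriented so the mean correlation with member genes is positive.
    Rows are unit-norm over samples; unassigned genes are excluded."""
    rows, names = [], []
    for lab in sorted(set(labels) - {UNASSIGNED}):
        members = labels.index[labels == lab]
        if len(members) < 2:
            raise ValidationError(f"module {lab} has fewer than 2 genes")
        x = em.values.loc[members].to_numpy(dtype=float)
        x = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
        _, _, vt = np.linalg.svd(x, full_matrices=False)
        eig = vt[0]
        orient = np.sign((x @ eig).mean())
        rows.append(eig * (orient if orient != 0 else 1.0))
        names.append(lab)
    if not rows:
        raise ValidationError("no modules to summarize")
    return pd.DataFrame(rows, index=names, columns=em.values.columns)


def merge_close_modules(em: ExpressionMatrix, labels: pd.Series,
                        merge_height: float = 0.25) -> pd.Series:
    """Merge modules whose eigengene dissimilarity (1 - correlation) falls
    below ``merge_height`` under average linkage; recompute eigengenes and
    iterate until stable. Height 0.25 corresponds to correlation 0.75."""
    if merge_height <= 0:
        return labels.copy()
    labels = labels.copy()
    while True:
        module_ids = sorted(set(labels) - {UNASSIGNED})
        if len(module_ids) < 2:
            break
        eig = module_eigengenes(em, labels)
        diss = 1.0 - np.corrcoef(eig.to_numpy())
        np.fill_diagonal(diss, 0.0)
        tree = linkage(squareform(np.clip(diss, 0, None), checks=False),
                       method="average")
        groups = fcluster(tree, t=merge_height, criterion="distance")
        if len(set(groups)) == len(module_ids):
            break
        mapping = {lab: g for lab, g in zip(eig.index, groups)}
        labels = labels.map(lambda l: UNASSIGNED if l == UNASSIGNED else mapping[l])
    return relabel_by_size(labels)


def module_trait_select(eigengenes: pd.DataFrame, metadata: SampleMetadata,
                        r_threshold: float = 0.3):
    """Pearson correlation of each eigengene with the phenotype code
    (normal=0, polyp=1) and its two-sided t-test p-value; modules with
    |r| > ``r_threshold`` are selected. Returns (table, selected ids)."""
    y = metadata.phenotype_code.loc[list(eigengenes.columns)].to_numpy()
    n = len(y)
    if n < 3:
        raise ValidationError("need >=3 samples for module-trait correlation")
    rows = []
    for lab in eigengenes.index:
        r = float(np.corrcoef(eigengenes.loc[lab].to_numpy(), y)[0, 1])
        t = r * np.sqrt((n - 2) / max(1e-300, 1.0 - r * r))
        p = float(2 * stats.t.sf(abs(t), df=n - 2))
        rows.append((lab, r, p))
    table = pd.DataFrame(rows, columns=["module", "r", "p"]).set_index("module")
    selected = [lab for lab in table.index if abs(table.loc[lab, "r"]) > r_threshold]
    return table, selected


def run_wgcna(em: ExpressionMatrix, power: int | None = None,
              r2_cut: float = 0.8, cut_height: float = 0.95,
              min_module_size: int = 30, merge_height: float = 0.25,
              r_threshold: float = 0.3) -> CoexpressionResult:
    """Full module-detection pass; ``power=None`` selects the soft threshold
    automatically by the scale-free criterion."""
    if power is None:
        power = pick_soft_threshold(em, r2_cut=r2_cut).power
    tom = tom_from_expression(em, power)
    labels = detect_modules(tom, min_module_size=min_module_size,
                            cut_height=cut_height)
    labels = merge_close_modules(em, labels, merge_height=merge_height)
    if (labels != UNASSIGNED).sum() == 0:
        raise ValidationError("no modules detected; lower min_module_size "
                              "or raise cut_height")
    eigengenes = module_eigengenes(em, labels)
    table, selected = module_trait_select(eigengenes, em.metadata, r_threshold)
    return CoexpressionResult(power=power, tom=tom, labels=labels,
                              eigengenes=eigengenes, module_trait=table,
                              selected=selected)
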