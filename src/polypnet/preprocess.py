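"""Cohort assembly: probe filtering, median aggregation, batch correction.

The batch correction is a parametric empirical-Bayes location/scale
adjustment of the ComBat family: genes are standardized, per-batch per-gene
additive (gamma) and multiplicative (delta^2) batch parameters are estimated,
shrunk toward batch-level normal / inverse-gamma priors by an iterated EB
update, and the data are adjusted and rescaled back to the grand mean and
pooled variance. Phenotype is deliberately NOT a covariate of the
adjustment by default; with phenotype balanced across batches the biological
signal survives correction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, ProbeMatrix, SampleMetadata, ValidationError


def drop_unannotated_and_aggregate(pm: ProbeMatrix) -> ExpressionMatrix:
    """Remove probes without a gene annotation, then collapse each gene's
    probes to their per-sample median. Output genes are sorted by id."""
    annotated = pm.probe_to_gene.dropna()
    if annotated.empty:
        raise ValidationError("no annotated probes remain")
    values = pm.values.loc[annotated.index]
    collapsed = values.groupby(annotated.reindex(values.index)).median()
    collapsed = collapsed.sort_index()
    collapsed.index.name = "gene_id"
    return ExpressionMatrix(collapsed, pm.metadata)


def assemble_cohort(matrices: list[ExpressionMatrix],
                    batch_labels: list[str] | None = None) -> ExpressionMatrix:
    """Column-concatenate cohorts on the intersection of their gene ids.

    Each input becomes one batch; ``batch_labels`` overrides the batch
    column (defaults to the inputs' own batch labels, which must then be
    distinct per input).
    """
    if not matrices:
        raise ValidationError("no matrices supplied")
    if batch_labels is not None and len(batch_labels) != len(matrices):
        raise ValidationError("batch_labels length mismatch")

    common = set(matrices[0].values.index)
    for em in matrices[1:]:
        common &= set(em.values.index)
    if not common:
        raise ValidationError("gene intersection across inputs is empty")
    genes = sorted(common)

    seen: set[str] = set()
    blocks, meta_rows = [], []
    for i, em in enumerate(matrices):
        dup = seen & set(em.values.columns)
        if dup:
            raise ValidationError(f"duplicate sample ids across inputs: {sorted(dup)[:5]}")
        seen |= set(em.values.columns)
        blocks.append(em.values.loc[genes])
        meta = em.metadata.table.copy()
        if batch_labels is not None:
            meta["batch"] = batch_labels[i]
        meta_rows.append(meta)
    values = pd.concat(blocks, axis=1)
    metadata = SampleMetadata(pd.concat(meta_rows, axis=0))
    return ExpressionMatrix(values, metadata)


def combat_adjust(em: ExpressionMatrix, shrink: bool = True,
                  conv: float = 1e-4, max_iter: int = 100) -> ExpressionMatrix:
    """Parametric empirical-Bayes location/scale batch adjustment.

    With ``shrink=False`` the per-batch estimates are applied directly
    (no prior shrinkage), which removes a pure location offset exactly.
    """
    x = em.values.to_numpy(dtype=float)
    batches = em.metadata.table["batch"].to_numpy()
    batch_ids = list(dict.fromkeys(batches))
    if len(batch_ids) < 2:
        raise ValidationError("batch correction requires >=2 batches")
    cols = {b: np.flatnonzero(batches == b) for b in batch_ids}
    for b, idx in cols.items():
        if len(idx) < 2:
            raise ValidationError(f"batch {b!r} has fewer than 2 samples")

    n_genes, n_samples = x.shape
    n_b = np.array([len(cols[b]) for b in batch_ids], dtype=float)

    batch_means = np.column_stack([x[:, cols[b]].mean(axis=1) for b in batch_ids])
    grand_mean = batch_means @ (n_b / n_samples)
    col_batch = np.array([batch_ids.index(b) for b in batches])
    resid = x - batch_means[:, col_batch]
    var_pooled = (resid ** 2).sum(axis=1) / n_samples
    zero = np.flatnonzero(var_pooled <= 0)
    if zero.size:
        names = [em.genes[i] for i in zero[:10]]
        raise ValidationError(f"zero-variance genes: {names}")

    sd = np.sqrt(var_pooled)
    z = (x - grand_mean[:, None]) / sd[:, None]

    z_adj = np.empty_like(z)
    for j, b in enumerate(batch_ids):
        idx = cols[b]
        zb = z[:, idx]
        gamma_hat = zb.mean(axis=1)
        delta_hat = zb.var(axis=1, ddof=1)
        if shrink:
            gamma_star, delta_star = _eb_shrink(zb, gamma_hat, delta_hat,
                                                n_b[j], conv, max_iter)
        else:
            gamma_star, delta_star = gamma_hat, delta_hat
        z_adj[:, idx] = (zb - gamma_star[:, None]) / np.sqrt(delta_star)[:, None]

    adjusted = z_adj * sd[:, None] + grand_mean[:, None]
    out = pd.DataFrame(adjusted, index=em.values.index, columns=em.values.columns)
    return ExpressionMatrix(out, em.metadata)


def _eb_shrink(zb, gamma_hat, delta_hat, n, conv, max_iter):
    """Iterated EB update of (gamma*, delta*) under normal / inverse-gamma
    priors with method-of-moments hyperparameters."""
    gamma_bar = gamma_hat.mean()
    t2 = gamma_hat.var(ddof=1)
    a_prior = _aprior(delta_hat)
    b_prior = _bprior(delta_hat)

    gamma_star = gamma_hat.copy()
    delta_star = delta_hat.copy()
    for _ in range(max_iter):
        gamma_new = (n * t2 * gamma_hat + delta_star * gamma_bar) \
            / (n * t2 + delta_star)
        ssq = ((zb - gamma_new[:, None]) ** 2).sum(axis=1)
        delta_new = (0.5 * ssq + b_prior) / (n / 2.0 + a_prior - 1.0)
        change = max(np.abs(gamma_new - gamma_star).max() / np.abs(gamma_star).max()
                     if np.abs(gamma_star).max() > 0 else 0.0,
                     np.abs(delta_new - delta_star).max() / delta_star.max())
        gamma_star, delta_star = gamma_new, delta_new
        if change < conv:
            break
    return gamma_star, delta_star


def _aprior(delta_hat):
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (2 * s2 + m ** 2) / s2


def _bprior(delta_hat):
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (m * s2 + m ** 3) / s2
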