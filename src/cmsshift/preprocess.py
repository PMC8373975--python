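"""Expression preprocessing: RPM/log2, batch integration, averaging, centering.

The transformations applied before any signature work: counts are scaled to
reads per million and log2-transformed with a +1 pseudocount; platform
(batch) effects are removed with a parametric empirical-Bayes location/scale
adjustment of the ComBat family; treatment replicates are averaged on the
log scale; and profiles are mean-centered gene-wise within each cell line.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import DataError, ExpressionMatrix, validate_annotation

logger = logging.getLogger(__name__)


def rpm_log2(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Normalize counts to reads per million and log2-transform.

    value = log2(1e6 * count / column_total + 1). The +1 pseudocount pins
    zero counts at 0. Raises if any column has a zero total (the sample
    carries no reads to normalize by).
    """
    vals = counts.values.to_numpy(dtype=float)
    if (vals < 0).any():
        raise DataError("negative counts")
    totals = vals.sum(axis=0)
    bad = np.flatnonzero(totals <= 0)
    if bad.size:
        names = [str(counts.samples[i]) for i in bad]
        raise DataError(f"all-zero columns cannot be normalized: {names}")
    rpm = vals * (1e6 / totals[None, :])
    out = pd.DataFrame(np.log2(rpm + 1.0), index=counts.genes, columns=counts.samples)
    return counts.with_values(out, layer="log2rpm")


@dataclass
class BatchModel:
    """Fitted location/scale batch model.

    grand_mean, pooled_var: per-gene standardization parameters.
    gamma_star, delta2_star: shrunken per-batch per-gene location and scale.
    priors: per-batch empirical-Bayes hyperparameters
    (gamma_bar, tau2_bar, a_prior, b_prior).
    """

    genes: pd.Index
    batches: list[str]
    grand_mean: np.ndarray
    pooled_var: np.ndarray
    gamma_star: pd.DataFrame      # batches x genes
    delta2_star: pd.DataFrame     # batches x genes
    priors: dict[str, dict[str, float]]


def _aprior(d2: np.ndarray) -> float:
    m, s2 = d2.mean(), d2.var(ddof=1)
    return (2 * s2 + m**2) / s2


def _bprior(d2: np.ndarray) -> float:
    m, s2 = d2.mean(), d2.var(ddof=1)
    return (m * s2 + m**3) / s2


def _eb_fit(z: np.ndarray, gamma_bar: float, tau2_bar: float, a: float, b: float,
            tol: float = 1e-8, max_iter: int = 200) -> tuple[np.ndarray, np.ndarray]:
    """Iterative posterior-mode solution for one batch's (gamma*, delta2*).

    z is the standardized data for the batch (genes x samples). Location is
    shrunk toward a normal prior, scale toward an inverse-gamma prior; the
    two conditional modes are iterated to a joint fixed point.
    """
    n = z.shape[1]
    g_hat = z.mean(axis=1)
    d2_hat = z.var(axis=1, ddof=1)
    g_star = g_hat.copy()
    d2_star = d2_hat.copy()
    for _ in range(max_iter):
        g_new = (n * tau2_bar * g_hat + d2_star * gamma_bar) / (n * tau2_bar + d2_star)
        sse = ((z - g_new[:, None]) ** 2).sum(axis=1)
        d2_new = (0.5 * sse + b) / (n / 2 + a - 1)
        change = max(
            np.max(np.abs(g_new - g_star) / (np.abs(g_star) + 1e-12)),
            np.max(np.abs(d2_new - d2_star) / d2_star),
        )
        g_star, d2_star = g_new, d2_new
        if change < tol:
            break
    return g_star, d2_star


def batch_adjust(
    matrix: ExpressionMatrix, batches: pd.Series, shrink: bool = True
) -> tuple[ExpressionMatrix, BatchModel]:
    """Remove per-batch location/scale effects by empirical Bayes.

    Gene values are standardized by grand mean and pooled variance; per-batch
    per-gene means and variances of the standardized data are shrunk toward
    batch-level normal / inverse-gamma priors; the shrunken location is
    subtracted and the shrunken scale divided out; grand mean and variance
    are then restored. With one batch the input is returned unchanged. No
    biological covariates are preserved (none are supplied to this model).

    With ``shrink=False`` the raw per-batch per-gene estimates are used
    instead of their posterior modes; this variant removes a pure gene-wise
    location offset exactly, whereas shrinkage deliberately leaves a small
    residual for genes whose apparent batch effect deviates from the batch
    consensus.
    """
    if matrix.layer not in ("log2rpm", "adjusted"):
        raise DataError(f"batch_adjust expects a log2 layer, got '{matrix.layer}'")
    batches = pd.Series(batches)
    batches.index = batches.index.astype(str)
    missing = matrix.samples.difference(batches.index)
    if len(missing):
        raise DataError(f"samples without batch assignment: {sorted(missing)[:10]}")
    batches = batches.loc[matrix.samples].astype(str)
    levels = sorted(batches.unique())
    x = matrix.values.to_numpy(dtype=float)
    n_genes, n_samples = x.shape

    counts = batches.value_counts()
    singletons = [b for b in levels if counts[b] < 2]
    if len(levels) > 1 and singletons:
        raise DataError(
            f"batch(es) with a single sample (variance inestimable): {singletons}"
        )
    if len(levels) == 1:
        model = BatchModel(
            genes=matrix.genes, batches=levels,
            grand_mean=x.mean(axis=1), pooled_var=x.var(axis=1, ddof=0),
            gamma_star=pd.DataFrame(0.0, index=levels, columns=matrix.genes),
            delta2_star=pd.DataFrame(1.0, index=levels, columns=matrix.genes),
            priors={},
        )
        return matrix.with_values(matrix.values.copy(), layer="adjusted"), model

    masks = {b: (batches == b).to_numpy() for b in levels}
    # batch-size-weighted grand mean; pooled variance of residuals from batch means
    batch_means = np.column_stack([x[:, masks[b]].mean(axis=1) for b in levels])
    weights = np.array([masks[b].sum() for b in levels], dtype=float) / n_samples
    grand_mean = batch_means @ weights
    fitted = np.zeros_like(x)
    for j, b in enumerate(levels):
        fitted[:, masks[b]] = batch_means[:, [j]]
    pooled_var = ((x - fitted) ** 2).mean(axis=1)
    if (pooled_var <= 0).any():
        bad = matrix.genes[pooled_var <= 0]
        raise DataError(f"zero-variance genes cannot be standardized: {list(bad[:10])}")

    sd = np.sqrt(pooled_var)
    z = (x - grand_mean[:, None]) / sd[:, None]

    gamma_star = pd.DataFrame(index=levels, columns=matrix.genes, dtype=float)
    delta2_star = pd.DataFrame(index=levels, columns=matrix.genes, dtype=float)
    priors: dict[str, dict[str, float]] = {}
    adjusted = np.empty_like(z)
    for b in levels:
        zb = z[:, masks[b]]
        g_hat = zb.mean(axis=1)
        d2_hat = zb.var(axis=1, ddof=1)
        gamma_bar = float(g_hat.mean())
        tau2_bar = float(g_hat.var(ddof=1))
        a, bb = float(_aprior(d2_hat)), float(_bprior(d2_hat))
        if shrink:
            g_star, d2_star = _eb_fit(zb, gamma_bar, tau2_bar, a, bb)
        else:
            g_star, d2_star = g_hat, d2_hat
        gamma_star.loc[b] = g_star
        delta2_star.loc[b] = d2_star
        priors[b] = {"gamma_bar": gamma_bar, "tau2_bar": tau2_bar,
                     "a_prior": a, "b_prior": bb}
        adjusted[:, masks[b]] = (zb - g_star[:, None]) / np.sqrt(d2_star)[:, None]

    out = adjusted * sd[:, None] + grand_mean[:, None]
    model = BatchModel(
        genes=matrix.genes, batches=levels, grand_mean=grand_mean,
        pooled_var=pooled_var, gamma_star=gamma_star, delta2_star=delta2_star,
        priors=priors,
    )
    result = matrix.with_values(
        pd.DataFrame(out, index=matrix.genes, columns=matrix.samples), layer="adjusted"
    )
    logger.info("batch_adjust: %d genes, %d samples, %d batches", n_genes, n_samples, len(levels))
    return result, model


def average_replicates(
    matrix: ExpressionMatrix,
    annotation: pd.DataFrame,
    by: tuple[str, ...] = ("cell_line", "treatment"),
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Average replicate columns on the log scale.

    Returns one column per unique combination of ``by`` (arithmetic mean of
    its replicates) plus the collapsed annotation. Column names join the
    ``by`` values with '_'.
    """
    ann = validate_annotation(annotation, matrix, required=tuple(by))
    keys = ann[list(by)].astype(str).agg("_".join, axis=1)
    grouped = matrix.values.T.groupby(keys, sort=True).mean().T
    new_ann = (
        ann.assign(_key=keys)
        .drop_duplicates("_key")
        .set_index("_key")[list(by)]
        .loc[grouped.columns]
    )
    new_ann.index.name = "sample_id"
    return matrix.with_values(grouped, layer="averaged"), new_ann


def center_within_group(
    matrix: ExpressionMatrix,
    annotation: pd.DataFrame,
    group: str = "cell_line",
) -> ExpressionMatrix:
    """Subtract each gene's mean within each group of columns.

    For every gene and every group (cell line), the gene's mean across that
    group's columns is removed, so scores downstream compare profiles within
    a cell line rather than absolute expression. A group with a single
    column becomes all zeros; a warning is emitted because correlations on
    such columns are degenerate.
    """
    ann = validate_annotation(annotation, matrix, required=(group,))
    out = matrix.values.copy()
    for g, ids in ann.groupby(group, sort=False).groups.items():
        cols = list(ids)
        if len(cols) == 1:
            logger.warning(
                "group '%s' has a single column; centered values are all zero", g
            )
        out[cols] = out[cols].sub(out[cols].mean(axis=1), axis=0)
    return matrix.with_values(out, layer="centered")
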