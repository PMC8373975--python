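"""CMS4-vs-CMS2 signature derivation and correlation scoring.

The central computation: starting from a labeled reference cohort and a set
of cell-line profiles, genes are filtered for minimum expression in every
profile, then for cross-dataset conservation by a correlation-of-correlations
score, then tested for differential expression between the mesenchymal
(CMS4) and canonical (CMS2) subtypes with an empirical-Bayes moderated
t-statistic. The signature is the log2 fold changes of the most
significantly up- and down-regulated genes (10 + 10 by default), and a
profile's CMS4-ness is its Pearson correlation with those weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .core import DataError, ExpressionMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# gene universe filters
# ---------------------------------------------------------------------------

def filter_min_expression(profiles: ExpressionMatrix, min_reads: int = 1) -> list[str]:
    """Genes with at least ``min_reads`` in every profile column."""
    if profiles.layer != "counts":
        raise DataError(f"filter_min_expression expects raw counts, got '{profiles.layer}'")
    keep = (profiles.values >= min_reads).all(axis=1)
    out = list(profiles.genes[keep])
    logger.info("filter_min_expression: %d of %d genes retained", len(out), len(keep))
    return out


@dataclass
class CoCScore:
    """Per-gene conservation scores between two datasets, in [-1, 1]."""

    scores: pd.Series
    universe: list[str]

    def passing(self, threshold: float = 0.1) -> list[str]:
        return list(self.scores.index[self.scores >= threshold])


def _rowwise_corr_offdiag(r_a: np.ndarray, r_b: np.ndarray) -> np.ndarray:
    """Pearson correlation of matching rows of two square matrices, diagonal excluded."""
    m = r_a.shape[0]
    mask = ~np.eye(m, dtype=bool)
    xa = r_a[mask].reshape(m, m - 1)
    xb = r_b[mask].reshape(m, m - 1)
    xa = xa - xa.mean(axis=1, keepdims=True)
    xb = xb - xb.mean(axis=1, keepdims=True)
    denom = np.sqrt((xa**2).sum(axis=1) * (xb**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return (xa * xb).sum(axis=1) / denom


def correlation_of_correlations(
    mat_a: ExpressionMatrix, mat_b: ExpressionMatrix, genes: list[str] | None = None
) -> CoCScore:
    """Cross-dataset co-expression conservation score per gene.

    Within each dataset the Pearson correlation of every candidate gene with
    every other candidate gene is computed; a gene's score is the Pearson
    correlation, across partner genes (self excluded), between its
    co-expression vector in dataset A and in dataset B. Symmetric in its two
    arguments. Zero-variance genes in either dataset are dropped with a
    warning (their correlations are undefined).
    """
    if genes is None:
        genes = list(mat_a.genes.intersection(mat_b.genes))
    genes = list(genes)
    missing = [g for g in genes if g not in mat_a.genes or g not in mat_b.genes]
    if missing:
        raise DataError(f"genes absent from one dataset: {missing[:10]}")
    if mat_a.shape[1] < 3 or mat_b.shape[1] < 3:
        raise DataError("correlation_of_correlations needs >=3 samples per dataset")
    a = mat_a.values.loc[genes].to_numpy(dtype=float)
    b = mat_b.values.loc[genes].to_numpy(dtype=float)
    var_a = a.var(axis=1)
    var_b = b.var(axis=1)
    ok = (var_a > 0) & (var_b > 0)
    if not ok.all():
        dropped = [g for g, o in zip(genes, ok) if not o]
        logger.warning(
            "correlation_of_correlations: %d zero-variance genes dropped: %s...",
            len(dropped), dropped[:5],
        )
        genes = [g for g, o in zip(genes, ok) if o]
        a, b = a[ok], b[ok]
    if len(genes) < 3:
        raise DataError("fewer than 3 non-degenerate genes in common")
    r_a = np.corrcoef(a)
    r_b = np.corrcoef(b)
    scores = _rowwise_corr_offdiag(r_a, r_b)
    return CoCScore(scores=pd.Series(scores, index=genes), universe=genes)


# ---------------------------------------------------------------------------
# moderated t differential expression
# ---------------------------------------------------------------------------

@dataclass
class DETable:
    """Per-gene differential-expression results (CMS4 minus CMS2)."""

    table: pd.DataFrame              # log2fc, t_ordinary, t_moderated, p, p_adj, s2_post
    d0: float                        # prior degrees of freedom
    s02: float                       # prior variance

    def __getitem__(self, col: str) -> pd.Series:
        return self.table[col]


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration on 1/trigamma."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) / x < 1e-10:
            break
    return float(x)


def fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment fit of a scaled F distribution to sample variances.

    Models s2 ~ s02 * F(df, d0) on the log scale: with z = log(s2),
    e = z - digamma(df/2) + log(df/2) has mean log(s02) + digamma(d0/2)
    - log(d0/2) and excess variance trigamma(d0/2). Returns (d0, s02);
    d0 = inf when the variances show no excess spread (complete shrinkage).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        raise DataError("too few positive sample variances to fit the prior")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2) + np.log(df / 2)
    e_mean = e.mean()
    e_var = e.var(ddof=1) - special.polygamma(1, df / 2)
    if e_var > 0:
        half_d0 = _trigamma_inverse(e_var)
        d0 = 2 * half_d0
        s02 = float(np.exp(e_mean + special.digamma(half_d0) - np.log(half_d0)))
    else:
        d0 = np.inf
        s02 = float(np.exp(e_mean))
    return d0, s02


def moderated_t_de(
    matrix: ExpressionMatrix,
    labels: pd.Series,
    group_test: str = "CMS4",
    group_ref: str = "CMS2",
) -> DETable:
    """Two-class empirical-Bayes moderated t test per gene.

    For gene g with pooled two-sample variance s2_g on d_g = n - 2 degrees
    of freedom, the posterior variance is
    s2_post = (d0*s02 + d_g*s2_g) / (d0 + d_g), with (d0, s02) estimated by
    a moment fit of a scaled F distribution to the s2_g. The moderated t is
    log2FC / (sqrt(s2_post) * c) with c = sqrt(1/n1 + 1/n2), referred to a
    t distribution with d0 + d_g degrees of freedom. BH adjustment over all
    tested genes.
    """
    labels = pd.Series(labels)
    labels.index = labels.index.astype(str)
    labels = labels.reindex(matrix.samples)
    test_cols = labels.index[labels == group_test]
    ref_cols = labels.index[labels == group_ref]
    if len(test_cols) < 2 or len(ref_cols) < 2:
        raise DataError(
            f"need >=2 samples per class; got {len(test_cols)} {group_test}, "
            f"{len(ref_cols)} {group_ref}"
        )
    x_t = matrix.values[test_cols].to_numpy(dtype=float)
    x_r = matrix.values[ref_cols].to_numpy(dtype=float)
    n1, n2 = x_t.shape[1], x_r.shape[1]
    df_resid = n1 + n2 - 2
    mean_t = x_t.mean(axis=1)
    mean_r = x_r.mean(axis=1)
    log2fc = mean_t - mean_r
    ss = ((x_t - mean_t[:, None]) ** 2).sum(axis=1) + ((x_r - mean_r[:, None]) ** 2).sum(axis=1)
    s2 = ss / df_resid
    c = np.sqrt(1.0 / n1 + 1.0 / n2)

    d0, s02 = fit_f_dist(s2, df_resid)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s02)
        df_total = np.inf
    else:
        s2_post = (d0 * s02 + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid

    with np.errstate(divide="ignore", invalid="ignore"):
        t_ord = log2fc / (np.sqrt(s2) * c)
        t_mod = log2fc / (np.sqrt(s2_post) * c)
    if np.isinf(df_total):
        p = 2 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2 * stats.t.sf(np.abs(t_mod), df_total)
    p_adj = multipletests(p, method="fdr_bh")[1]
    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "t_ordinary": t_ord,
            "t_moderated": t_mod,
            "p": p,
            "p_adj": p_adj,
            "s2_post": s2_post,
        },
        index=matrix.genes,
    )
    return DETable(table=table, d0=float(d0), s02=s02)


# ---------------------------------------------------------------------------
# signature construction and scoring
# ---------------------------------------------------------------------------

@dataclass
class CMSSignature:
    """Ordered signature genes with log2FC weights (up first, then down)."""

    genes: list[str]
    weights: pd.Series              # indexed by gene, values = log2FC
    k_up: int
    k_down: int
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.genes) != self.k_up + self.k_down:
            raise DataError("signature size does not match k_up + k_down")
        if len(set(self.genes)) != len(self.genes):
            raise DataError("duplicate genes in signature")

    def to_dict(self) -> dict:
        return {
            "genes": self.genes,
            "weights": {g: float(self.weights[g]) for g in self.genes},
            "k_up": self.k_up,
            "k_down": self.k_down,
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CMSSignature":
        weights = pd.Series({g: d["weights"][g] for g in d["genes"]})
        return cls(
            genes=list(d["genes"]), weights=weights,
            k_up=d["k_up"], k_down=d["k_down"],
            provenance=d.get("provenance", {}),
        )


def build_signature(de: DETable, k_up: int = 10, k_down: int = 10) -> CMSSignature:
    """Select the most significant up- and down-regulated genes.

    Genes are ranked by p ascending within each sign of log2FC; ties break
    by larger |log2FC|, then lexicographic gene id. Weights are the log2
    fold changes themselves.
    """
    t = de.table
    up = t[t["log2fc"] > 0]
    down = t[t["log2fc"] < 0]
    if len(up) < k_up or len(down) < k_down:
        raise DataError(
            f"insufficient genes: {len(up)} upregulated (need {k_up}), "
            f"{len(down)} downregulated (need {k_down})"
        )

    def top(sub: pd.DataFrame, k: int) -> list[str]:
        order = sub.assign(_absfc=sub["log2fc"].abs(), _gene=sub.index).sort_values(
            ["p", "_absfc", "_gene"], ascending=[True, False, True], kind="mergesort"
        )
        return list(order.index[:k])

    genes_up = top(up, k_up)
    genes_down = top(down, k_down)
    genes = genes_up + genes_down
    weights = t.loc[genes, "log2fc"]
    return CMSSignature(
        genes=genes, weights=weights, k_up=k_up, k_down=k_down,
        provenance={"n_tested": int(len(t)), "d0": de.d0, "s02": de.s02},
    )


def score_samples(signature: CMSSignature, profiles: ExpressionMatrix) -> pd.Series:
    """Pearson correlation of each profile column with the signature weights.

    Computed over the signature genes present in the profile matrix (at
    least 3 required; missing genes are logged). A column that is constant
    over the signature genes has an undefined correlation and is reported
    as NA with a warning. Invariant to any gene-wise constant added to the
    profiles (Pearson centers both vectors).
    """
    shared = [g for g in signature.genes if g in profiles.genes]
    missing = [g for g in signature.genes if g not in profiles.genes]
    if missing:
        logger.warning("score_samples: %d signature genes missing: %s", len(missing), missing)
    if len(shared) < 3:
        raise DataError(f"only {len(shared)} signature genes present; need >=3")
    w = signature.weights[shared].to_numpy(dtype=float)
    x = profiles.values.loc[shared].to_numpy(dtype=float)
    wc = w - w.mean()
    xc = x - x.mean(axis=0, keepdims=True)
    denom = np.sqrt((xc**2).sum(axis=0) * (wc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc * wc[:, None]).sum(axis=0) / denom
    const = denom == 0
    if const.any():
        logger.warning(
            "score_samples: constant columns over signature genes: %s",
            list(profiles.samples[const]),
        )
        r = np.where(const, np.nan, r)
    return pd.Series(r, index=profiles.samples, name="cms4_score")


def derive_signature(
    reference_log2: ExpressionMatrix,
    labels: pd.Series,
    profile_counts: ExpressionMatrix,
    profile_log2: ExpressionMatrix | None = None,
    min_reads: int = 1,
    coc_threshold: float = 0.1,
    k_up: int = 10,
    k_down: int = 10,
) -> tuple[CMSSignature, dict]:
    """Run the full derivation: expression filter, conservation filter, DE, top genes.

    ``reference_log2`` is the batch-adjusted log2 reference cohort;
    ``profile_counts`` the raw cell-line counts (for the min-read filter);
    ``profile_log2`` the log2 profiles for the conservation filter (derived
    from the counts via RPM/log2 when not given). Returns the signature and
    a dict of stage gene counts.
    """
    from .preprocess import rpm_log2

    if profile_log2 is None:
        profile_log2 = rpm_log2(profile_counts)
    stage_counts: dict[str, int] = {"input_genes": int(len(reference_log2.genes))}

    expressed = filter_min_expression(profile_counts, min_reads=min_reads)
    expressed = [g for g in expressed if g in reference_log2.genes]
    stage_counts["min_expression"] = len(expressed)

    coc = correlation_of_correlations(
        reference_log2.subset_genes(expressed), profile_log2.subset_genes(expressed)
    )
    conserved = coc.passing(coc_threshold)
    stage_counts["conserved"] = len(conserved)
    logger.info(
        "derive_signature: %d expressed -> %d conserved (threshold %.2f)",
        len(expressed), len(conserved), coc_threshold,
    )

    de = moderated_t_de(reference_log2.subset_genes(conserved), labels)
    signature = build_signature(de, k_up=k_up, k_down=k_down)
    signature.provenance.update(stage_counts)
    signature.provenance["coc_threshold"] = coc_threshold
    signature.provenance["min_reads"] = min_reads
    return signature, stage_counts
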