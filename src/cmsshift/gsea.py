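"""Weighted Kolmogorov-Smirnov gene-set enrichment with permutation nulls.

Implements the classic two-class enrichment test: genes are ranked by a
signal-to-noise statistic between phenotype classes, each gene set gets a
running-sum enrichment score (hit increments proportional to |stat|^w,
miss increments uniform), and significance comes from sample-label (or
gene) permutation: NES normalizes by the mean same-sign permutation score,
nominal p is the same-sign permutation tail, and FDR q pools normalized
scores across sets.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import DataError, ExpressionMatrix

logger = logging.getLogger(__name__)


def signal_to_noise(
    matrix: np.ndarray, class_a: np.ndarray, class_b: np.ndarray, sd_floor_frac: float = 0.2
) -> np.ndarray:
    """Per-gene signal-to-noise ratio (mean_a - mean_b) / (sd_a + sd_b).

    Each class standard deviation is floored at ``sd_floor_frac`` times the
    absolute class mean (and at a small absolute floor), matching the usual
    behavior of the reference desktop implementation.
    """
    xa, xb = matrix[:, class_a], matrix[:, class_b]
    ma, mb = xa.mean(axis=1), xb.mean(axis=1)
    sa, sb = xa.std(axis=1, ddof=1), xb.std(axis=1, ddof=1)
    sa = np.maximum(np.maximum(sa, sd_floor_frac * np.abs(ma)), sd_floor_frac * 0.1)
    sb = np.maximum(np.maximum(sb, sd_floor_frac * np.abs(mb)), sd_floor_frac * 0.1)
    return (ma - mb) / (sa + sb)


def enrichment_score(
    ranked_genes: list[str],
    ranking_stat: np.ndarray,
    gene_set: set[str] | list[str],
    weight_exponent: float = 1.0,
) -> tuple[float, np.ndarray, list[str]]:
    """Running-sum enrichment score of a gene set on a ranked list.

    The list must be ordered by decreasing ranking statistic. In-set genes
    ("hits") add |stat|^weight_exponent, normalized so hit mass sums to 1;
    out-of-set genes subtract 1/(N - N_hits). The enrichment score is the
    running sum's deviation of maximal magnitude; the leading edge holds the
    in-set genes at or before the maximum (at or after the minimum for a
    negative score). Returns (ES, running_sum, leading_edge).
    """
    genes = list(ranked_genes)
    n = len(genes)
    if len(set(genes)) != n:
        raise DataError("ranked list contains duplicate genes")
    stat = np.asarray(ranking_stat, dtype=float)
    if stat.shape != (n,):
        raise DataError("ranking_stat length does not match ranked list")
    in_set = np.fromiter((g in set(gene_set) for g in genes), dtype=bool, count=n)
    n_hit = int(in_set.sum())
    if n_hit == 0:
        raise DataError("gene set shares no genes with the ranked universe")
    if n_hit == n:
        raise DataError("gene set covers the whole universe; miss mass undefined")

    hit_w = np.abs(stat[in_set]) ** weight_exponent
    total = hit_w.sum()
    if total == 0:
        hit_w = np.ones(n_hit)   # all-zero stats: fall back to unweighted hits
        total = float(n_hit)
    incr = np.where(in_set, 0.0, -1.0 / (n - n_hit))
    incr[in_set] = hit_w / total
    running = np.cumsum(incr)
    i_ext = int(np.argmax(np.abs(running)))
    es = float(running[i_ext])
    if es >= 0:
        leading = [g for j, g in enumerate(genes) if in_set[j] and j <= i_ext]
    else:
        leading = [g for j, g in enumerate(genes) if in_set[j] and j >= i_ext + 1]
    return es, running, leading


@dataclass
class GseaResult:
    """Per-set enrichment result."""

    es: float
    nes: float
    p: float
    fdr_q: float
    leading_edge: list[str]
    n_perm: int
    perm_mode: str


def _rank(matrix: np.ndarray, a_idx: np.ndarray, b_idx: np.ndarray) -> np.ndarray:
    """Indices sorting genes by decreasing signal-to-noise (stable)."""
    stat = signal_to_noise(matrix, a_idx, b_idx)
    return np.argsort(-stat, kind="stable"), stat


def gsea_test(
    matrix: ExpressionMatrix,
    class_labels: pd.Series,
    sets: dict[str, list[str]],
    n_perm: int = 1000,
    perm_mode: str = "sample",
    seed: int = 0,
    weight_exponent: float = 1.0,
) -> pd.DataFrame:
    """Two-class enrichment test for a collection of gene sets.

    ``class_labels`` must take exactly two values; genes are ranked by
    signal-to-noise (first label minus second, labels sorted). Sample
    permutation shuffles class assignments (exhaustive enumeration replaces
    Monte Carlo, with a logged downgrade, when the number of distinct label
    splits is at most ``n_perm``); gene permutation rescores random gene
    sets of matching size. With fewer than 3 samples in either class, sample
    mode automatically falls back to gene mode. Returns a DataFrame indexed
    by set name with columns es, nes, p, fdr_q, leading_edge, n_perm,
    perm_mode.
    """
    labels = pd.Series(class_labels)
    labels.index = labels.index.astype(str)
    labels = labels.reindex(matrix.samples)
    levels = sorted(labels.dropna().unique())
    if len(levels) != 2:
        raise DataError(f"gsea_test needs exactly 2 classes, got {levels}")
    a_idx = np.flatnonzero((labels == levels[0]).to_numpy())
    b_idx = np.flatnonzero((labels == levels[1]).to_numpy())
    if perm_mode == "sample" and (len(a_idx) < 3 or len(b_idx) < 3):
        logger.warning(
            "class sizes %d/%d too small for sample permutation; using gene mode",
            len(a_idx), len(b_idx),
        )
        perm_mode = "gene"
    if perm_mode not in ("sample", "gene"):
        raise DataError(f"unknown perm_mode '{perm_mode}'")

    x = matrix.values.to_numpy(dtype=float)
    genes = list(matrix.genes)
    rng = np.random.default_rng(seed)

    order, stat = _rank(x, a_idx, b_idx)
    ranked_genes = [genes[i] for i in order]
    ranked_stat = stat[order]

    set_names = list(sets)
    obs = {}
    for name in set_names:
        members = [g for g in sets[name] if g in matrix.genes]
        if not members:
            raise DataError(f"gene set '{name}' shares no genes with the matrix")
        obs[name] = enrichment_score(ranked_genes, ranked_stat, members, weight_exponent)

    # --- permutation null ---
    perm_es = {name: [] for name in set_names}
    if perm_mode == "sample":
        n = len(a_idx) + len(b_idx)
        used = np.concatenate([a_idx, b_idx])
        n_a = len(a_idx)
        total_splits = math.comb(n, n_a)
        if total_splits <= n_perm:
            logger.warning(
                "only %d distinct label splits; downgrading to exhaustive enumeration",
                total_splits,
            )
            splits = [np.array(c) for c in itertools.combinations(range(n), n_a)]
        else:
            splits = [rng.permutation(n)[:n_a] for _ in range(n_perm)]
        for split in splits:
            mask = np.zeros(len(used), dtype=bool)
            mask[split] = True
            pa, pb = used[mask], used[~mask]
            p_order, p_stat = _rank(x, pa, pb)
            p_genes = [genes[i] for i in p_order]
            p_ranked = p_stat[p_order]
            for name in set_names:
                members = [g for g in sets[name] if g in matrix.genes]
                es, _, _ = enrichment_score(p_genes, p_ranked, members, weight_exponent)
                perm_es[name].append(es)
    else:
        for name in set_names:
            size = len([g for g in sets[name] if g in matrix.genes])
            for _ in range(n_perm):
                rand = rng.choice(len(genes), size=size, replace=False)
                members = [genes[i] for i in rand]
                es, _, _ = enrichment_score(ranked_genes, ranked_stat, members, weight_exponent)
                perm_es[name].append(es)

    # --- NES, nominal p, pooled FDR ---
    nes_obs: dict[str, float] = {}
    p_nom: dict[str, float] = {}
    nes_perm_all: list[float] = []
    nes_perm_by_set: dict[str, np.ndarray] = {}
    for name in set_names:
        es = obs[name][0]
        pe = np.asarray(perm_es[name])
        same_sign = pe[pe >= 0] if es >= 0 else pe[pe < 0]
        n_same = len(same_sign)
        if n_same == 0:
            logger.warning("set '%s': no same-sign permutation scores; NES undefined", name)
            nes_obs[name] = np.nan
            p_nom[name] = 1.0
            nes_perm_by_set[name] = np.array([])
            continue
        mean_abs = np.abs(same_sign).mean()
        nes_obs[name] = es / mean_abs
        p_nom[name] = (1 + int((np.abs(same_sign) >= abs(es)).sum())) / (1 + n_same)
        # normalize each permutation score by its own sign's mean
        pos, neg = pe[pe >= 0], pe[pe < 0]
        normed = np.concatenate(
            [
                pos / pos.mean() if len(pos) else pos,
                neg / np.abs(neg).mean() if len(neg) else neg,
            ]
        )
        nes_perm_by_set[name] = normed
        nes_perm_all.extend(normed.tolist())

    nes_all = np.asarray(nes_perm_all)
    obs_nes_vals = np.asarray([nes_obs[n_] for n_ in set_names])
    fdr: dict[str, float] = {}
    for name in set_names:
        nes = nes_obs[name]
        if np.isnan(nes):
            fdr[name] = np.nan
            continue
        if nes >= 0:
            denom_perm = (nes_all >= 0).sum()
            num_perm = (nes_all >= nes).sum()
            denom_obs = (obs_nes_vals >= 0).sum()
            num_obs = (obs_nes_vals >= nes).sum()
        else:
            denom_perm = (nes_all < 0).sum()
            num_perm = (nes_all <= nes).sum()
            denom_obs = (obs_nes_vals < 0).sum()
            num_obs = (obs_nes_vals <= nes).sum()
        frac_perm = num_perm / denom_perm if denom_perm else 1.0
        frac_obs = num_obs / denom_obs if denom_obs else 1.0
        fdr[name] = float(min(1.0, frac_perm / frac_obs)) if frac_obs > 0 else 1.0

    rows = []
    for name in set_names:
        es, _, leading = obs[name]
        rows.append(
            {
                "set": name,
                "es": es,
                "nes": nes_obs[name],
                "p": p_nom[name],
                "fdr_q": fdr[name],
                "leading_edge": ",".join(leading),
                "n_perm": len(perm_es[name]),
                "perm_mode": perm_mode,
            }
        )
    return pd.DataFrame(rows).set_index("set")
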