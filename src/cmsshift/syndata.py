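"""Synthetic data with the statistical structure the pipeline assumes.

Every generator here emulates one input of the analysis: a two-platform
reference cohort of colorectal tumors with CMS2/CMS4 labels and planted
differentially expressed genes, cancer-sphere cell-line profiles whose
treated arms drift toward the mesenchymal (CMS4) pole, limiting-dilution
assays under the single-hit model, study-level effects with between-study
heterogeneity, and proportional-hazards survival times.

All randomness flows from a single integer seed; each generator derives its
own stream by a fixed offset so stages can be re-run independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import ConfigError, ExpressionMatrix

# Fixed per-generator seed offsets (kept small so seed + offset < 2**31).
_SEED_COHORT = 11
_SEED_PROFILES = 23
_SEED_LDA = 37
_SEED_META = 53
_SEED_SURVIVAL = 71


@dataclass
class CohortConfig:
    """Parameters of the simulated two-platform reference cohort.

    The defaults describe a cohort like the one the signature is derived
    from: two sequencing platforms merged into one dataset, a minority of
    mesenchymal (CMS4) samples, and a planted set of genes separating CMS4
    from CMS2 at a known log2 fold change.
    """

    n_genes: int = 2000
    n_samples_per_platform: tuple[int, int] = (120, 80)
    n_cms2: int = 120
    n_cms4: int = 80
    n_de_genes: int = 100
    de_log2fc_magnitude: float = 2.0
    batch_shift_sd: float = 0.5      # log2 units, additive per-gene offset on platform 2
    batch_scale_sd: float = 0.2      # sd of log dispersion inflation on platform 2
    dispersion: float = 0.05         # negative-binomial dispersion (Var = m + a*m^2)
    library_size_range: tuple[int, int] = (500_000, 1_500_000)
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_genes", "n_de_genes", "n_cms2", "n_cms4"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if any(n <= 0 for n in self.n_samples_per_platform):
            raise ConfigError("n_samples_per_platform entries must be > 0")
        if self.n_de_genes > self.n_genes:
            raise ConfigError("n_de_genes exceeds n_genes")
        if self.n_cms2 + self.n_cms4 > sum(self.n_samples_per_platform):
            raise ConfigError(
                "n_cms2 + n_cms4 exceeds total samples (n_samples_per_platform)"
            )
        if self.dispersion < 0:
            raise ConfigError("dispersion must be >= 0")
        if self.batch_shift_sd < 0 or self.batch_scale_sd < 0:
            raise ConfigError("batch_shift_sd and batch_scale_sd must be >= 0")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise ConfigError("library_size_range must satisfy 0 < low <= high")


@dataclass
class GroundTruth:
    """Planted parameters of a simulated study, for downstream recovery checks."""

    de_log2fc: dict[str, float] = field(default_factory=dict)   # gene id -> signed log2FC
    base_log2: dict[str, float] = field(default_factory=dict)   # gene id -> baseline log2 abundance
    batch_shift: dict[str, float] = field(default_factory=dict)  # platform-2 additive offsets
    batch_scale: dict[str, float] = field(default_factory=dict)  # platform-2 dispersion inflation
    lda_frequencies: dict[str, float] = field(default_factory=dict)
    meta_mu: float | None = None
    meta_tau2: float | None = None
    hazard_ratio: float | None = None

    def validate(self) -> None:
        for arm, f in self.lda_frequencies.items():
            if not (0 < f <= 1):
                raise ConfigError(f"lda frequency for arm '{arm}' outside (0, 1]")
        if self.meta_tau2 is not None and self.meta_tau2 < 0:
            raise ConfigError("meta_tau2 must be >= 0")


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: np.ndarray) -> np.ndarray:
    """Gamma-Poisson counts with Var = m + a*m^2; Poisson where a == 0."""
    mean = np.asarray(mean, dtype=float)
    a = np.broadcast_to(np.asarray(dispersion, dtype=float), mean.shape)
    out = np.empty(mean.shape, dtype=np.int64)
    pois = a <= 0
    if pois.any():
        out[pois] = rng.poisson(mean[pois])
    if (~pois).any():
        shape = 1.0 / a[~pois]
        lam = rng.gamma(shape, mean[~pois] * a[~pois])
        out[~pois] = rng.poisson(lam)
    return out


def simulate_reference_cohort(
    config: CohortConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame, GroundTruth]:
    """Simulate a labeled two-platform reference cohort of counts.

    Returns the raw count matrix, a sample annotation with ``platform`` and
    ``cms_label`` columns, and the :class:`GroundTruth` holding every planted
    parameter. Half of the planted DE genes are up in CMS4, half down, each
    by ``de_log2fc_magnitude`` log2 units. Platform-2 samples carry gene-wise
    additive (log2 scale) mean offsets and multiplicative dispersion
    distortions mirroring the location/scale model the adjustment stage fits.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + _SEED_COHORT)

    n_genes = config.n_genes
    genes = [f"G{i:05d}" for i in range(n_genes)]
    n1, n2 = config.n_samples_per_platform
    n_total = n1 + n2
    samples = [f"S{i:04d}" for i in range(n_total)]
    platform = np.array(["hiseq"] * n1 + ["ga"] * n2)

    # CMS labels interleaved across platforms so batch and biology are not confounded
    labels = np.array(
        ["CMS2"] * config.n_cms2
        + ["CMS4"] * config.n_cms4
        + ["other"] * (n_total - config.n_cms2 - config.n_cms4)
    )
    rng.shuffle(labels)

    base_log2 = rng.normal(5.0, 1.5, size=n_genes)
    de_idx = rng.choice(n_genes, size=config.n_de_genes, replace=False)
    signs = np.ones(config.n_de_genes)
    signs[config.n_de_genes // 2:] = -1.0
    de_log2fc = np.zeros(n_genes)
    de_log2fc[de_idx] = signs * config.de_log2fc_magnitude

    gamma = rng.normal(0.0, config.batch_shift_sd, size=n_genes)       # additive, log2
    log_delta = rng.normal(0.0, config.batch_scale_sd, size=n_genes)   # dispersion inflation

    is_cms4 = labels == "CMS4"
    is_p2 = platform == "ga"
    # per-sample, per-gene log2 signal
    log2_signal = (
        base_log2[:, None]
        + de_log2fc[:, None] * is_cms4[None, :]
        + gamma[:, None] * is_p2[None, :]
    )
    rel = np.exp2(log2_signal)
    props = rel / rel.sum(axis=0, keepdims=True)
    lib = rng.integers(config.library_size_range[0], config.library_size_range[1] + 1, size=n_total)
    mean = props * lib[None, :]
    disp = np.where(is_p2[None, :], config.dispersion * np.exp(2 * log_delta[:, None]), config.dispersion)
    counts = _nb_counts(rng, mean, disp)

    matrix = ExpressionMatrix(
        pd.DataFrame(counts, index=genes, columns=samples), layer="counts"
    )
    annotation = pd.DataFrame(
        {"platform": platform, "cms_label": labels},
        index=pd.Index(samples, name="sample_id"),
    )
    truth = GroundTruth(
        de_log2fc={genes[i]: float(de_log2fc[i]) for i in de_idx},
        base_log2={g: float(b) for g, b in zip(genes, base_log2)},
        batch_shift={g: float(v) for g, v in zip(genes, gamma)},
        batch_scale={g: float(np.exp(v)) for g, v in zip(genes, log_delta)},
    )
    return matrix, annotation, truth


def simulate_cellline_profiles(
    config: CohortConfig,
    truth: GroundTruth,
    shift_fraction: float,
    n_cell_lines: int = 2,
    treatments: Sequence[str] = ("medium", "s_asc_cm", "v_asc_cm"),
    n_replicates: int = 2,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Simulate cancer-sphere cell-line count profiles.

    Columns span cell line x treatment x replicate. Arms other than the
    first treatment (the control medium) move the planted DE genes by
    ``shift_fraction`` times their true log2 fold change toward the CMS4
    pole; replicate noise is independent negative-binomial. Cell lines start
    from the epithelial (CMS2) baseline, each with a small stable identity
    offset so within-cell-line centering has structure to remove.
    """
    config.validate()
    if not (0.0 <= shift_fraction <= 1.0):
        raise ConfigError("shift_fraction must lie in [0, 1]")
    rng = np.random.default_rng(config.seed + _SEED_PROFILES)

    genes = list(truth.base_log2)
    base = np.array([truth.base_log2[g] for g in genes])
    fc = np.array([truth.de_log2fc.get(g, 0.0) for g in genes])
    n_genes = len(genes)

    cols, cell_col, treat_col, rep_col = [], [], [], []
    blocks = []
    for cl in range(n_cell_lines):
        identity = rng.normal(0.0, 0.3, size=n_genes)  # stable cell-line offset
        for treat_i, treat in enumerate(treatments):
            shift = 0.0 if treat_i == 0 else shift_fraction
            log2_signal = base + identity + shift * fc
            rel = np.exp2(log2_signal)
            props = rel / rel.sum()
            for rep in range(n_replicates):
                lib = rng.integers(
                    config.library_size_range[0], config.library_size_range[1] + 1
                )
                counts = _nb_counts(rng, props * lib, config.dispersion)
                blocks.append(counts)
                cols.append(f"CL{cl + 1}_{treat}_r{rep + 1}")
                cell_col.append(f"CL{cl + 1}")
                treat_col.append(treat)
                rep_col.append(rep + 1)

    matrix = ExpressionMatrix(
        pd.DataFrame(np.column_stack(blocks), index=genes, columns=cols),
        layer="counts",
    )
    annotation = pd.DataFrame(
        {"cell_line": cell_col, "treatment": treat_col, "replicate": rep_col},
        index=pd.Index(cols, name="sample_id"),
    )
    return matrix, annotation


def simulate_lda(
    groups: Sequence[tuple[float, Sequence[int], int]],
    seed: int = 0,
    labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Simulate limiting-dilution assays under the exact single-hit model.

    Each group is ``(f, doses, n_wells)``: with active-cell frequency ``f``,
    a well seeded with ``d`` cells responds unless every cell is inactive,
    so responses ~ Binomial(n_wells, 1 - (1 - f)**d) per dose. Returns a
    tidy table with columns arm, dose, n_tested, n_response.
    """
    rng = np.random.default_rng(seed + _SEED_LDA)
    rows = []
    for i, (f, doses, n_wells) in enumerate(groups):
        if not (0 < f <= 1):
            raise ConfigError(f"group {i}: frequency f={f} outside (0, 1]")
        arm = labels[i] if labels is not None else f"arm{i + 1}"
        for d in doses:
            d = int(d)
            if d < 1:
                raise ConfigError(f"group {i}: dose {d} must be a positive integer")
            p_resp = -np.expm1(d * np.log1p(-f)) if f < 1 else 1.0
            rows.append(
                {
                    "arm": arm,
                    "dose": d,
                    "n_tested": n_wells,
                    "n_response": int(rng.binomial(n_wells, p_resp)),
                }
            )
    return pd.DataFrame(rows)


def simulate_meta(
    mu: float,
    tau2: float,
    k: int,
    v_range: tuple[float, float] = (0.01, 0.1),
    missing_ci_fraction: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate study-level ratio-scale effects with heterogeneity.

    Study i has within-study variance v_i ~ Uniform(v_range) and log-effect
    y_i ~ Normal(mu, tau2 + v_i). The emitted table reports the effect on
    the ratio scale with a 95% CI from v_i; a ``missing_ci_fraction`` share
    of studies has the CI withheld and only the two-sided Wald p retained,
    exercising the missing-CI reconstruction route.
    """
    if tau2 < 0:
        raise ConfigError("tau2 must be >= 0")
    if not (0 <= missing_ci_fraction <= 1):
        raise ConfigError("missing_ci_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed + _SEED_META)
    from scipy import stats

    v = rng.uniform(v_range[0], v_range[1], size=k)
    y = rng.normal(mu, np.sqrt(tau2 + v))
    z975 = stats.norm.ppf(0.975)
    n_missing = int(round(missing_ci_fraction * k))
    missing = np.zeros(k, dtype=bool)
    if n_missing:
        missing[rng.choice(k, size=n_missing, replace=False)] = True
    p = 2 * stats.norm.sf(np.abs(y) / np.sqrt(v))
    rows = []
    for i in range(k):
        rows.append(
            {
                "study": f"study{i + 1:03d}",
                "effect": float(np.exp(y[i])),
                "ci_low": np.nan if missing[i] else float(np.exp(y[i] - z975 * np.sqrt(v[i]))),
                "ci_high": np.nan if missing[i] else float(np.exp(y[i] + z975 * np.sqrt(v[i]))),
                "p": float(p[i]),
                "n": int(rng.integers(50, 2000)),
            }
        )
    return pd.DataFrame(rows)


def simulate_survival(
    n_per_group: int,
    hazard_ratio: float,
    baseline_rate: float = 0.1,
    censor_rate: float = 0.02,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate two-arm survival data with exponential hazards.

    Group "b" has its hazard multiplied by ``hazard_ratio``; censoring is an
    independent exponential clock (``censor_rate`` 0 disables it). Columns:
    time, event, group.
    """
    if hazard_ratio <= 0:
        raise ConfigError("hazard_ratio must be > 0")
    if baseline_rate <= 0:
        raise ConfigError("baseline_rate must be > 0")
    if censor_rate < 0:
        raise ConfigError("censor_rate must be >= 0")
    rng = np.random.default_rng(seed + _SEED_SURVIVAL)
    rates = np.concatenate(
        [np.full(n_per_group, baseline_rate), np.full(n_per_group, baseline_rate * hazard_ratio)]
    )
    t_event = rng.exponential(1.0 / rates)
    if censor_rate > 0:
        t_cens = rng.exponential(1.0 / censor_rate, size=2 * n_per_group)
    else:
        t_cens = np.full(2 * n_per_group, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    group = ["a"] * n_per_group + ["b"] * n_per_group
    return pd.DataFrame({"time": time, "event": event, "group": group})
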