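"""Canned end-to-end experiments on synthetic data.

Each function runs one self-contained study — simulate, analyze, measure —
and returns plain numbers, so the whole pipeline's statistical behavior
(signature recovery, shift detection, frequency-fold coverage, estimator
calibration) can be reproduced from a single seed. These back the
reproduction script and the top-level checks of the test suite.
"""

from __future__ import annotations

import numpy as np

from . import clinstats, gsea, limiting_dilution, syndata
from .cms_signature import build_signature, derive_signature, moderated_t_de, score_samples
from .preprocess import average_replicates, batch_adjust, center_within_group, rpm_log2

#: Dose ladder used throughout the in-vivo-style dilution experiments.
DOSE_LADDER = (10, 100, 1000, 10_000)


def signature_recovery(seed: int) -> dict:
    """Derive a signature from a 2000-gene, 100+100-sample labeled cohort.

    100 genes are planted at |log2FC| = 2; returns how many of the 10
    selected genes in each direction are planted ones.
    """
    cfg = syndata.CohortConfig(
        n_genes=2000, n_samples_per_platform=(100, 100), n_cms2=100, n_cms4=100,
        n_de_genes=100, de_log2fc_magnitude=2.0, seed=seed,
    )
    matrix, annotation, truth = syndata.simulate_reference_cohort(cfg)
    adjusted, _ = batch_adjust(rpm_log2(matrix), annotation["platform"])
    sig = build_signature(moderated_t_de(adjusted, annotation["cms_label"]))
    up_planted = {g for g, v in truth.de_log2fc.items() if v > 0}
    down_planted = {g for g, v in truth.de_log2fc.items() if v < 0}
    return {
        "up_recovered": len(set(sig.genes[: sig.k_up]) & up_planted),
        "down_recovered": len(set(sig.genes[sig.k_up:]) & down_planted),
        "k": sig.k_up,
        "n_genes": cfg.n_genes,
    }


def reprogramming_trial(seed: int, shift_fraction: float) -> float:
    """One full signature-and-score run; returns score(treated) - score(control).

    The signature is derived with the complete filter chain from a fresh
    labeled cohort plus the 12-profile study design (2 cell lines x 3
    treatments x 2 replicates, treated arms at the design shift of 0.8 —
    the conservation filter needs the co-expression that the observed
    treatment response induces). The scored data are a separate evaluation
    experiment: one cell line, a control arm (medium) and a treated arm
    (visceral adipose conditioned medium), 6 replicates each, whose treated
    arm moves by ``shift_fraction``; at 0 the two arms are exchangeable and
    the comparison is a coin flip.
    """
    from dataclasses import replace

    cfg = syndata.CohortConfig(
        n_genes=800, n_samples_per_platform=(40, 40), n_cms2=40, n_cms4=40,
        n_de_genes=60, de_log2fc_magnitude=2.0, seed=seed,
    )
    matrix, annotation, truth = syndata.simulate_reference_cohort(cfg)
    adjusted, _ = batch_adjust(rpm_log2(matrix), annotation["platform"])
    derivation_profiles, _ = syndata.simulate_cellline_profiles(cfg, truth, 0.8)
    sig, _ = derive_signature(adjusted, annotation["cms_label"], derivation_profiles)

    eval_cfg = replace(cfg, seed=cfg.seed + 500)
    profiles, prof_ann = syndata.simulate_cellline_profiles(
        eval_cfg, truth, shift_fraction,
        n_cell_lines=1, treatments=("medium", "v_asc_cm"), n_replicates=6,
    )
    averaged, avg_ann = average_replicates(rpm_log2(profiles), prof_ann)
    centered = center_within_group(averaged, avg_ann)
    scores = score_samples(sig, centered)
    treated = scores[avg_ann.index[avg_ann["treatment"] == "v_asc_cm"]].mean()
    control = scores[avg_ann.index[avg_ann["treatment"] == "medium"]].mean()
    return float(treated - control)


def reprogramming_detection(seeds, shift_fraction: float) -> int:
    """Number of seeds whose treated arm outscores its own control arm."""
    return sum(reprogramming_trial(s, shift_fraction) > 0 for s in seeds)


def lda_fold_trial(seed: int, f_treated: float = 1 / 175, f_control: float = 1 / 1000,
                   n_wells: int = 12):
    """Simulate and fit the two-arm dilution experiment; returns the comparison.

    Arms follow the in-vivo design: the dose ladder 10/100/1000/10000 with 12
    replicates per dose, control frequency 1 in 1000 and treated 1 in 175
    (a true 5.71-fold enrichment of tumor-initiating cells).
    """
    tbl = syndata.simulate_lda(
        [(f_treated, DOSE_LADDER, n_wells), (f_control, DOSE_LADDER, n_wells)],
        seed=seed, labels=("treated", "control"),
    )
    groups = [
        limiting_dilution.LDAGroup.from_frame(sub)
        for _, sub in tbl.groupby("arm", sort=False)
    ]
    return limiting_dilution.compare_groups(groups)


def lda_fold_coverage(seeds) -> dict:
    """Coverage of the fold CI and LRT rejections across seeds."""
    true_fold = (1 / 175) / (1 / 1000)
    covered = rejected = 0
    folds = []
    for s in seeds:
        comp = lda_fold_trial(s)
        folds.append(comp.fold)
        if comp.fold_ci is not None and comp.fold_ci[0] <= true_fold <= comp.fold_ci[1]:
            covered += 1
        if comp.p < 1e-4:
            rejected += 1
    return {"covered": covered, "rejected": rejected,
            "median_fold": float(np.median(folds)), "n": len(list(seeds))}


def lda_lrt_null_calibration(n_reps: int, seed: int, alpha: float = 0.05) -> float:
    """Rejection rate of the equal-frequency LRT when frequencies truly agree."""
    rejections = 0
    for r in range(n_reps):
        tbl = syndata.simulate_lda(
            [(1 / 1000, DOSE_LADDER, 12)] * 3, seed=seed + 1000 + r,
        )
        groups = [
            limiting_dilution.LDAGroup.from_frame(sub)
            for _, sub in tbl.groupby("arm", sort=False)
        ]
        comp = limiting_dilution.compare_groups(groups)
        rejections += comp.p < alpha
    return rejections / n_reps


def gsea_null_calibration(seed: int, n_sets: int = 50, n_perm: int = 200,
                          alpha: float = 0.05) -> float:
    """Nominal-p rejection rate for random gene sets on label-free data."""
    from .core import ExpressionMatrix
    import pandas as pd

    rng = np.random.default_rng(seed + 7)
    n_genes, n_per_class = 400, 10
    x = rng.normal(5, 1, size=(n_genes, 2 * n_per_class))
    genes = [f"G{i:04d}" for i in range(n_genes)]
    samples = [f"s{j}" for j in range(2 * n_per_class)]
    matrix = ExpressionMatrix(pd.DataFrame(x, index=genes, columns=samples), "log2rpm")
    labels = pd.Series(["a"] * n_per_class + ["b"] * n_per_class, index=samples)
    sets = {
        f"SET{k}": [genes[i] for i in rng.choice(n_genes, size=15, replace=False)]
        for k in range(n_sets)
    }
    res = gsea.gsea_test(matrix, labels, sets, n_perm=n_perm, perm_mode="sample",
                         seed=seed + 13)
    return float((res["p"] < alpha).mean())


def logrank_null_calibration(n_reps: int, seed: int, n_per_group: int = 50,
                             alpha: float = 0.05) -> float:
    """Log-rank rejection rate when the two arms share one hazard."""
    rejections = 0
    for r in range(n_reps):
        tbl = syndata.simulate_survival(n_per_group, 1.0, seed=seed + 2000 + r)
        rejections += clinstats.logrank_test(tbl)[1] < alpha
    return rejections / n_reps


def meta_recovery(seed: int, k: int = 200, mu: float = 0.3, tau2: float = 0.04) -> dict:
    """Pool k simulated studies and report the recovered (mu, tau2)."""
    studies = clinstats.studies_from_frame(syndata.simulate_meta(mu, tau2, k, seed=seed))
    res = clinstats.reml_meta(studies)
    return {"mu_hat": res.mu, "se": res.se, "tau2_hat": res.tau2, "k": k,
            "i2": res.i2}


def survival_hr_recovery(seed: int, n_per_group: int = 500,
                         hazard_ratio: float = 2.0) -> dict:
    """Cox and log-rank recovery of a known two-arm hazard ratio."""
    tbl = syndata.simulate_survival(n_per_group, hazard_ratio, seed=seed)
    tbl["grp"] = (tbl["group"] == "b").astype(float)
    fit = clinstats.cox_fit(tbl, ["grp"])
    chi2, p = clinstats.logrank_test(tbl)
    return {"hr_hat": float(fit.hr["grp"]), "wald_p": float(fit.p["grp"]),
            "logrank_chi2": chi2, "logrank_p": p, "n": 2 * n_per_group}
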