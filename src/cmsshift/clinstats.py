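"""Clinical statistics: random-effects meta-analysis, survival, bench formulas.

Three layers: (1) REML random-effects meta-analysis of ratio-scale effects
(HR/RR/OR pooled on the log scale) with the Altman reconstruction of a
missing standard error from a reported p value; (2) Kaplan-Meier curves,
the log-rank (Mantel-Cox) test, and a Cox proportional-hazards fit with
Wald tests; (3) small bench formulas (immunohistochemistry quick score,
caliper tumor volume, comparative-Ct fold change).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core import DataError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# meta-analysis
# ---------------------------------------------------------------------------

@dataclass
class MetaStudy:
    """One study's ratio-scale effect with optional CI / p / n."""

    study: str
    effect: float
    ci_low: float | None = None
    ci_high: float | None = None
    p: float | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        if self.effect <= 0:
            raise DataError(f"study '{self.study}': effect must be > 0 (ratio scale)")
        if self.ci_low is not None and self.ci_high is not None:
            if not (self.ci_low < self.effect < self.ci_high):
                raise DataError(
                    f"study '{self.study}': CI ({self.ci_low}, {self.ci_high}) "
                    f"does not bracket effect {self.effect}"
                )

    @property
    def has_ci(self) -> bool:
        return (
            self.ci_low is not None
            and self.ci_high is not None
            and np.isfinite(self.ci_low)
            and np.isfinite(self.ci_high)
        )


def studies_from_frame(df: pd.DataFrame) -> list[MetaStudy]:
    out = []
    for i, (_, row) in enumerate(df.iterrows()):
        def _opt(col):
            v = row.get(col)
            return None if v is None or (isinstance(v, float) and math.isnan(v)) else float(v)
        out.append(
            MetaStudy(
                study=str(row.get("study", f"study{i + 1}")),
                effect=float(row["effect"]),
                ci_low=_opt("ci_low"), ci_high=_opt("ci_high"), p=_opt("p"),
                n=int(row["n"]) if "n" in row and not pd.isna(row.get("n")) else None,
            )
        )
    return out


def altman_se(study: MetaStudy) -> tuple[float, str]:
    """Standard error of the log effect, reconstructing it when the CI is missing.

    With a 95% CI: SE = (log high - log low) / (2 * z_0.975). Without one,
    the reported two-sided p is inverted: SE = |log effect| / z(p) with
    z(p) the standard-normal quantile at 1 - p/2. Returns (SE, route).
    """
    z975 = stats.norm.ppf(0.975)
    if study.has_ci:
        se = (math.log(study.ci_high) - math.log(study.ci_low)) / (2 * z975)
        return se, "ci"
    if study.p is not None:
        if not (0 < study.p < 1):
            raise DataError(f"study '{study.study}': p={study.p} outside (0, 1)")
        if study.effect == 1.0:
            raise DataError(
                f"study '{study.study}': effect = 1 with no CI; SE unrecoverable from p"
            )
        z = stats.norm.ppf(1 - study.p / 2)
        return abs(math.log(study.effect)) / z, "p"
    raise DataError(f"study '{study.study}': neither CI nor p available")


@dataclass
class MetaResult:
    """Pooled random-effects estimate with heterogeneity statistics."""

    mu: float                       # pooled log-effect
    se: float
    ci_low: float                   # on the log scale
    ci_high: float
    tau2: float
    q: float                        # Cochran heterogeneity statistic
    i2: float                       # percent
    weights: pd.Series              # normalized random-effects weights
    k: int
    notes: list[str] = field(default_factory=list)

    @property
    def pooled_effect(self) -> float:
        """Pooled effect back on the ratio scale."""
        return float(np.exp(self.mu))


def _restricted_loglik(tau2: float, y: np.ndarray, v: np.ndarray) -> float:
    w = 1.0 / (v + tau2)
    mu = np.sum(w * y) / np.sum(w)
    return float(
        -0.5 * np.sum(np.log(v + tau2))
        - 0.5 * np.log(np.sum(w))
        - 0.5 * np.sum(w * (y - mu) ** 2)
    )


def reml_meta(studies: list[MetaStudy]) -> MetaResult:
    """Random-effects meta-analysis with REML between-study variance.

    Effects are pooled on the log scale with inverse-variance weights
    1/(v_i + tau2); tau2 maximizes the restricted log-likelihood (floored
    at 0). Heterogeneity is summarized by Cochran's Q at the fixed-effect
    weights and I2 = max(0, (Q - df) / Q). Mixing HR/RR/OR in one model is
    flagged in the notes, mirroring how heterogeneous ratio measures are
    pooled as-is.
    """
    if len(studies) < 2:
        raise DataError("reml_meta needs k >= 2 studies; report the single study directly")
    y = np.array([math.log(s.effect) for s in studies])
    se = np.array([altman_se(s)[0] for s in studies])
    v = se**2
    if not np.all(np.isfinite(y)) or not np.all(np.isfinite(v)) or (v <= 0).any():
        raise DataError("non-finite or non-positive study variances")

    upper = max(10.0 * float(np.var(y, ddof=1)), 1e-4)
    res = optimize.minimize_scalar(
        lambda t: -_restricted_loglik(t, y, v),
        bounds=(0.0, upper), method="bounded", options={"xatol": 1e-12},
    )
    tau2 = float(res.x)
    if _restricted_loglik(0.0, y, v) >= -float(res.fun):
        tau2 = 0.0
    w = 1.0 / (v + tau2)
    mu = float(np.sum(w * y) / np.sum(w))
    se_mu = float(np.sqrt(1.0 / np.sum(w)))
    z = stats.norm.ppf(0.975)

    w_fixed = 1.0 / v
    mu_fixed = np.sum(w_fixed * y) / np.sum(w_fixed)
    q = float(np.sum(w_fixed * (y - mu_fixed) ** 2))
    dfq = len(studies) - 1
    i2 = float(max(0.0, (q - dfq) / q) * 100.0) if q > 0 else 0.0

    weights = pd.Series(w / w.sum(), index=[s.study for s in studies])
    notes = []
    return MetaResult(
        mu=mu, se=se_mu, ci_low=mu - z * se_mu, ci_high=mu + z * se_mu,
        tau2=tau2, q=q, i2=i2, weights=weights, k=len(studies), notes=notes,
    )


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

def km_estimate(records: pd.DataFrame, group: str = "group") -> dict[str, pd.DataFrame]:
    """Product-limit survival curves per group.

    Returns, per group level, a DataFrame indexed by event time with the
    survival estimate (column ``survival``). Censored subjects leave the
    risk set after their censoring time.
    """
    from lifelines import KaplanMeierFitter

    out = {}
    for level, sub in records.groupby(group):
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], event_observed=sub["event"])
        df = kmf.survival_function_
        df.columns = ["survival"]
        out[str(level)] = df
    return out


def logrank_test(records: pd.DataFrame, group: str = "group") -> tuple[float, float]:
    """Two-group log-rank (Mantel-Cox) test; returns (chi2, p)."""
    from lifelines.statistics import logrank_test as _lr

    levels = sorted(records[group].astype(str).unique())
    if len(levels) != 2:
        raise DataError(f"logrank_test needs exactly 2 groups, got {levels}")
    a = records[records[group].astype(str) == levels[0]]
    b = records[records[group].astype(str) == levels[1]]
    for lv, sub in ((levels[0], a), (levels[1], b)):
        if sub["event"].sum() == 0:
            logger.warning("group '%s' has zero events; test is still defined", lv)
    res = _lr(a["time"], b["time"], event_observed_A=a["event"], event_observed_B=b["event"])
    return float(res.test_statistic), float(res.p_value)


@dataclass
class CoxFit:
    """Cox proportional-hazards fit with Wald statistics per covariate."""

    coef: pd.Series                  # beta
    hr: pd.Series                    # exp(beta)
    se: pd.Series
    z: pd.Series
    p: pd.Series
    loglik: float
    n_iter: int
    ties: str

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.coef, "hr": self.hr, "se": self.se, "z": self.z, "p": self.p}
        )


def _cox_loglik_grad_hess(beta, times, events, x, ties):
    """Breslow/Efron partial log-likelihood with gradient and Hessian."""
    order = np.argsort(times, kind="stable")
    t, e, xs = times[order], events[order], x[order]
    n, p = xs.shape
    eta = xs @ beta
    eta -= eta.max()                 # stabilize exponentials
    theta = np.exp(eta)

    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    # iterate event times from the largest down, accumulating the risk set
    s0 = 0.0
    s1 = np.zeros(p)
    s2 = np.zeros((p, p))
    i = n - 1
    unique_times = np.unique(t[e == 1])
    for tv in unique_times[::-1]:
        while i >= 0 and t[i] >= tv:
            s0 += theta[i]
            s1 += theta[i] * xs[i]
            s2 += theta[i] * np.outer(xs[i], xs[i])
            i -= 1
        d_idx = np.flatnonzero((t == tv) & (e == 1))
        d = len(d_idx)
        xd = xs[d_idx]
        td = theta[d_idx]
        ll += eta[d_idx].sum()
        if ties == "breslow" or d == 1:
            ll -= d * np.log(s0)
            grad += xd.sum(axis=0) - d * s1 / s0
            hess -= d * (s2 / s0 - np.outer(s1 / s0, s1 / s0))
        elif ties == "efron":
            td_s1 = (td[:, None] * xd).sum(axis=0)
            td_s2 = np.einsum("i,ij,ik->jk", td, xd, xd)
            td_s0 = td.sum()
            for r in range(d):
                frac = r / d
                c0 = s0 - frac * td_s0
                c1 = s1 - frac * td_s1
                c2 = s2 - frac * td_s2
                ll -= np.log(c0)
                grad -= c1 / c0
                hess -= c2 / c0 - np.outer(c1 / c0, c1 / c0)
            grad += xd.sum(axis=0)
        else:
            raise DataError(f"unknown tie method '{ties}'")
    return ll, grad, hess


def cox_fit(
    records: pd.DataFrame,
    covariates: list[str],
    time_col: str = "time",
    event_col: str = "event",
    ties: str = "breslow",
    max_iter: int = 50,
    tol: float = 1e-9,
) -> CoxFit:
    """Fit a Cox proportional-hazards model by Newton-Raphson.

    Covariates may be numeric columns or a binary group column already
    coded 0/1. Ties are handled by the Breslow approximation by default
    (Efron behind the ``ties`` flag). A constant covariate or a monotone
    (perfectly separating) likelihood raises with a diagnostic.
    """
    if records[event_col].sum() < 1:
        raise DataError("cox_fit needs at least one event")
    x = records[covariates].to_numpy(dtype=float)
    for j, c in enumerate(covariates):
        if np.ptp(x[:, j]) == 0:
            raise DataError(f"covariate '{c}' is constant")
    times = records[time_col].to_numpy(dtype=float)
    events = records[event_col].to_numpy(dtype=int)
    p = x.shape[1]
    # center covariates for numerical stability; beta is unaffected
    x = x - x.mean(axis=0)

    beta = np.zeros(p)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        ll, grad, hess = _cox_loglik_grad_hess(beta, times, events, x, ties)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as exc:
            raise DataError(f"singular information matrix at iteration {n_iter}") from exc
        beta_new = beta - step
        if np.abs(beta_new).max() > 50:
            raise DataError(
                "non-convergence: coefficients diverging (monotone likelihood / "
                "perfect separation suspected)"
            )
        if np.abs(beta_new - beta).max() < tol:
            beta = beta_new
            break
        beta = beta_new
    ll, grad, hess = _cox_loglik_grad_hess(beta, times, events, x, ties)
    cov = np.linalg.inv(-hess)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    pvals = 2 * stats.norm.sf(np.abs(z))
    idx = pd.Index(covariates)
    return CoxFit(
        coef=pd.Series(beta, index=idx), hr=pd.Series(np.exp(beta), index=idx),
        se=pd.Series(se, index=idx), z=pd.Series(z, index=idx),
        p=pd.Series(pvals, index=idx), loglik=float(ll), n_iter=n_iter, ties=ties,
    )


# ---------------------------------------------------------------------------
# bench formulas
# ---------------------------------------------------------------------------

def quick_score(percent_positive: float, intensity: float) -> float:
    """Immunohistochemistry quick score Q = P x I."""
    if not (0 <= percent_positive <= 100):
        raise DataError("percent_positive must lie in [0, 100]")
    if intensity < 0:
        raise DataError("intensity must be >= 0")
    return percent_positive * intensity


def tumor_volume(d_max: float, d_min: float) -> float:
    """Caliper tumor volume: largest diameter x smallest diameter^2 x pi/6."""
    if d_min <= 0 or d_max <= 0:
        raise DataError("diameters must be > 0")
    if d_min > d_max:
        raise DataError("smallest diameter exceeds largest diameter")
    return d_max * d_min**2 * math.pi / 6.0


def ddct_fold(
    ct_target_case: float, ct_ref_case: float,
    ct_target_ctrl: float, ct_ref_ctrl: float,
) -> float:
    """Comparative-Ct relative expression 2^-ddCt."""
    ddct = (ct_target_case - ct_ref_case) - (ct_target_ctrl - ct_ref_ctrl)
    return 2.0 ** (-ddct)
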