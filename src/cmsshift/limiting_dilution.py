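"""Single-hit limiting-dilution analysis of active-cell frequency.

A well (or injection site) seeded with d cells responds unless every cell
is inactive, so under the single-hit model P(negative) = (1 - f)^d for
active-cell frequency f. The fitter maximizes the exact binomial
log-likelihood over log f, reports a profile-likelihood 95% CI, and
compares experimental arms with a likelihood-ratio test plus the fold
change of frequencies. A complementary log-log GLM fit of the same model
is provided as an independent cross-check.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core import DataError

logger = logging.getLogger(__name__)

_CHI2_DROP = stats.chi2.ppf(0.95, 1) / 2        # 1.9207 log-likelihood units
_LOGF_MIN = -30.0                               # f = e^-30 ~ 9e-14: effective zero


@dataclass
class LDAGroup:
    """Dose-response table for one experimental arm."""

    label: str
    dose: np.ndarray
    n_tested: np.ndarray
    n_response: np.ndarray

    def __post_init__(self) -> None:
        self.dose = np.asarray(self.dose, dtype=float)
        self.n_tested = np.asarray(self.n_tested, dtype=int)
        self.n_response = np.asarray(self.n_response, dtype=int)
        if len(self.dose) == 0:
            raise DataError(f"arm '{self.label}': empty dose table")
        if (self.dose < 1).any() or not np.allclose(self.dose, np.round(self.dose)):
            raise DataError(f"arm '{self.label}': doses must be positive integers")
        if ((self.n_response < 0) | (self.n_response > self.n_tested)).any():
            raise DataError(f"arm '{self.label}': responses outside [0, n_tested]")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, label: str | None = None) -> "LDAGroup":
        return cls(
            label=label if label is not None else str(df["arm"].iloc[0]),
            dose=df["dose"].to_numpy(),
            n_tested=df["n_tested"].to_numpy(),
            n_response=df["n_response"].to_numpy(),
        )


def _loglik(log_f: float, dose, n_tested, n_response) -> float:
    """Binomial log-likelihood at frequency exp(log_f), constants dropped."""
    f = np.exp(log_f)
    if f >= 1.0:
        f = 1.0 - 1e-15
    log_q = dose * np.log1p(-f)                     # log P(negative well)
    with np.errstate(divide="ignore"):
        log_p = np.log(-np.expm1(log_q))            # log P(responding well)
    ll = n_response * log_p + (n_tested - n_response) * log_q
    return float(np.sum(ll))


@dataclass
class LDAFit:
    """Fitted single-hit frequency with profile-likelihood 95% CI."""

    label: str
    frequency: float
    ci_low: float
    ci_high: float
    loglik: float
    boundary: str | None = None      # 'all_positive' | 'all_negative' | None
    se_log_f: float | None = None

    @property
    def one_in(self) -> int:
        """ELDA-style report: the frequency as '1 in N' cells."""
        return int(round(1.0 / self.frequency)) if self.frequency > 0 else 0

    def summary(self) -> dict:
        return {
            "arm": self.label,
            "frequency": self.frequency,
            "one_in": self.one_in,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "boundary": self.boundary,
        }


def _profile_bound(ll_target, dose, nt, nr, lo: float, hi: float) -> float:
    """Root of profile log-likelihood minus target on [lo, hi] in log f."""
    g = lambda u: _loglik(u, dose, nt, nr) - ll_target
    return optimize.brentq(g, lo, hi, xtol=1e-10)


def fit_frequency(group: LDAGroup) -> LDAFit:
    """Maximum-likelihood active-cell frequency under the single-hit model.

    Optimizes the exact (1-f)^d binomial likelihood over log f and inverts
    the likelihood ratio for a 95% CI (chi2_1 drop of 1.9207). All-responding
    data put the estimate at the f = 1 boundary with a one-sided lower
    bound; all-negative data put it at the 0 boundary with a one-sided
    upper bound; both are flagged.
    """
    dose, nt, nr = group.dose, group.n_tested, group.n_response
    all_pos = (nr == nt).all()
    all_neg = (nr == 0).all()
    if all_pos:
        ll_max = _loglik(0.0, dose, nt, nr)   # f -> 1 (log f -> 0)
        ci_low = float(np.exp(_profile_bound(ll_max - _CHI2_DROP, dose, nt, nr, _LOGF_MIN, -1e-12)))
        logger.warning("arm '%s': every well responded; frequency at upper boundary", group.label)
        return LDAFit(group.label, 1.0, ci_low, 1.0, ll_max, boundary="all_positive")
    if all_neg:
        ll_max = 0.0                           # f -> 0: likelihood -> 1
        # one-sided 95% upper bound: solve ll(f) = -chi2_1(0.90)/2 one-sided?
        # Use the same LR drop as the two-sided machinery for consistency.
        ci_high = float(np.exp(_profile_bound(ll_max - _CHI2_DROP, dose, nt, nr, _LOGF_MIN, -1e-12)))
        logger.warning("arm '%s': no well responded; frequency at zero boundary", group.label)
        return LDAFit(group.label, 0.0, 0.0, ci_high, ll_max, boundary="all_negative")

    res = optimize.minimize_scalar(
        lambda u: -_loglik(u, dose, nt, nr),
        bounds=(_LOGF_MIN, -1e-12),
        method="bounded",
        options={"xatol": 1e-12},
    )
    u_hat = float(res.x)
    ll_max = -float(res.fun)
    target = ll_max - _CHI2_DROP
    lo = _profile_bound(target, dose, nt, nr, _LOGF_MIN, u_hat)
    if _loglik(-1e-12, dose, nt, nr) > target:
        hi = -1e-12   # CI reaches the f = 1 boundary
    else:
        hi = _profile_bound(target, dose, nt, nr, u_hat, -1e-12)
    # observed information in log f for Wald-style fold CIs downstream
    h = 1e-5
    d2 = (_loglik(u_hat + h, dose, nt, nr) - 2 * ll_max + _loglik(u_hat - h, dose, nt, nr)) / h**2
    se = float(1.0 / np.sqrt(-d2)) if d2 < 0 else None
    return LDAFit(
        group.label, float(np.exp(u_hat)), float(np.exp(lo)), float(np.exp(hi)),
        ll_max, se_log_f=se,
    )


@dataclass
class LDAComparison:
    """Multi-arm comparison: fold change and likelihood-ratio test."""

    fits: list[LDAFit]
    lrt: float
    df: int
    p: float
    fold: float | None = None
    fold_ci: tuple[float, float] | None = None


def compare_groups(groups: list[LDAGroup]) -> LDAComparison:
    """Likelihood-ratio test of equal frequency across arms.

    LRT = 2 * (sum of separate maximized log-likelihoods - pooled maximized
    log-likelihood), referred to chi2 with n_groups - 1 df. For two arms the
    fold change f_first / f_last is reported with a Wald 95% CI on the log
    scale; a fold is undefined (with a warning) when an arm sits at the zero
    boundary.
    """
    if len(groups) < 2:
        raise DataError("compare_groups needs >=2 arms")
    fits = [fit_frequency(g) for g in groups]
    pooled = LDAGroup(
        label="pooled",
        dose=np.concatenate([g.dose for g in groups]),
        n_tested=np.concatenate([g.n_tested for g in groups]),
        n_response=np.concatenate([g.n_response for g in groups]),
    )
    fit_common = fit_frequency(pooled)
    lrt = max(0.0, 2.0 * (sum(f.loglik for f in fits) - fit_common.loglik))
    df = len(groups) - 1
    p = float(stats.chi2.sf(lrt, df))

    fold = fold_ci = None
    if len(groups) == 2:
        fa, fb = fits[0], fits[1]
        if fa.frequency > 0 and fb.frequency > 0:
            fold = fa.frequency / fb.frequency
            if fa.se_log_f is not None and fb.se_log_f is not None:
                se = np.hypot(fa.se_log_f, fb.se_log_f)
                z = stats.norm.ppf(0.975)
                fold_ci = (float(fold * np.exp(-z * se)), float(fold * np.exp(z * se)))
        else:
            logger.warning("an arm sits at the zero boundary; fold change undefined")
    return LDAComparison(fits=fits, lrt=lrt, df=df, p=p, fold=fold, fold_ci=fold_ci)


def fit_frequency_glm(group: LDAGroup) -> float:
    """Cross-check fit via a binomial GLM with complementary log-log link.

    The single-hit model is exactly a cloglog regression of well response on
    an intercept with offset log(dose): cloglog P(response) = log d +
    log(-log(1 - f)). Returns the implied frequency.
    """
    import statsmodels.api as sm

    endog = np.column_stack([group.n_response, group.n_tested - group.n_response])
    exog = np.ones((len(group.dose), 1))
    model = sm.GLM(
        endog, exog,
        family=sm.families.Binomial(link=sm.families.links.CLogLog()),
        offset=np.log(group.dose),
    )
    res = model.fit()
    beta0 = float(res.params[0])
    return float(-np.expm1(-np.exp(beta0)))
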