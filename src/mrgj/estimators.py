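"""Causal-effect estimators for two-sample MR from harmonized instruments.

Every estimator combines per-SNP Wald ratios theta_j = beta_out_j / beta_exp_j
with first-order standard errors se_j = se_out_j / |beta_exp_j|:

* **IVW** — inverse-variance weighted mean of the ratios; algebraically equal
  to weighted least squares of beta_out on beta_exp through the origin with
  weights 1/se_out².  The default multiplicative random-effects model inflates
  the fixed-effects SE by sqrt(max(1, Q/(J−1))) so heterogeneity widens, and
  never narrows, the interval.
* **MR-Egger** — weighted regression of beta_out on beta_exp *with* an
  intercept after orienting each SNP to beta_exp >= 0; the intercept estimates
  the mean directional pleiotropic effect (its test is the pleiotropy check),
  and the slope is a causal estimate that is consistent under InSIDE.
  Inference uses the t distribution with J−2 df.
* **Weighted median** — the weight-0.5 quantile of the ordered ratios;
  consistent when valid instruments carry more than half the weight.
* **Simple / weighted mode** — argmax of a normal-kernel density over the
  ratios; consistent when the largest group of instruments sharing one ratio
  value is valid (ZEMPA).  Bandwidth h = phi·0.9·min(sd, IQR/1.349)·J^(−1/5).

Median and mode standard errors come from a parametric bootstrap: each ratio
is redrawn from N(theta_j, se_j²) and the estimator recomputed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from mrgj.harmonize import HarmonizedSet

logger = logging.getLogger(__name__)

Z_975 = 1.959964  # two-sided 95% normal quantile

DEFAULT_N_BOOT = 1000
DEFAULT_BOOT_SEED = 20241126


class EstimatorError(ValueError):
    pass


@dataclass
class MREstimate:
    """One method's causal estimate on the outcome log-odds scale."""

    method: str
    nsnp: int
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    or_: float
    or_low: float
    or_high: float

    def as_dict(self) -> dict:
        return {
            "method": self.method,
            "nsnp": self.nsnp,
            "beta": self.beta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "pval": self.pval,
            "or": self.or_,
            "or_low": self.or_low,
            "or_high": self.or_high,
        }


def wald_summary(beta: float, se: float) -> tuple[float, float, float, tuple[float, float, float]]:
    """95% CI, two-sided normal p, and odds-ratio scale for an estimate."""
    if se <= 0:
        raise EstimatorError("se must be positive")
    ci_low = beta - Z_975 * se
    ci_high = beta + Z_975 * se
    pval = 2.0 * stats.norm.sf(abs(beta) / se)
    return ci_low, ci_high, pval, (np.exp(beta), np.exp(ci_low), np.exp(ci_high))


def _estimate(method: str, nsnp: int, beta: float, se: float, pval: float | None = None) -> MREstimate:
    ci_low, ci_high, p_norm, (or_, or_lo, or_hi) = wald_summary(beta, se)
    return MREstimate(
        method=method,
        nsnp=nsnp,
        beta=float(beta),
        se=float(se),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        pval=float(p_norm if pval is None else pval),
        or_=float(or_),
        or_low=float(or_lo),
        or_high=float(or_hi),
    )


def wald_ratios(h: HarmonizedSet) -> pd.DataFrame:
    """Per-SNP Wald ratios with first-order SEs and inverse-variance weights.

    SNPs with beta_exp = 0 have no defined ratio and are excluded with a log
    entry.
    """
    t = h.table if isinstance(h, HarmonizedSet) else h
    zero = t["beta_exp"] == 0
    if zero.any():
        logger.warning(
            "excluding %d SNP(s) with zero exposure beta: %s",
            int(zero.sum()),
            list(t.loc[zero, "variant_id"]),
        )
        t = t[~zero]
    theta = t["beta_out"] / t["beta_exp"]
    se_theta = t["se_out"] / t["beta_exp"].abs()
    return pd.DataFrame(
        {
            "variant_id": t["variant_id"].to_numpy(),
            "theta": theta.to_numpy(float),
            "se_theta": se_theta.to_numpy(float),
            "weight": 1.0 / se_theta.to_numpy(float) ** 2,
        }
    )


def _q_statistic(theta: np.ndarray, weight: np.ndarray, pooled: float) -> float:
    return float(np.sum(weight * (theta - pooled) ** 2))


def ivw(ratios: pd.DataFrame, effects_model: str = "multiplicative_random") -> MREstimate:
    """Inverse-variance weighted estimate of the causal effect.

    ``effects_model`` is ``"fixed"`` or ``"multiplicative_random"`` (default);
    the latter inflates the SE by sqrt(max(1, Q/(J−1))).
    """
    if effects_model not in ("fixed", "multiplicative_random"):
        raise EstimatorError(f"unknown effects model {effects_model!r}")
    theta = np.asarray(ratios["theta"], dtype=float)
    w = np.asarray(ratios["weight"], dtype=float)
    j = len(theta)
    if j == 0:
        raise EstimatorError("no Wald ratios supplied")
    if j == 1:
        warnings.warn("single instrument: IVW degenerates to the Wald ratio")
    beta = float(np.sum(w * theta) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    if effects_model == "multiplicative_random" and j >= 2:
        q = _q_statistic(theta, w, beta)
        se *= np.sqrt(max(1.0, q / (j - 1)))
    return _estimate("ivw", j, beta, se)


def egger(h: HarmonizedSet) -> tuple[MREstimate, dict]:
    """MR-Egger regression: (slope estimate, intercept triple).

    Each SNP is oriented so beta_exp >= 0 (both betas negated where needed),
    then beta_out is regressed on beta_exp with an intercept and weights
    1/se_out².  SEs are inflated by sqrt(max(1, Q_E/(J−2))); p-values use the
    t distribution with J−2 df.  The intercept triple carries the horizontal
    pleiotropy test.
    """
    t = h.table if isinstance(h, HarmonizedSet) else h
    j = len(t)
    if j < 3:
        raise EstimatorError("MR-Egger needs at least 3 instruments")
    sign = np.where(t["beta_exp"].to_numpy(float) < 0, -1.0, 1.0)
    bx = sign * t["beta_exp"].to_numpy(float)
    by = sign * t["beta_out"].to_numpy(float)
    w = 1.0 / t["se_out"].to_numpy(float) ** 2
    if np.ptp(bx) == 0:
        raise EstimatorError("all exposure betas identical after orientation")
    fit = sm.WLS(by, sm.add_constant(bx), weights=w).fit()
    # fit.scale = Q_E/(J-2); rescale so the inflation is floored at 1
    scale = float(fit.scale)
    infl = np.sqrt(max(1.0, scale) / scale)
    se_int, se_slope = fit.bse[0] * infl, fit.bse[1] * infl
    b_int, b_slope = fit.params[0], fit.params[1]
    p_slope = 2.0 * stats.t.sf(abs(b_slope / se_slope), df=j - 2)
    p_int = 2.0 * stats.t.sf(abs(b_int / se_int), df=j - 2)
    slope = _estimate("egger_slope", j, b_slope, se_slope, pval=p_slope)
    intercept = {"estimate": float(b_int), "se": float(se_int), "pval": float(p_int)}
    return slope, intercept


def _weighted_median_point(theta: np.ndarray, weight: np.ndarray) -> float:
    order = np.argsort(theta, kind="mergesort")
    th = theta[order]
    p = weight[order] / np.sum(weight)
    s = np.cumsum(p) - p / 2.0
    if s[0] >= 0.5:
        return float(th[0])
    if s[-1] <= 0.5:
        return float(th[-1])
    return float(np.interp(0.5, s, th))


def _parametric_bootstrap(point_fn, theta, se_theta, n_boot, seed) -> float:
    if n_boot < 2:
        raise EstimatorError("n_boot must be at least 2")
    if n_boot < 100:
        warnings.warn("n_boot < 100 gives unstable bootstrap SEs")
    rng = np.random.default_rng(seed)
    draws = theta + se_theta * rng.standard_normal((n_boot, len(theta)))
    boots = np.array([point_fn(d) for d in draws])
    return float(np.std(boots, ddof=1))


def weighted_median(
    ratios: pd.DataFrame,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = DEFAULT_BOOT_SEED,
) -> MREstimate:
    """Weighted-median estimator with parametric-bootstrap SE."""
    theta = np.asarray(ratios["theta"], dtype=float)
    w = np.asarray(ratios["weight"], dtype=float)
    if len(theta) < 3:
        raise EstimatorError("weighted median needs at least 3 instruments")
    beta = _weighted_median_point(theta, w)
    se_theta = np.asarray(ratios["se_theta"], dtype=float)
    se = _parametric_bootstrap(
        lambda d: _weighted_median_point(d, w), theta, se_theta, n_boot, seed
    )
    return _estimate("weighted_median", len(theta), beta, se)


def _kde_argmax(theta: np.ndarray, weight: np.ndarray, phi: float) -> float:
    sd = np.std(theta, ddof=1)
    iqr = np.subtract(*np.percentile(theta, [75, 25]))
    spread = min(sd, iqr / 1.349) if iqr > 0 else sd
    h = phi * 0.9 * spread * len(theta) ** (-1 / 5)
    if h == 0:
        return float(theta[0])
    grid = np.linspace(theta.min() - 3 * h, theta.max() + 3 * h, 512)
    dens = np.sum(
        weight[:, None] * np.exp(-0.5 * ((grid[None, :] - theta[:, None]) / h) ** 2),
        axis=0,
    )
    return float(grid[np.argmax(dens)])


def mode_estimate(
    ratios: pd.DataFrame,
    weighted: bool = False,
    phi: float = 1.0,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = DEFAULT_BOOT_SEED,
) -> MREstimate:
    """Mode-based estimator (simple when unweighted, weighted otherwise).

    The estimate is the argmax of a normal-kernel smoothed density of the
    Wald ratios on a 512-point grid spanning [min−3h, max+3h]; ``phi``
    multiplies the default bandwidth.  SE by parametric bootstrap.
    """
    if phi <= 0:
        raise EstimatorError("phi must be positive")
    theta = np.asarray(ratios["theta"], dtype=float)
    if len(theta) < 3:
        raise EstimatorError("mode estimators need at least 3 instruments")
    w = np.asarray(ratios["weight"], dtype=float) if weighted else np.ones_like(theta)
    w = w / np.sum(w)
    method = "weighted_mode" if weighted else "simple_mode"
    if np.ptp(theta) == 0:
        warnings.warn("all Wald ratios identical: mode is degenerate with zero SE")
        val = float(theta[0])
        return MREstimate(
            method=method, nsnp=len(theta), beta=val, se=0.0,
            ci_low=val, ci_high=val, pval=float("nan"),
            or_=float(np.exp(val)), or_low=float(np.exp(val)), or_high=float(np.exp(val)),
        )
    beta = _kde_argmax(theta, w, phi)
    se_theta = np.asarray(ratios["se_theta"], dtype=float)
    se = _parametric_bootstrap(
        lambda d: _kde_argmax(d, w, phi), theta, se_theta, n_boot, seed
    )
    return _estimate(method, len(theta), beta, se)


def fit_all(
    h: HarmonizedSet,
    methods: tuple[str, ...] = ("ivw", "egger", "weighted_median", "simple_mode", "weighted_mode"),
    effects_model: str = "multiplicative_random",
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = DEFAULT_BOOT_SEED,
) -> tuple[list[MREstimate], dict | None]:
    """Fit the requested estimators; returns (estimates, Egger intercept)."""
    ratios = wald_ratios(h)
    estimates: list[MREstimate] = []
    intercept = None
    for m in methods:
        if m == "ivw":
            estimates.append(ivw(ratios, effects_model=effects_model))
        elif m == "egger":
            slope, intercept = egger(h)
            estimates.append(slope)
        elif m == "weighted_median":
            estimates.append(weighted_median(ratios, n_boot=n_boot, seed=seed))
        elif m == "simple_mode":
            estimates.append(mode_estimate(ratios, weighted=False, n_boot=n_boot, seed=seed))
        elif m == "weighted_mode":
            estimates.append(mode_estimate(ratios, weighted=True, n_boot=n_boot, seed=seed))
        else:
            raise EstimatorError(f"unknown method {m!r}")
    return estimates, intercept
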