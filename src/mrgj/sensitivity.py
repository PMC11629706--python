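"""Heterogeneity, pleiotropy, influence, and directionality diagnostics.

* Cochran's Q — weighted sum of squared deviations of per-SNP Wald ratios
  from the pooled estimate, referred to chi-square with J−1 df (IVW) or J−2
  (Egger, where deviations are regression residuals).  P > 0.05 is read as no
  material heterogeneity.
* Egger intercept test — a non-zero intercept indicates directional
  horizontal pleiotropy; p > 0.05 is read as none detected.
* Leave-one-out — IVW recomputed with each SNP removed in turn; a SNP is
  flagged influential if its exclusion flips the sign of the estimate or
  moves the p-value across 0.05.
* Steiger directionality — compares the variance the instruments explain in
  the exposure versus the outcome; the causal arrow is deemed correct when
  the exposure R² is larger.  For a binary outcome the observed-scale
  approximation r² = z²/(z² + n) per SNP is used, which needs no outcome EAF.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from mrgj.estimators import MREstimate, egger, ivw, wald_ratios
from mrgj.harmonize import HarmonizedSet
from mrgj.instruments import snp_r2


class SensitivityError(ValueError):
    pass


@dataclass
class HeterogeneityResult:
    method: str  # "ivw" | "egger"
    q: float
    df: int
    pval: float


@dataclass
class SteigerResult:
    r2_exposure: float
    r2_outcome: float
    correct_direction: bool
    pval: float


def cochran_q(ratios: pd.DataFrame, pooled, method: str = "ivw") -> HeterogeneityResult:
    """Cochran's Q of Wald ratios about a pooled estimate.

    ``pooled`` is an MREstimate or a plain pooled beta.  df is J−1 for IVW
    and J−2 for Egger (residual-based Q should be supplied for the latter).
    """
    theta = np.asarray(ratios["theta"], dtype=float)
    w = np.asarray(ratios["weight"], dtype=float)
    j = len(theta)
    if j < 2:
        raise SensitivityError("Cochran's Q needs at least 2 instruments")
    beta = pooled.beta if isinstance(pooled, MREstimate) else float(pooled)
    q = float(np.sum(w * (theta - beta) ** 2))
    df = j - 1 if method == "ivw" else j - 2
    if df < 1:
        raise SensitivityError("not enough instruments for the requested df")
    return HeterogeneityResult(method=method, q=q, df=df, pval=float(stats.chi2.sf(q, df)))


def heterogeneity_tests(h: HarmonizedSet) -> list[HeterogeneityResult]:
    """IVW and Egger heterogeneity statistics for a harmonized set."""
    ratios = wald_ratios(h)
    pooled = ivw(ratios, effects_model="fixed")
    results = [cochran_q(ratios, pooled, method="ivw")]
    if h.nsnp >= 3:
        t = h.table
        sign = np.where(t["beta_exp"].to_numpy(float) < 0, -1.0, 1.0)
        bx, by = sign * t["beta_exp"].to_numpy(float), sign * t["beta_out"].to_numpy(float)
        w = 1.0 / t["se_out"].to_numpy(float) ** 2
        slope, intercept = egger(h)
        resid = by - intercept["estimate"] - slope.beta * bx
        q_e = float(np.sum(w * resid**2))
        df = h.nsnp - 2
        results.append(
            HeterogeneityResult(method="egger", q=q_e, df=df, pval=float(stats.chi2.sf(q_e, df)))
        )
    return results


def egger_intercept_test(intercept: dict, alpha: float = 0.05) -> dict:
    """Verdict on horizontal pleiotropy from the Egger intercept triple."""
    verdict = (
        "no_horizontal_pleiotropy_detected"
        if intercept["pval"] > alpha
        else "horizontal_pleiotropy_detected"
    )
    return {**intercept, "alpha": alpha, "verdict": verdict}


def leave_one_out(
    h: HarmonizedSet,
    effects_model: str = "multiplicative_random",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Leave-one-out IVW table with influence flags.

    One row per excluded SNP plus an all-SNP row (excluded_variant_id "none").
    ``sign_flip`` marks exclusions that change the sign of the estimate;
    ``p_crossing`` marks exclusions that move the p-value across ``alpha``.
    """
    if h.nsnp < 3:
        raise SensitivityError("leave-one-out needs at least 3 instruments")
    ratios = wald_ratios(h)
    full = ivw(ratios, effects_model=effects_model)
    rows = []
    for i in range(len(ratios)):
        sub = ratios.drop(index=i)
        est = ivw(sub, effects_model=effects_model)
        rows.append(
            {
                "excluded_variant_id": ratios.loc[i, "variant_id"],
                "beta": est.beta,
                "se": est.se,
                "pval": est.pval,
                "sign_flip": bool(np.sign(est.beta) != np.sign(full.beta)),
                "p_crossing": bool((est.pval < alpha) != (full.pval < alpha)),
            }
        )
    rows.append(
        {
            "excluded_variant_id": "none",
            "beta": full.beta,
            "se": full.se,
            "pval": full.pval,
            "sign_flip": False,
            "p_crossing": False,
        }
    )
    out = pd.DataFrame(rows)
    out["influential"] = out["sign_flip"] | out["p_crossing"]
    return out


def steiger_test(
    h: HarmonizedSet,
    n_exp: float | None = None,
    n_out: float | None = None,
) -> SteigerResult:
    """MR-Steiger directionality test over the full instrument set.

    Exposure R² sums the per-SNP variance explained (normalized form once the
    set has >= 10 SNPs); outcome R² sums z²/(z² + n) per SNP.  The p-value
    compares Fisher-transformed sqrt(R²) values with variances 1/(n−3) on
    each side (two-sided).
    """
    t = h.table
    j = len(t)
    if j == 0:
        raise SensitivityError("empty instrument set")
    n_exp = float(t["n_exp"].mean()) if n_exp is None else float(n_exp)
    n_out = float(t["n_out"].mean()) if n_out is None else float(n_out)
    if n_exp <= 3 or n_out <= 3:
        raise SensitivityError("need n > 3 on both sides")
    r2_exp = sum(
        snp_r2(
            row["eaf_exp"], row["beta_exp"], se=row["se_exp"], n=row["n_exp"], variant_count=j
        )
        for _, row in t.iterrows()
    )
    z_out = t["beta_out"].to_numpy(float) / t["se_out"].to_numpy(float)
    r2_out = float(np.sum(z_out**2 / (z_out**2 + n_out)))
    r2_exp = min(r2_exp, 1.0 - 1e-12)
    r2_out = min(r2_out, 1.0 - 1e-12)
    z = (np.arctanh(np.sqrt(r2_exp)) - np.arctanh(np.sqrt(r2_out))) / np.sqrt(
        1.0 / (n_exp - 3.0) + 1.0 / (n_out - 3.0)
    )
    return SteigerResult(
        r2_exposure=float(r2_exp),
        r2_outcome=float(r2_out),
        correct_direction=bool(r2_exp > r2_out),
        pval=float(2.0 * stats.norm.sf(abs(z))),
    )
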