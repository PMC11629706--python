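"""Statistical validation studies run against the synthetic generator.

Each study simulates many independent exposure/outcome GWAS pairs under a
known truth, pushes every replicate through the same harmonization and
estimation code the pipeline uses, and summarizes how well the estimators
recover that truth:

* ``recovery_study`` — mean IVW estimate and empirical 95% CI coverage under
  a fixed causal effect with valid instruments;
* ``type1_study`` — IVW rejection rate under a null effect and Cochran's Q
  rejection rate under exact homogeneity;
* ``egger_recovery_study`` — mean Egger intercept and slope under directional
  pleiotropy with InSIDE holding;
* ``median_robustness_study`` — bias of the weighted median versus IVW when
  a minority of instruments is invalid;
* ``ivw_wls_agreement`` — numerical agreement of the IVW estimator with an
  independent weighted-least-squares-through-origin solve;
* ``clump_agreement`` — agreement of greedy clumping with an exhaustive
  reference that re-scans the full candidate list each round.

Replicate seeds are derived from one master seed, so every study is exactly
reproducible.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from mrgj.estimators import _weighted_median_point, egger, ivw, wald_ratios
from mrgj.harmonize import HarmonizedSet, harmonize
from mrgj.instruments import clump
from mrgj.io import LDMatrix, SumStats
from mrgj.sensitivity import cochran_q
from mrgj.simulate import SimulationConfig, simulate_pair

#: default sample sizes of the emulated study design
N_EXP = 18_000
N_OUT = 148_000
CASE_FRACTION = 1086 / 148307


def _rep_seeds(seed: int, n_reps: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n_reps) % (2**31)


def _simulate_harmonized(cfg: SimulationConfig):
    exposure, outcome, truth = simulate_pair(cfg)
    return harmonize(exposure, outcome), truth


def _base_config(seed: int, **overrides) -> SimulationConfig:
    base = dict(
        j_snps=50,
        n_exp=N_EXP,
        n_out=N_OUT,
        case_fraction=CASE_FRACTION,
        palindrome_fraction=0.0,
        strand_flip_fraction=0.0,
        seed=int(seed),
    )
    base.update(overrides)
    return SimulationConfig(**base)


def recovery_study(
    n_reps: int = 500,
    beta_causal: float = 0.5,
    j_snps: int = 50,
    seed: int = 1,
) -> dict:
    """IVW recovery of a fixed causal effect with valid instruments.

    Returns the mean estimate, its Monte-Carlo SE, and the empirical
    coverage of the 95% interval (in percent).
    """
    betas, covered = [], []
    for s in _rep_seeds(seed, n_reps):
        h, _ = _simulate_harmonized(_base_config(s, j_snps=j_snps, beta_causal=beta_causal))
        est = ivw(wald_ratios(h))
        betas.append(est.beta)
        covered.append(est.ci_low <= beta_causal <= est.ci_high)
    betas = np.asarray(betas)
    return {
        "n_reps": n_reps,
        "beta_causal": beta_causal,
        "mean_beta": float(betas.mean()),
        "mc_se": float(betas.std(ddof=1) / np.sqrt(n_reps)),
        "coverage_pct": float(100.0 * np.mean(covered)),
    }


def type1_study(n_reps: int = 2000, j_snps: int = 50, alpha: float = 0.05, seed: int = 2) -> dict:
    """Rejection rates under the null: IVW test and Cochran's Q."""
    ivw_rej, q_rej = 0, 0
    for s in _rep_seeds(seed, n_reps):
        h, _ = _simulate_harmonized(_base_config(s, beta_causal=0.0, j_snps=j_snps))
        ratios = wald_ratios(h)
        est = ivw(ratios)
        if est.pval < alpha:
            ivw_rej += 1
        pooled = ivw(ratios, effects_model="fixed")
        if cochran_q(ratios, pooled).pval < alpha:
            q_rej += 1
    return {
        "n_reps": n_reps,
        "alpha": alpha,
        "ivw_rejection_rate": ivw_rej / n_reps,
        "q_rejection_rate": q_rej / n_reps,
    }


def egger_recovery_study(
    n_reps: int = 500,
    mean_alpha: float = 0.1,
    sd_alpha: float = 0.08,
    beta_causal: float = 0.5,
    j_snps: int = 50,
    seed: int = 3,
) -> dict:
    """Egger intercept/slope recovery under directional pleiotropy (InSIDE held)."""
    intercepts, slopes = [], []
    for s in _rep_seeds(seed, n_reps):
        cfg = _base_config(
            s,
            beta_causal=beta_causal,
            j_snps=j_snps,
            pleiotropy="directional",
            mean_alpha=mean_alpha,
            sd_alpha=sd_alpha,
        )
        h, _ = _simulate_harmonized(cfg)
        slope, intercept = egger(h)
        intercepts.append(intercept["estimate"])
        slopes.append(slope.beta)
    intercepts, slopes = np.asarray(intercepts), np.asarray(slopes)
    return {
        "n_reps": n_reps,
        "mean_alpha": mean_alpha,
        "beta_causal": beta_causal,
        "mean_intercept": float(intercepts.mean()),
        "intercept_mc_se": float(intercepts.std(ddof=1) / np.sqrt(n_reps)),
        "mean_slope": float(slopes.mean()),
        "slope_mc_se": float(slopes.std(ddof=1) / np.sqrt(n_reps)),
    }


def median_robustness_study(
    n_reps: int = 500,
    invalid_fraction: float = 0.4,
    mean_alpha: float = 0.8,
    beta_causal: float = 0.5,
    j_snps: int = 50,
    seed: int = 4,
) -> dict:
    """Weighted-median versus IVW bias with a minority of invalid instruments.

    Directional pleiotropy corrupts ``invalid_fraction`` of the SNPs (about
    the same fraction of total weight in expectation); the weighted median
    should stay far less biased than IVW.
    """
    wm, iv = [], []
    for s in _rep_seeds(seed, n_reps):
        cfg = _base_config(
            s,
            beta_causal=beta_causal,
            j_snps=j_snps,
            pleiotropy="directional",
            mean_alpha=mean_alpha,
            sd_alpha=0.05,
            pleiotropy_fraction=invalid_fraction,
        )
        h, _ = _simulate_harmonized(cfg)
        ratios = wald_ratios(h)
        iv.append(ivw(ratios).beta)
        wm.append(
            _weighted_median_point(
                ratios["theta"].to_numpy(), ratios["weight"].to_numpy()
            )
        )
    bias_ivw = float(np.mean(iv) - beta_causal)
    bias_wm = float(np.mean(wm) - beta_causal)
    return {
        "n_reps": n_reps,
        "invalid_fraction": invalid_fraction,
        "bias_ivw": bias_ivw,
        "bias_weighted_median": bias_wm,
        "abs_bias_ratio": abs(bias_wm) / abs(bias_ivw),
    }


def ivw_wls_agreement(n_instances: int = 200, seed: int = 5) -> dict:
    """Max |difference| between IVW and an independent WLS-through-origin solve.

    The reference route solves the weighted normal equation
    beta = (x' W y) / (x' W x) with W = diag(1/se_out²) directly — no Wald
    ratios involved — and its SE as (x' W x)^{-1/2}.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        j = int(rng.integers(3, 30))
        bx = rng.normal(0.3, 0.1, j)
        bx[np.abs(bx) < 1e-3] = 0.1  # keep ratios defined
        by = rng.normal(0.15, 0.1, j)
        se_out = rng.uniform(0.01, 0.2, j)
        table = pd.DataFrame(
            {
                "variant_id": [f"rs{i}" for i in range(j)],
                "beta_exp": bx,
                "se_exp": 0.01,
                "beta_out": by,
                "se_out": se_out,
            }
        )
        ratios = wald_ratios(HarmonizedSet(table=table))
        mine = ivw(ratios, effects_model="fixed")
        w = 1.0 / se_out**2
        ref_beta = float(np.sum(bx * w * by) / np.sum(bx * w * bx))
        ref_se = float(np.sum(bx * w * bx) ** -0.5)
        worst = max(worst, abs(mine.beta - ref_beta), abs(mine.se - ref_se))
    return {"n_instances": n_instances, "max_abs_diff": worst}


def reference_clump(df: pd.DataFrame, ld: LDMatrix, r2_threshold: float, window_kb: float) -> set:
    """Exhaustive clumping reference: re-sorts and re-scans every round."""
    alive = df.copy()
    kept = []
    while len(alive):
        alive = alive.sort_values(["pval", "chrom", "pos", "variant_id"])
        index = alive.iloc[0]
        kept.append(index["variant_id"])
        drop = [index.name]
        for idx, row in alive.iloc[1:].iterrows():
            if (
                row["chrom"] == index["chrom"]
                and abs(row["pos"] - index["pos"]) <= window_kb * 1000
                and ld.r2_between(index["variant_id"], row["variant_id"]) >= r2_threshold
            ):
                drop.append(idx)
        alive = alive.drop(index=drop)
    return set(kept)


def _random_clump_instance(rng: np.random.Generator, n: int = 20):
    ids = [f"rs{i:03d}" for i in range(n)]
    sizes = []
    while sum(sizes) < n:
        sizes.append(min(int(rng.integers(1, 5)), n - sum(sizes)))
    r2 = np.zeros((n, n))
    pos = np.zeros(n, dtype=np.int64)
    chrom = []
    i = 0
    for b, size in enumerate(sizes):
        r2[i : i + size, i : i + size] = rng.uniform(0, 1)
        spacing = 1000 if rng.random() < 0.5 else 20_000_000
        for k in range(size):
            pos[i + k] = 1 + b * 50_000_000 + k * spacing
        chrom += [str(b % 3 + 1)] * size
        i += size
    np.fill_diagonal(r2, 1.0)
    table = pd.DataFrame(
        {
            "variant_id": ids,
            "chrom": chrom,
            "pos": pos,
            "effect_allele": "A",
            "other_allele": "G",
            "eaf": 0.3,
            "beta": 0.1,
            "se": 0.01,
            "pval": rng.uniform(1e-12, 1e-4, n),
            "n": np.int64(10_000),
        }
    )
    return SumStats(trait_id="t", table=table), LDMatrix(variant_ids=ids, r2=r2)


def clump_agreement(
    n_instances: int = 100,
    n_snps: int = 20,
    r2_threshold: float = 0.3,
    window_kb: float = 10_000,
    seed: int = 6,
) -> dict:
    """Fraction of random instances where greedy clumping matches the reference."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_instances):
        s, ld = _random_clump_instance(rng, n_snps)
        mine = set(clump(s, ld, r2_threshold=r2_threshold, window_kb=window_kb).table["variant_id"])
        ref = reference_clump(s.table, ld, r2_threshold, window_kb)
        agree += mine == ref
    return {"n_instances": n_instances, "agreement_rate": agree / n_instances}
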