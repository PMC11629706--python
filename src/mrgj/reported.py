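"""Published MR results for gut microbiota / metabolic pathways and pyogenic arthritis.

The source GWAS downloads (microbiome taxa, microbial metabolic pathways, and
the pyogenic-arthritis case-control cohort) are too large to ship, so the
published per-exposure IVW summaries below serve as fixed reference inputs
for internal-consistency validation: a printed p-value and odds ratio jointly
determine the standard error on the log-OR scale, from which the 95% CI
bounds can be recomputed and compared against the printed bounds.

Each row: taxonomic level or "pathway", exposure label, instrument count,
IVW p, OR with 95% CI, Egger intercept and its p, Cochran's Q and its p, and
the Steiger directionality verdict.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from mrgj.estimators import Z_975

_COLUMNS = [
    "classification", "exposure", "nsnp", "ivw_p", "or", "ci_low", "ci_high",
    "egger_intercept", "intercept_p", "q", "q_p", "steiger",
]

#: significant taxa (levels class/order/genus/species)
REPORTED_TAXA = pd.DataFrame(
    [
        ["Class", "Betaproteobacteria", 13, 0.0018, 1.63, 1.20, 2.22, -0.105, 0.155, 14.4, 0.273, True],
        ["Order", "Burkholderiales", 14, 0.0007, 1.68, 1.24, 2.27, -0.083, 0.198, 10.7, 0.629, True],
        ["Genus", "Sutterellaceae unclassified", 6, 0.015, 1.44, 1.07, 1.93, -0.066, 0.515, 5.2, 0.385, True],
        ["Genus", "Lachnospiraceae unnamed", 6, 0.020, 0.58, 0.36, 0.92, 0.212, 0.109, 6.6, 0.250, True],
        ["Genus", "Roseburia", 15, 0.030, 0.75, 0.57, 0.97, -0.006, 0.922, 17.3, 0.240, True],
        ["Genus", "Erysipelotrichaceae unnamed", 13, 0.027, 0.81, 0.67, 0.98, -0.024, 0.744, 3.1, 0.994, True],
        ["Species", "Faecalibacterium", 14, 0.037, 0.88, 0.77, 0.99, 0.003, 0.948, 3.7, 0.993, True],
        ["Species", "Finegoldia", 9, 0.039, 0.69, 0.49, 0.98, -0.0007, 0.994, 3.7, 0.883, True],
    ],
    columns=_COLUMNS,
)

#: significant microbial metabolic pathways
REPORTED_PATHWAYS = pd.DataFrame(
    [
        ["pathway", "D-galactose degradation V (Leloir)", 11, 0.0005, 0.57, 0.42, 0.79, 0.022, 0.761, 7.1, 0.711, True],
        ["pathway", "phosphopantothenate biosynthesis I", 11, 0.007, 0.65, 0.48, 0.89, 0.033, 0.699, 10.0, 0.436, True],
        ["pathway", "L-histidine degradation I", 12, 0.009, 1.44, 1.07, 1.93, -0.083, 0.258, 11.8, 0.377, True],
        ["pathway", "D-galactose degradation I (Leloir)", 13, 0.009, 0.67, 0.49, 0.91, -0.027, 0.700, 18.2, 0.108, True],
        ["pathway", "N-acetylneuraminate degradation superpathway", 12, 0.017, 0.67, 0.48, 0.93, 0.047, 0.432, 12.9, 0.293, True],
        ["pathway", "fucose and rhamnose degradation superpathway", 8, 0.028, 1.33, 1.03, 1.71, -0.051, 0.607, 7.1, 0.415, True],
        ["pathway", "chorismate biosynthesis from 3-dehydroquinate", 10, 0.033, 1.47, 1.03, 2.10, 0.091, 0.340, 5.9, 0.742, True],
        ["pathway", "ubiquinol-8 biosynthesis (prokaryotic)", 12, 0.037, 1.26, 1.01, 1.56, 0.022, 0.782, 12.4, 0.328, True],
        ["pathway", "urea cycle", 8, 0.043, 0.66, 0.44, 0.99, 0.092, 0.589, 6.3, 0.499, True],
        ["pathway", "coenzyme A biosynthesis I (prokaryotic)", 10, 0.047, 1.44, 1.00, 2.08, -0.047, 0.566, 4.5, 0.869, True],
        ["pathway", "tRNA processing", 11, 0.048, 1.37, 1.00, 1.86, 0.034, 0.641, 12.4, 0.257, True],
        ["pathway", "tetrahydrofolate biosynthesis superpathway", 13, 0.048, 0.78, 0.61, 1.00, 0.007, 0.937, 15.1, 0.234, True],
        ["pathway", "hexuronide and hexuronate degradation superpathway", 11, 0.049, 1.40, 1.00, 1.96, -0.002, 0.973, 6.6, 0.760, True],
    ],
    columns=_COLUMNS,
)


def reported_estimates() -> pd.DataFrame:
    """All published significant exposure rows (taxa then pathways)."""
    return pd.concat([REPORTED_TAXA, REPORTED_PATHWAYS], ignore_index=True)


def wald_consistency(rows: pd.DataFrame | None = None) -> pd.DataFrame:
    """Back-solve each row's SE from (p, OR) and recompute its 95% CI.

    For a two-sided normal Wald test, se = ln(OR) / z(p) with
    z(p) = Phi^{-1}(1 - p/2).  An internally consistent row reproduces its
    printed CI bounds up to print rounding; the returned table carries the
    recomputed bounds and their absolute deviations from the printed ones.
    """
    rows = reported_estimates() if rows is None else rows
    z = stats.norm.isf(rows["ivw_p"] / 2.0)
    log_or = np.log(rows["or"])
    se = np.abs(log_or) / z
    lo = np.exp(log_or - Z_975 * se)
    hi = np.exp(log_or + Z_975 * se)
    out = rows[["classification", "exposure", "ivw_p", "or", "ci_low", "ci_high"]].copy()
    out["se_backsolved"] = se
    out["ci_low_recomputed"] = lo
    out["ci_high_recomputed"] = hi
    out["dev_low"] = np.abs(lo - rows["ci_low"])
    out["dev_high"] = np.abs(hi - rows["ci_high"])
    out["max_dev"] = np.maximum(out["dev_low"], out["dev_high"])
    return out
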