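"""Instrumental-variable selection for two-sample MR.

Candidate SNPs are filtered in the order used throughout gut-microbiome MR
studies: exposure significance threshold, greedy LD clumping (index SNP by
smallest p; neighbours within a distance window and above an r² threshold are
removed), then instrument-strength filtering.

Instrument strength uses the variance explained per SNP,

    R² = 2·EAF·(1−EAF)·β²                                        (i < 10)
    R² = 2·EAF·(1−EAF)·β² / [2·EAF·(1−EAF)·β² + 2·EAF·(1−EAF)·N·SE²]   (i ≥ 10)

where i is the number of instruments, and the F statistic for i regressors,

    F = R²·(N − 1 − i) / [(1 − R²)·i].

Per-SNP weak-instrument filtering evaluates each SNP with i = 1 and the first
R² form; the second form feeds the set-level R² once a set holds 10 or more
SNPs.  SNPs are retained when F exceeds the threshold (default 10, the
conventional weak-instrument cutoff).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mrgj.harmonize import HarmonizedSet
from mrgj.io import LDMatrix, SumStats

logger = logging.getLogger(__name__)


class InstrumentError(ValueError):
    pass


@dataclass
class InstrumentSet:
    """Instruments surviving all filters, with strength bookkeeping.

    ``filter_log`` is an ordered list of (stage, n_before, n_after);
    ``per_snp_strength`` maps each retained SNP to its (r2, F) computed with
    i = 1; ``set_strength`` is (total R², set-level F, i).
    """

    table: pd.DataFrame
    filter_log: list[tuple[str, int, int]] = field(default_factory=list)
    per_snp_strength: pd.DataFrame | None = None
    set_strength: tuple[float, float, int] | None = None
    dropped: list[tuple[str, str]] = field(default_factory=list)

    @property
    def nsnp(self) -> int:
        return len(self.table)


def filter_by_pvalue(candidates: SumStats, threshold: float) -> SumStats:
    """Keep records with exposure p-value strictly below ``threshold``."""
    if not 0 < threshold <= 1:
        raise InstrumentError("p-value threshold must be in (0, 1]")
    kept = candidates.subset((candidates.table["pval"] < threshold).to_numpy())
    if kept.nsnp == 0:
        logger.warning("p-value filter at %g left no candidates", threshold)
    return kept


def clump(
    candidates: SumStats,
    ld: LDMatrix,
    r2_threshold: float = 0.001,
    window_kb: float = 10_000,
) -> SumStats:
    """Greedy LD clumping: retain approximately independent index SNPs.

    Repeatedly selects the remaining SNP with the smallest p-value (ties broken
    by chromosome, position, then variant_id, so the result is independent of
    input order) and removes every other remaining SNP on the same chromosome
    within ``window_kb`` kilobases whose r² with the index is at or above
    ``r2_threshold``.
    """
    if not 0 <= r2_threshold <= 1:
        raise InstrumentError("r2_threshold must be in [0, 1]")
    if window_kb <= 0:
        raise InstrumentError("window_kb must be positive")
    df = candidates.table
    missing = [v for v in df["variant_id"] if v not in ld]
    if missing:
        raise InstrumentError(f"candidate(s) absent from LD matrix: {missing}")

    order = df.sort_values(
        ["pval", "chrom", "pos", "variant_id"], kind="mergesort"
    ).index.to_list()
    window_bp = window_kb * 1000.0
    remaining = set(order)
    kept_ids = []
    for idx in order:
        if idx not in remaining:
            continue
        remaining.discard(idx)
        index_snp = df.loc[idx]
        kept_ids.append(index_snp["variant_id"])
        for other in list(remaining):
            row = df.loc[other]
            if (
                row["chrom"] == index_snp["chrom"]
                and abs(row["pos"] - index_snp["pos"]) <= window_bp
                and ld.r2_between(index_snp["variant_id"], row["variant_id"]) >= r2_threshold
            ):
                remaining.discard(other)
    return candidates.subset(kept_ids)


def snp_r2(
    eaf: float,
    beta: float,
    se: float | None = None,
    n: float | None = None,
    variant_count: int = 1,
) -> float:
    """Variance in the exposure explained by one SNP.

    With fewer than 10 instruments the plain form 2·EAF·(1−EAF)·β² is used;
    with 10 or more, the normalized form that divides by the total of signal
    and noise variance (which requires ``se`` and ``n``).
    """
    if not 0 < eaf < 1:
        raise InstrumentError("EAF must lie strictly inside (0, 1)")
    signal = 2.0 * eaf * (1.0 - eaf) * beta**2
    if variant_count < 10:
        return signal
    if se is None or n is None:
        raise InstrumentError("se and n are required for the i >= 10 form")
    if se <= 0 or n < 2:
        raise InstrumentError("need se > 0 and n >= 2")
    noise = 2.0 * eaf * (1.0 - eaf) * n * se**2
    return signal / (signal + noise)


def f_statistic(r2: float, n: float, i: int = 1) -> float:
    """Instrument-strength F for ``i`` regressors on ``n`` samples."""
    if not 0 <= r2 < 1:
        raise InstrumentError("r2 must lie in [0, 1)")
    if i < 1:
        raise InstrumentError("i must be >= 1")
    if n <= i + 1:
        raise InstrumentError("need n > i + 1")
    return r2 * (n - 1 - i) / ((1.0 - r2) * i)


def per_snp_strength(table: pd.DataFrame) -> pd.DataFrame:
    """Per-SNP (r2, F) with i = 1, from exposure-side EAF, beta, and n."""
    rows = []
    for _, row in table.iterrows():
        r2 = snp_r2(row["eaf_exp"], row["beta_exp"], variant_count=1)
        rows.append(
            {
                "variant_id": row["variant_id"],
                "r2_snp": r2,
                "f_snp": f_statistic(r2, row["n_exp"], i=1),
            }
        )
    return pd.DataFrame(rows, columns=["variant_id", "r2_snp", "f_snp"])


def set_strength(table: pd.DataFrame) -> tuple[float, float, int]:
    """Set-level (total R², F, i) over the retained instruments.

    Per-SNP R² are summed (instruments are LD-independent after clumping, so
    variances add); the normalized R² form is used once i >= 10.  N entering
    the F statistic is the mean exposure sample size across instruments.
    """
    i = len(table)
    if i == 0:
        return 0.0, 0.0, 0
    r2_total = sum(
        snp_r2(
            row["eaf_exp"],
            row["beta_exp"],
            se=row["se_exp"],
            n=row["n_exp"],
            variant_count=i,
        )
        for _, row in table.iterrows()
    )
    n_mean = float(table["n_exp"].mean())
    r2_total = min(r2_total, 1.0 - 1e-12)
    return r2_total, f_statistic(r2_total, n_mean, i=i), i


def filter_weak_instruments(h: HarmonizedSet, f_threshold: float = 10.0) -> InstrumentSet:
    """Drop SNPs whose single-SNP F does not exceed ``f_threshold``.

    The surviving set's strength (summed R², set-level F) is recomputed and
    recorded alongside the per-SNP values.
    """
    strength = per_snp_strength(h.table)
    keep = (strength["f_snp"] > f_threshold).to_numpy()
    dropped = list(h.dropped) + [
        (v, "weak_instrument") for v in strength.loc[~keep, "variant_id"]
    ]
    kept_table = h.table[keep].reset_index(drop=True)
    return InstrumentSet(
        table=kept_table,
        filter_log=[("f_filter", len(h.table), int(keep.sum()))],
        per_snp_strength=strength[keep].reset_index(drop=True),
        set_strength=set_strength(kept_table),
        dropped=dropped,
    )


def exclude_confounder_snps(candidates, exclusion_list) -> "SumStats | HarmonizedSet":
    """Remove SNPs named on a user-supplied confounder exclusion list.

    Accepts either a SumStats or a HarmonizedSet; listed IDs absent from the
    input are ignored with a warning.  An empty list (the outcome of a
    phenotype scan that finds no confounder-associated SNPs) is the identity.
    """
    ids = list(exclusion_list)
    if isinstance(candidates, HarmonizedSet):
        present = set(candidates.table["variant_id"])
    else:
        present = set(candidates.table["variant_id"])
    absent = [v for v in ids if v not in present]
    if absent:
        logger.warning("exclusion list ids not found: %s", absent)
    to_drop = [v for v in ids if v in present]
    if isinstance(candidates, HarmonizedSet):
        return candidates.drop_ids(to_drop, "confounder_exclusion")
    keep = ~candidates.table["variant_id"].isin(to_drop)
    result = candidates.subset(keep.to_numpy())
    result = dataclasses.replace(
        result, rejected=[(v, "confounder_exclusion") for v in to_drop]
    )
    return result
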