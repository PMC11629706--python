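"""Reading, validation, and writing of GWAS summary statistics and LD matrices.

The canonical in-memory container is a :class:`SumStats`: trait metadata plus a
pandas DataFrame with one row per variant association.  Column names follow the
internal canonical schema below; files on disk may use any naming, mapped at
read time through a schema dictionary (the shipped default follows
GWAS-SSF-style names).

Coordinates are 1-based, the usual GWAS convention.  Alleles are restricted to
single canonical bases A/C/G/T; indels and multi-allelic records are rejected
so every variant is a SNP.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: canonical column order used everywhere inside the package
CANONICAL_COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
]

#: default mapping canonical name -> on-disk column name (GWAS-SSF style)
DEFAULT_SCHEMA = {
    "variant_id": "rsid",
    "chrom": "chromosome",
    "pos": "base_pair_location",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "effect_allele_frequency",
    "beta": "beta",
    "se": "standard_error",
    "pval": "p_value",
    "n": "n",
}

VALID_BASES = frozenset("ACGT")

# %.17g is lossless for IEEE-754 doubles, so write/read round-trips exactly
_FLOAT_FMT = "%.17g"


class SumStatsError(ValueError):
    """Base error for summary-statistics I/O and validation."""


class SchemaError(SumStatsError):
    """A required column is missing from the input table."""


class DuplicateVariantError(SumStatsError):
    """The same variant_id occurs more than once."""


class LDMatrixError(ValueError):
    """An LD matrix violates its shape, range, or symmetry contract."""


@dataclass
class SumStats:
    """GWAS summary statistics for a single trait.

    ``table`` holds one validated row per variant with the canonical columns.
    ``rejected`` records (variant_id, reason) pairs for input rows that failed
    validation; no partially-invalid record is ever kept.
    """

    trait_id: str
    trait_type: str = "continuous"  # "continuous" | "binary"
    table: pd.DataFrame = field(default_factory=pd.DataFrame)
    n_cases: int | None = None
    n_controls: int | None = None
    rejected: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.trait_type not in ("continuous", "binary"):
            raise SumStatsError(f"unknown trait_type {self.trait_type!r}")
        if self.trait_type == "binary" and (self.n_cases is None or self.n_controls is None):
            raise SumStatsError("binary traits require n_cases and n_controls")
        if self.table.empty and not len(self.table.columns):
            self.table = pd.DataFrame(columns=CANONICAL_COLUMNS)
        dup = self.table["variant_id"].duplicated()
        if dup.any():
            offenders = sorted(self.table.loc[dup, "variant_id"].unique())
            raise DuplicateVariantError(f"duplicate variant_id: {offenders}")

    @property
    def nsnp(self) -> int:
        return len(self.table)

    def subset(self, mask_or_ids) -> "SumStats":
        """New SumStats restricted to a boolean mask or an id collection."""
        arr = np.asarray(mask_or_ids)
        if arr.dtype == bool:
            sub = self.table[arr]
        else:
            ids = set(mask_or_ids)
            sub = self.table[self.table["variant_id"].isin(ids)]
        return dataclasses.replace(self, table=sub.reset_index(drop=True), rejected=[])


@dataclass
class LDMatrix:
    """Squared-correlation (r²) matrix between variants.

    Symmetric with unit diagonal and all entries in [0, 1].  ``positions`` is
    optional (files carry only IDs; the simulator fills positions in).
    """

    variant_ids: list[str]
    r2: np.ndarray
    positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        k = len(self.variant_ids)
        if self.r2.shape != (k, k):
            raise LDMatrixError(f"r2 must be {k}x{k}, got {self.r2.shape}")
        if np.nanmin(self.r2) < 0 or np.nanmax(self.r2) > 1:
            raise LDMatrixError("r2 entries must lie in [0, 1]")
        asym = np.max(np.abs(self.r2 - self.r2.T)) if k else 0.0
        if asym > 1e-8:
            raise LDMatrixError(f"r2 asymmetric beyond tolerance ({asym:.3g})")
        if asym > 0:
            self.r2 = (self.r2 + self.r2.T) / 2.0
        if k and np.max(np.abs(np.diag(self.r2) - 1.0)) > 1e-8:
            raise LDMatrixError("r2 diagonal must be 1")
        np.fill_diagonal(self.r2, 1.0)
        self._index = {v: i for i, v in enumerate(self.variant_ids)}
        if len(self._index) != k:
            raise LDMatrixError("variant_ids must be unique")

    def r2_between(self, a: str, b: str) -> float:
        return float(self.r2[self._index[a], self._index[b]])

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index


def _validate_rows(df: pd.DataFrame, require_eaf: bool = True):
    """Split a canonical-column table into valid rows and per-row rejections.

    Returns (valid DataFrame, list of (variant_id, reason)).  The first
    violated invariant per row is reported.
    """
    reasons = pd.Series("", index=df.index, dtype=object)

    def flag(mask, reason):
        hit = mask & (reasons == "")
        reasons[hit] = reason

    ea = df["effect_allele"].astype(str).str.upper()
    oa = df["other_allele"].astype(str).str.upper()
    flag(~ea.isin(VALID_BASES) | ~oa.isin(VALID_BASES), "invalid allele")
    flag(ea == oa, "identical alleles")
    eaf = pd.to_numeric(df["eaf"], errors="coerce")
    if require_eaf:
        flag(eaf.isna(), "missing EAF")
    flag(eaf.notna() & ((eaf < 0) | (eaf > 1)), "EAF out of [0,1]")
    se = pd.to_numeric(df["se"], errors="coerce")
    flag(se.isna() | (se <= 0), "nonpositive SE")
    beta = pd.to_numeric(df["beta"], errors="coerce")
    flag(beta.isna() | ~np.isfinite(beta), "missing beta")
    pval = pd.to_numeric(df["pval"], errors="coerce")
    flag(pval.isna() | (pval <= 0) | (pval > 1), "p-value out of (0,1]")
    n = pd.to_numeric(df["n"], errors="coerce")
    flag(n.isna() | (n < 2), "invalid sample size")
    pos = pd.to_numeric(df["pos"], errors="coerce")
    flag(pos.isna() | (pos < 1), "invalid position")

    bad = reasons != ""
    rejected = list(zip(df.loc[bad, "variant_id"].astype(str), reasons[bad]))
    good = df[~bad].copy()
    good["effect_allele"] = ea[~bad]
    good["other_allele"] = oa[~bad]
    good["variant_id"] = good["variant_id"].astype(str)
    good["chrom"] = good["chrom"].astype(str)
    good["pos"] = pos[~bad].astype(np.int64)
    good["eaf"] = eaf[~bad].astype(float)
    good["beta"] = beta[~bad].astype(float)
    good["se"] = se[~bad].astype(float)
    good["pval"] = pval[~bad].astype(float)
    good["n"] = n[~bad].astype(np.int64)
    return good[CANONICAL_COLUMNS].reset_index(drop=True), rejected


def read_sumstats(
    path,
    schema: dict | None = None,
    trait_id: str | None = None,
    trait_type: str = "continuous",
    n_cases: int | None = None,
    n_controls: int | None = None,
    require_eaf: bool = True,
    sep: str = "\t",
) -> SumStats:
    """Read a delimited summary-statistics table into a validated SumStats.

    ``schema`` maps canonical field names to the file's column names; the
    shipped :data:`DEFAULT_SCHEMA` (GWAS-SSF-style names) is used when omitted.
    Rows violating record invariants are dropped and listed, with reasons, in
    ``SumStats.rejected``.  ``require_eaf=False`` permits missing EAF (intended
    for outcome-side data, where EAF is not needed for instrument candidacy).
    """
    schema = dict(DEFAULT_SCHEMA if schema is None else schema)
    raw = pd.read_csv(
        path,
        sep=sep,
        dtype={schema.get("chrom", "chromosome"): str},
        float_precision="round_trip",
    )
    missing = [col for col in schema.values() if col not in raw.columns]
    if missing:
        raise SchemaError(f"missing mapped column(s): {missing}")
    df = raw.rename(columns={v: k for k, v in schema.items()})[CANONICAL_COLUMNS]
    dup = df["variant_id"].duplicated()
    if dup.any():
        offenders = sorted(df.loc[dup, "variant_id"].astype(str).unique())
        raise DuplicateVariantError(f"duplicate variant_id: {offenders}")
    good, rejected = _validate_rows(df, require_eaf=require_eaf)
    if trait_type == "binary" and n_cases is not None and n_controls is not None:
        total = n_cases + n_controls
        bad_n = good["n"] != total
        if bad_n.any():
            rejected += [
                (v, "n inconsistent with n_cases + n_controls")
                for v in good.loc[bad_n, "variant_id"]
            ]
            good = good[~bad_n].reset_index(drop=True)
    return SumStats(
        trait_id=trait_id or str(path),
        trait_type=trait_type,
        table=good,
        n_cases=n_cases,
        n_controls=n_controls,
        rejected=rejected,
    )


def write_sumstats(s: SumStats, path, schema: dict | None = None) -> str:
    """Write a SumStats table as TSV with deterministic column order.

    Floats are written with 17 significant digits, so a write/read round trip
    is lossless and write/read/write is byte-identical.
    """
    schema = dict(DEFAULT_SCHEMA if schema is None else schema)
    out = s.table[CANONICAL_COLUMNS].rename(columns=schema)
    out.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT, na_rep="NA")
    return str(path)


def read_ld_matrix(path) -> LDMatrix:
    """Read a square TSV r² matrix with variant IDs as header row and column.

    Asymmetry beyond 1e-8 is an error; below it the matrix is symmetrized by
    averaging.  Entries outside [0, 1] and non-square tables are errors.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids = [str(c) for c in df.columns]
    if list(df.index.astype(str)) != ids or df.shape[0] != df.shape[1]:
        raise LDMatrixError("LD matrix must be square with matching row/column IDs")
    return LDMatrix(variant_ids=ids, r2=df.to_numpy(dtype=float))


def write_ld_matrix(ld: LDMatrix, path) -> str:
    df = pd.DataFrame(ld.r2, index=ld.variant_ids, columns=ld.variant_ids)
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)
    return str(path)
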