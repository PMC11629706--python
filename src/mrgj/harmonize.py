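"""Align exposure and outcome associations onto a shared effect allele.

Two-sample MR combines per-SNP effects from two independent GWAS, which may
report the same variant with the alleles in the opposite order, on the
opposite strand, or both.  Harmonization rewrites the outcome association so
its beta and EAF refer to the exposure's effect allele:

* identical alleles: kept unchanged;
* swapped alleles: outcome beta negated, EAF complemented;
* strand complements: alleles complemented, then the two cases above;
* palindromic SNPs (A/T or C/G): the strand cannot be inferred from alleles,
  so the pair is kept only when both allele frequencies are far enough from
  0.5 to identify the minor allele on both sides and they agree; otherwise
  the SNP is dropped as ambiguous;
* irreconcilable allele pairs are dropped.

The causal quantity beta_out/beta_exp is invariant to which allele is called
the effect allele, so harmonization never changes a downstream estimate —
it only makes the per-SNP pairs comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from mrgj.io import SumStats

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: columns of the harmonized instrument table
HARMONIZED_COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf_exp",
    "beta_exp",
    "se_exp",
    "pval_exp",
    "n_exp",
    "eaf_out",
    "beta_out",
    "se_out",
    "n_out",
    "action",
    "palindromic",
]


class HarmonizeError(ValueError):
    pass


def complement_allele(a: str) -> str:
    """Watson-Crick complement of a single base (A<->T, C<->G)."""
    try:
        return COMPLEMENT[a]
    except KeyError:
        raise ValueError(f"not a canonical base: {a!r}") from None


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True for A/T and C/G pairs, whose strand is unresolvable from alleles."""
    return COMPLEMENT[effect_allele] == other_allele


@dataclass
class HarmonizedSet:
    """Exposure-outcome aligned instruments plus the dropped-SNP log.

    ``table`` has one row per retained SNP (columns ``HARMONIZED_COLUMNS``);
    ``dropped`` lists (variant_id, reason) for the rest of the intersection.
    """

    table: pd.DataFrame
    dropped: list[tuple[str, str]] = field(default_factory=list)

    @property
    def nsnp(self) -> int:
        return len(self.table)

    def drop_ids(self, ids, reason: str) -> "HarmonizedSet":
        ids = set(ids)
        keep = ~self.table["variant_id"].isin(ids)
        dropped = self.dropped + [(v, reason) for v in self.table.loc[~keep, "variant_id"]]
        return HarmonizedSet(table=self.table[keep].reset_index(drop=True), dropped=dropped)


def harmonize(
    exposure: SumStats,
    outcome: SumStats,
    palindrome_eaf_margin: float = 0.08,
) -> HarmonizedSet:
    """Harmonize shared SNPs of two summary-statistics sets.

    ``palindrome_eaf_margin`` is the half-width of the ambiguity zone around
    EAF 0.5: a palindromic SNP is kept only if both EAFs satisfy
    ``|eaf - 0.5| > margin`` and agree on the minor allele after any needed
    allele swap.  The default 0.08 (keep only when both EAFs are below 0.42
    or above 0.58) is the conventional conservative choice.
    """
    if not 0 <= palindrome_eaf_margin <= 0.5:
        raise ValueError("palindrome_eaf_margin must be in [0, 0.5]")
    exp = exposure.table.set_index("variant_id")
    out = outcome.table.set_index("variant_id")
    shared = [v for v in exp.index if v in out.index]
    if not shared:
        raise HarmonizeError("no shared variants between exposure and outcome")

    rows = []
    dropped: list[tuple[str, str]] = []
    for vid in shared:
        e = exp.loc[vid]
        o = out.loc[vid]
        ea_e, oa_e = e["effect_allele"], e["other_allele"]
        ea_o, oa_o = o["effect_allele"], o["other_allele"]
        beta_o, eaf_o = float(o["beta"]), o["eaf"]
        palindromic = is_palindromic(ea_e, oa_e)

        if palindromic:
            if {ea_o, oa_o} != {ea_e, oa_e}:
                dropped.append((vid, "allele_mismatch"))
                continue
            eaf_e = e["eaf"]
            if pd.isna(eaf_e) or pd.isna(eaf_o):
                dropped.append((vid, "palindromic_ambiguous"))
                continue
            action = "none"
            if ea_o != ea_e:  # written with alleles in the opposite order
                beta_o = -beta_o
                eaf_o = 1.0 - eaf_o
                action = "swapped"
            inside_margin = (
                abs(eaf_e - 0.5) <= palindrome_eaf_margin
                or abs(eaf_o - 0.5) <= palindrome_eaf_margin
            )
            if inside_margin or ((eaf_e < 0.5) != (eaf_o < 0.5)):
                dropped.append((vid, "palindromic_ambiguous"))
                continue
        else:
            if {ea_o, oa_o} == {ea_e, oa_e}:
                if ea_o == ea_e:
                    action = "none"
                else:
                    beta_o = -beta_o
                    eaf_o = 1.0 - eaf_o if pd.notna(eaf_o) else eaf_o
                    action = "swapped"
            elif {COMPLEMENT[ea_o], COMPLEMENT[oa_o]} == {ea_e, oa_e}:
                if COMPLEMENT[ea_o] == ea_e:
                    action = "strand_flipped"
                else:
                    beta_o = -beta_o
                    eaf_o = 1.0 - eaf_o if pd.notna(eaf_o) else eaf_o
                    action = "swapped_and_flipped"
            else:
                dropped.append((vid, "allele_mismatch"))
                continue

        rows.append(
            {
                "variant_id": vid,
                "chrom": e["chrom"],
                "pos": int(e["pos"]),
                "effect_allele": ea_e,
                "other_allele": oa_e,
                "eaf_exp": e["eaf"],
                "beta_exp": float(e["beta"]),
                "se_exp": float(e["se"]),
                "pval_exp": float(e["pval"]),
                "n_exp": int(e["n"]),
                "eaf_out": eaf_o,
                "beta_out": beta_o,
                "se_out": float(o["se"]),
                "n_out": int(o["n"]),
                "action": action,
                "palindromic": palindromic,
            }
        )

    table = pd.DataFrame(rows, columns=HARMONIZED_COLUMNS)
    return HarmonizedSet(table=table, dropped=dropped)
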