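import numpy as np
import pandas as pd
import pytest

from mrgj.instruments import (
    InstrumentError,
    clump,
    exclude_confounder_snps,
    f_statistic,
    filter_by_pvalue,
    filter_weak_instruments,
    per_snp_strength,
    set_strength,
    snp_r2,
)
from mrgj.io import LDMatrix, SumStats

from conftest import make_harmonized, sumstats_frame


def stats_for(rows):
    return SumStats(trait_id="t", table=sumstats_frame(rows))


class TestPvalueFilter:
    def test_direct_comparison(self):
        s = stats_for([{"pval": 2e-6}, {"pval": 5e-5}])
        assert list(filter_by_pvalue(s, 1e-5).table["variant_id"]) == ["rs0001"]

    def test_threshold_one_keeps_all(self):
        s = stats_for([{"pval": p} for p in (0.9, 0.5, 1.0)])
        # pval == 1 is kept? strict inequality: pval < 1 keeps 0.9, 0.5 only
        assert filter_by_pvalue(s, 1).nsnp == 2

    def test_matches_brute_force_count(self, rng):
        pvals = rng.uniform(0, 1, size=1000) ** 3  # skew small
        s = stats_for([{"pval": max(p, 1e-300)} for p in pvals])
        kept = filter_by_pvalue(s, 1e-3)
        assert kept.nsnp == sum(1 for p in s.table["pval"] if p < 1e-3)

    def test_order_preserved(self):
        s = stats_for([{"pval": 1e-7}, {"pval": 0.5}, {"pval": 1e-9}])
        assert list(filter_by_pvalue(s, 1e-5).table["variant_id"]) == ["rs0001", "rs0003"]

    def test_monotone_in_threshold(self, rng):
        s = stats_for([{"pval": p} for p in rng.uniform(0, 1, 50)])
        counts = [filter_by_pvalue(s, t).nsnp for t in (1e-3, 1e-2, 0.1, 0.5)]
        assert counts == sorted(counts)


def reference_clump(df, ld, r2_threshold, window_kb):
    """Exhaustive reference: re-scan the full candidate list each round."""
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


def random_instance(rng, n=20):
    """Random candidates with block LD, positions, and p-values."""
    ids = [f"rs{i:03d}" for i in range(n)]
    sizes = []
    while sum(sizes) < n:
        sizes.append(min(int(rng.integers(1, 5)), n - sum(sizes)))
    r2 = np.zeros((n, n))
    i = 0
    pos = np.zeros(n, dtype=int)
    chrom = []
    for b, size in enumerate(sizes):
        val = rng.uniform(0, 1)
        r2[i : i + size, i : i + size] = val
        # half the blocks are tightly spaced, half spread beyond the window
        spacing = 1000 if rng.random() < 0.5 else 20_000_000
        for k in range(size):
            pos[i + k] = 1 + b * 50_000_000 + k * spacing
        chrom += [str(b % 3 + 1)] * size
        i += size
    np.fill_diagonal(r2, 1.0)
    ld = LDMatrix(variant_ids=ids, r2=r2)
    rows = [
        {"variant_id": ids[k], "chrom": chrom[k], "pos": int(pos[k]), "pval": float(rng.uniform(1e-12, 1e-4))}
        for k in range(n)
    ]
    df = sumstats_frame(rows)
    df["variant_id"] = ids
    return SumStats(trait_id="t", table=df), ld


class TestClump:
    def make(self, pvals, r2, pos=None, chrom="1"):
        n = len(pvals)
        ids = [f"rs{i:03d}" for i in range(n)]
        rows = [
            {
                "variant_id": ids[i],
                "pval": pvals[i],
                "pos": 1000 + i if pos is None else pos[i],
                "chrom": chrom,
            }
            for i in range(n)
        ]
        df = sumstats_frame(rows)
        df["variant_id"] = ids
        return SumStats(trait_id="t", table=df), LDMatrix(variant_ids=ids, r2=np.asarray(r2, float))

    def test_no_ld_keeps_everything(self):
        s, ld = self.make([1e-6, 1e-7, 1e-8], np.eye(3))
        assert clump(s, ld, r2_threshold=0.001).nsnp == 3

    def test_total_ld_keeps_smallest_p(self):
        s, ld = self.make([1e-6, 1e-9, 1e-7], np.ones((3, 3)))
        kept = clump(s, ld, r2_threshold=0.001)
        assert list(kept.table["variant_id"]) == ["rs001"]
        assert kept.table.loc[0, "pval"] == 1e-9

    def test_window_limits_removal(self):
        # full LD but far apart: both kept
        s, ld = self.make([1e-6, 1e-7], np.ones((2, 2)), pos=[1, 200_000_000])
        assert clump(s, ld, window_kb=10_000).nsnp == 2

    def test_different_chromosomes_never_clumped(self):
        ids = ["rs000", "rs001"]
        rows = [
            {"variant_id": "rs000", "chrom": "1", "pos": 1000, "pval": 1e-9},
            {"variant_id": "rs001", "chrom": "2", "pos": 1000, "pval": 1e-6},
        ]
        df = sumstats_frame(rows)
        df["variant_id"] = ids
        s = SumStats(trait_id="t", table=df)
        ld = LDMatrix(variant_ids=ids, r2=np.ones((2, 2)))
        assert clump(s, ld).nsnp == 2

    def test_missing_candidate_named(self):
        s, ld = self.make([1e-6], np.eye(1))
        s2 = stats_for([{"pval": 1e-6}])  # id rs0001 absent from ld
        with pytest.raises(InstrumentError, match="rs0001"):
            clump(s2, ld)

    def test_matches_exhaustive_reference(self, rng):
        for _ in range(25):
            s, ld = random_instance(rng)
            mine = set(clump(s, ld, r2_threshold=0.3, window_kb=10_000).table["variant_id"])
            ref = reference_clump(s.table, ld, 0.3, 10_000)
            assert mine == ref

    def test_invariant_to_input_order(self, rng):
        s, ld = random_instance(rng)
        shuffled = SumStats(
            trait_id="t",
            table=s.table.sample(frac=1, random_state=1).reset_index(drop=True),
        )
        a = set(clump(s, ld, 0.3).table["variant_id"])
        b = set(clump(shuffled, ld, 0.3).table["variant_id"])
        assert a == b

    def test_monotone_in_r2_threshold(self, rng):
        s, ld = random_instance(rng)
        counts = [clump(s, ld, r2_threshold=t).nsnp for t in (0.001, 0.1, 0.5, 0.9)]
        assert counts == sorted(counts)


class TestStrength:
    def test_snp_r2_plugin(self):
        assert snp_r2(0.5, 0.1, variant_count=1) == pytest.approx(0.005)

    def test_zero_beta_zero_r2(self):
        assert snp_r2(0.3, 0.0, variant_count=1) == 0
        assert snp_r2(0.3, 0.0, se=0.01, n=1000, variant_count=12) == 0

    def test_normalized_form_hand_arithmetic(self):
        got = snp_r2(0.3, 0.05, se=0.01, n=10_000, variant_count=12)
        sig = 2 * 0.3 * 0.7 * 0.0025
        noise = 2 * 0.3 * 0.7 * 10_000 * 0.0001
        assert got == pytest.approx(sig / (sig + noise), abs=1e-15)

    def test_degenerate_eaf(self):
        with pytest.raises(InstrumentError):
            snp_r2(0.0, 0.1)

    def test_f_plugin(self):
        assert f_statistic(0.01, 10_000, 1) == pytest.approx(0.01 * 9998 / 0.99, abs=1e-9)
        assert f_statistic(0.0, 100, 1) == 0.0
        assert f_statistic(0.5, 103, 1) == pytest.approx(101.0)

    def test_f_domain_errors(self):
        with pytest.raises(InstrumentError):
            f_statistic(1.0, 100, 1)
        with pytest.raises(InstrumentError):
            f_statistic(0.1, 2, 1)

    def test_r2_additivity_for_independent_snps(self):
        h = make_harmonized(beta_exp=[0.1, 0.2, 0.15], beta_out=[0.05, 0.1, 0.07])
        total, _, i = set_strength(h.table)
        per = per_snp_strength(h.table)
        assert i == 3
        assert total == pytest.approx(per["r2_snp"].sum())


class TestWeakInstrumentFilter:
    def test_all_strong_retained(self):
        h = make_harmonized(beta_exp=[0.2] * 4, beta_out=[0.1] * 4)
        inst = filter_weak_instruments(h, f_threshold=10)
        assert inst.nsnp == 4
        assert (inst.per_snp_strength["f_snp"] > 10).all()

    def test_boundary_snp_dropped_and_logged(self):
        # choose beta so F is just below / above 10 at n=10_000, eaf=0.3
        def beta_for_f(f):
            r2 = f / (f + 10_000 - 2)
            return np.sqrt(r2 / (2 * 0.3 * 0.7))

        h = make_harmonized(
            beta_exp=[beta_for_f(9.9), beta_for_f(50)],
            beta_out=[0.1, 0.1],
            n_exp=10_000,
        )
        inst = filter_weak_instruments(h, f_threshold=10)
        assert inst.nsnp == 1
        assert inst.dropped == [("rs0001", "weak_instrument")]
        assert inst.filter_log == [("f_filter", 2, 1)]

    def test_reported_range_matches_recomputation(self, rng):
        h = make_harmonized(
            beta_exp=rng.normal(0.1, 0.03, 30), beta_out=rng.normal(0, 0.1, 30)
        )
        inst = filter_weak_instruments(h, f_threshold=10)
        f = [
            f_statistic(snp_r2(r["eaf_exp"], r["beta_exp"]), r["n_exp"], 1)
            for _, r in inst.table.iterrows()
        ]
        assert inst.per_snp_strength["f_snp"].min() == pytest.approx(min(f))
        assert inst.per_snp_strength["f_snp"].max() == pytest.approx(max(f))
        assert (inst.per_snp_strength["f_snp"] > 10).all()


class TestConfounderExclusion:
    def test_empty_list_identity(self):
        s = stats_for([{}, {}])
        assert exclude_confounder_snps(s, []).nsnp == 2

    def test_absent_id_noop_with_warning(self, caplog):
        s = stats_for([{}])
        with caplog.at_level("WARNING"):
            out = exclude_confounder_snps(s, ["rs_missing"])
        assert out.nsnp == 1
        assert "rs_missing" in caplog.text

    def test_two_present_ids_removed(self):
        h = make_harmonized(beta_exp=[0.1] * 4, beta_out=[0.05] * 4)
        out = exclude_confounder_snps(h, ["rs0002", "rs0004"])
        assert out.nsnp == 2
        assert ("rs0002", "confounder_exclusion") in out.dropped
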