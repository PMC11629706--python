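import numpy as np
import pandas as pd
import pytest

from mrgj.harmonize import HARMONIZED_COLUMNS, HarmonizedSet


def make_harmonized(
    beta_exp,
    beta_out,
    se_exp=0.01,
    se_out=0.05,
    eaf=0.3,
    n_exp=18_340,
    n_out=148_307,
) -> HarmonizedSet:
    """Build a HarmonizedSet directly from effect arrays (no allele games)."""
    beta_exp = np.asarray(beta_exp, dtype=float)
    beta_out = np.asarray(beta_out, dtype=float)
    j = len(beta_exp)
    table = pd.DataFrame(
        {
            "variant_id": [f"rs{i + 1:04d}" for i in range(j)],
            "chrom": "1",
            "pos": np.arange(j, dtype=np.int64) * 30_000_000 + 1,
            "effect_allele": "A",
            "other_allele": "G",
            "eaf_exp": np.broadcast_to(np.asarray(eaf, float), j).copy(),
            "beta_exp": beta_exp,
            "se_exp": np.broadcast_to(np.asarray(se_exp, float), j).copy(),
            "pval_exp": 1e-8,
            "n_exp": np.broadcast_to(np.asarray(n_exp), j).astype(np.int64),
            "eaf_out": np.broadcast_to(np.asarray(eaf, float), j).copy(),
            "beta_out": beta_out,
            "se_out": np.broadcast_to(np.asarray(se_out, float), j).copy(),
            "n_out": np.broadcast_to(np.asarray(n_out), j).astype(np.int64),
            "action": "none",
            "palindromic": False,
        },
        columns=HARMONIZED_COLUMNS,
    )
    return HarmonizedSet(table=table)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def sumstats_frame(rows: list[dict]) -> pd.DataFrame:
    """Canonical-column table from partial row dicts with sane defaults."""
    defaults = {
        "chrom": "1",
        "pos": 1000,
        "effect_allele": "A",
        "other_allele": "G",
        "eaf": 0.3,
        "beta": 0.1,
        "se": 0.01,
        "pval": 1e-6,
        "n": 10_000,
    }
    full = []
    for i, row in enumerate(rows):
        r = {"variant_id": f"rs{i + 1:04d}", **defaults, **row}
        full.append(r)
    from mrgj.io import CANONICAL_COLUMNS

    return pd.DataFrame(full)[CANONICAL_COLUMNS]
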