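"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator emulates the data shapes of a gut-microbiome MR study: a
continuous exposure GWAS (microbial taxon abundance, n in the tens of
thousands), a binary-outcome GWAS on the log-odds scale with a rare outcome
(about 1,100 cases against roughly 150,000 controls), block-structured LD,
palindromic and strand-flipped allele records, and configurable horizontal
pleiotropy (none / balanced / directional, with the InSIDE assumption held or
violated).

Effects are on the standardized-genotype, standardized-exposure scale so the
sampling standard errors are closed-form:

    se_exp = 1 / sqrt(2·maf·(1−maf)·n_exp)
    se_out = 1 / sqrt(2·maf·(1−maf)·n_out·cf·(1−cf))

with cf the case fraction.  Per SNP j the generator draws a minor-allele
frequency, a SNP-exposure effect gamma_j, and a direct (pleiotropic) outcome
effect alpha_j; the true SNP-outcome effect is
Gamma_j = beta_causal·gamma_j + alpha_j, and observed betas add normal noise
with the analytic SEs.  Binary-outcome effects are generated directly on the
log-odds scale with effective-n SE inflation; no individual-level logistic
sampling is performed.

One master seed drives an independent substream per SNP, so growing j_snps
never perturbs the draws of earlier SNPs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from mrgj.io import LDMatrix, SumStats, write_ld_matrix, write_sumstats
import pandas as pd

_NONPALINDROMIC_PAIRS = [
    ("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
    ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T"),
]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: bp spacing between LD blocks; larger than the default 10,000 kb clump window
_BLOCK_SPACING_BP = 30_000_000
_WITHIN_BLOCK_BP = 10_000


class SimulationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Ground-truth parameters of one simulated exposure-outcome pair.

    Defaults mirror the sample sizes of the emulated study design: an
    exposure GWAS of 18,340 participants and a binary outcome GWAS of 1,086
    cases among 148,307 subjects.  ``gamma_mean``/``gamma_sd`` set the
    distribution of SNP-exposure effects; the defaults place instruments
    firmly in the strong-instrument regime with heterogeneous strength, the
    regime in which the implemented estimators are consistent.
    ``pleiotropy_fraction`` is the share of SNPs receiving a direct outcome
    effect (1 = all).  ``noise_scale`` scales the sampling noise of the
    observed betas and exists for validation (0 gives the noiseless limit).
    """

    j_snps: int = 13
    n_exp: int = 18_340
    n_out: int = 148_307
    case_fraction: float = 1086 / 148307
    beta_causal: float = 0.0
    maf_range: tuple[float, float] = (0.10, 0.45)
    gamma_mean: float = 0.30
    gamma_sd: float = 0.08
    pleiotropy: str = "none"  # "none" | "balanced" | "directional"
    mean_alpha: float = 0.0
    sd_alpha: float = 0.08
    pleiotropy_fraction: float = 1.0
    inside_violated: bool = False
    ld_blocks: list[tuple[int, float]] | None = None  # (block size, within-block r²)
    palindrome_fraction: float = 0.10
    strand_flip_fraction: float = 0.05
    noise_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.j_snps < 1:
            raise SimulationError("j_snps must be >= 1")
        for name in ("case_fraction", "palindrome_fraction", "strand_flip_fraction",
                     "pleiotropy_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise SimulationError(f"{name} must lie in [0, 1]")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise SimulationError("maf_range must lie within (0, 0.5]")
        if self.gamma_sd < 0 or self.sd_alpha < 0 or self.noise_scale < 0:
            raise SimulationError("sd parameters must be >= 0")
        if self.pleiotropy not in ("none", "balanced", "directional"):
            raise SimulationError(f"unknown pleiotropy regime {self.pleiotropy!r}")
        if self.ld_blocks is not None and sum(s for s, _ in self.ld_blocks) != self.j_snps:
            raise SimulationError("ld_blocks sizes must sum to j_snps")


def _blocks(cfg: SimulationConfig) -> list[tuple[int, float]]:
    if cfg.ld_blocks is None:
        return [(1, 0.0)] * cfg.j_snps
    return list(cfg.ld_blocks)


def _positions(cfg: SimulationConfig) -> np.ndarray:
    """1-based positions: blocks far apart, members within one clump window."""
    pos = np.empty(cfg.j_snps, dtype=np.int64)
    i = 0
    for b, (size, _) in enumerate(_blocks(cfg)):
        base = 1 + b * _BLOCK_SPACING_BP
        for k in range(size):
            pos[i] = base + k * _WITHIN_BLOCK_BP
            i += 1
    return pos


def _variant_ids(cfg: SimulationConfig) -> list[str]:
    return [f"rs{j + 1:06d}" for j in range(cfg.j_snps)]


def simulate_pair(cfg: SimulationConfig) -> tuple[SumStats, SumStats, dict]:
    """Generate one exposure/outcome summary-statistics pair plus the truth.

    The truth record carries every latent per-SNP quantity (maf, gamma,
    alpha, Gamma, analytic SEs, palindrome and strand-flip indicators) and
    the scalar configuration.
    """
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(cfg.j_snps)
    j = cfg.j_snps
    maf = np.empty(j)
    gamma = np.empty(j)
    alpha = np.zeros(j)
    invalid = np.zeros(j, dtype=bool)
    noise_e = np.empty(j)
    noise_o = np.empty(j)
    pal = np.zeros(j, dtype=bool)
    flip = np.zeros(j, dtype=bool)
    pair_idx = np.empty(j, dtype=int)
    eaf_jitter = np.empty(j)

    for k in range(j):
        rng = np.random.default_rng(children[k])
        maf[k] = rng.uniform(*cfg.maf_range)
        gamma[k] = rng.normal(cfg.gamma_mean, cfg.gamma_sd)
        u_pleio = rng.random()
        a_noise = rng.normal()
        noise_e[k] = rng.normal()
        noise_o[k] = rng.normal()
        pal[k] = rng.random() < cfg.palindrome_fraction
        pair_idx[k] = rng.integers(0, 8)
        flip[k] = rng.random() < cfg.strand_flip_fraction
        eaf_jitter[k] = rng.normal()
        if cfg.pleiotropy != "none" and u_pleio < cfg.pleiotropy_fraction:
            invalid[k] = True
            mean = cfg.mean_alpha if cfg.pleiotropy == "directional" else 0.0
            alpha[k] = mean + cfg.sd_alpha * a_noise
            if cfg.inside_violated:
                alpha[k] += 0.5 * (gamma[k] - cfg.gamma_mean)

    se_exp = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * cfg.n_exp)
    cf = cfg.case_fraction
    se_out = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * cfg.n_out * cf * (1.0 - cf))
    big_gamma = cfg.beta_causal * gamma + alpha
    beta_exp = gamma + cfg.noise_scale * se_exp * noise_e
    beta_out = big_gamma + cfg.noise_scale * se_out * noise_o
    p_exp = 2.0 * stats.norm.sf(np.abs(beta_exp) / se_exp)
    p_out = 2.0 * stats.norm.sf(np.abs(beta_out) / se_out)
    # p-values below double precision round to 0 and would fail validation
    tiny = np.nextafter(0.0, 1.0)
    p_exp = np.clip(p_exp, tiny, 1.0)
    p_out = np.clip(p_out, tiny, 1.0)

    ids = _variant_ids(cfg)
    pos = _positions(cfg)
    ea = np.empty(j, dtype=object)
    oa = np.empty(j, dtype=object)
    ea_o = np.empty(j, dtype=object)
    oa_o = np.empty(j, dtype=object)
    for k in range(j):
        if pal[k]:
            ea[k], oa[k] = _PALINDROMIC_PAIRS[pair_idx[k] % 4]
        else:
            ea[k], oa[k] = _NONPALINDROMIC_PAIRS[pair_idx[k]]
        if flip[k]:
            ea_o[k], oa_o[k] = _COMPLEMENT[ea[k]], _COMPLEMENT[oa[k]]
        else:
            ea_o[k], oa_o[k] = ea[k], oa[k]

    eaf_exp = maf
    eaf_out = np.clip(maf + 0.005 * eaf_jitter, 0.001, 0.999)

    exp_table = pd.DataFrame(
        {
            "variant_id": ids,
            "chrom": "1",
            "pos": pos,
            "effect_allele": ea,
            "other_allele": oa,
            "eaf": eaf_exp,
            "beta": beta_exp,
            "se": se_exp,
            "pval": p_exp,
            "n": np.int64(cfg.n_exp),
        }
    )
    n_cases = int(round(cf * cfg.n_out))
    out_table = pd.DataFrame(
        {
            "variant_id": ids,
            "chrom": "1",
            "pos": pos,
            "effect_allele": ea_o,
            "other_allele": oa_o,
            "eaf": eaf_out,
            "beta": beta_out,
            "se": se_out,
            "pval": p_out,
            "n": np.int64(cfg.n_out),
        }
    )
    exposure = SumStats(trait_id="sim_exposure", trait_type="continuous", table=exp_table)
    outcome = SumStats(
        trait_id="sim_outcome",
        trait_type="binary",
        table=out_table,
        n_cases=n_cases,
        n_controls=cfg.n_out - n_cases,
    )
    truth = {
        "beta_causal": cfg.beta_causal,
        "variant_id": ids,
        "maf": maf,
        "gamma": gamma,
        "alpha": alpha,
        "invalid": invalid,
        "big_gamma": big_gamma,
        "se_exp": se_exp,
        "se_out": se_out,
        "palindromic": pal,
        "strand_flipped": flip,
        "config": asdict(cfg),
    }
    return exposure, outcome, truth


def simulate_ld_blocks(cfg: SimulationConfig) -> LDMatrix:
    """Block-diagonal r² matrix matching the IDs/positions of simulate_pair."""
    j = cfg.j_snps
    r2 = np.zeros((j, j))
    i = 0
    for size, within_r2 in _blocks(cfg):
        if not 0 <= within_r2 <= 1:
            raise SimulationError("within-block r2 must lie in [0, 1]")
        r2[i : i + size, i : i + size] = within_r2
        i += size
    np.fill_diagonal(r2, 1.0)
    return LDMatrix(variant_ids=_variant_ids(cfg), r2=r2, positions=_positions(cfg))


#: named study-like scenarios: (beta_causal, j_snps index blocks, extras)
_SCENARIOS: dict[str, dict] = {
    "null": {"beta_causal": 0.0, "blocks": 14},
    "strong_positive": {"beta_causal": float(np.log(1.63)), "blocks": 13},
    "protective": {"beta_causal": float(np.log(0.70)), "blocks": 14},
    "directional_pleiotropy": {
        "beta_causal": 0.0,
        "blocks": 20,
        "pleiotropy": "directional",
        "mean_alpha": 0.3,
        "sd_alpha": 0.08,
    },
    "high_heterogeneity": {
        "beta_causal": 0.3,
        "blocks": 20,
        "pleiotropy": "balanced",
        "sd_alpha": 0.3,
    },
}


def scenario_config(name: str, seed: int) -> SimulationConfig:
    """SimulationConfig for a named fixture scenario.

    Each scenario holds ``blocks`` LD blocks of two SNPs at r² = 0.8, so
    clumping reduces the candidates to one index SNP per block.
    """
    spec_ = dict(_SCENARIOS[name])
    blocks = spec_.pop("blocks")
    return SimulationConfig(
        j_snps=2 * blocks,
        ld_blocks=[(2, 0.8)] * blocks,
        seed=seed,
        **spec_,
    )


def make_fixture_suite(out_dir, seed: int = 20241126) -> dict:
    """Write the five named scenarios as TSV files plus a JSON manifest.

    Scenarios: a null effect, a harmful signal (true OR about 1.6), a
    protective signal (true OR about 0.7), a directional-pleiotropy trap, and
    a high-heterogeneity trap.  Re-running with the same seed reproduces
    byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scenario_seeds = np.random.SeedSequence(seed).generate_state(len(_SCENARIOS)) % (2**31)
    manifest = {"suite_seed": int(seed), "scenarios": {}}
    for (name, _), sc_seed in zip(_SCENARIOS.items(), scenario_seeds):
        cfg = scenario_config(name, int(sc_seed))
        exposure, outcome, truth = simulate_pair(cfg)
        ld = simulate_ld_blocks(cfg)
        d = out_dir / name
        d.mkdir(exist_ok=True)
        write_sumstats(exposure, d / "exposure.tsv")
        write_sumstats(outcome, d / "outcome.tsv")
        write_ld_matrix(ld, d / "ld.tsv")
        manifest["scenarios"][name] = {
            "seed": int(sc_seed),
            "j_snps": cfg.j_snps,
            "beta_causal": cfg.beta_causal,
            "true_or": float(np.exp(cfg.beta_causal)),
            "pleiotropy": cfg.pleiotropy,
            "n_exp": cfg.n_exp,
            "n_out": cfg.n_out,
            "case_fraction": cfg.case_fraction,
        }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
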