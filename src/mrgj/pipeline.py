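"""Orchestration: many exposures against one outcome, report generation.

The stage order per exposure is: exposure significance filter -> LD clumping
-> harmonization with the outcome -> confounder-list exclusion -> per-SNP
F filtering -> estimators -> sensitivity suite.  Every filter's before/after
counts are logged so a reported instrument count is auditable.  Exposures
that end with fewer than 2 instruments are reported as
"insufficient_instruments" rather than silently dropped, and a failure in one
exposure never affects another.

Significance follows the raw IVW rule (p < alpha, default 0.05) with no
multiplicity adjustment by default; a Benjamini-Hochberg column is available
because raw thresholds over hundreds of exposures are a known limitation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from mrgj import estimators as est
from mrgj import sensitivity as sens
from mrgj.harmonize import harmonize
from mrgj.instruments import (
    clump,
    exclude_confounder_snps,
    filter_by_pvalue,
    filter_weak_instruments,
)
from mrgj.io import read_ld_matrix, read_sumstats

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.17g"

REPORT_COLUMNS = [
    "classification",
    "exposure_id",
    "status",
    "nsnp",
    "ivw_p",
    "or_ci_text",
    "egger_intercept",
    "intercept_p",
    "q",
    "q_p",
    "steiger",
    "significant",
]

DEFAULT_METHODS = ("ivw", "egger", "weighted_median", "simple_mode", "weighted_mode")


class PipelineError(ValueError):
    pass


@dataclass
class RunConfig:
    """Configuration of a multi-exposure MR run.

    ``exposures`` is a list of dicts with keys ``id``, ``path``, and optional
    ``classification`` (taxonomic level or "pathway") and ``ld`` (per-exposure
    LD matrix path overriding the shared one).
    """

    exposures: list[dict]
    outcome: dict  # {"path": ..., "n_cases": ..., "n_controls": ...}
    ld: str | None = None
    pval_threshold: float = 1e-5
    clump_r2: float = 0.001
    clump_kb: float = 10_000
    f_min: float = 10.0
    alpha: float = 0.05
    palindrome_eaf_margin: float = 0.08
    exclude: list[str] = field(default_factory=list)
    methods: tuple[str, ...] = DEFAULT_METHODS
    effects_model: str = "multiplicative_random"
    n_boot: int = est.DEFAULT_N_BOOT
    seed: int = est.DEFAULT_BOOT_SEED
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise PipelineError("alpha must lie in (0, 1)")
        for e in self.exposures:
            if not Path(e["path"]).exists():
                raise PipelineError(f"exposure file not found: {e['path']}")
        if self.outcome and not Path(self.outcome["path"]).exists():
            raise PipelineError(f"outcome file not found: {self.outcome['path']}")
        if self.ld is not None and not Path(self.ld).exists():
            raise PipelineError(f"LD matrix file not found: {self.ld}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "methods" in raw:
            raw["methods"] = tuple(raw["methods"])
        return cls(**raw)


def format_or_ci(or_: float, lo: float, hi: float) -> str:
    """Report-style odds-ratio text, e.g. ``"1.68 (1.24-2.27)"``."""
    return f"{or_:.2f} ({lo:.2f}-{hi:.2f})"


def _empty_row(exposure_id: str, classification: str, status: str, nsnp: int) -> dict:
    return {
        "classification": classification,
        "exposure_id": exposure_id,
        "status": status,
        "nsnp": nsnp,
        "ivw_p": np.nan,
        "or_ci_text": "",
        "egger_intercept": np.nan,
        "intercept_p": np.nan,
        "q": np.nan,
        "q_p": np.nan,
        "steiger": "",
        "significant": False,
    }


def _analyse_exposure(exp_entry: dict, outcome, ld_shared, cfg: RunConfig):
    """Run the full per-exposure pipeline; returns (report row, artifacts)."""
    exposure_id = exp_entry["id"]
    classification = exp_entry.get("classification", "")
    exposure = read_sumstats(
        exp_entry["path"], trait_id=exposure_id, trait_type="continuous"
    )
    filter_log = [("input", exposure.nsnp, exposure.nsnp)]

    candidates = filter_by_pvalue(exposure, cfg.pval_threshold)
    filter_log.append(("pval_filter", exposure.nsnp, candidates.nsnp))

    ld = ld_shared
    if exp_entry.get("ld"):
        ld = read_ld_matrix(exp_entry["ld"])
    if ld is not None and candidates.nsnp:
        n_before = candidates.nsnp
        candidates = clump(candidates, ld, r2_threshold=cfg.clump_r2, window_kb=cfg.clump_kb)
        filter_log.append(("clump", n_before, candidates.nsnp))

    if candidates.nsnp == 0:
        return (
            _empty_row(exposure_id, classification, "insufficient_instruments", 0),
            {"filter_log": filter_log, "dropped": []},
        )

    h = harmonize(candidates, outcome, palindrome_eaf_margin=cfg.palindrome_eaf_margin)
    filter_log.append(("harmonize", candidates.nsnp, h.nsnp))
    h = exclude_confounder_snps(h, cfg.exclude)
    filter_log.append(("confounder_exclusion", filter_log[-1][2], h.nsnp))
    inst = filter_weak_instruments(h, f_threshold=cfg.f_min)
    filter_log.append(("f_filter", h.nsnp, inst.nsnp))
    artifacts: dict = {
        "filter_log": filter_log,
        "dropped": inst.dropped,
        "instruments": inst.table,
        "per_snp_strength": inst.per_snp_strength,
        "set_strength": inst.set_strength,
    }

    if inst.nsnp < 2:
        return (
            _empty_row(exposure_id, classification, "insufficient_instruments", inst.nsnp),
            artifacts,
        )

    h_final = dataclasses.replace(h, table=inst.table, dropped=inst.dropped)
    # median/mode/Egger estimators are undefined below 3 instruments
    methods = tuple(m for m in cfg.methods if m == "ivw" or inst.nsnp >= 3)
    estimates, intercept = est.fit_all(
        h_final,
        methods=methods,
        effects_model=cfg.effects_model,
        n_boot=cfg.n_boot,
        seed=cfg.seed,
    )
    est_df = pd.DataFrame([e.as_dict() for e in estimates])
    het = sens.heterogeneity_tests(h_final)
    het_df = pd.DataFrame([dataclasses.asdict(r) for r in het])
    loo = sens.leave_one_out(h_final, effects_model=cfg.effects_model, alpha=cfg.alpha) \
        if inst.nsnp >= 3 else None
    steiger = sens.steiger_test(h_final)
    artifacts.update(
        {
            "estimates": est_df,
            "intercept": sens.egger_intercept_test(intercept) if intercept else None,
            "heterogeneity": het_df,
            "loo": loo,
            "steiger": dataclasses.asdict(steiger),
        }
    )

    ivw_est = next(e for e in estimates if e.method == "ivw")
    q_ivw = het[0]
    row = {
        "classification": classification,
        "exposure_id": exposure_id,
        "status": "ok",
        "nsnp": inst.nsnp,
        "ivw_p": ivw_est.pval,
        "or_ci_text": format_or_ci(ivw_est.or_, ivw_est.or_low, ivw_est.or_high),
        "egger_intercept": intercept["estimate"] if intercept else np.nan,
        "intercept_p": intercept["pval"] if intercept else np.nan,
        "q": q_ivw.q,
        "q_p": q_ivw.pval,
        "steiger": str(steiger.correct_direction),
        "significant": bool(ivw_est.pval < cfg.alpha),
    }
    return row, artifacts


def run_pipeline(cfg: RunConfig) -> tuple[pd.DataFrame, dict]:
    """Run every exposure against the outcome; returns (report, artifacts).

    Per-exposure errors are captured in the report's ``status`` column and do
    not stop the run.  When ``cfg.out_dir`` is set the report, plot-ready
    tables, and a JSON run summary are written there deterministically (no
    timestamps).
    """
    outcome = None
    if cfg.exposures:
        n_cases = cfg.outcome.get("n_cases")
        n_controls = cfg.outcome.get("n_controls")
        binary = n_cases is not None and n_controls is not None
        outcome = read_sumstats(
            cfg.outcome["path"],
            trait_id=cfg.outcome.get("id", "outcome"),
            trait_type="binary" if binary else "continuous",
            n_cases=n_cases,
            n_controls=n_controls,
            require_eaf=False,
        )
    ld_shared = read_ld_matrix(cfg.ld) if cfg.ld else None

    rows, artifacts = [], {}
    for entry in cfg.exposures:
        try:
            row, art = _analyse_exposure(entry, outcome, ld_shared, cfg)
        except Exception as exc:  # per-exposure isolation
            logger.error("[%s] failed: %s", entry["id"], exc)
            row = _empty_row(entry["id"], entry.get("classification", ""), f"error: {exc}", 0)
            art = {"filter_log": [], "dropped": []}
        rows.append(row)
        artifacts[entry["id"]] = art

    report = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    report = flag_significant(report, alpha=cfg.alpha)
    if cfg.out_dir:
        render_report(report, artifacts, cfg.out_dir)
        _write_run_summary(cfg, report, artifacts)
    return report, artifacts


def flag_significant(rows: pd.DataFrame, alpha: float = 0.05, fdr: bool = False) -> pd.DataFrame:
    """Set ``significant`` by the raw rule ivw_p < alpha (strict inequality).

    With ``fdr=True`` a Benjamini-Hochberg adjusted column ``ivw_p_bh`` and
    ``significant_bh`` are added.
    """
    rows = rows.copy()
    rows["significant"] = rows["ivw_p"] < alpha
    if fdr:
        from statsmodels.stats.multitest import multipletests

        ok = rows["ivw_p"].notna()
        rows["ivw_p_bh"] = np.nan
        rows["significant_bh"] = False
        if ok.any():
            rej, adj, _, _ = multipletests(rows.loc[ok, "ivw_p"], alpha=alpha, method="fdr_bh")
            rows.loc[ok, "ivw_p_bh"] = adj
            rows.loc[ok, "significant_bh"] = rej
    return rows


def render_report(report: pd.DataFrame, artifacts: dict, out_dir) -> list[str]:
    """Write the report plus plot-ready tables; returns the file list.

    Files: ``report.tsv`` (summary-table style), ``forest.tsv`` (method, beta,
    CI per exposure, forest-plot ready), ``loo_<exposure>.tsv`` per exposure
    (leave-one-out), and ``pvalue_matrix.tsv`` (exposures x methods p-values
    with per-method significance flags).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    path = out_dir / "report.tsv"
    report.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    written.append(str(path))

    forest_rows, pmat_rows = [], []
    for exposure_id, art in artifacts.items():
        est_df = art.get("estimates")
        if est_df is not None:
            for _, r in est_df.iterrows():
                forest_rows.append(
                    {
                        "exposure_id": exposure_id,
                        "method": r["method"],
                        "nsnp": r["nsnp"],
                        "beta": r["beta"],
                        "se": r["se"],
                        "ci_low": r["ci_low"],
                        "ci_high": r["ci_high"],
                        "pval": r["pval"],
                        "or": r["or"],
                        "or_ci_text": format_or_ci(r["or"], r["or_low"], r["or_high"]),
                    }
                )
            prow = {"exposure_id": exposure_id}
            for _, r in est_df.iterrows():
                prow[f"p_{r['method']}"] = r["pval"]
                prow[f"sig_{r['method']}"] = bool(r["pval"] < 0.05)
            pmat_rows.append(prow)
        loo = art.get("loo")
        if loo is not None:
            lpath = out_dir / f"loo_{exposure_id}.tsv"
            loo.to_csv(lpath, sep="\t", index=False, float_format=_FLOAT_FMT)
            written.append(str(lpath))

    fpath = out_dir / "forest.tsv"
    pd.DataFrame(forest_rows).to_csv(fpath, sep="\t", index=False, float_format=_FLOAT_FMT)
    written.append(str(fpath))
    ppath = out_dir / "pvalue_matrix.tsv"
    pd.DataFrame(pmat_rows).to_csv(ppath, sep="\t", index=False, float_format=_FLOAT_FMT)
    written.append(str(ppath))
    return written


def run_fixture_suite(
    fixture_dir,
    out_dir=None,
    n_boot: int = est.DEFAULT_N_BOOT,
    seed: int = est.DEFAULT_BOOT_SEED,
) -> pd.DataFrame:
    """Run every scenario written by ``make_fixture_suite`` end to end.

    Each scenario pairs its own exposure and outcome file, so the pipeline is
    invoked once per scenario; the per-scenario report rows are concatenated
    in manifest order.
    """
    fixture_dir = Path(fixture_dir)
    with open(fixture_dir / "manifest.json") as fh:
        manifest = json.load(fh)
    rows = []
    for name, meta in manifest["scenarios"].items():
        n_cases = int(round(meta["case_fraction"] * meta["n_out"]))
        cfg = RunConfig(
            exposures=[
                {
                    "id": name,
                    "path": str(fixture_dir / name / "exposure.tsv"),
                    "ld": str(fixture_dir / name / "ld.tsv"),
                    "classification": "scenario",
                }
            ],
            outcome={
                "path": str(fixture_dir / name / "outcome.tsv"),
                "n_cases": n_cases,
                "n_controls": meta["n_out"] - n_cases,
            },
            out_dir=str(Path(out_dir) / name) if out_dir else None,
            n_boot=n_boot,
            seed=seed,
        )
        report, _ = run_pipeline(cfg)
        rows.append(report)
    return pd.concat(rows, ignore_index=True)


def _write_run_summary(cfg: RunConfig, report: pd.DataFrame, artifacts: dict) -> None:
    summary = {
        "config": {
            "pval_threshold": cfg.pval_threshold,
            "clump_r2": cfg.clump_r2,
            "clump_kb": cfg.clump_kb,
            "f_min": cfg.f_min,
            "alpha": cfg.alpha,
            "palindrome_eaf_margin": cfg.palindrome_eaf_margin,
            "effects_model": cfg.effects_model,
            "methods": list(cfg.methods),
            "n_boot": cfg.n_boot,
            "seed": cfg.seed,
        },
        "assumptions": [
            "palindromic SNPs resolved by EAF or dropped (margin "
            f"{cfg.palindrome_eaf_margin}); harmonization defaults are assumptions, "
            "not inputs, of the source GWAS"
        ],
        "n_exposures": len(report),
        "n_significant": int(report["significant"].sum()),
        "filter_logs": {
            k: [list(t) for t in v.get("filter_log", [])] for k, v in artifacts.items()
        },
        "dropped": {k: [list(t) for t in v.get("dropped", [])] for k, v in artifacts.items()},
    }
    with open(Path(cfg.out_dir) / "run_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
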