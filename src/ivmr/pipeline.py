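"""Pipeline orchestration: harmonize -> rescale -> run every requested
estimator per outcome, and collect a tidy results table."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .data import harmonize, read_summary_stats, rescale_exposure
from .errors import ConfigurationError, IvmrError
from .estimators import egger, i2_gx, ivw, simex_egger, weighted_median
from .hetpen import hetpen
from .presso import presso
from .sensitivity import bonferroni_threshold, leave_one_out

log = logging.getLogger("ivmr")

ALL_METHODS = ("ivw", "wm", "egger", "simex", "hetpen", "presso", "loo")


@dataclass(frozen=True)
class AnalysisConfig:
    """Everything needed to replay one multi-outcome analysis run."""

    exposure_path: str
    outcomes: tuple[tuple[str, str], ...]  # (path, label)
    methods: tuple[str, ...] = ("ivw",)
    scale: float = 1.0
    family_size: int = 8
    family_alpha: float = 0.05
    palindrome_policy: str = "freq-infer"
    seed: int = 0
    n_boot: int = 1000
    n_sim: int = 1000
    column_map: dict | None = None
    out_dir: str | None = None

    def __post_init__(self):
        if not self.outcomes:
            raise ConfigurationError("at least one outcome file is required")
        bad = [m for m in self.methods if m not in ALL_METHODS]
        if bad:
            raise ConfigurationError(
                f"unknown method(s): {', '.join(bad)}; "
                f"choose from {', '.join(ALL_METHODS)}"
            )

    def hash(self) -> str:
        payload = json.dumps(
            {k: v for k, v in self.__dict__.items()}, sort_keys=True, default=str
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _row(method, outcome, est, extra=None):
    row = {
        "method": method, "outcome": outcome, "n_snps": est.n_snps,
        "beta": est.beta, "se": est.se, "or": est.odds_ratio,
        "or_low": est.or_low, "or_high": est.or_high, "pval": est.pval,
        "label": "",
    }
    if extra:
        row.update(extra)
    return row


def run_analysis(config: AnalysisConfig) -> pd.DataFrame:
    """Run the configured estimators against every outcome.

    Per-outcome failures are caught, logged, and reported as error rows;
    an empty result table raises. Deterministic given the config seeds.
    """
    threshold = bonferroni_threshold(config.family_size, config.family_alpha)
    exposure = read_summary_stats(config.exposure_path,
                                  column_map=config.column_map)
    rows: list[dict] = []
    failures: list[str] = []
    for path, label in config.outcomes:
        try:
            outcome = read_summary_stats(path, column_map=config.column_map)
            hset = harmonize(exposure, outcome,
                             palindrome_policy=config.palindrome_policy)
            hset = rescale_exposure(hset, config.scale)
            rows.extend(_run_methods(hset, label, config))
        except IvmrError as exc:
            log.error("outcome %s failed: %s", label, exc)
            failures.append(f"{label}: {exc}")
    if not rows:
        raise IvmrError(
            "no results produced; failures: " + "; ".join(failures)
        )
    df = pd.DataFrame(rows)
    df["significant"] = df["pval"] < threshold.exact
    df.attrs["config_hash"] = config.hash()
    df.attrs["version"] = __version__
    df.attrs["failures"] = failures
    log.info("ivmr %s run %s: %d rows, family threshold %.3g",
             __version__, config.hash(), len(df), threshold.exact)
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / "results.tsv", sep="\t", index=False,
                  float_format="%.10g")
        (out / "run_log.json").write_text(json.dumps({
            "version": __version__, "config_hash": config.hash(),
            "config": json.loads(json.dumps(config.__dict__, default=str)),
            "family_threshold": threshold.exact, "failures": failures,
        }, indent=2))
    return df


def _run_methods(hset, label, config):
    rows = []
    for method in config.methods:
        if method == "ivw":
            est, het = ivw(hset)
            rows.append(_row("ivw", label, est, {
                "cochran_q": het.cochran_q, "q_pval": het.q_pval,
                "i2_gx": het.i2_gx,
            }))
        elif method == "wm":
            est = weighted_median(hset, n_boot=config.n_boot, seed=config.seed)
            rows.append(_row("wm", label, est))
        elif method == "egger":
            est, het = egger(hset)
            rows.append(_row("egger", label, est, {
                "egger_intercept": het.egger_intercept,
                "egger_intercept_pval": het.egger_intercept_pval,
                "i2_gx": het.i2_gx,
            }))
        elif method == "simex":
            est = simex_egger(hset, n_sim=config.n_sim, seed=config.seed)
            rows.append(_row("simex", label, est, {"i2_gx": i2_gx(hset)}))
        elif method == "hetpen":
            avg = hetpen(hset)
            ci_txt = ";".join(f"[{lo:.6g},{hi:.6g}]" for lo, hi in avg.ci_set)
            rows.append({
                "method": "hetpen", "outcome": label, "n_snps": hset.n_snps,
                "beta": avg.mode, "se": np.nan,
                "or": float(np.exp(avg.mode)),
                "or_low": float(np.exp(avg.ci_low)),
                "or_high": float(np.exp(avg.ci_high)),
                "pval": np.nan, "label": ci_txt,
            })
        elif method == "presso":
            res = presso(hset, n_sim=max(config.n_sim, 1000), seed=config.seed)
            rows.append(_row("presso-raw", label, res.estimate_raw, {
                "presso_global_pval": res.global_pval,
                "label": ",".join(res.outliers) or "no-outliers",
            }))
            if res.estimate_outlier_corrected is not None:
                rows.append(_row("presso-corrected", label,
                                 res.estimate_outlier_corrected, {
                                     "presso_distortion_pval": res.distortion_pval,
                                     "label": ",".join(res.outliers),
                                 }))
        elif method == "loo":
            for rsid, est in leave_one_out(hset):
                rows.append(_row("loo", label, est, {"label": f"minus:{rsid}"}))
    return rows


def forest_plot(df: pd.DataFrame, path) -> None:
    """Plain forest plot of the tidy results table (OR, 95% CI) to PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = df.dropna(subset=["or_low", "or_high"]).reset_index(drop=True)
    labels = [f"{r.outcome} / {r.method}" for r in sub.itertuples()]
    y = np.arange(len(sub))[::-1]
    fig, ax = plt.subplots(figsize=(6, 0.4 * len(sub) + 1.5))
    ax.errorbar(sub["or"], y,
                xerr=[sub["or"] - sub["or_low"], sub["or_high"] - sub["or"]],
                fmt="s", color="black", ecolor="black", capsize=2)
    ax.axvline(1.0, color="grey", lw=0.8, ls="--")
    ax.set_yticks(y, labels)
    ax.set_xlabel("Odds ratio (95% CI)")
    ax.set_xscale("log")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
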