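"""Config-driven orchestration: forward MR, MVMR, mediation, reverse MR.

Each exposure-outcome analysis runs the fixed stage order
select -> clump -> harmonize -> outlier removal -> weak-instrument filter
-> estimators -> sensitivity, with per-stage counts and removal reasons
recorded so the instrument accounting is auditable. Mediation combines the
univariable total effect, the univariable exposure-to-mediator effect, and
the multivariable-adjusted mediator-to-outcome effect.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import estimators as est
from . import sensitivity as sens
from .errors import ConfigError, MrkitError
from .gwas_io import LdMatrix, SummaryDataset, read_ld_matrix, read_summary
from .instruments import (
    DEFAULTS,
    HarmonizedSet,
    f_statistics,
    harmonize,
    ld_clump,
    select_by_pvalue,
)
from .mvmr import build_mvmr_input, mediate, mv_egger, mv_ivw

logger = logging.getLogger(__name__)

_MODES = ("forward", "mvmr", "mediation", "reverse", "all")
_ALL_METHODS = ("ivw", "egger", "weighted_median", "simple_mode", "weighted_mode")


@dataclass
class PipelineConfig:
    """Everything one pipeline invocation needs, loadable from YAML."""

    exposure_path: str | None = None
    mediator_path: str | None = None
    outcome_path: str | None = None
    ld_path: str | None = None
    exposure_columns: dict | None = None
    mediator_columns: dict | None = None
    outcome_columns: dict | None = None
    exposure_trait_type: str = "quantitative"
    mediator_trait_type: str = "binary"
    outcome_trait_type: str = "binary"

    p_threshold: float = DEFAULTS["p_threshold"]
    relaxed_p_threshold: float = DEFAULTS["relaxed_p_threshold"]
    min_instruments: int = DEFAULTS["min_instruments"]
    clump_r2: float = DEFAULTS["clump_r2"]
    clump_window_kb: float = DEFAULTS["clump_window_kb"]
    palindrome_band: float = DEFAULTS["palindrome_band"]
    freq_source: str = DEFAULTS["freq_source"]
    weak_f_cutoff: float = DEFAULTS["weak_f_cutoff"]
    remove_weak: bool = True

    methods: tuple = _ALL_METHODS
    effects: str = "random"
    n_boot: int = 5000
    phi: float = 1.0
    seed: int | None = None

    run_presso: bool = True
    presso_n_sim: int = 1000
    outlier_alpha: float = 0.05

    mode: str = "all"
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ConfigError(f"unknown mode {self.mode!r}")
        unknown = [m for m in self.methods if m not in _ALL_METHODS]
        if unknown:
            raise ConfigError(f"unknown method(s): {unknown}")
        stochastic = (
            any(m in self.methods for m in ("weighted_median", "simple_mode", "weighted_mode"))
            or self.run_presso
        )
        if stochastic and self.seed is None:
            raise ConfigError("seed is required when any stochastic step is enabled")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ConfigError(f"unknown config key(s): {sorted(bad)}")
        if "methods" in raw:
            raw["methods"] = tuple(raw["methods"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["methods"] = list(d["methods"])
        return d

    def fingerprint(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Consolidated output of one pipeline run."""

    config_fingerprint: str
    blocks: dict = field(default_factory=dict)
    notes: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"config_fingerprint": self.config_fingerprint,
                "blocks": self.blocks, "notes": self.notes}

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return json.loads(obj.to_json(orient="records"))
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _mr_row(r: est.MrResult) -> dict:
    row = {
        "method": r.method,
        "n_snps": r.n_snps,
        "beta": r.beta,
        "se": r.se,
        "ci_low": r.ci_low,
        "ci_high": r.ci_high,
        "or": r.or_,
        "or_low": r.or_low,
        "or_high": r.or_high,
        "pvalue": r.pvalue,
    }
    if "intercept" in r.extras:
        row["egger_intercept"] = r.extras["intercept"]
        row["egger_intercept_p"] = r.extras["intercept_p"]
    return row


def _run_estimators(h: HarmonizedSet, cfg: PipelineConfig) -> list[est.MrResult]:
    if h.n_snps == 1:
        return [est.wald_ratio_result(h)]
    out: list[est.MrResult] = []
    seed = cfg.seed if cfg.seed is not None else 0
    for m in cfg.methods:
        try:
            if m == "ivw":
                out.append(est.ivw(h, effects=cfg.effects))
            elif m == "egger":
                out.append(est.egger(h))
            elif m == "weighted_median":
                out.append(est.weighted_median(h, n_boot=cfg.n_boot, seed=seed))
            elif m == "simple_mode":
                out.append(est.mode_estimate(h, weighted=False, phi=cfg.phi,
                                             n_boot=cfg.n_boot, seed=seed + 1))
            elif m == "weighted_mode":
                out.append(est.mode_estimate(h, weighted=True, phi=cfg.phi,
                                             n_boot=cfg.n_boot, seed=seed + 2))
        except MrkitError as exc:
            logger.warning("estimator %s skipped: %s", m, exc)
    if not out:
        raise MrkitError("no estimator could run")
    return out


def analyze_pair(
    exposure: SummaryDataset,
    outcome: SummaryDataset,
    ld: LdMatrix | None,
    cfg: PipelineConfig,
    label: str,
) -> dict:
    """One full exposure-outcome analysis; returns a report block."""
    counts = {}
    selected = select_by_pvalue(
        exposure, cfg.p_threshold, cfg.relaxed_p_threshold, cfg.min_instruments
    )
    counts["selected"] = len(selected)
    relaxed = bool(selected.meta.get("threshold_relaxed"))

    sub_ld = ld
    clumped = ld_clump(selected, sub_ld, cfg.clump_r2, cfg.clump_window_kb)
    counts["clumped"] = len(clumped)

    h = harmonize(clumped, outcome, cfg.palindrome_band, cfg.freq_source)
    counts["harmonized"] = h.n_snps

    presso_block = None
    if cfg.run_presso and h.n_snps >= 4:
        presso, h = sens.mr_presso(
            h, n_sim=cfg.presso_n_sim, seed=(cfg.seed or 0), outlier_alpha=cfg.outlier_alpha
        )
        n_out = int(presso.presso_outliers["outlier"].sum())
        if n_out:
            # report the global test on the final (outlier-removed) set
            presso_final, _ = sens.mr_presso(
                h, n_sim=cfg.presso_n_sim, seed=(cfg.seed or 0) + 1,
                outlier_alpha=cfg.outlier_alpha,
            )
            global_p = presso_final.presso_global_p
        else:
            global_p = presso.presso_global_p
        presso_block = {
            "n_outliers_removed": n_out,
            "global_p": global_p,
            "distortion_p": presso.distortion_p,
        }
    counts["after_outlier_removal"] = h.n_snps

    fstats = f_statistics(h, cfg.weak_f_cutoff)
    n_weak = int(fstats.weak_flags.sum())
    if cfg.remove_weak and n_weak and n_weak < h.n_snps:
        h = h.subset(~fstats.weak_flags)
        fstats = f_statistics(h, cfg.weak_f_cutoff)
    counts["after_weak_filter"] = h.n_snps

    results = _run_estimators(h, cfg)

    sensitivity = {}
    if h.n_snps >= 2:
        q_ivw = sens.cochran_q(h, "ivw")
        sensitivity["q_ivw"] = {"q": q_ivw.q, "df": q_ivw.df, "pvalue": q_ivw.pvalue}
    if h.n_snps >= 3:
        q_egger = sens.cochran_q(h, "egger")
        sensitivity["q_egger"] = {"q": q_egger.q, "df": q_egger.df, "pvalue": q_egger.pvalue}
        pl = sens.egger_intercept_test(h)
        sensitivity["egger_intercept"] = {
            "estimate": pl.egger_intercept,
            "se": pl.intercept_se,
            "pvalue": pl.intercept_p,
        }
        loo = sens.leave_one_out(h)
        sensitivity["leave_one_out_stable"] = loo.stable
    if presso_block is not None:
        sensitivity["presso"] = presso_block
    hetero = sensitivity.get("q_ivw", {}).get("pvalue", 1.0) < cfg.alpha
    sensitivity["heterogeneous"] = bool(hetero)
    # under heterogeneity the random-effects IVW is the labelled primary
    primary = "ivw_re" if (hetero or cfg.effects == "random") else "ivw_fe"

    block = {
        "label": label,
        "exposure": exposure.trait_name,
        "outcome": outcome.trait_name,
        "counts": counts,
        "threshold_relaxed": relaxed,
        "p_threshold_used": selected.meta.get("p_threshold_used"),
        "mean_f": fstats.mean_f,
        "n_weak_flagged": n_weak,
        "estimates": [_mr_row(r) for r in results],
        "primary_method": primary,
        "sensitivity": sensitivity,
    }
    return block, h, results


def run_pipeline(
    cfg: PipelineConfig,
    exposure: SummaryDataset | None = None,
    mediator: SummaryDataset | None = None,
    outcome: SummaryDataset | None = None,
    ld: LdMatrix | None = None,
) -> RunReport:
    """Execute the configured analyses and return a consolidated report.

    Datasets may be passed in-memory; otherwise they are loaded from the
    configured paths. A failing reverse analysis is recorded as a note and
    does not invalidate the forward results.
    """
    if exposure is None:
        if cfg.exposure_path is None:
            raise ConfigError("exposure dataset or exposure_path required")
        exposure = read_summary(cfg.exposure_path, cfg.exposure_columns,
                                cfg.exposure_trait_type, "exposure")
    if outcome is None:
        if cfg.outcome_path is None:
            raise ConfigError("outcome dataset or outcome_path required")
        outcome = read_summary(cfg.outcome_path, cfg.outcome_columns,
                               cfg.outcome_trait_type, "outcome")
    need_mediator = cfg.mode in ("mvmr", "mediation", "all")
    if need_mediator and mediator is None:
        if cfg.mediator_path is None:
            raise ConfigError(f"mode {cfg.mode!r} requires a mediator dataset")
        mediator = read_summary(cfg.mediator_path, cfg.mediator_columns,
                                cfg.mediator_trait_type, "mediator")
    if ld is None and cfg.ld_path is not None:
        ld = read_ld_matrix(cfg.ld_path)

    report = RunReport(config_fingerprint=cfg.fingerprint())

    forward_block = forward_h = forward_results = None
    if cfg.mode in ("forward", "mvmr", "mediation", "all", "reverse"):
        forward_block, forward_h, forward_results = analyze_pair(
            exposure, outcome, ld, cfg, "exposure->outcome"
        )
        report.blocks["forward"] = forward_block

    xz_block = None
    if need_mediator:
        xz_block, _, xz_results = analyze_pair(
            exposure, mediator, ld, cfg, "exposure->mediator"
        )
        report.blocks["exposure_mediator"] = xz_block

    mvmr_block = None
    if cfg.mode in ("mvmr", "mediation", "all"):
        inp = build_mvmr_input(
            [exposure, mediator], outcome, ld,
            cfg.p_threshold, cfg.relaxed_p_threshold, cfg.min_instruments,
            cfg.clump_r2, cfg.clump_window_kb, cfg.palindrome_band,
        )
        res_ivw = mv_ivw(inp)
        mvmr_block = {
            "n_snps": inp.n_snps,
            "exposures": res_ivw.exposures,
            "mv_ivw": json.loads(res_ivw.to_frame().to_json(orient="records")),
            "q_ivw": {"q": res_ivw.q, "df": res_ivw.q_df, "pvalue": res_ivw.q_pvalue},
        }
        try:
            res_egger = mv_egger(inp)
            mvmr_block["mv_egger"] = json.loads(res_egger.to_frame().to_json(orient="records"))
            mvmr_block["q_egger"] = {"q": res_egger.q, "df": res_egger.q_df,
                                     "pvalue": res_egger.q_pvalue}
            mvmr_block["egger_intercept"] = {"estimate": res_egger.intercept,
                                             "pvalue": res_egger.intercept_p}
        except MrkitError as exc:
            report.notes.append(f"mv_egger skipped: {exc}")
        report.blocks["mvmr"] = mvmr_block

    if cfg.mode in ("mediation", "all"):
        if forward_block is None or mvmr_block is None or xz_block is None:
            raise ConfigError("mediation requires the forward and MVMR stages")
        total_row = _primary_estimate(forward_block)
        xz_row = _primary_estimate(xz_block)
        med_name = mediator.trait_name
        res_ivw_betas = {r["exposure"]: r for r in mvmr_block["mv_ivw"]}
        zy = res_ivw_betas[med_name]
        med = mediate(
            total=total_row["beta"],
            exposure_mediator=xz_row["beta"],
            mediator_outcome_adjusted=zy["beta"],
            se_total=total_row["se"],
            se_exposure_mediator=xz_row["se"],
            se_mediator_outcome=zy["se"],
        )
        report.blocks["mediation"] = {
            "total": med.total,
            "exposure_mediator": med.exposure_mediator,
            "mediator_outcome_adjusted": med.mediator_outcome_adjusted,
            "indirect": med.indirect,
            "direct": med.direct,
            "proportion": med.proportion,
            "indirect_se": med.indirect_se,
            "proportion_ci": list(med.proportion_ci),
            "sign_warning": med.sign_warning,
            "printed": med.printed(),
        }

    if cfg.mode in ("reverse", "all"):
        try:
            rev_block, _, _ = analyze_pair(outcome, exposure, ld, cfg, "outcome->exposure")
            report.blocks["reverse"] = rev_block
            if rev_block["threshold_relaxed"]:
                report.notes.append(
                    f"reverse analysis relaxed the threshold to "
                    f"{rev_block['p_threshold_used']:g}"
                )
        except MrkitError as exc:
            report.notes.append(f"reverse analysis failed: {exc}")

    return report


def _primary_estimate(block: dict) -> dict:
    want = block["primary_method"]
    rows = {r["method"]: r for r in block["estimates"]}
    if want in rows:
        return rows[want]
    for fallback in ("ivw_re", "ivw_fe", "wald_ratio"):
        if fallback in rows:
            return rows[fallback]
    raise MrkitError("no usable primary estimate in block")


def compare_methods(block: dict, alpha: float = 0.05) -> pd.DataFrame:
    """Method-concordance table for one analysis block.

    Per method: estimate, CI, p, sign agreement with the IVW estimate, and
    a significance flag at ``alpha``. Requires at least two methods.
    """
    rows = block["estimates"] if isinstance(block, dict) else [_mr_row(r) for r in block]
    if len(rows) < 2:
        raise ValueError("nothing to compare: need at least two methods")
    ivw_row = next((r for r in rows if r["method"].startswith("ivw")), rows[0])
    out = []
    for r in rows:
        out.append(
            {
                "method": r["method"],
                "beta": r["beta"],
                "ci_low": r["ci_low"],
                "ci_high": r["ci_high"],
                "pvalue": r["pvalue"],
                "agrees_with_ivw_sign": np.sign(r["beta"]) == np.sign(ivw_row["beta"]),
                "significant": r["pvalue"] < alpha,
            }
        )
    return pd.DataFrame(out)
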