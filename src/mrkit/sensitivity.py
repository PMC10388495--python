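"""Heterogeneity, pleiotropy, outlier, and influence diagnostics.

Cochran's Q against the IVW or Egger fit; the Egger intercept test for
directional pleiotropy; a simulation-based residual-sum-of-squares outlier
procedure (global test, per-SNP outlier test with Bonferroni correction,
and a distortion test); leave-one-out influence analysis; and plot-ready
scatter/forest/funnel tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientSnpsError
from .estimators import MrResult, _ivw_fit, _orient_positive, _wls, ivw, wald_ratios
from .instruments import HarmonizedSet


@dataclass
class HeterogeneityResult:
    method: str  # "ivw" | "egger"
    q: float
    df: int
    pvalue: float


@dataclass
class PleiotropyResult:
    egger_intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None
    presso_rss_obs: float | None = None
    presso_global_p: float | None = None
    presso_outliers: pd.DataFrame | None = None
    distortion_p: float | None = None


@dataclass
class LeaveOneOutResult:
    table: pd.DataFrame  # one row per excluded SNP + an "all" row
    full: MrResult
    stable: bool


def cochran_q(h: HarmonizedSet, method: str = "ivw") -> HeterogeneityResult:
    """Cochran's Q around the fixed-effect IVW line or the Egger line.

    Q = sum_j w_j (Gamma_j - fitted_j)^2 with w_j = 1/se_Gamma_j^2;
    df = J-1 (IVW, no intercept) or J-2 (Egger, with intercept); p from the
    upper chi-square tail.
    """
    j = h.n_snps
    if method == "ivw":
        if j < 2:
            raise InsufficientSnpsError("cochran_q(ivw) needs J >= 2")
        _, _, q = _ivw_fit(h.gamma, h.Gamma, h.se_Gamma)
        df = j - 1
    elif method == "egger":
        if j < 3:
            raise InsufficientSnpsError("cochran_q(egger) needs J >= 3")
        gamma, Gamma = _orient_positive(h.gamma, h.Gamma)
        w = 1.0 / h.se_Gamma**2
        X = np.column_stack([np.ones(j), gamma])
        _, _, q = _wls(X, Gamma, w)
        df = j - 2
    else:
        raise ValueError("method must be 'ivw' or 'egger'")
    p = float(max(stats.chi2.sf(q, df), np.finfo(float).tiny))
    return HeterogeneityResult(method=method, q=float(q), df=df, pvalue=min(p, 1.0))


def egger_intercept_test(h: HarmonizedSet) -> PleiotropyResult:
    """Directional-pleiotropy test: the Egger intercept with its t(J-2) p."""
    from .estimators import egger  # local import keeps module load order flat

    res = egger(h)
    return PleiotropyResult(
        egger_intercept=res.extras["intercept"],
        intercept_se=res.extras["intercept_se"],
        intercept_p=res.extras["intercept_p"],
    )


def _loo_ivw_beta(gamma, Gamma, w):
    """Leave-one-out fixed-effect IVW estimates, vectorized over SNPs."""
    num = np.sum(w * gamma * Gamma)
    den = np.sum(w * gamma**2)
    return (num - w * gamma * Gamma) / (den - w * gamma**2)


def mr_presso(
    h: HarmonizedSet,
    n_sim: int = 1000,
    seed: int = 0,
    outlier_alpha: float = 0.05,
    n_distortion: int = 1000,
) -> tuple[PleiotropyResult, HarmonizedSet]:
    """Simulation-based pleiotropy residual test with outlier removal.

    Global test: the observed weighted residual sum of squares around the
    leave-one-out IVW expectations is ranked against ``n_sim`` parametric
    simulations (Gamma* ~ N(beta_loo_j * gamma_j, se_Gamma_j), gamma* ~
    N(gamma_j, se_gamma_j)); p = (1 + #{RSS_sim >= RSS_obs})/(n_sim + 1).

    Outlier test: each SNP's observed weighted squared residual is ranked in
    its own simulated distribution; empirical p-values are Bonferroni
    corrected over J and SNPs below ``outlier_alpha`` are removed from the
    returned corrected set.

    Distortion test: the shift between the all-SNP and outlier-removed IVW
    estimates is compared with the shift distribution under random removal
    of the same number of SNPs. Missing when no outliers are found.
    """
    j = h.n_snps
    if j < 4:
        raise InsufficientSnpsError("mr_presso needs J >= 4")
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    rng = np.random.default_rng(seed)
    w = 1.0 / h.se_Gamma**2

    beta_loo = _loo_ivw_beta(h.gamma, h.Gamma, w)
    obs_terms = w * (h.Gamma - beta_loo * h.gamma) ** 2
    rss_obs = float(np.sum(obs_terms))

    g_sim = h.gamma + h.se_gamma * rng.standard_normal((n_sim, j))
    G_sim = beta_loo * h.gamma + h.se_Gamma * rng.standard_normal((n_sim, j))
    num_s = np.sum(w * g_sim * G_sim, axis=1, keepdims=True)
    den_s = np.sum(w * g_sim**2, axis=1, keepdims=True)
    beta_loo_s = (num_s - w * g_sim * G_sim) / (den_s - w * g_sim**2)
    sim_terms = w * (G_sim - beta_loo_s * g_sim) ** 2
    rss_sim = sim_terms.sum(axis=1)

    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))

    outlier_p = np.mean(sim_terms >= obs_terms[None, :], axis=0)
    corrected = np.minimum(outlier_p * j, 1.0)
    flags = corrected < outlier_alpha
    outliers = pd.DataFrame(
        {
            "snp_id": h.snp_ids,
            "pvalue": outlier_p,
            "pvalue_bonferroni": corrected,
            "outlier": flags,
        }
    )

    distortion_p = None
    corrected_set = h
    if flags.any():
        if (~flags).sum() < 2:
            # removing the flags would leave <2 SNPs; keep the input set
            flags = np.zeros(j, dtype=bool)
            outliers["outlier"] = flags
        else:
            corrected_set = h.subset(~flags)
            beta_all, _, _ = _ivw_fit(h.gamma, h.Gamma, h.se_Gamma)
            beta_corr, _, _ = _ivw_fit(
                corrected_set.gamma, corrected_set.Gamma, corrected_set.se_Gamma
            )
            diff_obs = abs(beta_all - beta_corr)
            k = int(flags.sum())
            diffs = np.empty(n_distortion)
            for i in range(n_distortion):
                drop = rng.choice(j, size=k, replace=False)
                keep = np.ones(j, dtype=bool)
                keep[drop] = False
                b, _, _ = _ivw_fit(h.gamma[keep], h.Gamma[keep], h.se_Gamma[keep])
                diffs[i] = abs(beta_all - b)
            distortion_p = float((1 + np.sum(diffs >= diff_obs)) / (n_distortion + 1))

    result = PleiotropyResult(
        presso_rss_obs=rss_obs,
        presso_global_p=global_p,
        presso_outliers=outliers,
        distortion_p=distortion_p,
    )
    return result, corrected_set


def leave_one_out(h: HarmonizedSet) -> LeaveOneOutResult:
    """Random-effects IVW recomputed excluding each SNP in turn.

    The stability flag is true when the full-set estimate lies inside every
    leave-one-out 95% CI.
    """
    j = h.n_snps
    if j < 3:
        raise InsufficientSnpsError("leave_one_out needs J >= 3")
    full = ivw(h, effects="random")
    rows = []
    stable = True
    for k in range(j):
        mask = np.ones(j, dtype=bool)
        mask[k] = False
        res = ivw(h.subset(mask), effects="random")
        inside = res.ci_low <= full.beta <= res.ci_high
        stable &= inside
        rows.append((h.snp_ids[k], res.beta, res.se, res.ci_low, res.ci_high))
    rows.append(("all", full.beta, full.se, full.ci_low, full.ci_high))
    table = pd.DataFrame(rows, columns=["excluded_snp", "beta", "se", "ci_low", "ci_high"])
    return LeaveOneOutResult(table=table, full=full, stable=bool(stable))


def plot_data(h: HarmonizedSet, results: list[MrResult]) -> dict[str, pd.DataFrame]:
    """Plot-ready tables: scatter (with per-method fit lines), forest, funnel.

    The funnel centre line and the forest "combined" row are the IVW
    estimate from ``results`` when present (random-effects preferred).
    """
    if not results:
        raise ValueError("plot_data needs at least one MrResult")
    wr = wald_ratios(h)
    scatter = pd.DataFrame(
        {
            "snp_id": h.snp_ids,
            "gamma": h.gamma,
            "se_gamma": h.se_gamma,
            "Gamma": h.Gamma,
            "se_Gamma": h.se_Gamma,
        }
    )
    lines = []
    for r in results:
        lines.append(
            {
                "method": r.method,
                "slope": r.beta,
                "intercept": r.extras.get("intercept", 0.0),
            }
        )
    by_method = {r.method: r for r in results}
    combined = by_method.get("ivw_re") or by_method.get("ivw_fe") or results[0]

    forest_rows = [
        {"label": s, "beta": b, "se": e, "ci_low": b - 1.96 * e, "ci_high": b + 1.96 * e}
        for s, b, e in zip(wr.snp_ids, wr.beta, wr.se)
    ]
    forest_rows.append(
        {
            "label": f"combined ({combined.method})",
            "beta": combined.beta,
            "se": combined.se,
            "ci_low": combined.ci_low,
            "ci_high": combined.ci_high,
        }
    )
    funnel = pd.DataFrame(
        {"snp_id": wr.snp_ids, "beta": wr.beta, "precision": 1.0 / wr.se}
    )
    funnel["center"] = combined.beta
    return {
        "scatter": scatter,
        "scatter_lines": pd.DataFrame(lines),
        "forest": pd.DataFrame(forest_rows),
        "funnel": funnel,
    }
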