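"""Two-sample MR estimators on harmonized summary data.

Implements the Wald ratio, fixed/random-effects inverse-variance weighted
(IVW) estimator, Egger regression, the weighted median, and the simple and
weighted mode estimators. All return :class:`MrResult` with the effect on
the outcome's beta scale (log-odds for binary traits), a 95% CI, and the
exponentiated odds-ratio counterparts.

Conventions: random-effects IVW uses multiplicative overdispersion with the
scale floored at 1 (so it nests fixed effects); Egger inference uses a
t(J-2) reference, everything else a normal reference; bootstrap standard
errors are parametric and fully determined by the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import InsufficientSnpsError
from .instruments import HarmonizedSet

_TINY_P = 1e-300


@dataclass
class MrResult:
    """One estimator's causal-effect estimate.

    ``beta`` is on the outcome beta scale; ``or_`` and its CI are the
    exponentiated counterparts. ``extras`` carries method-specific output
    (Egger intercept triple, RE scale factor, bootstrap replicate count...).
    """

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    or_: float
    or_low: float
    or_high: float
    pvalue: float
    n_snps: int
    extras: dict = field(default_factory=dict)


def _result(method, beta, se, n_snps, df=None, extras=None) -> MrResult:
    """Assemble an MrResult; normal reference unless a t df is given."""
    beta, se = float(beta), float(se)
    if df is None:
        crit = 1.96
        p = 2.0 * stats.norm.sf(abs(beta) / se) if se > 0 else _TINY_P
    else:
        crit = float(stats.t.ppf(0.975, df))
        p = 2.0 * stats.t.sf(abs(beta) / se, df) if se > 0 else _TINY_P
    lo, hi = beta - crit * se, beta + crit * se
    return MrResult(
        method=method,
        beta=beta,
        se=se,
        ci_low=lo,
        ci_high=hi,
        or_=float(np.exp(beta)),
        or_low=float(np.exp(lo)),
        or_high=float(np.exp(hi)),
        pvalue=float(max(p, _TINY_P)),
        n_snps=int(n_snps),
        extras=extras or {},
    )


def or_from_beta(beta: float, se: float) -> tuple[float, float, float]:
    """Odds ratio with 95% CI: (exp(b), exp(b - 1.96 se), exp(b + 1.96 se))."""
    if se < 0:
        raise ValueError("se must be non-negative")
    return (
        float(np.exp(beta)),
        float(np.exp(beta - 1.96 * se)),
        float(np.exp(beta + 1.96 * se)),
    )


@dataclass
class WaldRatios:
    snp_ids: np.ndarray
    beta: np.ndarray
    se: np.ndarray


def wald_ratios(h: HarmonizedSet) -> WaldRatios:
    """Per-SNP ratio estimates: beta_j = Gamma_j/gamma_j, se_j = se_Gamma_j/|gamma_j|.

    First-order standard errors (exposure-side uncertainty ignored), which
    is the scale the IVW weights imply.
    """
    if np.any(h.gamma == 0):
        bad = h.snp_ids[h.gamma == 0]
        raise ZeroDivisionError(f"zero exposure beta for SNP(s): {list(bad[:5])}")
    return WaldRatios(
        snp_ids=np.asarray(h.snp_ids),
        beta=h.Gamma / h.gamma,
        se=h.se_Gamma / np.abs(h.gamma),
    )


def wald_ratio_result(h: HarmonizedSet) -> MrResult:
    """Single-SNP causal estimate (the J = 1 fallback in the pipeline)."""
    if h.n_snps != 1:
        raise InsufficientSnpsError("wald_ratio_result is for exactly one SNP")
    wr = wald_ratios(h)
    return _result("wald_ratio", wr.beta[0], wr.se[0], 1)


def _ivw_fit(gamma, Gamma, se_Gamma):
    """Closed-form zero-intercept WLS of Gamma on gamma, weights 1/se_Gamma^2."""
    w = 1.0 / se_Gamma**2
    den = np.sum(w * gamma**2)
    beta = np.sum(w * gamma * Gamma) / den
    se_fixed = np.sqrt(1.0 / den)
    q = float(np.sum(w * (Gamma - beta * gamma) ** 2))
    return float(beta), float(se_fixed), q


def ivw(h: HarmonizedSet, effects: str = "random") -> MrResult:
    """Inverse-variance weighted estimate.

    ``effects="fixed"`` uses the plain WLS standard error;
    ``effects="random"`` inflates it by max(1, sqrt(Q/(J-1))) (multiplicative
    overdispersion), where Q is Cochran's Q at the IVW estimate. Normal
    reference for p-values and the CI in both cases.
    """
    if effects not in ("fixed", "random"):
        raise ValueError("effects must be 'fixed' or 'random'")
    j = h.n_snps
    if j < 2:
        raise InsufficientSnpsError("ivw needs J >= 2; use wald_ratios for a single SNP")
    beta, se_fixed, q = _ivw_fit(h.gamma, h.Gamma, h.se_Gamma)
    scale = max(1.0, np.sqrt(q / (j - 1)))
    se = se_fixed * scale if effects == "random" else se_fixed
    return _result(
        f"ivw_{'re' if effects == 'random' else 'fe'}",
        beta, se, j,
        extras={"q": q, "re_scale": float(scale), "se_fixed": se_fixed},
    )


def _orient_positive(gamma, Gamma):
    """Flip each SNP's (gamma, Gamma) jointly so gamma >= 0."""
    sign = np.where(gamma < 0, -1.0, 1.0)
    return gamma * sign, Gamma * sign


def _wls(X, y, w):
    """Weighted least squares; returns (coef, unscaled covariance, weighted RSS)."""
    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    yw = y * sw
    xtx = Xw.T @ Xw
    try:
        xtx_inv = np.linalg.inv(xtx)
    except np.linalg.LinAlgError as exc:
        raise InsufficientSnpsError("collinear exposures") from exc
    coef = xtx_inv @ (Xw.T @ yw)
    resid = yw - Xw @ coef
    return coef, xtx_inv, float(resid @ resid)


def egger(h: HarmonizedSet) -> MrResult:
    """Egger regression: WLS of Gamma on gamma with a free intercept.

    Each SNP is first oriented so gamma_j >= 0. The slope is the causal
    estimate; the intercept estimates average directional pleiotropy and is
    reported in ``extras`` with its SE and t(J-2) p-value. Standard errors
    carry the multiplicative overdispersion factor max(1, sqrt(Q/(J-2))).
    """
    j = h.n_snps
    if j < 3:
        raise InsufficientSnpsError("egger needs J >= 3")
    gamma, Gamma = _orient_positive(h.gamma, h.Gamma)
    w = 1.0 / h.se_Gamma**2
    X = np.column_stack([np.ones(j), gamma])
    coef, cov_u, rss = _wls(X, Gamma, w)
    df = j - 2
    scale2 = max(1.0, rss / df)
    ses = np.sqrt(np.diag(cov_u) * scale2)
    icpt, slope = coef
    icpt_se, slope_se = ses
    icpt_p = float(max(2.0 * stats.t.sf(abs(icpt) / icpt_se, df), _TINY_P))
    return _result(
        "egger", slope, slope_se, j, df=df,
        extras={
            "intercept": float(icpt),
            "intercept_se": float(icpt_se),
            "intercept_p": icpt_p,
            "q_egger": rss,
            "scale": float(np.sqrt(scale2)),
        },
    )


def weighted_median_estimate(ratio_beta: np.ndarray, weights: np.ndarray,
                             tiebreak: np.ndarray | None = None) -> float:
    """Weighted median of ratio estimates by cumulative-midpoint interpolation.

    Sort the ratios, normalize the weights, form midpoint positions
    s_j = cumsum(w)_j - w_j/2, and linearly interpolate the sorted ratios
    at s = 0.5. Ties in the ratio order are broken by ``tiebreak`` (snp_id
    in the pipeline) for determinism.
    """
    if tiebreak is None:
        order = np.argsort(ratio_beta, kind="mergesort")
    else:
        order = np.lexsort((np.asarray(tiebreak), ratio_beta))
    b = ratio_beta[order]
    w = weights[order] / np.sum(weights)
    s = np.cumsum(w) - w / 2.0
    return float(np.interp(0.5, s, b))


def weighted_median(h: HarmonizedSet, n_boot: int = 5000, seed: int = 0) -> MrResult:
    """Weighted-median estimator with a seeded parametric-bootstrap SE.

    Weights are gamma_j^2/se_Gamma_j^2 (the ratio inverse variances). Each
    bootstrap replicate redraws gamma* ~ N(gamma, se_gamma) and
    Gamma* ~ N(Gamma, se_Gamma) and recomputes the weighted median.
    """
    j = h.n_snps
    if j < 3:
        raise InsufficientSnpsError("weighted_median needs J >= 3")
    wr = wald_ratios(h)
    weights = h.gamma**2 / h.se_Gamma**2
    est = weighted_median_estimate(wr.beta, weights, tiebreak=h.snp_ids)
    se = _boot_se(h, seed, n_boot, lambda rb, rw: weighted_median_estimate(rb, rw))
    return _result("weighted_median", est, se, j, extras={"n_boot": n_boot, "seed": seed})


def _boot_se(h: HarmonizedSet, seed: int, n_boot: int, point_fn) -> float:
    """SE of a ratio-based point estimator over parametric bootstrap draws.

    ``point_fn(ratios, weights)`` receives the replicate's Wald ratios and
    their inverse-variance weights.
    """
    rng = np.random.default_rng(seed)
    g = h.gamma + h.se_gamma * rng.standard_normal((n_boot, h.n_snps))
    G = h.Gamma + h.se_Gamma * rng.standard_normal((n_boot, h.n_snps))
    g = np.where(g == 0, np.finfo(float).tiny, g)
    est = np.empty(n_boot)
    for i in range(n_boot):
        ratios = G[i] / g[i]
        weights = g[i] ** 2 / h.se_Gamma**2
        est[i] = point_fn(ratios, weights)
    return float(np.std(est, ddof=1))


def _kde_mode(ratios: np.ndarray, weights: np.ndarray, phi: float, grid_size: int = 512):
    """Argmax of a weighted normal-kernel density over the ratio estimates.

    Bandwidth h = phi * 0.9 * min(sd, IQR/1.349) * J^(-1/5). Returns
    (mode, bandwidth); a zero bandwidth (all ratios identical) returns the
    common value directly.
    """
    jj = len(ratios)
    sd = float(np.std(ratios, ddof=1)) if jj > 1 else 0.0
    iqr = float(stats.iqr(ratios))
    spread = min(sd, iqr / 1.349) if iqr > 0 else sd
    bw = phi * 0.9 * spread * jj ** (-1 / 5)
    if bw <= 0 or not np.isfinite(bw):
        return float(ratios[0]), 0.0
    grid = np.linspace(ratios.min() - 3 * bw, ratios.max() + 3 * bw, grid_size)
    z = (grid[:, None] - ratios[None, :]) / bw
    dens = np.exp(-0.5 * z**2) @ (weights / weights.sum())
    return float(grid[np.argmax(dens)]), float(bw)


def mode_estimate(
    h: HarmonizedSet,
    weighted: bool = True,
    phi: float = 1.0,
    n_boot: int = 5000,
    seed: int = 0,
) -> MrResult:
    """Mode-based estimate (simple or weighted) of the Wald-ratio density.

    The simple mode uses equal kernel weights; the weighted mode weights
    each ratio by its inverse variance. SE via the same seeded parametric
    bootstrap as the weighted median.
    """
    j = h.n_snps
    if j < 3:
        raise InsufficientSnpsError("mode_estimate needs J >= 3")
    wr = wald_ratios(h)
    iv_w = h.gamma**2 / h.se_Gamma**2

    def point(ratios, weights):
        kw = weights if weighted else np.ones_like(ratios)
        return _kde_mode(ratios, kw, phi)[0]

    est, bw = _kde_mode(wr.beta, iv_w if weighted else np.ones(j), phi)
    se = _boot_se(h, seed, n_boot, point)
    method = "weighted_mode" if weighted else "simple_mode"
    return _result(method, est, se, j, extras={"bandwidth": bw, "phi": phi,
                                               "n_boot": n_boot, "seed": seed})
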