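"""Multivariable MR and product-of-coefficients mediation.

MV-IVW regresses outcome associations on the J x K exposure-association
matrix without an intercept (weights 1/se_Gamma^2, multiplicative
overdispersion floored at 1); MV-Egger adds an intercept after orienting
every SNP so the first exposure's beta is non-negative, with t(J-K-1)
inference. ``mediate`` implements the decomposition
indirect = b_XZ * b_ZY, direct = total - indirect,
proportion = 100 * indirect / total, with delta-method uncertainty.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import HarmonizationError, InsufficientSnpsError
from .estimators import _wls
from .gwas_io import LdMatrix, SummaryDataset
from .instruments import DEFAULTS, HarmonizedSet, harmonize, ld_clump, select_by_pvalue

logger = logging.getLogger(__name__)

_TINY_P = 1e-300


@dataclass
class MvmrInput:
    """Joint instrument set for K exposures against one outcome."""

    snp_ids: np.ndarray
    exposure_names: list[str]
    exposure_betas: np.ndarray  # J x K
    exposure_ses: np.ndarray  # J x K
    Gamma: np.ndarray
    se_Gamma: np.ndarray

    def __post_init__(self) -> None:
        self.exposure_betas = np.atleast_2d(np.asarray(self.exposure_betas, float))
        self.exposure_ses = np.atleast_2d(np.asarray(self.exposure_ses, float))
        j, k = self.exposure_betas.shape
        if len(self.Gamma) != j or len(self.se_Gamma) != j:
            raise HarmonizationError("outcome arrays do not match exposure matrix")
        if (self.exposure_ses <= 0).any() or (np.asarray(self.se_Gamma) <= 0).any():
            raise HarmonizationError("non-positive standard errors in MVMR input")

    @property
    def n_snps(self) -> int:
        return self.exposure_betas.shape[0]

    @property
    def n_exposures(self) -> int:
        return self.exposure_betas.shape[1]


@dataclass
class MvmrResult:
    """Per-exposure adjusted effects from one multivariable fit."""

    method: str  # "mv_ivw" | "mv_egger"
    exposures: list[str]
    beta: np.ndarray
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    pvalue: np.ndarray
    n_snps: int
    q: float
    q_df: int
    q_pvalue: float
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "exposure": self.exposures,
                "method": self.method,
                "beta": self.beta,
                "se": self.se,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "pvalue": self.pvalue,
                "n_snps": self.n_snps,
            }
        )

    def beta_for(self, exposure: str) -> float:
        return float(self.beta[self.exposures.index(exposure)])

    def se_for(self, exposure: str) -> float:
        return float(self.se[self.exposures.index(exposure)])


@dataclass
class MediationResult:
    """Product-of-coefficients decomposition of a total effect.

    ``direct + indirect == total`` holds at machine precision by
    construction (direct is defined as the difference).
    """

    total: float
    exposure_mediator: float
    mediator_outcome_adjusted: float
    indirect: float
    direct: float
    proportion: float  # percent
    indirect_se: float
    proportion_se: float
    proportion_ci: tuple[float, float]
    sign_warning: bool

    def printed(self, ndigits: int = 3) -> dict:
        """The decomposition as a results table would print it.

        Components are rounded to ``ndigits`` decimals first and the
        proportion is computed from the rounded components (how such tables
        are conventionally derived), then rounded to two decimals.
        """
        total_p = round(self.total, ndigits)
        ind_p = round(self.indirect, ndigits)
        return {
            "total": total_p,
            "indirect": ind_p,
            "direct": round(total_p - ind_p, ndigits),
            "proportion": round(100.0 * ind_p / total_p, 2),
        }


def build_mvmr_input(
    exposure_sets: list[SummaryDataset],
    outcome: SummaryDataset,
    ld: LdMatrix | None = None,
    p_threshold: float = DEFAULTS["p_threshold"],
    relaxed_p_threshold: float = DEFAULTS["relaxed_p_threshold"],
    min_instruments: int = DEFAULTS["min_instruments"],
    clump_r2: float = DEFAULTS["clump_r2"],
    clump_window_kb: float = DEFAULTS["clump_window_kb"],
    palindrome_band: float = DEFAULTS["palindrome_band"],
) -> MvmrInput:
    """Assemble a joint instrument set for K >= 2 exposures.

    Takes the union of each exposure's significant SNPs, jointly clumps it
    (greedy, ordered by the minimum p across exposures), then aligns every
    dataset to the first exposure's effect alleles; SNPs missing from any
    dataset, palindromic-ambiguous, or irreconcilable are dropped with
    logged reasons.
    """
    if len(exposure_sets) < 2:
        raise ValueError("build_mvmr_input needs K >= 2 exposures")
    k = len(exposure_sets)

    selected = [
        select_by_pvalue(ds, p_threshold, relaxed_p_threshold, min_instruments)
        for ds in exposure_sets
    ]
    union_ids: list[str] = []
    seen = set()
    for sel in selected:
        for s in sel.table["snp_id"]:
            if s not in seen:
                seen.add(s)
                union_ids.append(s)

    # union table for joint clumping: position/chrom from the first exposure
    # carrying the SNP, p = min across exposures
    first = exposure_sets[0]
    rows = []
    for s in union_ids:
        carrier = next(
            ds for ds in exposure_sets if s in set(ds.table["snp_id"])
        )
        row = carrier.table.loc[carrier.table["snp_id"] == s].iloc[0].copy()
        row["pvalue"] = min(
            float(ds.table.loc[ds.table["snp_id"] == s, "pvalue"].iloc[0])
            for ds in exposure_sets
            if s in set(ds.table["snp_id"])
        )
        rows.append(row)
    union_ds = SummaryDataset(
        "mvmr_union", first.trait_type, pd.DataFrame(rows).reset_index(drop=True)
    )
    clumped = ld_clump(union_ds, ld, clump_r2, clump_window_kb)
    ids = clumped.table["snp_id"].tolist()

    # pairwise-harmonize every dataset against exposure 1's alleles
    ref = exposure_sets[0].subset([s for s in ids if s in set(exposure_sets[0].snp_ids)])
    usable = set(ref.table["snp_id"])
    dropped = {s: "missing_in_first_exposure" for s in ids if s not in usable}

    aligned: dict[str, HarmonizedSet] = {}
    for ds in exposure_sets[1:] + [outcome]:
        try:
            hz = harmonize(ref, ds, palindrome_band=palindrome_band)
        except HarmonizationError as exc:
            raise HarmonizationError(f"MVMR alignment failed for {ds.trait_name!r}: {exc}")
        aligned[ds.trait_name] = hz
        keep = set(hz.snp_ids)
        for s in list(usable):
            if s not in keep:
                usable.discard(s)
                dropped.setdefault(s, f"dropped_aligning_{ds.trait_name}")

    final_ids = [s for s in ids if s in usable]
    if dropped:
        logger.info("MVMR assembly dropped %d SNP(s): %s", len(dropped),
                    pd.Series(list(dropped.values())).value_counts().to_dict())
    if len(final_ids) <= k:
        raise InsufficientSnpsError(
            f"MVMR needs J > K: J={len(final_ids)}, K={k}"
        )

    ref_tab = ref.table.set_index("snp_id")
    betas = np.empty((len(final_ids), k))
    ses = np.empty((len(final_ids), k))
    betas[:, 0] = ref_tab.loc[final_ids, "beta"].to_numpy(float)
    ses[:, 0] = ref_tab.loc[final_ids, "se"].to_numpy(float)
    for col, ds in enumerate(exposure_sets[1:], start=1):
        hz = aligned[ds.trait_name]
        idx = {s: i for i, s in enumerate(hz.snp_ids)}
        rows_i = [idx[s] for s in final_ids]
        betas[:, col] = hz.Gamma[rows_i]
        ses[:, col] = hz.se_Gamma[rows_i]
    hz_out = aligned[outcome.trait_name]
    idx = {s: i for i, s in enumerate(hz_out.snp_ids)}
    rows_i = [idx[s] for s in final_ids]

    return MvmrInput(
        snp_ids=np.asarray(final_ids),
        exposure_names=[ds.trait_name for ds in exposure_sets],
        exposure_betas=betas,
        exposure_ses=ses,
        Gamma=hz_out.Gamma[rows_i],
        se_Gamma=hz_out.se_Gamma[rows_i],
    )


def _mv_fit(inp: MvmrInput, intercept: bool) -> MvmrResult:
    j, k = inp.n_snps, inp.n_exposures
    X = inp.exposure_betas
    Gamma = inp.Gamma
    if intercept:
        if j <= k + 1:
            raise InsufficientSnpsError(f"mv_egger needs J > K+1: J={j}, K={k}")
        sign = np.where(X[:, 0] < 0, -1.0, 1.0)
        X = X * sign[:, None]
        Gamma = Gamma * sign
        X = np.column_stack([np.ones(j), X])
        df = j - k - 1
    else:
        if j <= k:
            raise InsufficientSnpsError(f"mv_ivw needs J > K: J={j}, K={k}")
        df = j - k
    w = 1.0 / inp.se_Gamma**2
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise InsufficientSnpsError("collinear exposures")
    coef, cov_u, rss = _wls(X, Gamma, w)
    scale2 = max(1.0, rss / df)
    ses = np.sqrt(np.diag(cov_u) * scale2)

    q = rss
    q_p = float(min(max(stats.chi2.sf(q, df), np.finfo(float).tiny), 1.0))

    if intercept:
        icpt, icpt_se = float(coef[0]), float(ses[0])
        beta, se = coef[1:], ses[1:]
        crit = float(stats.t.ppf(0.975, df))
        pvals = 2.0 * stats.t.sf(np.abs(beta) / se, df)
        icpt_p = float(max(2.0 * stats.t.sf(abs(icpt) / icpt_se, df), _TINY_P))
        method = "mv_egger"
    else:
        beta, se = coef, ses
        crit = 1.96
        pvals = 2.0 * stats.norm.sf(np.abs(beta) / se)
        icpt = icpt_se = icpt_p = None
        method = "mv_ivw"

    return MvmrResult(
        method=method,
        exposures=list(inp.exposure_names),
        beta=beta,
        se=se,
        ci_low=beta - crit * se,
        ci_high=beta + crit * se,
        pvalue=np.maximum(pvals, _TINY_P),
        n_snps=j,
        q=float(q),
        q_df=df,
        q_pvalue=q_p,
        intercept=icpt,
        intercept_se=icpt_se,
        intercept_p=icpt_p,
    )


def mv_ivw(inp: MvmrInput) -> MvmrResult:
    """Multivariable IVW: zero-intercept WLS of Gamma on the exposure matrix."""
    return _mv_fit(inp, intercept=False)


def mv_egger(inp: MvmrInput) -> MvmrResult:
    """Multivariable Egger: as MV-IVW but with an intercept, SNPs oriented
    so the first exposure's beta is non-negative; t(J-K-1) inference."""
    return _mv_fit(inp, intercept=True)


def mediate(
    total: float,
    exposure_mediator: float,
    mediator_outcome_adjusted: float,
    se_total: float = 0.0,
    se_exposure_mediator: float = 0.0,
    se_mediator_outcome: float = 0.0,
) -> MediationResult:
    """Product-of-coefficients mediation decomposition.

    indirect = exposure_mediator * mediator_outcome_adjusted;
    direct = total - indirect; proportion = 100 * indirect / total.
    Delta-method SEs treat the three inputs as independent (they come from
    non-overlapping regressions). A sign warning is raised when the
    indirect and total effects disagree in sign, in which case the
    proportion is not interpretable as a percentage of the effect.
    """
    if total == 0:
        raise ValueError("total effect must be non-zero")
    if min(se_total, se_exposure_mediator, se_mediator_outcome) < 0:
        raise ValueError("standard errors must be non-negative")
    bxz, bzy = exposure_mediator, mediator_outcome_adjusted
    indirect = bxz * bzy
    direct = total - indirect
    proportion = 100.0 * indirect / total
    ind_var = bxz**2 * se_mediator_outcome**2 + bzy**2 * se_exposure_mediator**2
    ind_se = float(np.sqrt(ind_var))
    # delta method on R = 100*I/T with I, T independent
    if indirect**2 > 0:
        rel = ind_var / indirect**2 + se_total**2 / total**2
        prop_se = abs(proportion) * float(np.sqrt(rel))
    else:
        prop_se = 100.0 * ind_se / abs(total)
    return MediationResult(
        total=total,
        exposure_mediator=bxz,
        mediator_outcome_adjusted=bzy,
        indirect=indirect,
        direct=direct,
        proportion=proportion,
        indirect_se=ind_se,
        proportion_se=prop_se,
        proportion_ci=(proportion - 1.96 * prop_se, proportion + 1.96 * prop_se),
        sign_warning=bool(indirect * total < 0),
    )
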