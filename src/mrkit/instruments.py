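"""Instrument selection, LD clumping, allele harmonization, and strength.

Selection keeps SNPs below a genome-wide threshold (default 5e-8), relaxing
to a secondary threshold (default 5e-6) when too few survive. Clumping is
the greedy thin-by-p-value algorithm: a candidate is discarded only when it
is BOTH in LD (r² >= threshold) with an already-accepted SNP AND within the
physical window of it on the same chromosome. Harmonization aligns outcome
effects to the exposure effect allele, resolving strand flips and removing
palindromic SNPs whose allele frequency is too close to 0.5 to call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import HarmonizationError, InsufficientSnpsError, NoInstrumentsError
from .gwas_io import LdMatrix, SummaryDataset

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Default thresholds used across the pipeline.
DEFAULTS = {
    "p_threshold": 5e-8,
    "relaxed_p_threshold": 5e-6,
    "min_instruments": 3,
    "clump_r2": 0.001,
    "clump_window_kb": 10_000,
    "palindrome_band": 0.08,
    "freq_source": "exposure",
    "weak_f_cutoff": 10.0,
}


@dataclass
class HarmonizedSet:
    """Exposure/outcome effects aligned to a common effect allele per SNP.

    ``gamma``/``se_gamma`` are the exposure associations, ``Gamma``/
    ``se_Gamma`` the outcome associations on the exposure's effect allele.
    ``provenance`` records kept/flipped/strand decisions per surviving SNP;
    ``removed`` records every dropped SNP with its reason.
    """

    snp_ids: np.ndarray
    gamma: np.ndarray
    se_gamma: np.ndarray
    Gamma: np.ndarray
    se_Gamma: np.ndarray
    eaf: np.ndarray
    effect_allele: np.ndarray = None
    other_allele: np.ndarray = None
    provenance: pd.DataFrame = None
    removed: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["snp_id", "reason"]))

    def __post_init__(self) -> None:
        for name in ("snp_ids", "gamma", "se_gamma", "Gamma", "se_Gamma", "eaf"):
            setattr(self, name, np.asarray(getattr(self, name)))
        j = len(self.snp_ids)
        if j < 1:
            raise HarmonizationError("harmonized set is empty")
        for name in ("gamma", "se_gamma", "Gamma", "se_Gamma", "eaf"):
            if len(getattr(self, name)) != j:
                raise HarmonizationError(f"array length mismatch in {name}")
        if (self.se_gamma <= 0).any() or (self.se_Gamma <= 0).any():
            raise HarmonizationError("non-positive standard errors")
        if self.provenance is None:
            self.provenance = pd.DataFrame({"snp_id": self.snp_ids, "action": "kept"})

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def subset(self, mask: np.ndarray) -> "HarmonizedSet":
        mask = np.asarray(mask, dtype=bool)
        return HarmonizedSet(
            snp_ids=self.snp_ids[mask],
            gamma=self.gamma[mask],
            se_gamma=self.se_gamma[mask],
            Gamma=self.Gamma[mask],
            se_Gamma=self.se_Gamma[mask],
            eaf=self.eaf[mask],
            effect_allele=None if self.effect_allele is None else np.asarray(self.effect_allele)[mask],
            other_allele=None if self.other_allele is None else np.asarray(self.other_allele)[mask],
            provenance=self.provenance[self.provenance["snp_id"].isin(self.snp_ids[mask])].reset_index(drop=True),
            removed=self.removed,
        )


@dataclass
class InstrumentStats:
    """Per-SNP instrument strength: F = (gamma/se_gamma)^2."""

    f_stat: np.ndarray
    mean_f: float
    weak_flags: np.ndarray  # F < cutoff


def select_by_pvalue(
    dataset: SummaryDataset,
    threshold: float = DEFAULTS["p_threshold"],
    relaxed_threshold: float = DEFAULTS["relaxed_p_threshold"],
    min_instruments: int = DEFAULTS["min_instruments"],
) -> SummaryDataset:
    """Keep SNPs with p < threshold, relaxing when too few survive.

    The threshold actually applied is recorded in ``meta["p_threshold_used"]``
    together with ``meta["threshold_relaxed"]``.
    """
    if not (0 < threshold <= relaxed_threshold < 1):
        raise ValueError("need 0 < threshold <= relaxed_threshold < 1")
    strict = dataset.table["pvalue"] < threshold
    used, relaxed = threshold, False
    keep = strict
    if int(strict.sum()) < min_instruments:
        keep = dataset.table["pvalue"] < relaxed_threshold
        used, relaxed = relaxed_threshold, True
        logger.info(
            "%s: %d SNP(s) at p<%g, relaxing to p<%g (%d SNPs)",
            dataset.trait_name, int(strict.sum()), threshold, relaxed_threshold, int(keep.sum()),
        )
    if int(keep.sum()) == 0:
        raise NoInstrumentsError(
            f"no instruments for {dataset.trait_name!r} even at p < {relaxed_threshold:g}"
        )
    out = SummaryDataset(
        dataset.trait_name,
        dataset.trait_type,
        dataset.table.loc[keep].reset_index(drop=True),
        dict(dataset.meta),
    )
    out.meta["p_threshold_used"] = used
    out.meta["threshold_relaxed"] = relaxed
    return out


def ld_clump(
    dataset: SummaryDataset,
    ld: LdMatrix | None = None,
    r2_max: float = DEFAULTS["clump_r2"],
    window_kb: float = DEFAULTS["clump_window_kb"],
) -> SummaryDataset:
    """Greedy p-value-ordered clumping.

    A remaining SNP is discarded when, relative to some accepted SNP, it is
    on the same chromosome, within ``window_kb``, AND has r² >= ``r2_max``.
    Without an LD matrix the r² condition is assumed true inside the window
    (distance-only clumping) and a warning is logged. Ties in p are broken
    by snp_id for determinism.
    """
    tab = dataset.table
    if ld is not None:
        missing = [s for s in tab["snp_id"] if s not in ld]
        if missing:
            raise NoInstrumentsError(f"SNP(s) missing from LD matrix: {missing[:5]}")
    else:
        logger.warning("%s: no LD matrix; falling back to distance-only clumping", dataset.trait_name)

    order = tab.sort_values(["pvalue", "snp_id"], kind="mergesort").index.tolist()
    window_bp = window_kb * 1000.0
    accepted: list[int] = []
    for i in order:
        si, ci, pi = tab.at[i, "snp_id"], tab.at[i, "chrom"], tab.at[i, "pos"]
        conflict = False
        for a in accepted:
            if tab.at[a, "chrom"] != ci:
                continue
            if abs(tab.at[a, "pos"] - pi) > window_bp:
                continue
            if ld is None or ld.lookup(si, tab.at[a, "snp_id"]) >= r2_max:
                conflict = True
                break
        if not conflict:
            accepted.append(i)

    keep = tab.index.isin(accepted)
    out = SummaryDataset(
        dataset.trait_name, dataset.trait_type, tab.loc[keep].reset_index(drop=True),
        dict(dataset.meta),
    )
    out.meta["n_clumped_out"] = int(len(tab) - len(out))
    return out


def _is_palindromic(ea: str, oa: str) -> bool:
    return _COMPLEMENT[ea] == oa


def harmonize(
    exposure: SummaryDataset,
    outcome: SummaryDataset,
    palindrome_band: float = DEFAULTS["palindrome_band"],
    freq_source: str = DEFAULTS["freq_source"],
) -> HarmonizedSet:
    """Align outcome effects to the exposure effect allele per shared SNP.

    Resolution per SNP: exact allele match is kept; an effect/other swap
    flips the sign of the outcome beta; a strand complement is applied first
    when needed. Palindromic (A/T, C/G) SNPs whose governing allele
    frequency falls in ``0.5 +/- palindrome_band`` — or is missing — are
    removed, as are irreconcilable allele pairs. Every removal is logged
    with its reason.
    """
    if freq_source not in ("exposure", "outcome"):
        raise ValueError("freq_source must be 'exposure' or 'outcome'")
    exp = exposure.table.set_index("snp_id", drop=False)
    out = outcome.table.set_index("snp_id", drop=False)
    shared = [s for s in exposure.table["snp_id"] if s in out.index]
    if not shared:
        raise HarmonizationError(
            f"no shared SNPs between {exposure.trait_name!r} and {outcome.trait_name!r}"
        )

    kept_rows = []
    removed = []
    for s in shared:
        e, o = exp.loc[s], out.loc[s]
        ea, oa = e["effect_allele"], e["other_allele"]
        o_ea, o_oa = o["effect_allele"], o["other_allele"]
        palindromic = _is_palindromic(ea, oa)
        action = None
        flip = False

        if (o_ea, o_oa) == (ea, oa):
            action = "kept"
        elif (o_ea, o_oa) == (oa, ea):
            action, flip = "flipped", True
        elif not palindromic:
            c_ea, c_oa = _COMPLEMENT[o_ea], _COMPLEMENT[o_oa]
            if (c_ea, c_oa) == (ea, oa):
                action = "strand"
            elif (c_ea, c_oa) == (oa, ea):
                action, flip = "strand+flipped", True

        if action is None:
            removed.append((s, "allele_mismatch"))
            continue

        if palindromic:
            gov = e["eaf"] if freq_source == "exposure" else o["eaf"]
            if pd.isna(gov):
                removed.append((s, "palindromic_missing_eaf"))
                continue
            if abs(gov - 0.5) <= palindrome_band:
                removed.append((s, "palindromic_intermediate_eaf"))
                continue

        g_beta = -o["beta"] if flip else o["beta"]
        if freq_source == "exposure":
            aligned_eaf = e["eaf"]
        else:
            aligned_eaf = (1.0 - o["eaf"]) if flip else o["eaf"]
        kept_rows.append(
            (s, e["beta"], e["se"], g_beta, o["se"], aligned_eaf, ea, oa, action)
        )

    if not kept_rows:
        raise HarmonizationError("harmonization removed every shared SNP")

    frame = pd.DataFrame(
        kept_rows,
        columns=["snp_id", "gamma", "se_gamma", "Gamma", "se_Gamma", "eaf", "ea", "oa", "action"],
    )
    removed_df = pd.DataFrame(removed, columns=["snp_id", "reason"])
    n_removed = len(removed_df)
    if n_removed:
        logger.info(
            "harmonize %s~%s: removed %d of %d shared SNP(s): %s",
            exposure.trait_name, outcome.trait_name, n_removed, len(shared),
            removed_df["reason"].value_counts().to_dict(),
        )
    return HarmonizedSet(
        snp_ids=frame["snp_id"].to_numpy(),
        gamma=frame["gamma"].to_numpy(float),
        se_gamma=frame["se_gamma"].to_numpy(float),
        Gamma=frame["Gamma"].to_numpy(float),
        se_Gamma=frame["se_Gamma"].to_numpy(float),
        eaf=frame["eaf"].to_numpy(float),
        effect_allele=frame["ea"].to_numpy(),
        other_allele=frame["oa"].to_numpy(),
        provenance=frame[["snp_id", "action"]].copy(),
        removed=removed_df,
    )


def f_statistics(h: HarmonizedSet, weak_cutoff: float = DEFAULTS["weak_f_cutoff"]) -> InstrumentStats:
    """Per-SNP F statistics, F_j = (gamma_j / se_gamma_j)^2.

    Instruments with F below ``weak_cutoff`` (default 10) are flagged weak;
    whether they are removed is pipeline policy, not decided here.
    """
    if h.n_snps < 1:
        raise InsufficientSnpsError("need at least one SNP")
    f = (h.gamma / h.se_gamma) ** 2
    return InstrumentStats(f_stat=f, mean_f=float(np.mean(f)), weak_flags=f < weak_cutoff)
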