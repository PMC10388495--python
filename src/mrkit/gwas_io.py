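"""Read, validate, and write GWAS summary statistics and LD matrices.

All on-disk formats are plain delimited text: summary-statistics tables with
a header row, LD matrices as labelled square tables. Column naming in input
files is decoupled from the internal schema through an explicit column map
(default dialect: ``snp, chr, pos, ea, oa, eaf, beta, se, p, n``), because
GWAS summary formats vary and silent mis-mapping is the dominant failure
mode.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")

#: Default input dialect -> internal column names.
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "snp": "snp_id",
    "chr": "chrom",
    "pos": "pos",
    "ea": "effect_allele",
    "oa": "other_allele",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "p": "pvalue",
    "n": "n",
}

#: Internal schema, in canonical order.
SCHEMA = [
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "n",
]

_MANDATORY = ["snp_id", "chrom", "pos", "effect_allele", "other_allele", "beta", "se", "pvalue"]


@dataclass(frozen=True)
class SnpRecord:
    """One GWAS summary association.

    ``beta`` is the per-allele effect of ``effect_allele`` on the trait
    (log-odds for binary traits); ``eaf`` and ``n`` may be missing (NaN/None).
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pvalue: float
    n: float


@dataclass
class SummaryDataset:
    """A named collection of summary associations for a single trait.

    Backed by a :class:`pandas.DataFrame` in the internal :data:`SCHEMA`;
    record order is the load order and is never silently changed.
    """

    trait_name: str
    trait_type: str  # "quantitative" | "binary"
    table: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.trait_type not in ("quantitative", "binary"):
            raise ConfigError(f"unknown trait_type {self.trait_type!r}")
        missing = [c for c in SCHEMA if c not in self.table.columns]
        if missing:
            raise ConfigError(f"summary table missing columns: {missing}")
        if len(self.table) == 0:
            raise ConfigError(f"dataset {self.trait_name!r} is empty")
        if self.table["snp_id"].duplicated().any():
            dups = self.table.loc[self.table["snp_id"].duplicated(), "snp_id"].tolist()
            raise ConfigError(f"duplicate snp_id values: {dups[:5]}")
        if (self.table["se"] <= 0).any():
            raise ConfigError("non-positive standard errors present")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def snp_ids(self) -> list[str]:
        return self.table["snp_id"].tolist()

    def records(self) -> Iterator[SnpRecord]:
        for row in self.table.itertuples(index=False):
            yield SnpRecord(
                snp_id=row.snp_id,
                chrom=str(row.chrom),
                pos=int(row.pos),
                effect_allele=row.effect_allele,
                other_allele=row.other_allele,
                eaf=row.eaf,
                beta=row.beta,
                se=row.se,
                pvalue=row.pvalue,
                n=row.n,
            )

    def subset(self, snp_ids: Sequence[str]) -> "SummaryDataset":
        """Rows for ``snp_ids``, preserving this dataset's order."""
        keep = self.table["snp_id"].isin(set(snp_ids))
        return SummaryDataset(
            self.trait_name, self.trait_type, self.table.loc[keep].reset_index(drop=True),
            dict(self.meta),
        )


@dataclass
class LdMatrix:
    """Pairwise squared-correlation (r²) matrix over named SNPs."""

    snp_ids: list[str]
    r2: np.ndarray
    positions: dict[str, int] | None = None

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        k = len(self.snp_ids)
        if self.r2.shape != (k, k):
            raise ConfigError("LD matrix shape does not match SNP label count")
        if not np.allclose(self.r2, self.r2.T, atol=0, rtol=0):
            raise ConfigError("LD matrix is not symmetric")
        if (self.r2 < 0).any() or (self.r2 > 1).any():
            raise ConfigError("LD r² entries outside [0, 1]")
        if not np.all(np.diag(self.r2) == 1.0):
            raise ConfigError("LD matrix diagonal must be exactly 1")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def lookup(self, a: str, b: str) -> float:
        return float(self.r2[self._index[a], self._index[b]])

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index


def read_summary(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait_type: str = "quantitative",
    trait_name: str | None = None,
    zp_tolerance: float = 0.05,
) -> SummaryDataset:
    """Load a delimited summary-statistics table.

    Parameters
    ----------
    path
        Tab- or comma-delimited text file with a header row.
    column_map
        Mapping from input column names to the default dialect keys
        (``snp, chr, pos, ea, oa, eaf, beta, se, p, n``). ``None`` means the
        file already uses the default dialect.
    trait_type
        ``"quantitative"`` or ``"binary"`` (betas on the log-odds scale).
    zp_tolerance
        Warn when ``|p - 2*Phi(-|beta/se|)|`` exceeds this for any row;
        published summaries are rounded, so this never fails the load.

    Rows with unparseable ``beta``/``se``, non-positive ``se``, p-values
    outside (0, 1], or invalid alleles are dropped with a logged count.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"summary file not found: {path}")
    try:
        raw = pd.read_csv(path, sep=None, engine="python", dtype=str)
    except (pd.errors.EmptyDataError, csv.Error):
        raise ConfigError(f"summary file is empty or undelimited: {path}") from None
    if len(raw) == 0:
        raise ConfigError(f"summary file has no data rows: {path}")

    dialect = dict(DEFAULT_COLUMN_MAP)
    if column_map is not None:
        rename = {src: dialect[key] for key, src in column_map.items() if key in dialect}
    else:
        rename = {k: v for k, v in dialect.items() if k in raw.columns}
    df = raw.rename(columns=rename)

    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise ConfigError(f"missing mandatory column(s) {missing} in {path}")
    for opt in ("eaf", "n"):
        if opt not in df.columns:
            df[opt] = np.nan

    df = df[SCHEMA].copy()
    for col in ("pos", "eaf", "beta", "se", "pvalue", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["snp_id"] = df["snp_id"].astype(str)
    df["chrom"] = df["chrom"].astype(str)
    df["effect_allele"] = df["effect_allele"].str.upper()
    df["other_allele"] = df["other_allele"].str.upper()

    n_in = len(df)
    ok = (
        df["beta"].notna()
        & df["se"].notna()
        & (df["se"] > 0)
        & df["pvalue"].notna()
        & (df["pvalue"] > 0)
        & (df["pvalue"] <= 1)
        & df["pos"].notna()
        & df["effect_allele"].isin(VALID_ALLELES)
        & df["other_allele"].isin(VALID_ALLELES)
        & (df["effect_allele"] != df["other_allele"])
    )
    # eaf outside (0,1) is treated as missing, not a row-dropping offence
    bad_eaf = df["eaf"].notna() & ((df["eaf"] <= 0) | (df["eaf"] >= 1))
    df.loc[bad_eaf, "eaf"] = np.nan
    df = df.loc[ok].reset_index(drop=True)
    dropped = n_in - len(df)
    if dropped:
        logger.warning("%s: dropped %d invalid row(s) of %d", path.name, dropped, n_in)
    if len(df) == 0:
        raise ConfigError(f"no valid rows after validation in {path}")

    if df["snp_id"].duplicated().any():
        n_dup = int(df["snp_id"].duplicated().sum())
        logger.warning("%s: dropped %d duplicate snp_id row(s), keeping first", path.name, n_dup)
        df = df.drop_duplicates("snp_id", keep="first").reset_index(drop=True)

    z = np.abs(df["beta"] / df["se"])
    p_implied = 2 * stats.norm.sf(z)
    n_bad = int((np.abs(df["pvalue"] - p_implied) > zp_tolerance).sum())
    if n_bad:
        logger.warning(
            "%s: %d row(s) where pvalue disagrees with beta/se beyond %.3g",
            path.name, n_bad, zp_tolerance,
        )

    ds = SummaryDataset(trait_name or path.stem, trait_type, df)
    ds.meta["source_path"] = str(path)
    ds.meta["n_dropped_at_load"] = dropped
    return ds


def write_summary(dataset: SummaryDataset, path: str | Path, sep: str = "\t") -> None:
    """Write a dataset back out in the default dialect (round-trip stable)."""
    inv = {v: k for k, v in DEFAULT_COLUMN_MAP.items()}
    out = dataset.table.rename(columns=inv)
    out.to_csv(path, sep=sep, index=False, float_format="%.12g")


def format_or_ci(or_: float, low: float, high: float, ndigits: int = 3) -> str:
    """Render an odds ratio with its CI, e.g. ``0.703 (0.508, 0.973)``."""
    fmt = f"%.{ndigits}f"
    return f"{fmt % or_} ({fmt % low}, {fmt % high})"


def _to_frame(results) -> pd.DataFrame:
    if isinstance(results, pd.DataFrame):
        if len(results) == 0:
            raise ConfigError("write_results: empty result collection")
        return results.copy()
    rows = list(results)
    if not rows:
        raise ConfigError("write_results: empty result collection")
    recs = []
    for r in rows:
        if dataclasses.is_dataclass(r):
            d = dataclasses.asdict(r)
        elif isinstance(r, Mapping):
            d = dict(r)
        else:
            raise ConfigError(f"write_results: unsupported result type {type(r)!r}")
        extras = d.pop("extras", None)
        if isinstance(extras, Mapping):
            d.update({f"extra_{k}": v for k, v in extras.items()})
        recs.append(d)
    return pd.DataFrame(recs)


def write_results(results, path: str | Path, sep: str = "\t") -> pd.DataFrame:
    """Write a results collection as a delimited table plus a JSON dump.

    The table goes to ``path``; a machine-readable copy goes to
    ``path + ".json"``. If the rows carry ``or_``/``or_low``/``or_high``
    columns an ``or_ci`` display column is added. Returns the frame written.
    """
    df = _to_frame(results)
    if {"or_", "or_low", "or_high"}.issubset(df.columns):
        df["or_ci"] = [
            format_or_ci(o, lo, hi)
            for o, lo, hi in zip(df["or_"], df["or_low"], df["or_high"])
        ]
    path = Path(path)
    try:
        df.to_csv(path, sep=sep, index=False, float_format="%.12g")
        with open(str(path) + ".json", "w") as fh:
            json.dump(
                json.loads(df.to_json(orient="records")),
                fh, indent=2, sort_keys=True, allow_nan=True,
            )
    except OSError as exc:
        raise ConfigError(f"cannot write results to {path}: {exc}") from exc
    return df


def read_results(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    """Read back a table written by :func:`write_results`."""
    return pd.read_csv(path, sep=sep)


def read_ld_matrix(path: str | Path, asymmetry_tol: float = 1e-6) -> LdMatrix:
    """Load a labelled square r² table.

    Asymmetries up to ``asymmetry_tol`` are repaired by averaging; larger
    ones are a hard error, as are non-square tables and entries outside
    [0, 1].
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"LD matrix file not found: {path}")
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    if df.shape[0] != df.shape[1]:
        raise ConfigError(f"LD matrix is not square: {df.shape}")
    labels = [str(x) for x in df.index]
    if [str(c) for c in df.columns] != labels:
        raise ConfigError("LD matrix row and column labels disagree")
    m = df.to_numpy(dtype=float)
    if np.isnan(m).any():
        raise ConfigError("LD matrix contains non-numeric entries")
    if (m < -1e-12).any() or (m > 1 + 1e-12).any():
        raise ConfigError("LD r² entries outside [0, 1]")
    asym = np.abs(m - m.T).max()
    if asym > asymmetry_tol:
        raise ConfigError(f"LD matrix asymmetric beyond tolerance ({asym:.3g})")
    m = (m + m.T) / 2.0
    np.fill_diagonal(m, 1.0)
    m = np.clip(m, 0.0, 1.0)
    return LdMatrix(labels, m)


def write_ld_matrix(ld: LdMatrix, path: str | Path, sep: str = "\t") -> None:
    pd.DataFrame(ld.r2, index=ld.snp_ids, columns=ld.snp_ids).to_csv(
        path, sep=sep, float_format="%.12g"
    )
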