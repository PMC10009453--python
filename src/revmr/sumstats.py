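"""GWAS summary-statistic tables: reading, writing, instrument selection.

The on-disk dialect is the flat file used by common two-sample MR tooling:
a header row followed by tab- (or comma-) separated columns

    SNP  effect_allele  other_allele  eaf  beta  se  pval  n

``beta`` is the per-allele association — log-odds units for a binary
disease trait, SD units for a continuous metabolic trait.  ``eaf`` (effect
allele frequency) and ``n`` may be missing.  Rows violating basic sanity
constraints (se <= 0, p outside (0, 1], identical alleles, eaf outside
(0, 1)) are dropped at read time and tallied, never silently kept.

Instrument selection follows standard MR practice: retain genome-wide
significant variants (strictly ``p < 5e-8``), then greedily clump by LD so
that no retained pair has squared correlation above ``r2 > 0.001``, keeping
the variant with the smallest p-value in each correlated set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import EmptyInputError, FormatError, MatrixError, MissingLdError

logger = logging.getLogger(__name__)

#: canonical column order of the summary-statistics dialect
COLUMNS = ["rsid", "effect_allele", "other_allele", "eaf", "beta", "se", "pval", "n"]

#: default header-name mapping from common upstream spellings
DEFAULT_COLUMN_MAP = {
    "SNP": "rsid",
    "snp": "rsid",
    "rsid": "rsid",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pval": "pval",
    "p": "pval",
    "n": "n",
}

VALID_BASES = frozenset("ACGT")

GENOME_WIDE_P = 5e-8
CLUMP_R2 = 0.001


@dataclass(frozen=True)
class SnpAssociation:
    """One variant's summary association with one trait."""

    rsid: str
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    pval: float
    n: int | None = None

    def is_valid(self) -> bool:
        return _row_valid(
            self.effect_allele, self.other_allele, self.eaf, self.se, self.pval
        )


def _row_valid(ea, oa, eaf, se, pval) -> bool:
    if not (isinstance(ea, str) and isinstance(oa, str)):
        return False
    if ea not in VALID_BASES or oa not in VALID_BASES or ea == oa:
        return False
    if not np.isfinite(se) or se <= 0:
        return False
    if not np.isfinite(pval) or not (0 < pval <= 1):
        return False
    if eaf is not None and not np.isnan(eaf) and not (0 < eaf < 1):
        return False
    return True


@dataclass
class SummaryStats:
    """A named table of per-variant summary associations.

    ``df`` holds one row per variant with the canonical :data:`COLUMNS`.
    ``n_dropped`` counts rows discarded at construction for violating the
    row invariants.  rsids are unique within a table.
    """

    trait_name: str
    trait_type: str  # "binary_disease" | "continuous"
    df: pd.DataFrame
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if self.trait_type not in ("binary_disease", "continuous"):
            raise FormatError(f"unknown trait_type {self.trait_type!r}")
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise FormatError(f"summary table missing columns {missing}")
        if self.df["rsid"].duplicated().any():
            dups = self.df.loc[self.df["rsid"].duplicated(), "rsid"].tolist()
            raise FormatError(f"duplicate rsids in table: {dups[:5]}")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def rsids(self) -> list[str]:
        return self.df["rsid"].tolist()

    def rows(self) -> Iterable[SnpAssociation]:
        for t in self.df.itertuples(index=False):
            eaf = None if pd.isna(t.eaf) else float(t.eaf)
            n = None if pd.isna(t.n) else int(t.n)
            yield SnpAssociation(
                t.rsid, t.effect_allele, t.other_allele, eaf,
                float(t.beta), float(t.se), float(t.pval), n,
            )

    def subset(self, rsids: Sequence[str]) -> "SummaryStats":
        keep = self.df[self.df["rsid"].isin(set(rsids))]
        return replace(self, df=keep.reset_index(drop=True), n_dropped=0)


@dataclass
class LdMatrix:
    """Pairwise squared-correlation matrix over an ordered set of variants."""

    rsids: list[str]
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        k = len(self.rsids)
        if self.r2.shape != (k, k):
            raise MatrixError(f"LD matrix shape {self.r2.shape} != ({k}, {k})")
        if not np.allclose(self.r2, self.r2.T, atol=1e-8):
            raise MatrixError("LD matrix is not symmetric")
        if not np.allclose(np.diag(self.r2), 1.0, atol=1e-8):
            raise MatrixError("LD matrix diagonal must be 1")
        if self.r2.min() < -1e-12 or self.r2.max() > 1 + 1e-8:
            raise MatrixError("LD r2 entries must lie in [0, 1]")
        self._index = {rs: i for i, rs in enumerate(self.rsids)}

    def value(self, a: str, b: str) -> float:
        try:
            return float(self.r2[self._index[a], self._index[b]])
        except KeyError as exc:
            raise MissingLdError(f"rsid {exc.args[0]!r} absent from LD matrix") from None


def _clean_frame(df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Enforce row invariants; return (valid rows, dropped count)."""
    df = df.copy()
    df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
    df["other_allele"] = df["other_allele"].astype(str).str.upper()
    for col in ("eaf", "beta", "se", "pval", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    ok = (
        df["effect_allele"].isin(list(VALID_BASES))
        & df["other_allele"].isin(list(VALID_BASES))
        & (df["effect_allele"] != df["other_allele"])
        & np.isfinite(df["beta"])
        & (df["se"] > 0)
        & (df["pval"] > 0)
        & (df["pval"] <= 1)
        & (df["eaf"].isna() | ((df["eaf"] > 0) & (df["eaf"] < 1)))
    )
    dropped = int((~ok).sum())
    return df.loc[ok, COLUMNS].reset_index(drop=True), dropped


def read_sumstats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait_type: str = "continuous",
    trait_name: str | None = None,
    sep: str | None = None,
) -> SummaryStats:
    """Read a summary-statistics flat file.

    ``column_map`` maps file header names onto the canonical names; headers
    already matching common spellings need no map.  Invalid rows are dropped
    and counted in the returned table's ``n_dropped``.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=sep if sep is not None else r"\t|,", engine="python")
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    rename = {src: dst for src, dst in cmap.items() if src in df.columns}
    df = df.rename(columns=rename)
    missing = [c for c in COLUMNS if c not in df.columns and c not in ("eaf", "n")]
    if missing:
        raise FormatError(f"{path.name}: missing mapped column(s) {missing}")
    for optional in ("eaf", "n"):
        if optional not in df.columns:
            df[optional] = np.nan
    clean, dropped = _clean_frame(df)
    if dropped:
        logger.info("%s: dropped %d invalid row(s)", path.name, dropped)
    if clean.empty:
        raise EmptyInputError(f"{path.name}: no valid summary-statistic rows")
    return SummaryStats(
        trait_name=trait_name or path.stem,
        trait_type=trait_type,
        df=clean,
        n_dropped=dropped,
    )


def write_sumstats(table: SummaryStats, path: str | Path) -> None:
    """Write a table in the canonical tab-separated dialect."""
    out = table.df[COLUMNS].rename(columns={"rsid": "SNP"})
    out.to_csv(path, sep="\t", index=False)


def read_ld_matrix(path: str | Path) -> LdMatrix:
    """Read a square tab-separated LD matrix with rsid header row/column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise FormatError("LD matrix row and column rsids disagree")
    return LdMatrix(rsids=list(df.index), r2=df.to_numpy(dtype=float))


def write_ld_matrix(ld: LdMatrix, path: str | Path) -> None:
    pd.DataFrame(ld.r2, index=ld.rsids, columns=ld.rsids).to_csv(path, sep="\t")


def select_instruments(t: SummaryStats, p_threshold: float = GENOME_WIDE_P) -> SummaryStats:
    """Retain variants with p strictly below the significance threshold."""
    if not (0 < p_threshold < 1) and p_threshold != 1.0:
        raise ValueError("p_threshold must be in (0, 1]")
    keep = t.df[t.df["pval"] < p_threshold]
    return replace(t, df=keep.reset_index(drop=True), n_dropped=0)


def ld_prune(t: SummaryStats, ld: LdMatrix, r2_threshold: float = CLUMP_R2) -> SummaryStats:
    """Greedy p-value-ordered LD clumping.

    Repeatedly retain the remaining variant with the smallest p-value
    (ties broken by rsid) and discard every remaining variant correlated
    with it at r2 strictly above the threshold.  The returned set is
    mutually independent at the threshold.
    """
    if not (0 <= r2_threshold < 1):
        raise ValueError("r2_threshold must be in [0, 1)")
    missing = [rs for rs in t.rsids if rs not in ld._index]
    if missing:
        raise MissingLdError(f"rsid {missing[0]!r} absent from LD matrix")
    order = t.df.sort_values(["pval", "rsid"], kind="mergesort")
    idx = np.array([ld._index[rs] for rs in order["rsid"]])
    sub = ld.r2[np.ix_(idx, idx)]
    alive = np.ones(len(idx), dtype=bool)
    kept_positions: list[int] = []
    for i in range(len(idx)):
        if not alive[i]:
            continue
        kept_positions.append(i)
        alive &= ~(sub[i] > r2_threshold)
        alive[i] = False
    kept_rsids = set(order.iloc[kept_positions]["rsid"])
    keep = t.df[t.df["rsid"].isin(kept_rsids)]
    return replace(t, df=keep.reset_index(drop=True), n_dropped=0)


def mean_f_statistic(t: SummaryStats) -> float:
    """Mean per-variant F statistic, (beta/se)^2 averaged over variants.

    Values above ~10 conventionally indicate strong instruments.
    """
    if len(t) == 0:
        raise EmptyInputError("cannot compute mean F on an empty table")
    z = t.df["beta"].to_numpy() / t.df["se"].to_numpy()
    return float(np.mean(z**2))


def exclude_snps(t: SummaryStats, rsids: Sequence[str]) -> SummaryStats:
    """Remove listed variants; absent rsids are noted, not errors."""
    rsids = list(rsids)
    present = set(t.rsids)
    absent = [rs for rs in rsids if rs not in present]
    if absent:
        logger.info("exclude_snps: %d rsid(s) not in table: %s", len(absent), absent[:5])
    keep = t.df[~t.df["rsid"].isin(set(rsids))]
    return replace(t, df=keep.reset_index(drop=True), n_dropped=0)
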