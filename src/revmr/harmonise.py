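"""Allele harmonisation of exposure and outcome summary statistics.

Two GWAS may report the same variant on different effect alleles or on
opposite strands.  Before any ratio of outcome to exposure effects is
meaningful, both tables must be expressed on a common effect allele.  For
each variant shared by the two tables:

* alleles identical → keep as-is;
* effect/other swapped → negate the outcome beta, complement its eaf;
* identical or swapped only after strand complement (A<->T, C<->G) →
  apply the complement first (``kept_strand_corrected``);
* palindromic (A/T or C/G) → strand is intrinsically ambiguous, so the
  effect allele frequency is the only disambiguator: the pair is kept only
  when both frequencies fall on the same side of 0.5 and both are outside
  the ambiguity window ``[limit, 1 - limit]`` (default limit 0.42);
* irreconcilable allele sets → dropped.

Every exclusion is a recorded disposition, never an exception.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import FormatError
from .sumstats import SummaryStats

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

KEPT_AS_IS = "kept_as_is"
KEPT_FLIPPED = "kept_flipped"
KEPT_STRAND = "kept_strand_corrected"
DROP_PALINDROMIC = "dropped_palindromic"
DROP_INCOMPATIBLE = "dropped_incompatible"

KEPT = (KEPT_AS_IS, KEPT_FLIPPED, KEPT_STRAND)
DISPOSITIONS = KEPT + (DROP_PALINDROMIC, DROP_INCOMPATIBLE)

#: columns of the harmonised pair frame
PAIR_COLUMNS = [
    "rsid", "effect_allele", "other_allele",
    "beta_exp", "se_exp", "eaf_exp",
    "beta_out", "se_out", "eaf_out",
    "flip", "disposition",
]

DEFAULT_PALINDROME_EAF_LIMIT = 0.42


def is_palindromic(a: str, b: str) -> bool:
    """A/T and C/G variants read identically on either strand."""
    return COMPLEMENT.get(a) == b


@dataclass
class HarmonisedSet:
    """Exposure/outcome effect pairs on a common effect-allele orientation.

    ``pairs`` holds one row per shared variant, kept or dropped, with a
    ``disposition`` label and a ``flip`` sign (-1 when the outcome beta was
    negated relative to its reported orientation; used to co-orient a
    second exposure in multivariable analyses).
    """

    exposure_name: str
    outcome_name: str
    pairs: pd.DataFrame
    exposure_type: str = "binary_disease"
    outcome_type: str = "continuous"

    def __post_init__(self) -> None:
        missing = [c for c in PAIR_COLUMNS if c not in self.pairs.columns]
        if missing:
            raise FormatError(f"harmonised frame missing columns {missing}")
        if self.pairs["rsid"].duplicated().any():
            raise FormatError("duplicate rsids in harmonised set")

    @property
    def kept(self) -> pd.DataFrame:
        return self.pairs[self.pairs["disposition"].isin(KEPT)]

    @property
    def n_kept(self) -> int:
        return int(len(self.kept))

    @property
    def n_dropped(self) -> int:
        return int(len(self.pairs)) - self.n_kept

    @property
    def tallies(self) -> dict[str, int]:
        counts = self.pairs["disposition"].value_counts().to_dict()
        return {d: int(counts.get(d, 0)) for d in DISPOSITIONS}

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(beta_exp, se_exp, beta_out, se_out) over kept pairs."""
        k = self.kept
        return (
            k["beta_exp"].to_numpy(float),
            k["se_exp"].to_numpy(float),
            k["beta_out"].to_numpy(float),
            k["se_out"].to_numpy(float),
        )

    @classmethod
    def from_arrays(
        cls,
        beta_exp: np.ndarray,
        se_exp: np.ndarray,
        beta_out: np.ndarray,
        se_out: np.ndarray,
        rsids: list[str] | None = None,
        exposure_name: str = "exposure",
        outcome_name: str = "outcome",
        exposure_type: str = "binary_disease",
    ) -> "HarmonisedSet":
        """Build a pre-aligned set directly from effect arrays.

        Convenience for simulation studies where both tables are generated
        on a common orientation and harmonisation would be a no-op.
        """
        beta_exp = np.asarray(beta_exp, float)
        j = beta_exp.size
        frame = pd.DataFrame(
            {
                "rsid": rsids if rsids is not None else [f"rs{i:06d}" for i in range(j)],
                "effect_allele": "A",
                "other_allele": "G",
                "beta_exp": beta_exp,
                "se_exp": np.asarray(se_exp, float),
                "eaf_exp": np.nan,
                "beta_out": np.asarray(beta_out, float),
                "se_out": np.asarray(se_out, float),
                "eaf_out": np.nan,
                "flip": 1,
                "disposition": KEPT_AS_IS,
            }
        )[PAIR_COLUMNS]
        return cls(exposure_name, outcome_name, frame, exposure_type, "continuous")


def _resolve(ea_e, oa_e, eaf_e, ea_o, oa_o, eaf_o, beta_o, limit):
    """Orient one outcome row onto the exposure's alleles.

    Returns (beta_out, eaf_out, flip, disposition).
    """
    if is_palindromic(ea_e, oa_e):
        # strand complement is indistinguishable from an allele swap;
        # align labels, then let frequency arbitrate
        if (ea_o, oa_o) == (ea_e, oa_e):
            flip = 1
        elif (ea_o, oa_o) == (oa_e, ea_e):
            flip = -1
        else:
            return np.nan, np.nan, 0, DROP_INCOMPATIBLE
        if np.isnan(eaf_e) or np.isnan(eaf_o):
            return np.nan, np.nan, 0, DROP_PALINDROMIC
        eaf_o_aligned = eaf_o if flip == 1 else 1.0 - eaf_o
        informative = (
            min(eaf_e, 1 - eaf_e) < min(limit, 1 - limit)
            and min(eaf_o_aligned, 1 - eaf_o_aligned) < min(limit, 1 - limit)
        )
        same_side = (eaf_e - 0.5) * (eaf_o_aligned - 0.5) > 0
        if informative and same_side:
            disp = KEPT_AS_IS if flip == 1 else KEPT_FLIPPED
            return flip * beta_o, eaf_o_aligned, flip, disp
        return np.nan, np.nan, 0, DROP_PALINDROMIC

    if (ea_o, oa_o) == (ea_e, oa_e):
        return beta_o, eaf_o, 1, KEPT_AS_IS
    if (ea_o, oa_o) == (oa_e, ea_e):
        return -beta_o, 1.0 - eaf_o, -1, KEPT_FLIPPED
    cea, coa = COMPLEMENT[ea_o], COMPLEMENT[oa_o]
    if (cea, coa) == (ea_e, oa_e):
        return beta_o, eaf_o, 1, KEPT_STRAND
    if (cea, coa) == (oa_e, ea_e):
        return -beta_o, 1.0 - eaf_o, -1, KEPT_STRAND
    return np.nan, np.nan, 0, DROP_INCOMPATIBLE


def harmonise(
    exposure: SummaryStats,
    outcome: SummaryStats,
    palindrome_eaf_limit: float = DEFAULT_PALINDROME_EAF_LIMIT,
) -> HarmonisedSet:
    """Pair exposure and outcome effects on the exposure's effect alleles.

    Variants absent from either table are omitted; everything else gets a
    disposition.  ``palindrome_eaf_limit`` in (0, 0.5) bounds the frequency
    window regarded as ambiguous for palindromic variants.
    """
    if not (0 < palindrome_eaf_limit < 0.5):
        raise ValueError("palindrome_eaf_limit must be in (0, 0.5)")
    merged = exposure.df.merge(
        outcome.df, on="rsid", suffixes=("_exp", "_out"), how="inner"
    )
    records = []
    for t in merged.itertuples(index=False):
        beta_out, eaf_out, flip, disp = _resolve(
            t.effect_allele_exp, t.other_allele_exp, t.eaf_exp,
            t.effect_allele_out, t.other_allele_out, t.eaf_out,
            t.beta_out, palindrome_eaf_limit,
        )
        kept = disp in KEPT
        records.append(
            (
                t.rsid, t.effect_allele_exp, t.other_allele_exp,
                t.beta_exp if kept else np.nan,
                t.se_exp if kept else np.nan,
                t.eaf_exp,
                beta_out if kept else np.nan,
                t.se_out if kept else np.nan,
                eaf_out if kept else np.nan,
                flip, disp,
            )
        )
    frame = pd.DataFrame(records, columns=PAIR_COLUMNS)
    return HarmonisedSet(
        exposure_name=exposure.trait_name,
        outcome_name=outcome.trait_name,
        pairs=frame,
        exposure_type=exposure.trait_type,
        outcome_type=outcome.trait_type,
    )


def orient_exposure_positive(h: HarmonisedSet) -> HarmonisedSet:
    """Negate both effects of pairs with a negative exposure effect.

    Per-variant ratios are unchanged; required by the MR-Egger orientation
    convention, under which the intercept's sign is meaningful.
    """
    pairs = h.pairs.copy()
    kept = pairs["disposition"].isin(KEPT)
    neg = kept & (pairs["beta_exp"] < 0)
    pairs.loc[neg, ["beta_exp", "beta_out"]] *= -1.0
    pairs.loc[neg, "flip"] *= -1
    return replace(h, pairs=pairs)


def write_harmonised(h: HarmonisedSet, path: str | Path) -> None:
    out = h.pairs.copy()
    out.insert(0, "exposure", h.exposure_name)
    out.insert(1, "outcome", h.outcome_name)
    out.to_csv(path, sep="\t", index=False)


def read_harmonised(path: str | Path) -> HarmonisedSet:
    df = pd.read_csv(path, sep="\t")
    required = ["exposure", "outcome"] + PAIR_COLUMNS
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"harmonised file missing columns {missing}")
    return HarmonisedSet(
        exposure_name=str(df["exposure"].iloc[0]),
        outcome_name=str(df["outcome"].iloc[0]),
        pairs=df[PAIR_COLUMNS].copy(),
    )
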