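"""Synthetic GWAS summary statistics with known ground truth.

The generator emulates the data structure a two-sample reverse-MR study
consumes, at desk scale, so every pipeline stage can be exercised and
validated against known truth without any external download:

* per-SNP exposure effects ``gamma_j`` on a log-odds liability scale,
  with sampling noise from the standard binary-trait GWAS approximation
  ``se = 1 / sqrt(2 * maf * (1 - maf) * n_eff)``,
  ``n_eff = 4 / (1/cases + 1/controls)``;
* outcome effects ``Gamma_j = theta * gamma_j + alpha_j + noise`` where
  ``alpha_j`` is horizontal pleiotropy (none / balanced / directional on
  a configurable fraction of instruments) and planted outlier SNPs get an
  extra offset expressed in outcome-SE units;
* harmonisation stressors: palindromic variants, strand-flipped and
  allele-swapped outcome rows, with the true orientation recorded;
* LD block structure for clumping;
* a correlated multi-trait outcome panel (sharing per-SNP noise through
  a trait correlation matrix), standing in for an NMR metabolomics panel;
* age-stratum outcome tables in which medication use attenuates or
  reverses the effective ``theta`` in proportion to per-stratum statin
  prevalence — the mechanism behind age-distorted liability effects.

Default scale mirrors a large disease GWAS (74,124 cases / 824,006
controls) against a 118,466-sample metabolite GWAS, with 150 instruments
and a 20-trait panel.  All randomness derives from ``cfg.seed`` through
named child streams, so adding strata or a panel never perturbs the
exposure draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import AlignmentError, ConfigError
from .sumstats import COLUMNS, LdMatrix, SummaryStats

_STREAMS = ("exposure", "exposure2", "outcome", "panel", "strata", "misc")

#: non-palindromic ordered allele pairs to draw from
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]
_PALINDROMES = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: statin-use prevalence by age tertile (youngest to oldest) in UK Biobank
DEFAULT_STATIN_PREVALENCES = (0.05, 0.17, 0.29)
DEFAULT_STRATUM_LABELS = ("age_39_53", "age_53_61", "age_61_73")


@dataclass
class PanelSpec:
    """Correlated multi-trait outcome panel configuration."""

    n_traits: int = 20
    trait_corr: float | np.ndarray = 0.3
    thetas: Sequence[float] | None = None

    def corr_matrix(self) -> np.ndarray:
        if np.isscalar(self.trait_corr):
            rho = float(self.trait_corr)
            if not (-1.0 / max(self.n_traits - 1, 1) <= rho <= 1):
                raise ConfigError("exchangeable trait_corr out of PSD range")
            m = np.full((self.n_traits, self.n_traits), rho)
            np.fill_diagonal(m, 1.0)
            return m
        m = np.asarray(self.trait_corr, float)
        if m.shape != (self.n_traits, self.n_traits):
            raise ConfigError("trait_corr shape does not match n_traits")
        if not np.allclose(m, m.T, atol=1e-8):
            raise ConfigError("trait_corr must be symmetric")
        if np.linalg.eigvalsh(m).min() < -1e-8:
            raise ConfigError("trait_corr is not positive semi-definite")
        return m

    def theta_vector(self, default_theta: float) -> np.ndarray:
        if self.thetas is None:
            return np.full(self.n_traits, default_theta)
        t = np.asarray(self.thetas, float)
        if t.size != self.n_traits:
            raise ConfigError("panel thetas length does not match n_traits")
        return t


@dataclass
class StrataSpec:
    """Age-tertile medication-mediation mechanism.

    Each stratum's effective causal effect is
    ``theta_s = theta + medication_modifier * prevalence_s``; a negative
    modifier with rising statin prevalence attenuates and eventually
    reverses the effect at older ages.
    """

    prevalences: Sequence[float] = DEFAULT_STATIN_PREVALENCES
    medication_modifier: float = 0.0
    labels: Sequence[str] = DEFAULT_STRATUM_LABELS

    def __post_init__(self) -> None:
        if len(self.prevalences) != len(self.labels):
            raise ConfigError("strata prevalences and labels differ in length")
        if any(not (0 <= p <= 1) for p in self.prevalences):
            raise ConfigError("medication prevalences must lie in [0, 1]")


@dataclass
class SecondExposureSpec:
    """A second disease liability sharing instruments with the first."""

    theta2: float = 0.1
    gamma_corr: float = 0.5
    gamma2_mean: float = 0.10
    gamma2_sd: float = 0.04
    n_cases2: int = 181522
    n_controls2: int = 984168  # cases + controls = 1,165,690 participants

    def __post_init__(self) -> None:
        if not (-1 <= self.gamma_corr <= 1):
            raise ConfigError("gamma_corr must lie in [-1, 1]")


@dataclass
class SimulationConfig:
    """Full generative specification for one synthetic study."""

    n_snp: int = 150
    theta: float = 0.3
    pleiotropy: str = "none"  # none | balanced | directional
    alpha_mean: float = 0.02
    alpha_sd: float = 0.02
    frac_invalid: float = 0.0
    n_outlier: int = 0
    outlier_offset: float = 0.0  # in units of the outcome SE
    gamma_mean: float = 0.12
    gamma_sd: float = 0.04
    n_cases: int = 74124
    n_controls: int = 824006
    n_out: int = 118466
    maf_range: tuple[float, float] = (0.05, 0.5)
    frac_palindromic: float = 0.0
    palindrome_eaf: float | None = None
    frac_strand_flipped: float = 0.0
    frac_allele_swapped: float = 0.0
    ld_n_blocks: int = 0
    ld_within_r2: float = 0.9
    panel: PanelSpec | None = None
    strata: StrataSpec | None = None
    second_exposure: SecondExposureSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snp < 1:
            raise ConfigError("n_snp must be positive")
        if self.pleiotropy not in ("none", "balanced", "directional"):
            raise ConfigError(f"unknown pleiotropy law {self.pleiotropy!r}")
        for name in ("frac_invalid", "frac_palindromic",
                     "frac_strand_flipped", "frac_allele_swapped"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.alpha_sd < 0 or self.gamma_sd < 0:
            raise ConfigError("standard deviations must be non-negative")
        if self.n_outlier < 0 or self.n_outlier > self.n_snp:
            raise ConfigError("n_outlier out of range")
        lo, hi = self.maf_range
        if not (0 < lo <= hi < 1):
            raise ConfigError("maf_range must satisfy 0 < lo <= hi < 1")
        if self.palindrome_eaf is not None and not (0 < self.palindrome_eaf < 1):
            raise ConfigError("palindrome_eaf must lie in (0, 1)")
        if min(self.n_cases, self.n_controls, self.n_out) < 2:
            raise ConfigError("sample sizes must exceed 1")
        if self.ld_n_blocks < 0 or not (0 <= self.ld_within_r2 <= 1):
            raise ConfigError("invalid LD block configuration")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "maf_range" in d:
            d["maf_range"] = tuple(d["maf_range"])
        for key, sub in (("panel", PanelSpec), ("strata", StrataSpec),
                         ("second_exposure", SecondExposureSpec)):
            if isinstance(d.get(key), dict):
                d[key] = sub(**d[key])
        try:
            return cls(**d)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def streams(self) -> dict[str, np.random.Generator]:
        children = np.random.SeedSequence(self.seed).spawn(len(_STREAMS))
        return {name: np.random.default_rng(s)
                for name, s in zip(_STREAMS, children)}


@dataclass
class SyntheticTruth:
    """Ground truth aligned one-to-one with the emitted tables."""

    rsids: list[str]
    maf: np.ndarray
    gamma: np.ndarray
    se_gamma: np.ndarray
    alpha: np.ndarray
    theta: float
    invalid: np.ndarray  # bool mask: alpha != 0 allowed
    outlier_rsids: list[str]
    palindromic: np.ndarray
    strand_flipped: np.ndarray
    allele_swapped: np.ndarray
    exposure_alleles: list[tuple[str, str]]
    eaf: np.ndarray
    gamma2: np.ndarray | None = None
    se_gamma2: np.ndarray | None = None
    theta2: float | None = None
    panel_thetas: np.ndarray | None = None
    stratum_thetas: dict[str, float] | None = None
    outcome_beta_native: np.ndarray | None = None

    @property
    def outlier_mask(self) -> np.ndarray:
        s = set(self.outlier_rsids)
        return np.array([rs in s for rs in self.rsids])


def _binary_se(maf: np.ndarray, n_cases: int, n_controls: int) -> np.ndarray:
    n_eff = 4.0 / (1.0 / n_cases + 1.0 / n_controls)
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n_eff)


def _continuous_se(maf: np.ndarray, n: int) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)


def _pvals(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta) / se)
    return np.clip(p, np.finfo(float).tiny, 1.0)


def _table(rsids, alleles, eaf, beta, se, n, name, trait_type) -> SummaryStats:
    df = pd.DataFrame(
        {
            "rsid": rsids,
            "effect_allele": [a for a, _ in alleles],
            "other_allele": [b for _, b in alleles],
            "eaf": eaf,
            "beta": beta,
            "se": se,
            "pval": _pvals(np.asarray(beta), np.asarray(se)),
            "n": n,
        }
    )[COLUMNS]
    return SummaryStats(trait_name=name, trait_type=trait_type, df=df)


def simulate_exposure(cfg: SimulationConfig) -> tuple[SummaryStats, SyntheticTruth]:
    """Draw the disease-liability GWAS and fix all per-SNP ground truth."""
    rng = cfg.streams()["exposure"]
    j = cfg.n_snp
    rsids = [f"rs{i + 1:06d}" for i in range(j)]
    maf = rng.uniform(*cfg.maf_range, size=j)
    gamma = rng.normal(cfg.gamma_mean, cfg.gamma_sd, size=j)
    se = _binary_se(maf, cfg.n_cases, cfg.n_controls)
    beta = gamma + rng.normal(size=j) * se

    n_pal = round(cfg.frac_palindromic * j)
    pal_idx = rng.choice(j, size=n_pal, replace=False)
    palindromic = np.zeros(j, bool)
    palindromic[pal_idx] = True
    non_pal = np.flatnonzero(~palindromic)

    def pick(frac: float, taken: np.ndarray) -> np.ndarray:
        pool = np.setdiff1d(non_pal, taken)
        k = min(round(frac * j), pool.size)
        return rng.choice(pool, size=k, replace=False) if k else np.empty(0, int)

    flip_idx = pick(cfg.frac_strand_flipped, np.empty(0, int))
    swap_idx = pick(cfg.frac_allele_swapped, flip_idx)
    strand_flipped = np.zeros(j, bool)
    strand_flipped[flip_idx] = True
    allele_swapped = np.zeros(j, bool)
    allele_swapped[swap_idx] = True

    alleles = []
    for i in range(j):
        choices = _PALINDROMES if palindromic[i] else _ALLELE_PAIRS
        alleles.append(choices[rng.integers(len(choices))])

    eaf = maf.copy()
    if cfg.palindrome_eaf is not None:
        eaf[palindromic] = cfg.palindrome_eaf

    invalid = np.zeros(j, bool)
    n_invalid = round(cfg.frac_invalid * j)
    if n_invalid:
        invalid[rng.choice(j, size=n_invalid, replace=False)] = True
    alpha = np.zeros(j)
    if cfg.pleiotropy == "balanced":
        alpha[invalid] = rng.normal(0.0, cfg.alpha_sd, size=invalid.sum())
    elif cfg.pleiotropy == "directional":
        alpha[invalid] = rng.normal(cfg.alpha_mean, cfg.alpha_sd, size=invalid.sum())

    valid_pool = np.flatnonzero(~invalid)
    out_idx = (rng.choice(valid_pool, size=cfg.n_outlier, replace=False)
               if cfg.n_outlier else np.empty(0, int))
    outlier_rsids = [rsids[i] for i in out_idx]

    gamma2 = se2 = None
    theta2 = None
    if cfg.second_exposure is not None:
        sx = cfg.second_exposure
        rng2 = cfg.streams()["exposure2"]
        z1 = ((gamma - cfg.gamma_mean) / cfg.gamma_sd
              if cfg.gamma_sd > 0 else np.zeros(j))
        z2 = rng2.normal(size=j)
        mix = sx.gamma_corr * z1 + np.sqrt(max(0.0, 1 - sx.gamma_corr**2)) * z2
        gamma2 = sx.gamma2_mean + sx.gamma2_sd * mix
        se2 = _binary_se(maf, sx.n_cases2, sx.n_controls2)
        theta2 = sx.theta2

    truth = SyntheticTruth(
        rsids=rsids, maf=maf, gamma=gamma, se_gamma=se, alpha=alpha,
        theta=cfg.theta, invalid=invalid, outlier_rsids=outlier_rsids,
        palindromic=palindromic, strand_flipped=strand_flipped,
        allele_swapped=allele_swapped, exposure_alleles=alleles, eaf=eaf,
        gamma2=gamma2, se_gamma2=se2, theta2=theta2,
    )
    n_total = cfg.n_cases + cfg.n_controls
    table = _table(rsids, alleles, eaf, beta, se, n_total,
                   "disease_liability", "binary_disease")
    return table, truth


def simulate_second_exposure(cfg: SimulationConfig, truth: SyntheticTruth) -> SummaryStats:
    """Emit the second liability's GWAS from truth drawn in simulate_exposure."""
    if truth.gamma2 is None or cfg.second_exposure is None:
        raise AlignmentError("truth carries no second exposure; configure second_exposure")
    rng = cfg.streams()["exposure2"]
    rng.normal(size=cfg.n_snp)  # skip the correlation draw consumed above
    beta2 = truth.gamma2 + rng.normal(size=cfg.n_snp) * truth.se_gamma2
    sx = cfg.second_exposure
    return _table(truth.rsids, truth.exposure_alleles, truth.eaf, beta2,
                  truth.se_gamma2, sx.n_cases2 + sx.n_controls2,
                  "disease_liability_2", "binary_disease")


def _scramble(truth: SyntheticTruth, beta: np.ndarray, eaf: np.ndarray
              ) -> tuple[list[tuple[str, str]], np.ndarray, np.ndarray]:
    """Re-express an outcome table under the recorded orientation stressors."""
    alleles: list[tuple[str, str]] = []
    beta = beta.copy()
    eaf = eaf.copy()
    for i, (a, b) in enumerate(truth.exposure_alleles):
        if truth.strand_flipped[i]:
            a, b = _COMPLEMENT[a], _COMPLEMENT[b]
        if truth.allele_swapped[i]:
            a, b = b, a
            beta[i] *= -1.0
            eaf[i] = 1.0 - eaf[i]
        alleles.append((a, b))
    return alleles, beta, eaf


def simulate_outcome(
    cfg: SimulationConfig,
    truth: SyntheticTruth,
    rng: np.random.Generator | None = None,
    name: str = "metabolite",
    theta: float | None = None,
    n_out: int | None = None,
) -> SummaryStats:
    """Draw one continuous-trait outcome GWAS tied to the exposure truth.

    ``theta`` and ``n_out`` override the config (used for strata); a caller
    may pass its own ``rng`` to draw independent replicates cheaply.
    """
    if len(truth.rsids) != cfg.n_snp:
        raise AlignmentError("truth does not match the configuration's n_snp")
    if rng is None:
        rng = cfg.streams()["outcome"]
    th = cfg.theta if theta is None else theta
    n = cfg.n_out if n_out is None else n_out
    se = _continuous_se(truth.maf, n)
    mean = th * truth.gamma + truth.alpha
    if truth.gamma2 is not None and truth.theta2 is not None:
        mean = mean + truth.theta2 * truth.gamma2
    mean = mean + truth.outlier_mask * cfg.outlier_offset * se
    beta = mean + rng.normal(size=cfg.n_snp) * se
    truth.outcome_beta_native = beta.copy()
    alleles, beta_emit, eaf_emit = _scramble(truth, beta, truth.eaf)
    return _table(truth.rsids, alleles, eaf_emit, beta_emit, se, n,
                  name, "continuous")


def simulate_panel(
    cfg: SimulationConfig,
    truth: SyntheticTruth,
    rng: np.random.Generator | None = None,
) -> tuple[list[SummaryStats], np.ndarray, list[str]]:
    """Draw a correlated multi-trait outcome panel.

    Per-SNP noise is shared across traits through the panel correlation
    (factor via eigendecomposition, so duplicated traits at r = 1 are
    legal).  Returns the tables, the generating trait correlation matrix
    and the trait names.
    """
    if cfg.panel is None:
        raise ConfigError("no panel configured")
    if rng is None:
        rng = cfg.streams()["panel"]
    corr = cfg.panel.corr_matrix()
    thetas = cfg.panel.theta_vector(cfg.theta)
    truth.panel_thetas = thetas
    evals, evecs = np.linalg.eigh(corr)
    factor = evecs * np.sqrt(np.clip(evals, 0.0, None))
    j, t = cfg.n_snp, cfg.panel.n_traits
    z = rng.standard_normal((j, t)) @ factor.T
    se = _continuous_se(truth.maf, cfg.n_out)
    names = [f"metab_{k + 1:03d}" for k in range(t)]
    tables = []
    for k in range(t):
        mean = thetas[k] * truth.gamma + truth.alpha
        mean = mean + truth.outlier_mask * cfg.outlier_offset * se
        beta = mean + z[:, k] * se
        alleles, beta_emit, eaf_emit = _scramble(truth, beta, truth.eaf)
        tables.append(_table(truth.rsids, alleles, eaf_emit, beta_emit, se,
                             cfg.n_out, names[k], "continuous"))
    return tables, corr, names


def simulate_age_strata(
    cfg: SimulationConfig,
    truth: SyntheticTruth,
    rng: np.random.Generator | None = None,
) -> dict[str, SummaryStats]:
    """Draw per-age-tertile outcome tables under medication mediation.

    Stratum s sees ``theta_s = theta + modifier * prevalence_s`` with
    independent noise and an equal split of the outcome sample size.
    """
    if cfg.strata is None:
        raise ConfigError("no strata configured")
    spec = cfg.strata
    base = cfg.streams()["strata"] if rng is None else rng
    seeds = base.integers(0, 2**31 - 1, size=len(spec.labels))
    n_s = cfg.n_out // len(spec.labels)
    out: dict[str, SummaryStats] = {}
    thetas: dict[str, float] = {}
    for label, prev, s in zip(spec.labels, spec.prevalences, seeds):
        th = cfg.theta + spec.medication_modifier * prev
        thetas[label] = th
        out[label] = simulate_outcome(
            cfg, truth, rng=np.random.default_rng(int(s)),
            name="metabolite", theta=th, n_out=n_s,
        )
    truth.stratum_thetas = thetas
    return out


def make_ld_matrix(cfg: SimulationConfig, truth: SyntheticTruth) -> LdMatrix:
    """Block-diagonal LD: contiguous blocks at ``ld_within_r2``, 0 between."""
    j = cfg.n_snp
    r2 = np.eye(j)
    if cfg.ld_n_blocks > 0:
        bounds = np.array_split(np.arange(j), cfg.ld_n_blocks)
        for block in bounds:
            ix = np.ix_(block, block)
            r2[ix] = cfg.ld_within_r2
            r2[block, block] = 1.0
    return LdMatrix(rsids=list(truth.rsids), r2=r2)


@dataclass
class SimulatedStudy:
    """Everything one pipeline run consumes, plus the generating truth."""

    exposure: SummaryStats
    truth: SyntheticTruth
    outcome: SummaryStats
    ld: LdMatrix
    exposure2: SummaryStats | None = None
    panel_tables: list[SummaryStats] = field(default_factory=list)
    panel_corr: np.ndarray | None = None
    panel_names: list[str] = field(default_factory=list)
    strata_tables: dict[str, SummaryStats] = field(default_factory=dict)


def simulate_study(cfg: SimulationConfig) -> SimulatedStudy:
    """Generate every table the configuration requests."""
    exposure, truth = simulate_exposure(cfg)
    outcome = simulate_outcome(cfg, truth)
    study = SimulatedStudy(
        exposure=exposure, truth=truth, outcome=outcome,
        ld=make_ld_matrix(cfg, truth),
    )
    if cfg.second_exposure is not None:
        study.exposure2 = simulate_second_exposure(cfg, truth)
    if cfg.panel is not None:
        study.panel_tables, study.panel_corr, study.panel_names = simulate_panel(cfg, truth)
    if cfg.strata is not None:
        study.strata_tables = simulate_age_strata(cfg, truth)
    return study
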