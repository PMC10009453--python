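"""Panel-wide MR across many outcome traits, with stratum contrasts.

A reverse-MR study applies the same instrument set to a whole panel of
circulating metabolic traits, within the full sample and within age
strata.  This module runs the estimator battery per outcome, contrasts
estimates between strata, derives the correlated-trait multiplicity
threshold from the panel's effective number of tests, and compares two
exposures' effect profiles across the panel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import HeterogeneityResult, MrEstimate, run_all_estimators
from .exceptions import (
    AlignmentError,
    EmptyInputError,
    InsufficientInstrumentsError,
    MatrixError,
    RevmrError,
)
from .harmonise import harmonise
from .sumstats import SummaryStats

logger = logging.getLogger(__name__)


@dataclass
class OutcomeResult:
    """Estimates and heterogeneity for one exposure-outcome pair."""

    estimates: dict[str, MrEstimate]
    heterogeneity: HeterogeneityResult
    n_snp: int


@dataclass
class PanelResult:
    """Per-outcome results for one exposure within one stratum."""

    exposure_name: str
    stratum_label: str
    results: dict[str, OutcomeResult]
    failures: dict[str, str] = field(default_factory=dict)

    @property
    def outcome_names(self) -> list[str]:
        return list(self.results)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per outcome x method."""
        rows = []
        for outcome, res in self.results.items():
            for method, e in res.estimates.items():
                rows.append(
                    {
                        "exposure": self.exposure_name,
                        "outcome": outcome,
                        "stratum": self.stratum_label,
                        "method": method,
                        "beta": e.beta,
                        "se": e.se,
                        "ci_low": e.ci_low,
                        "ci_high": e.ci_high,
                        "pval": e.pval,
                        "n_snp": e.n_snp,
                        "scaled_per_doubling": e.scaled_per_doubling,
                        "q": res.heterogeneity.q,
                        "q_df": res.heterogeneity.df,
                        "q_pval": res.heterogeneity.pval,
                    }
                )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class StratumContrast:
    """Difference of one outcome's estimate between two strata.

    The z-test assumes the strata are independent samples (true for
    disjoint age tertiles of a cohort); an artifact addition, since
    per-tertile studies typically report stratum estimates without a
    formal contrast.
    """

    outcome_name: str
    stratum_a: str
    stratum_b: str
    delta: float
    se_delta: float
    z: float
    pval: float


@dataclass(frozen=True)
class EffectiveTests:
    """Effective number of independent tests in a correlated panel."""

    n_components: int
    threshold: float
    threshold_rounded: float


@dataclass(frozen=True)
class ProfileComparison:
    """OLS comparison of two exposures' effect profiles over shared traits."""

    traits: list[str]
    x: np.ndarray
    y: np.ndarray
    slope: float
    intercept: float
    r2: float
    n_traits: int


def run_panel(
    exposure: SummaryStats,
    outcomes: Sequence[SummaryStats],
    stratum_label: str = "all_ages",
    palindrome_eaf_limit: float = 0.42,
    n_boot: int = 1000,
    seed: int = 0,
    phi: float = 1.0,
    re_model: str = "multiplicative_random",
    scale: bool | None = None,
) -> PanelResult:
    """Harmonise and run the full estimator battery against each outcome.

    Individual outcome failures are recorded in ``failures`` rather than
    aborting the panel; only a panel with zero successes raises.  Each
    outcome gets its own child seed in input order, so results are
    deterministic for a fixed seed and outcome ordering.
    """
    if len(outcomes) == 0:
        raise EmptyInputError("run_panel requires at least one outcome table")
    child_seeds = np.random.SeedSequence(seed).generate_state(len(outcomes)) % (2**31)
    results: dict[str, OutcomeResult] = {}
    failures: dict[str, str] = {}
    for outcome, sub_seed in zip(outcomes, child_seeds):
        try:
            h = harmonise(exposure, outcome, palindrome_eaf_limit)
            estimates, het = run_all_estimators(
                h, n_boot=n_boot, seed=int(sub_seed), phi=phi,
                re_model=re_model, scale=scale,
            )
            results[outcome.trait_name] = OutcomeResult(
                estimates=estimates, heterogeneity=het, n_snp=h.n_kept)
        except RevmrError as exc:
            logger.warning("panel outcome %s failed: %s", outcome.trait_name, exc)
            failures[outcome.trait_name] = str(exc)
    if not results:
        raise InsufficientInstrumentsError(
            "every outcome in the panel failed: " + "; ".join(failures.values()))
    return PanelResult(
        exposure_name=exposure.trait_name,
        stratum_label=stratum_label,
        results=results,
        failures=failures,
    )


def stratum_contrast(
    a: PanelResult, b: PanelResult, method: str = "ivw"
) -> list[StratumContrast]:
    """Per-outcome z-contrast of two independent strata's estimates."""
    if set(a.results) != set(b.results):
        raise AlignmentError("strata cover different outcome sets")
    out = []
    for name in a.results:
        ea = a.results[name].estimates.get(method)
        eb = b.results[name].estimates.get(method)
        if ea is None or eb is None:
            raise AlignmentError(f"method {method!r} missing for outcome {name!r}")
        delta = ea.beta - eb.beta
        se = float(np.hypot(ea.se, eb.se))
        z = delta / se if se > 0 else float("nan")
        p = 2.0 * float(stats.norm.sf(abs(z)))
        out.append(StratumContrast(name, a.stratum_label, b.stratum_label,
                                   delta, se, z, p))
    return out


def contrasts_to_frame(contrasts: Sequence[StratumContrast]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in contrasts])


def _round_one_sig_fig(x: float) -> float:
    if x == 0:
        return 0.0
    return float(f"{x:.0e}")


def effective_tests_threshold(
    panel_corr: np.ndarray,
    variance_fraction: float = 0.95,
    alpha: float = 0.05,
) -> EffectiveTests:
    """Multiplicity threshold from the panel's effective number of tests.

    The effective count is the smallest number of principal components of
    the trait correlation matrix explaining ``variance_fraction`` of the
    total variance; the threshold is ``alpha`` divided by that count,
    reported raw and rounded to one significant figure (0.05 over 33
    components gives 0.0015, i.e. 0.002 at one significant figure).
    """
    if not (0 < variance_fraction < 1):
        raise ValueError("variance_fraction must be in (0, 1)")
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    corr = np.asarray(panel_corr, float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise MatrixError("panel correlation must be square")
    if not np.allclose(corr, corr.T, atol=1e-8):
        raise MatrixError("panel correlation must be symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=1e-8):
        raise MatrixError("panel correlation must have unit diagonal")
    evals = np.linalg.eigvalsh(corr)
    if evals.min() < -1e-8:
        raise MatrixError("panel correlation is not positive semi-definite")
    evals = np.sort(np.clip(evals, 0.0, None))[::-1]
    target = variance_fraction * corr.shape[0]
    csum = np.cumsum(evals)
    k = int(np.searchsorted(csum, target - 1e-12) + 1)
    threshold = alpha / k
    return EffectiveTests(k, threshold, _round_one_sig_fig(threshold))


def profile_comparison(
    p1: PanelResult,
    p2: PanelResult,
    method: str = "ivw",
    trait_subset: Sequence[str] | None = None,
) -> ProfileComparison:
    """OLS of exposure 2's estimates on exposure 1's across shared traits.

    A slope near 1 with high R² means the two liabilities share a
    metabolic signature; a flat, low-R² cloud means distinct profiles.
    """
    shared = [t for t in p1.results if t in p2.results]
    if trait_subset is not None:
        wanted = set(trait_subset)
        shared = [t for t in shared if t in wanted]
    if len(shared) < 3:
        raise InsufficientInstrumentsError(
            f"profile comparison needs >= 3 shared traits, got {len(shared)}")
    x = np.array([p1.results[t].estimates[method].beta for t in shared])
    y = np.array([p2.results[t].estimates[method].beta for t in shared])
    fit = stats.linregress(x, y)
    return ProfileComparison(
        traits=shared, x=x, y=y,
        slope=float(fit.slope), intercept=float(fit.intercept),
        r2=float(fit.rvalue**2), n_traits=len(shared),
    )
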