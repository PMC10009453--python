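"""Outlier-robust and multivariable extensions of the IVW model.

**Radial MR** reparameterises the IVW regression so every instrument's
contribution to Cochran's Q is explicit: with first-order radial weights
``w_j = gamma_j^2 / se_out_j^2`` and Wald ratios ``b_j``, the radial fit
regresses ``sqrt(w_j) * b_j`` on ``sqrt(w_j)`` through the origin, whose
slope equals the IVW estimate, and attributes ``Q_j = w_j (b_j - beta)^2``
to instrument ``j``.  Instruments whose ``Q_j`` is improbably large under
a chi-square(1) reference are flagged as outliers — likely pleiotropic —
and the model is re-estimated without them.

**Multivariable MR** regresses the outcome effects jointly on two or more
exposures' effects (no intercept, weights ``1/se_out^2``), giving each
exposure's *direct* effect conditional on the others.  This is the
appropriate model when two liabilities (such as T2D and CAD) share
instruments, where univariable estimates absorb part of the other
disease's effect.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .exceptions import (
    CollinearityError,
    InsufficientInstrumentsError,
)
from .estimators import IVWEstimator, MrEstimate, _as_estimate, _normal_inference
from .harmonise import HarmonisedSet, harmonise
from .sumstats import LdMatrix, SummaryStats, ld_prune, select_instruments

logger = logging.getLogger(__name__)


@dataclass
class RadialResult:
    """Per-instrument Q decomposition and post-exclusion re-estimate."""

    per_snp_q: dict[str, float]
    outliers: list[str]
    estimate_with: MrEstimate
    estimate_without: MrEstimate
    q_total: float
    p_threshold_used: float

    def __post_init__(self) -> None:
        assert abs(self.q_total - sum(self.per_snp_q.values())) <= 1e-6 * max(1.0, self.q_total)


@dataclass
class MvmrEstimate:
    """Direct effects of several exposures estimated jointly."""

    exposure_names: list[str]
    betas: np.ndarray
    ses: np.ndarray
    pvals: np.ndarray
    n_snp: int
    conditioning_note: str = ""
    n_dropped: int = 0


class RadialIVW(RegressorMixin, BaseEstimator):
    """Radial (modified second-order weight free) IVW with Q-based outlier flags.

    Parameters
    ----------
    p_threshold : float
        Per-instrument upper-tail chi-square(1) probability below which an
        instrument is flagged.  Applied without multiplicity correction by
        default; set ``bonferroni=True`` to divide by the instrument count.
    iterate : bool
        If True, repeat flag-and-refit until no new outliers emerge;
        default is a single screening pass.
    """

    def __init__(self, p_threshold: float = 0.05, bonferroni: bool = False,
                 iterate: bool = False, re_model: str = "multiplicative_random"):
        self.p_threshold = p_threshold
        self.bonferroni = bonferroni
        self.iterate = iterate
        self.re_model = re_model

    @staticmethod
    def _radial_fit(ratios: np.ndarray, w: np.ndarray) -> tuple[float, np.ndarray]:
        beta = float(np.sum(w * ratios) / np.sum(w))
        return beta, w * (ratios - beta) ** 2

    def fit(self, X, y, y_se=None, x_se=None, rsids=None):
        if not (0 < self.p_threshold < 1):
            raise ValueError("p_threshold must be in (0, 1)")
        x = np.asarray(X, float).reshape(-1)
        y = np.asarray(y, float).ravel()
        y_se = np.asarray(y_se, float).ravel()
        j = len(y)
        if j < 3:
            raise InsufficientInstrumentsError(
                f"radial IVW requires at least 3 instruments, got {j}")
        if rsids is None:
            rsids = [f"snp{i}" for i in range(j)]
        ratios = y / x
        w = x**2 / y_se**2
        beta, q_contrib = self._radial_fit(ratios, w)
        cut = self.p_threshold / j if self.bonferroni else self.p_threshold
        q_crit = float(stats.chi2.isf(cut, 1))
        flagged = q_contrib > q_crit
        if self.iterate:
            while True:
                keep = ~flagged
                if keep.sum() < 3:
                    break
                b_k, _ = self._radial_fit(ratios[keep], w[keep])
                q_all = w * (ratios - b_k) ** 2
                new = (q_all > q_crit) & keep
                if not new.any():
                    break
                flagged |= new

        self.per_snp_q_ = {rs: float(q) for rs, q in zip(rsids, q_contrib)}
        self.q_total_ = float(q_contrib.sum())
        self.outliers_ = [rs for rs, f in zip(rsids, flagged) if f]
        self.beta_ = beta

        est_with = IVWEstimator(re_model=self.re_model).fit(x, y, y_se=y_se)
        self.estimate_with_ = est_with.to_estimate()
        keep = ~flagged
        if keep.sum() >= 2:
            est_wo = IVWEstimator(re_model=self.re_model).fit(
                x[keep], y[keep], y_se=y_se[keep])
            self.estimate_without_ = est_wo.to_estimate()
        else:
            self.estimate_without_ = self.estimate_with_
        return self

    def predict(self, X):
        return np.asarray(X, float).reshape(-1) * self.estimate_without_.beta

    def to_result(self) -> RadialResult:
        cut = (self.p_threshold / len(self.per_snp_q_)
               if self.bonferroni else self.p_threshold)
        return RadialResult(
            per_snp_q=self.per_snp_q_,
            outliers=list(self.outliers_),
            estimate_with=self.estimate_with_,
            estimate_without=self.estimate_without_,
            q_total=self.q_total_,
            p_threshold_used=cut,
        )


def radial_ivw(h: HarmonisedSet, p_threshold: float = 0.05,
               bonferroni: bool = False, iterate: bool = False) -> RadialResult:
    """Radial IVW over a harmonised set; see :class:`RadialIVW`."""
    k = h.kept
    est = RadialIVW(p_threshold=p_threshold, bonferroni=bonferroni, iterate=iterate)
    est.fit(
        k["beta_exp"].to_numpy(float),
        k["beta_out"].to_numpy(float),
        y_se=k["se_out"].to_numpy(float),
        rsids=k["rsid"].tolist(),
    )
    return est.to_result()


class MultivariableIVW(RegressorMixin, BaseEstimator):
    """Zero-intercept weighted regression of outcome on several exposures.

    SEs carry the same multiplicative overdispersion inflation as the
    univariable IVW, with residual degrees of freedom ``J - k``.
    """

    def __init__(self, re_model: str = "multiplicative_random",
                 condition_limit: float = 1e8):
        self.re_model = re_model
        self.condition_limit = condition_limit

    def fit(self, X, y, y_se=None):
        X = np.asarray(X, float)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(y, float).ravel()
        y_se = np.asarray(y_se, float).ravel()
        j, k = X.shape
        if j <= k:
            raise InsufficientInstrumentsError(
                f"multivariable IVW needs more instruments ({j}) than exposures ({k})")
        w = 1.0 / y_se**2
        xw = X * np.sqrt(w)[:, None]
        if np.linalg.cond(xw) > self.condition_limit:
            raise CollinearityError("exposure effect columns are collinear")
        xtwx = X.T @ (X * w[:, None])
        coef = np.linalg.solve(xtwx, X.T @ (w * y))
        resid = y - X @ coef
        q = float(np.sum(w * resid**2))
        # residual df J - max(k, 2) keeps the k = 1 path identical to the
        # univariable IVW inflation convention
        dof = j - max(k, 2)
        inflation = 1.0
        if self.re_model == "multiplicative_random" and dof > 0:
            inflation = max(1.0, math.sqrt(q / dof))
        cov = np.linalg.inv(xtwx) * inflation**2
        self.betas_ = coef
        self.ses_ = np.sqrt(np.diag(cov))
        self.pvals_ = 2.0 * stats.norm.sf(np.abs(coef) / self.ses_)
        self.n_snp_ = j
        self.q_ = q
        return self

    def predict(self, X):
        X = np.asarray(X, float)
        if X.ndim == 1:
            X = X[:, None]
        return X @ self.betas_


def mvmr_ivw(
    exposures: list[SummaryStats],
    outcome: SummaryStats,
    ld: LdMatrix | None = None,
    p_threshold: float = 5e-8,
    r2_threshold: float = 0.001,
    palindrome_eaf_limit: float = 0.42,
) -> MvmrEstimate:
    """Multivariable IVW from raw summary-statistic tables.

    Instruments are the union of each exposure's significant variants,
    LD-pruned jointly (best p across exposures) when an LD matrix is
    given.  Every retained variant must carry associations with *all*
    exposures and the outcome after harmonisation; others are dropped
    with a logged tally.  Exposure effects are co-oriented through the
    shared outcome orientation.
    """
    if len(exposures) < 2:
        raise ValueError("multivariable MR needs at least two exposures")

    selected = [select_instruments(e, p_threshold) for e in exposures]
    union: dict[str, float] = {}
    for sel in selected:
        for rs, p in zip(sel.df["rsid"], sel.df["pval"]):
            union[rs] = min(p, union.get(rs, 1.0))
    if ld is not None:
        import pandas as pd

        combined = SummaryStats(
            trait_name="union",
            trait_type="binary_disease",
            df=pd.DataFrame(
                {
                    "rsid": list(union),
                    "effect_allele": "A",
                    "other_allele": "G",
                    "eaf": np.nan,
                    "beta": 1.0,
                    "se": 1.0,
                    "pval": list(union.values()),
                    "n": np.nan,
                }
            ),
        )
        union = dict.fromkeys(ld_prune(combined, ld, r2_threshold).rsids)

    harmonised = [
        harmonise(e.subset(list(union)), outcome.subset(list(union)),
                  palindrome_eaf_limit)
        for e in exposures
    ]
    kept_sets = [set(h.kept["rsid"]) for h in harmonised]
    shared = sorted(set.intersection(*kept_sets) & set(union))
    n_dropped = len(union) - len(shared)
    if n_dropped:
        logger.info("mvmr_ivw: dropped %d variant(s) lacking associations in "
                    "every table", n_dropped)

    frames = [h.kept.set_index("rsid").loc[shared] for h in harmonised]
    # co-orient all exposures to the first exposure's orientation via the
    # shared outcome: flip_k * flip_1 maps exposure k onto orientation 1
    flip1 = frames[0]["flip"].to_numpy(float)
    cols = [frames[0]["beta_exp"].to_numpy(float)]
    for f in frames[1:]:
        rel = f["flip"].to_numpy(float) * flip1
        cols.append(f["beta_exp"].to_numpy(float) * rel)
    X = np.column_stack(cols)
    y = frames[0]["beta_out"].to_numpy(float)
    y_se = frames[0]["se_out"].to_numpy(float)

    est = MultivariableIVW().fit(X, y, y_se=y_se)
    return MvmrEstimate(
        exposure_names=[e.trait_name for e in exposures],
        betas=est.betas_,
        ses=est.ses_,
        pvals=est.pvals_,
        n_snp=est.n_snp_,
        conditioning_note=(
            "direct effects conditional on the other exposure(s); "
            "instruments are the LD-pruned union across exposures"
        ),
        n_dropped=n_dropped,
    )
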