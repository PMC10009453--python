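"""Two-sample MR estimators over harmonised summary statistics.

Each estimator consumes per-variant exposure effects ``gamma_j`` (with
standard errors) and outcome effects ``Gamma_j`` (with standard errors)
and estimates the causal effect ``theta`` of the exposure on the outcome
under its own identifying assumption:

* **IVW** — zero-intercept weighted regression of ``Gamma`` on ``gamma``
  with weights ``1/se_out^2``; consistent when every instrument is valid.
  Equivalent to an inverse-variance-weighted mean of per-variant Wald
  ratios with first-order weights ``gamma^2 / se_out^2``.
* **MR-Egger** — the same regression with an intercept; the slope is
  consistent under InSIDE even if all instruments are pleiotropic, and the
  intercept estimates average directional pleiotropy.  Exposure effects
  are oriented positive first so the intercept's sign is interpretable.
* **Weighted median** — the weighted 50th percentile of the Wald ratios;
  consistent when valid instruments carry at least half the weight.
* **Weighted mode** — the argmax of a weighted kernel density over the
  Wald ratios; consistent when the largest homogeneous cluster of
  instruments is valid (ZEMPA).

Estimators are scikit-learn compatible: construct with hyper-parameters,
``fit(X, y, x_se=..., y_se=...)`` on per-variant effect arrays, read
fitted attributes (``beta_``, ``se_``, ...).  The module-level functions
(:func:`ivw`, :func:`egger`, ...) are thin wrappers taking a
:class:`~revmr.harmonise.HarmonisedSet` and returning
:class:`MrEstimate` records.

For a binary disease exposure, effects are on a log-odds liability scale;
multiplying estimates and standard errors by ln 2 (~0.693) re-expresses
them per doubling of genetic liability (:func:`scale_per_doubling`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .exceptions import (
    DegenerateInstrumentError,
    InsufficientInstrumentsError,
    StateError,
)
from .harmonise import HarmonisedSet, orient_exposure_positive

LN2 = math.log(2.0)
Z95 = float(stats.norm.ppf(0.975))

METHODS = ("ivw", "egger_slope", "egger_intercept", "weighted_median", "weighted_mode")


@dataclass(frozen=True)
class MrEstimate:
    """One method's causal-effect estimate with normal-theory inference.

    After :func:`scale_per_doubling`, the unit is the SD difference in the
    outcome per doubling of genetic liability to the exposure.
    """

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snp: int
    scaled_per_doubling: bool = False


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's Q heterogeneity statistic for a fitted MR model."""

    q: float
    df: int
    pval: float


def _normal_inference(beta: float, se: float) -> tuple[float, float, float]:
    p = 2.0 * float(stats.norm.sf(abs(beta) / se)) if se > 0 else float("nan")
    return beta - Z95 * se, beta + Z95 * se, max(p, np.finfo(float).tiny)


def _as_estimate(method, beta, se, n_snp) -> MrEstimate:
    lo, hi, p = _normal_inference(beta, se)
    return MrEstimate(method, float(beta), float(se), lo, hi, p, int(n_snp))


def _check_xy(X, y, y_se, min_snps, label):
    X = np.atleast_1d(np.asarray(X, float))
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, float).ravel()
    if y_se is None:
        raise ValueError("y_se (outcome standard errors) is required")
    y_se = np.asarray(y_se, float).ravel()
    if not (len(X) == len(y) == len(y_se)):
        raise ValueError("X, y and y_se must have equal length")
    if len(y) < min_snps:
        raise InsufficientInstrumentsError(
            f"{label} requires at least {min_snps} instruments, got {len(y)}"
        )
    if np.any(y_se <= 0):
        raise ValueError("all outcome standard errors must be positive")
    return X, y, y_se


def wald_ratio(beta_exp: float, se_exp: float, beta_out: float, se_out: float) -> MrEstimate:
    """Single-variant causal estimate: Gamma/gamma with first-order SE."""
    if beta_exp == 0:
        raise DegenerateInstrumentError("zero exposure effect: Wald ratio undefined")
    beta = beta_out / beta_exp
    se = se_out / abs(beta_exp)
    return _as_estimate("wald", beta, se, 1)


class IVWEstimator(RegressorMixin, BaseEstimator):
    """Inverse-variance-weighted MR.

    Parameters
    ----------
    re_model : {"multiplicative_random", "fixed"}
        Under the multiplicative random-effects model (default) the fixed-
        effect SE is inflated by ``max(1, sqrt(Q / (J - 2)))``, letting
        between-instrument heterogeneity widen the interval but never
        narrow it.
    """

    def __init__(self, re_model: str = "multiplicative_random"):
        self.re_model = re_model

    def fit(self, X, y, y_se=None, x_se=None):
        if self.re_model not in ("multiplicative_random", "fixed"):
            raise ValueError(f"unknown re_model {self.re_model!r}")
        X, y, y_se = _check_xy(X, y, y_se, 2, "IVW")
        if X.shape[1] != 1:
            raise ValueError("IVW is univariable; use MultivariableIVW for k > 1")
        x = X[:, 0]
        w = 1.0 / y_se**2
        sxx = float(np.sum(w * x * x))
        beta = float(np.sum(w * x * y)) / sxx
        se_fixed = math.sqrt(1.0 / sxx)
        j = len(y)
        q = float(np.sum(w * (y - beta * x) ** 2))
        inflation = 1.0
        if self.re_model == "multiplicative_random" and j > 2:
            inflation = max(1.0, math.sqrt(q / (j - 2)))
        se = se_fixed * inflation
        self.beta_, self.se_ = beta, se
        self.ci_low_, self.ci_high_, self.pval_ = _normal_inference(beta, se)
        self.n_snp_ = j
        self.q_, self.q_df_ = q, j - 1
        self.q_pval_ = float(stats.chi2.sf(q, j - 1))
        return self

    def predict(self, X):
        X = np.atleast_2d(np.asarray(X, float).reshape(-1, 1))
        return X[:, 0] * self.beta_

    def to_estimate(self) -> MrEstimate:
        return MrEstimate("ivw", self.beta_, self.se_, self.ci_low_,
                          self.ci_high_, self.pval_, self.n_snp_)

    def heterogeneity(self) -> HeterogeneityResult:
        return HeterogeneityResult(self.q_, self.q_df_, self.q_pval_)


class EggerEstimator(RegressorMixin, BaseEstimator):
    """MR-Egger regression: weighted fit of Gamma on gamma with intercept.

    The intercept is the average directional pleiotropy; its p-value is
    the standard pleiotropy test.  SEs of both coefficients are inflated
    by ``max(1, sqrt(Q_E / (J - 2)))`` where ``Q_E`` is Rucker's Q about
    the Egger fit.  Exposure effects are oriented positive internally.
    """

    def fit(self, X, y, y_se=None, x_se=None):
        X, y, y_se = _check_xy(X, y, y_se, 3, "MR-Egger")
        x = X[:, 0].copy()
        y = y.copy()
        neg = x < 0
        x[neg] *= -1.0
        y[neg] *= -1.0
        w = 1.0 / y_se**2
        design = np.column_stack([np.ones_like(x), x])
        xtwx = design.T @ (design * w[:, None])
        xtwy = design.T @ (w * y)
        try:
            coef = np.linalg.solve(xtwx, xtwy)
            cov_unit = np.linalg.inv(xtwx)
        except np.linalg.LinAlgError as exc:
            raise InsufficientInstrumentsError(
                "Egger design singular (no spread in exposure effects)"
            ) from exc
        j = len(y)
        resid = y - design @ coef
        q = float(np.sum(w * resid**2))
        inflation = max(1.0, math.sqrt(q / (j - 2))) if j > 2 else 1.0
        ses = np.sqrt(np.diag(cov_unit)) * inflation
        self.intercept_, self.slope_ = float(coef[0]), float(coef[1])
        self.intercept_se_, self.slope_se_ = float(ses[0]), float(ses[1])
        self.n_snp_ = j
        self.q_, self.q_df_ = q, j - 2
        self.q_pval_ = float(stats.chi2.sf(q, j - 2))
        return self

    def predict(self, X):
        x = np.abs(np.asarray(X, float).reshape(-1))
        return self.intercept_ + self.slope_ * x

    def to_estimates(self) -> tuple[MrEstimate, MrEstimate]:
        slope = _as_estimate("egger_slope", self.slope_, self.slope_se_, self.n_snp_)
        icept = _as_estimate("egger_intercept", self.intercept_, self.intercept_se_, self.n_snp_)
        return slope, icept

    def heterogeneity(self) -> HeterogeneityResult:
        return HeterogeneityResult(self.q_, self.q_df_, self.q_pval_)


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios, kind="mergesort")
    r = ratios[order]
    w = weights[order] / weights.sum()
    s = np.cumsum(w) - 0.5 * w
    return float(np.interp(0.5, s, r))


def _bootstrap_se(fn, bx, sx, by, sy, n_boot, rng) -> float:
    """Parametric bootstrap over the normal sampling distributions."""
    j = bx.size
    bx_star = bx + sx * rng.standard_normal((n_boot, j))
    by_star = by + sy * rng.standard_normal((n_boot, j))
    est = np.empty(n_boot)
    for b in range(n_boot):
        est[b] = fn(bx_star[b], by_star[b])
    return float(np.std(est, ddof=1))


class WeightedMedianEstimator(RegressorMixin, BaseEstimator):
    """Weighted-median MR with parametric-bootstrap standard errors.

    The estimate is the inverse-variance-weighted 50th percentile of the
    per-variant Wald ratios (weights ``gamma^2/se_out^2``, linear
    interpolation over cumulative weight).  It tolerates up to half the
    total weight coming from invalid instruments.
    """

    def __init__(self, n_boot: int = 1000, random_state: int | None = 0):
        self.n_boot = n_boot
        self.random_state = random_state

    def fit(self, X, y, y_se=None, x_se=None):
        if self.n_boot < 100:
            raise ValueError("n_boot must be at least 100")
        X, y, y_se = _check_xy(X, y, y_se, 3, "weighted median")
        x = X[:, 0]
        if np.any(x == 0):
            raise DegenerateInstrumentError("zero exposure effect in weighted median")
        if x_se is None:
            raise ValueError("x_se (exposure standard errors) is required")
        x_se = np.asarray(x_se, float).ravel()

        def estimate(bx, by):
            return _weighted_median(by / bx, bx**2 / y_se**2)

        self.beta_ = estimate(x, y)
        rng = np.random.default_rng(self.random_state)
        self.se_ = _bootstrap_se(estimate, x, x_se, y, y_se, self.n_boot, rng)
        self.ci_low_, self.ci_high_, self.pval_ = _normal_inference(self.beta_, self.se_)
        self.n_snp_ = len(y)
        return self

    def predict(self, X):
        return np.asarray(X, float).reshape(-1) * self.beta_

    def to_estimate(self) -> MrEstimate:
        return MrEstimate("weighted_median", self.beta_, self.se_, self.ci_low_,
                          self.ci_high_, self.pval_, self.n_snp_)


def _mode_bandwidth(ratios: np.ndarray, phi: float) -> float:
    # Silverman-type plug-in on a robust scale; MAD guards against the
    # very outliers the mode estimator is meant to resist
    j = ratios.size
    sd = float(np.std(ratios, ddof=1)) if j > 1 else 0.0
    mad = float(stats.median_abs_deviation(ratios, scale="normal"))
    scale = min(sd, mad) if mad > 0 else sd
    return phi * 0.9 * scale * j ** (-1.0 / 5.0)


def _mode_point(ratios: np.ndarray, weights: np.ndarray, h: float, grid_size: int = 512) -> float:
    if h <= 0:
        return float(ratios[0])  # degenerate point mass
    lo, hi = ratios.min() - 3 * h, ratios.max() + 3 * h
    grid = np.linspace(lo, hi, grid_size)
    w = weights / weights.sum()
    dens = np.exp(-0.5 * ((grid[:, None] - ratios[None, :]) / h) ** 2) @ w
    peak = dens.max()
    cand = np.flatnonzero(dens >= peak * (1 - 1e-12))
    mid = (grid_size - 1) / 2.0
    best = cand[np.argmin(np.abs(cand - mid))]
    return float(grid[best])


class WeightedModeEstimator(RegressorMixin, BaseEstimator):
    """Mode-based MR: weighted kernel-density argmax of the Wald ratios.

    Parameters
    ----------
    phi : float
        Bandwidth multiplier on the MAD-based plug-in rule.  Must be > 0.
    n_boot, random_state : parametric-bootstrap SE controls.
    """

    def __init__(self, phi: float = 1.0, n_boot: int = 1000,
                 random_state: int | None = 0, grid_size: int = 512):
        self.phi = phi
        self.n_boot = n_boot
        self.random_state = random_state
        self.grid_size = grid_size

    def fit(self, X, y, y_se=None, x_se=None):
        if self.phi <= 0:
            raise ValueError("phi must be positive (zero bandwidth)")
        if self.n_boot < 100:
            raise ValueError("n_boot must be at least 100")
        X, y, y_se = _check_xy(X, y, y_se, 3, "weighted mode")
        x = X[:, 0]
        if np.any(x == 0):
            raise DegenerateInstrumentError("zero exposure effect in weighted mode")
        if x_se is None:
            raise ValueError("x_se (exposure standard errors) is required")
        x_se = np.asarray(x_se, float).ravel()

        def estimate(bx, by):
            r = by / bx
            return _mode_point(r, bx**2 / y_se**2, _mode_bandwidth(r, self.phi),
                               self.grid_size)

        self.beta_ = estimate(x, y)
        rng = np.random.default_rng(self.random_state)
        self.se_ = _bootstrap_se(estimate, x, x_se, y, y_se, self.n_boot, rng)
        self.ci_low_, self.ci_high_, self.pval_ = _normal_inference(self.beta_, self.se_)
        self.n_snp_ = len(y)
        return self

    def predict(self, X):
        return np.asarray(X, float).reshape(-1) * self.beta_

    def to_estimate(self) -> MrEstimate:
        return MrEstimate("weighted_mode", self.beta_, self.se_, self.ci_low_,
                          self.ci_high_, self.pval_, self.n_snp_)


# ---------------------------------------------------------------------------
# functional wrappers over HarmonisedSet


def ivw(h: HarmonisedSet, re_model: str = "multiplicative_random"
        ) -> tuple[MrEstimate, HeterogeneityResult]:
    bx, sx, by, sy = h.arrays()
    est = IVWEstimator(re_model=re_model).fit(bx, by, y_se=sy)
    return est.to_estimate(), est.heterogeneity()


def egger(h: HarmonisedSet) -> tuple[MrEstimate, MrEstimate, HeterogeneityResult]:
    bx, sx, by, sy = orient_exposure_positive(h).arrays()
    est = EggerEstimator().fit(bx, by, y_se=sy)
    slope, icept = est.to_estimates()
    return slope, icept, est.heterogeneity()


def weighted_median(h: HarmonisedSet, n_boot: int = 1000, seed: int = 0) -> MrEstimate:
    bx, sx, by, sy = h.arrays()
    est = WeightedMedianEstimator(n_boot=n_boot, random_state=seed).fit(
        bx, by, y_se=sy, x_se=sx)
    return est.to_estimate()


def weighted_mode(h: HarmonisedSet, phi: float = 1.0, n_boot: int = 1000,
                  seed: int = 0) -> MrEstimate:
    bx, sx, by, sy = h.arrays()
    est = WeightedModeEstimator(phi=phi, n_boot=n_boot, random_state=seed).fit(
        bx, by, y_se=sy, x_se=sx)
    return est.to_estimate()


def scale_per_doubling(e: MrEstimate) -> MrEstimate:
    """Re-express a liability-scale estimate per doubling of liability.

    Multiplies the estimate, SE and CI bounds by ln 2 (~0.693); z-scores
    and p-values are unchanged.
    """
    if e.scaled_per_doubling:
        raise StateError("estimate already scaled per doubling of liability")
    return replace(
        e,
        beta=e.beta * LN2,
        se=e.se * LN2,
        ci_low=e.ci_low * LN2,
        ci_high=e.ci_high * LN2,
        scaled_per_doubling=True,
    )


def run_all_estimators(
    h: HarmonisedSet,
    n_boot: int = 1000,
    seed: int = 0,
    phi: float = 1.0,
    re_model: str = "multiplicative_random",
    scale: bool | None = None,
) -> tuple[dict[str, MrEstimate], HeterogeneityResult]:
    """IVW, Egger slope + intercept, weighted median and weighted mode.

    Returns exactly five labelled estimates plus the IVW heterogeneity.
    ``scale=None`` scales per doubling of liability automatically when the
    exposure is a binary disease trait.
    """
    if scale is None:
        scale = h.exposure_type == "binary_disease"
    est_ivw, het = ivw(h, re_model=re_model)
    slope, icept, _ = egger(h)
    wm = weighted_median(h, n_boot=n_boot, seed=seed)
    mode = weighted_mode(h, phi=phi, n_boot=n_boot, seed=seed)
    out = {
        "ivw": est_ivw,
        "egger_slope": slope,
        "egger_intercept": icept,
        "weighted_median": wm,
        "weighted_mode": mode,
    }
    if scale:
        out = {k: scale_per_doubling(v) for k, v in out.items()}
    return out, het
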