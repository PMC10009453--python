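"""MR estimators: Wald, IVW, Egger, weighted median/mode, scaling."""

import math

import numpy as np
import pytest

from revmr.estimators import (
    LN2,
    EggerEstimator,
    IVWEstimator,
    WeightedMedianEstimator,
    WeightedModeEstimator,
    egger,
    ivw,
    run_all_estimators,
    scale_per_doubling,
    wald_ratio,
    weighted_median,
    weighted_mode,
)
from revmr.exceptions import (
    DegenerateInstrumentError,
    InsufficientInstrumentsError,
    StateError,
)
from revmr.harmonise import HarmonisedSet
from revmr.simulate import SimulationConfig, simulate_exposure, simulate_outcome


def hset(bx, by, sy, sx=None):
    bx = np.asarray(bx, float)
    sx = np.full_like(bx, 0.01) if sx is None else np.asarray(sx, float)
    return HarmonisedSet.from_arrays(bx, sx, np.asarray(by, float),
                                     np.asarray(sy, float))


def wls_oracle(X, y, w):
    """Independent weighted normal-equations solve: betas and unit-variance cov."""
    Xw = X * np.sqrt(w)[:, None]
    yw = y * np.sqrt(w)
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    cov = np.linalg.inv(Xw.T @ Xw)
    return beta, cov


class TestWaldRatio:
    def test_arithmetic_and_identity(self):
        e = wald_ratio(0.2, 0.01, 0.1, 0.02)
        assert e.beta == pytest.approx(0.5) and e.se == pytest.approx(0.1)
        e2 = wald_ratio(1.0, 0.01, 0.37, 0.05)
        assert e2.beta == pytest.approx(0.37) and e2.se == pytest.approx(0.05)

    def test_sign_symmetric_and_zero_exposure_rejected(self):
        a = wald_ratio(0.2, 0.01, 0.1, 0.02)
        b = wald_ratio(-0.2, 0.01, -0.1, 0.02)
        assert a.beta == pytest.approx(b.beta) and a.se == pytest.approx(b.se)
        with pytest.raises(DegenerateInstrumentError):
            wald_ratio(0.0, 0.01, 0.1, 0.02)


class TestIVW:
    def test_exact_proportionality_recovers_slope_with_zero_q(self):
        h = hset([0.1, 0.2, 0.4], [0.03, 0.06, 0.12], [0.01, 0.03, 0.02])
        e, het = ivw(h)
        assert e.beta == pytest.approx(0.3, abs=1e-12)
        assert het.q == pytest.approx(0.0, abs=1e-18)

    def test_single_snp_rejected_two_snp_closed_form(self):
        with pytest.raises(InsufficientInstrumentsError):
            ivw(hset([0.1], [0.02], [0.01]))
        bx = np.array([0.1, 0.25])
        by = np.array([0.04, 0.05])
        sy = np.array([0.01, 0.03])
        w = bx**2 / sy**2
        ratios = by / bx
        expected = np.sum(w * ratios) / np.sum(w)
        e, _ = ivw(hset(bx, by, sy))
        assert e.beta == pytest.approx(expected, rel=1e-12)

    def test_matches_wls_oracle_on_random_set(self, rng):
        bx = rng.normal(0.1, 0.05, 50)
        by = rng.normal(0, 0.02, 50)
        sy = rng.uniform(0.005, 0.05, 50)
        w = 1 / sy**2
        beta, cov = wls_oracle(bx[:, None], by, w)
        est = IVWEstimator(re_model="fixed").fit(bx, by, y_se=sy)
        assert est.beta_ == pytest.approx(beta[0], rel=1e-12)
        assert est.se_ == pytest.approx(math.sqrt(cov[0, 0]), rel=1e-12)

    def test_equals_weighted_mean_of_wald_ratios(self, rng):
        bx = rng.normal(0.1, 0.05, 30)
        by = rng.normal(0.02, 0.03, 30)
        sy = rng.uniform(0.01, 0.05, 30)
        e, _ = ivw(hset(bx, by, sy))
        w = bx**2 / sy**2
        assert e.beta == pytest.approx(np.sum(w * by / bx) / np.sum(w), rel=1e-12)

    def test_random_effects_never_narrower_than_fixed(self, rng):
        bx = rng.normal(0.1, 0.05, 40)
        by = 0.2 * bx + rng.normal(0, 0.05, 40)
        sy = np.full(40, 0.01)
        fixed = IVWEstimator(re_model="fixed").fit(bx, by, y_se=sy)
        rand = IVWEstimator().fit(bx, by, y_se=sy)
        assert rand.se_ >= fixed.se_
        assert rand.beta_ == pytest.approx(fixed.beta_)

    def test_q_invariant_to_snp_order(self, rng):
        bx = rng.normal(0.1, 0.05, 25)
        by = rng.normal(0.02, 0.02, 25)
        sy = rng.uniform(0.01, 0.03, 25)
        perm = rng.permutation(25)
        _, het1 = ivw(hset(bx, by, sy))
        _, het2 = ivw(hset(bx[perm], by[perm], sy[perm]))
        assert het1.q == pytest.approx(het2.q, rel=1e-12)


class TestEgger:
    def test_exact_linear_data_recovers_intercept_and_slope(self):
        bx = np.linspace(0.05, 0.4, 10)
        by = 0.01 + 0.2 * bx
        e = EggerEstimator().fit(bx, by, y_se=np.full(10, 0.02))
        assert e.intercept_ == pytest.approx(0.01, abs=1e-12)
        assert e.slope_ == pytest.approx(0.2, abs=1e-12)
        assert e.q_ == pytest.approx(0.0, abs=1e-16)

    def test_matches_wls_oracle_with_intercept(self, rng):
        bx = np.abs(rng.normal(0.1, 0.05, 60))
        by = rng.normal(0.02, 0.03, 60)
        sy = rng.uniform(0.01, 0.05, 60)
        w = 1 / sy**2
        X = np.column_stack([np.ones(60), bx])
        beta, cov = wls_oracle(X, by, w)
        resid = by - X @ beta
        q = float(np.sum(w * resid**2))
        inflation = max(1.0, math.sqrt(q / 58))
        e = EggerEstimator().fit(bx, by, y_se=sy)
        assert e.intercept_ == pytest.approx(beta[0], rel=1e-10, abs=1e-12)
        assert e.slope_ == pytest.approx(beta[1], rel=1e-10)
        assert e.slope_se_ == pytest.approx(math.sqrt(cov[1, 1]) * inflation, rel=1e-10)

    def test_balanced_pleiotropy_intercept_near_zero(self):
        # desk-scale replicate study: balanced alpha has zero mean, so the
        # average intercept should sit within Monte-Carlo error of zero
        R = 150
        iceps = np.empty(R)
        for r in range(R):
            cfg = SimulationConfig(seed=40000 + r, n_snp=200, n_out=20000,
                                   pleiotropy="balanced", frac_invalid=1.0,
                                   alpha_sd=0.02)
            exp, truth = simulate_exposure(cfg)
            out = simulate_outcome(cfg, truth)
            e = EggerEstimator().fit(exp.df["beta"].to_numpy(),
                                     out.df["beta"].to_numpy(),
                                     y_se=out.df["se"].to_numpy())
            iceps[r] = e.intercept_
        mc = iceps.std(ddof=1) / math.sqrt(R)
        assert abs(iceps.mean()) <= 3 * mc

    def test_requires_three_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            egger(hset([0.1, 0.2], [0.02, 0.04], [0.01, 0.01]))


class TestWeightedMedian:
    def test_central_value_with_equal_weights(self):
        bx = np.ones(3)
        by = np.array([0.1, 0.2, 0.3])
        e = weighted_median(hset(bx, by, np.ones(3) * 0.05), n_boot=100, seed=1)
        assert e.beta == pytest.approx(0.2, abs=1e-12)

    def test_identical_ratios_point_mass(self):
        bx = np.array([0.1, 0.2, 0.3, 0.15])
        e = weighted_median(hset(bx, 0.4 * bx, np.full(4, 0.01)),
                            n_boot=100, seed=2)
        assert e.beta == pytest.approx(0.4, abs=1e-12)
        assert e.se < 0.05

    def test_matches_brute_force_percentile_oracle(self, rng):
        bx = rng.normal(0.15, 0.04, 31)
        by = rng.normal(0.03, 0.02, 31)
        sy = rng.uniform(0.01, 0.05, 31)
        est = WeightedMedianEstimator(n_boot=100, random_state=0).fit(
            bx, by, y_se=sy, x_se=np.full(31, 0.01))
        # oracle: explicit cumulative-weight walk with linear interpolation
        ratios = by / bx
        w = bx**2 / sy**2
        order = np.argsort(ratios)
        r, wn = ratios[order], w[order] / w.sum()
        s = np.cumsum(wn) - wn / 2
        k = np.searchsorted(s, 0.5)
        expected = r[k - 1] + (r[k] - r[k - 1]) * (0.5 - s[k - 1]) / (s[k] - s[k - 1])
        assert est.beta_ == pytest.approx(expected, rel=1e-12)

    def test_bootstrap_se_deterministic_given_seed(self, rng):
        bx = rng.normal(0.15, 0.04, 20)
        by = 0.2 * bx + rng.normal(0, 0.01, 20)
        sy = np.full(20, 0.01)
        sx = np.full(20, 0.005)
        a = WeightedMedianEstimator(n_boot=200, random_state=7).fit(bx, by, y_se=sy, x_se=sx)
        b = WeightedMedianEstimator(n_boot=200, random_state=7).fit(bx, by, y_se=sy, x_se=sx)
        assert a.se_ == b.se_


class TestWeightedMode:
    def test_point_mass_returns_common_ratio(self):
        bx = np.array([0.1, 0.2, 0.4])
        e = weighted_mode(hset(bx, -0.2 * bx, np.full(3, 0.01)),
                          n_boot=100, seed=3)
        assert e.beta == pytest.approx(-0.2, abs=1e-9)

    def test_cluster_dominates_dispersed_ratios(self, rng):
        cluster = rng.normal(0.3, 0.005, 70)
        noise = rng.uniform(-2, 2, 30)
        ratios = np.concatenate([cluster, noise])
        bx = np.ones(100)
        sy = np.ones(100)
        est = WeightedModeEstimator(n_boot=100, random_state=0).fit(
            bx, ratios, y_se=sy, x_se=np.full(100, 1e-6))
        # independent naive density-grid argmax oracle
        from revmr.estimators import _mode_bandwidth
        h = _mode_bandwidth(ratios, 1.0)
        grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, 512)
        dens = [sum(math.exp(-0.5 * ((g - x) / h) ** 2) for x in ratios)
                for g in grid]
        expected = grid[int(np.argmax(dens))]
        step = grid[1] - grid[0]
        assert abs(est.beta_ - expected) <= step + 1e-12
        assert abs(est.beta_ - 0.3) <= 3 * step

    def test_permutation_invariance(self, rng):
        bx = rng.normal(0.2, 0.05, 40)
        by = 0.25 * bx + rng.normal(0, 0.01, 40)
        sy = rng.uniform(0.01, 0.02, 40)
        sx = np.full(40, 0.01)
        perm = rng.permutation(40)
        a = WeightedModeEstimator(n_boot=100, random_state=1).fit(bx, by, y_se=sy, x_se=sx)
        b = WeightedModeEstimator(n_boot=100, random_state=1).fit(
            bx[perm], by[perm], y_se=sy[perm], x_se=sx[perm])
        assert a.beta_ == pytest.approx(b.beta_, abs=1e-12)

    def test_zero_bandwidth_parameter_rejected(self):
        with pytest.raises(ValueError):
            WeightedModeEstimator(phi=0.0).fit(
                np.ones(3), np.ones(3), y_se=np.ones(3), x_se=np.ones(3))


class TestScalePerDoubling:
    def test_multiplies_by_ln2_and_preserves_p(self):
        from revmr.estimators import MrEstimate
        e = MrEstimate("ivw", 0.1, 0.02, 0.0608, 0.1392, 5.7e-7, 10)
        s = scale_per_doubling(e)
        assert s.beta == pytest.approx(0.1 * LN2)
        assert s.se == pytest.approx(0.02 * LN2)
        assert round(s.beta, 4) == pytest.approx(0.0693, abs=5e-5)
        assert s.pval == e.pval
        assert s.beta / s.se == pytest.approx(e.beta / e.se, rel=1e-12)

    def test_zero_beta_and_double_scaling_error(self):
        from revmr.estimators import MrEstimate
        e = MrEstimate("ivw", 0.0, 0.02, -0.039, 0.039, 1.0, 10)
        s = scale_per_doubling(e)
        assert s.beta == 0.0
        with pytest.raises(StateError):
            scale_per_doubling(s)


class TestRunAll:
    def test_proportional_toy_data_all_methods_agree(self, toy_harmonised):
        estimates, het = run_all_estimators(toy_harmonised, n_boot=100, seed=0,
                                            scale=False)
        assert set(estimates) == {"ivw", "egger_slope", "egger_intercept",
                                  "weighted_median", "weighted_mode"}
        for m in ("ivw", "egger_slope", "weighted_median"):
            assert estimates[m].beta == pytest.approx(0.3, abs=1e-9)
        assert estimates["weighted_mode"].beta == pytest.approx(0.3, abs=1e-6)
        assert estimates["egger_intercept"].beta == pytest.approx(0.0, abs=1e-12)
        assert het.q == pytest.approx(0.0, abs=1e-12)

    def test_binary_exposure_scaled_per_doubling(self, toy_harmonised):
        scaled, _ = run_all_estimators(toy_harmonised, n_boot=100, seed=0)
        raw, _ = run_all_estimators(toy_harmonised, n_boot=100, seed=0, scale=False)
        assert scaled["ivw"].scaled_per_doubling
        assert scaled["ivw"].beta == pytest.approx(raw["ivw"].beta * LN2)

    def test_joint_sign_flip_invariance(self, rng):
        bx = rng.normal(0.1, 0.05, 30)
        by = 0.2 * bx + rng.normal(0, 0.01, 30)
        sy = np.full(30, 0.01)
        sx = np.full(30, 0.005)
        flip = rng.random(30) < 0.5
        sgn = np.where(flip, -1.0, 1.0)
        a, _ = run_all_estimators(hset(bx, by, sy, sx), n_boot=100, seed=4, scale=False)
        b, _ = run_all_estimators(hset(bx * sgn, by * sgn, sy, sx),
                                  n_boot=100, seed=4, scale=False)
        for m in ("ivw", "egger_slope", "weighted_median", "weighted_mode"):
            assert a[m].beta == pytest.approx(b[m].beta, abs=1e-9)
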