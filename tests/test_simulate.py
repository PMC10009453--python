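"""Synthetic GWAS generator: determinism, invariants, recovery regimes."""

import numpy as np
import pytest

from revmr.estimators import IVWEstimator
from revmr.exceptions import ConfigError
from revmr.panel import effective_tests_threshold
from revmr.simulate import (
    PanelSpec,
    SimulationConfig,
    StrataSpec,
    make_ld_matrix,
    simulate_age_strata,
    simulate_exposure,
    simulate_outcome,
    simulate_panel,
    simulate_study,
)
from revmr.sumstats import ld_prune, mean_f_statistic, read_sumstats, write_sumstats


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"frac_invalid": 1.2},
        {"pleiotropy": "sideways"},
        {"maf_range": (0.0, 0.5)},
        {"n_outlier": 200, "n_snp": 100},
        {"gamma_sd": -0.1},
        {"palindrome_eaf": 1.5},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            SimulationConfig(**kwargs)

    def test_bad_strata_and_panel_specs_rejected(self):
        with pytest.raises(ConfigError):
            StrataSpec(prevalences=(0.1, 0.2, 1.4))
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ConfigError):
            simulate_panel(
                SimulationConfig(panel=PanelSpec(n_traits=2, trait_corr=bad)),
                simulate_exposure(SimulationConfig())[1])


class TestDeterminism:
    def test_fixed_seed_reproduces_tables_exactly(self):
        cfg = dict(seed=13, n_snp=40, frac_palindromic=0.1,
                   panel=PanelSpec(n_traits=3),
                   strata=StrataSpec(medication_modifier=-1.0))
        a = simulate_study(SimulationConfig(**cfg))
        b = simulate_study(SimulationConfig(**cfg))
        assert a.exposure.df.equals(b.exposure.df)
        assert a.outcome.df.equals(b.outcome.df)
        for ta, tb in zip(a.panel_tables, b.panel_tables):
            assert ta.df.equals(tb.df)
        for lab in a.strata_tables:
            assert a.strata_tables[lab].df.equals(b.strata_tables[lab].df)

    def test_strata_have_independent_noise(self):
        cfg = SimulationConfig(seed=14, strata=StrataSpec())
        _, truth = simulate_exposure(cfg)
        tabs = simulate_age_strata(cfg, truth)
        labs = list(tabs)
        assert not tabs[labs[0]].df["beta"].equals(tabs[labs[1]].df["beta"])

    def test_adding_strata_does_not_perturb_exposure_draws(self):
        plain = simulate_exposure(SimulationConfig(seed=15))[0]
        with_strata = simulate_exposure(
            SimulationConfig(seed=15, strata=StrataSpec()))[0]
        assert plain.df.equals(with_strata.df)


class TestExposure:
    def test_emitted_tables_pass_io_invariants_with_zero_drops(self, tmp_path):
        cfg = SimulationConfig(seed=16, n_snp=100, frac_palindromic=0.1,
                               frac_allele_swapped=0.2)
        study = simulate_study(cfg)
        for t in (study.exposure, study.outcome):
            p = tmp_path / f"{t.trait_name}.tsv"
            write_sumstats(t, p)
            back = read_sumstats(p)
            assert back.n_dropped == 0 and len(back) == len(t)

    def test_mean_f_strong_at_defaults_and_grows_with_sample_size(self):
        small = simulate_exposure(SimulationConfig(seed=17, n_cases=500,
                                                   n_controls=5000))[0]
        default = simulate_exposure(SimulationConfig(seed=17))[0]
        assert mean_f_statistic(default) > 10
        assert mean_f_statistic(default) > mean_f_statistic(small)

    def test_zero_gamma_sd_gives_constant_true_effects(self):
        _, truth = simulate_exposure(SimulationConfig(seed=18, gamma_sd=0.0))
        assert np.allclose(truth.gamma, truth.gamma[0])

    def test_se_follows_binary_approximation(self):
        cfg = SimulationConfig(seed=19, n_snp=20)
        table, truth = simulate_exposure(cfg)
        n_eff = 4.0 / (1 / cfg.n_cases + 1 / cfg.n_controls)
        expected = 1.0 / np.sqrt(2 * truth.maf * (1 - truth.maf) * n_eff)
        np.testing.assert_allclose(table.df["se"], expected, rtol=1e-12)


class TestOutcomeRegimes:
    def test_null_theta_type_one_error_calibrated(self):
        # desk-scale null study: rejection rate at alpha=0.05 stays near 0.05
        R = 400
        rej = 0
        for r in range(R):
            cfg = SimulationConfig(seed=50000 + r, theta=0.0, n_snp=80,
                                   n_out=20000)
            exp, truth = simulate_exposure(cfg)
            out = simulate_outcome(cfg, truth)
            est = IVWEstimator().fit(exp.df["beta"].to_numpy(),
                                     out.df["beta"].to_numpy(),
                                     y_se=out.df["se"].to_numpy())
            rej += est.pval_ < 0.05
        assert 0.02 <= rej / R <= 0.085

    def test_directional_pleiotropy_biases_ivw_by_mean_alpha_over_mean_gamma(self):
        R = 150
        biases = np.empty(R)
        for r in range(R):
            cfg = SimulationConfig(seed=60000 + r, pleiotropy="directional",
                                   frac_invalid=0.3, alpha_mean=0.02,
                                   alpha_sd=0.02, n_out=30000)
            exp, truth = simulate_exposure(cfg)
            out = simulate_outcome(cfg, truth)
            est = IVWEstimator().fit(exp.df["beta"].to_numpy(),
                                     out.df["beta"].to_numpy(),
                                     y_se=out.df["se"].to_numpy())
            biases[r] = est.beta_ - cfg.theta
        predicted = 0.3 * 0.02 / 0.12  # frac * alpha_mean / gamma_mean
        assert biases.mean() == pytest.approx(predicted, rel=0.3)

    def test_outlier_offsets_shift_only_planted_snps(self):
        cfg = SimulationConfig(seed=20, n_outlier=4, outlier_offset=12.0,
                               n_out=50000)
        exp, truth = simulate_exposure(cfg)
        out = simulate_outcome(cfg, truth)
        resid = (out.df["beta"].to_numpy() - cfg.theta * truth.gamma) / \
            out.df["se"].to_numpy()
        planted = truth.outlier_mask
        assert resid[planted].min() > 6
        assert np.abs(resid[~planted]).max() < 6


class TestPanelGeneration:
    def test_identity_panel_effective_tests(self):
        cfg = SimulationConfig(seed=22, n_snp=30,
                               panel=PanelSpec(n_traits=20, trait_corr=0.0))
        _, truth = simulate_exposure(cfg)
        _, corr, _ = simulate_panel(cfg, truth)
        assert effective_tests_threshold(corr).n_components == 19

    def test_duplicated_trait_gives_near_identical_estimates(self):
        corr = np.array([[1.0, 1.0, 0.0], [1.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        cfg = SimulationConfig(
            seed=23, n_out=30000,
            panel=PanelSpec(n_traits=3, trait_corr=corr, thetas=[0.2, 0.2, 0.2]))
        exp, truth = simulate_exposure(cfg)
        tables, corr_out, names = simulate_panel(cfg, truth)
        betas = []
        for t in tables[:2]:
            est = IVWEstimator().fit(exp.df["beta"].to_numpy(),
                                     t.df["beta"].to_numpy(),
                                     y_se=t.df["se"].to_numpy())
            betas.append(est.beta_)
        assert betas[0] == pytest.approx(betas[1], abs=1e-9)
        assert effective_tests_threshold(corr_out, 0.999).n_components == 2

    def test_recovery_improves_with_outcome_sample_size(self):
        rmse = {}
        for n_out in (2000, 200000):
            errs = []
            for r in range(30):
                cfg = SimulationConfig(
                    seed=70000 + r, n_out=n_out, n_snp=60,
                    panel=PanelSpec(n_traits=4, trait_corr=0.2,
                                    thetas=[0.3, 0.1, -0.1, 0.0]))
                exp, truth = simulate_exposure(cfg)
                tables, _, _ = simulate_panel(cfg, truth)
                for t, theta in zip(tables, truth.panel_thetas):
                    est = IVWEstimator().fit(exp.df["beta"].to_numpy(),
                                             t.df["beta"].to_numpy(),
                                             y_se=t.df["se"].to_numpy())
                    errs.append(est.beta_ - theta)
            rmse[n_out] = float(np.sqrt(np.mean(np.square(errs))))
        assert rmse[200000] < rmse[2000] / 3


class TestStrata:
    def test_zero_modifier_strata_exchangeable(self):
        zs = []
        for r in range(120):
            cfg = SimulationConfig(seed=80000 + r, n_snp=60, n_out=30000,
                                   strata=StrataSpec(medication_modifier=0.0))
            exp, truth = simulate_exposure(cfg)
            tabs = simulate_age_strata(cfg, truth)
            labs = list(tabs)
            bx = exp.df["beta"].to_numpy()
            fits = [IVWEstimator().fit(bx, tabs[l].df["beta"].to_numpy(),
                                       y_se=tabs[l].df["se"].to_numpy())
                    for l in (labs[0], labs[-1])]
            zs.append((fits[0].beta_ - fits[1].beta_) /
                      np.hypot(fits[0].se_, fits[1].se_))
        from scipy import stats
        assert stats.kstest(zs, "norm").pvalue > 0.01

    def test_negative_modifier_reverses_oldest_stratum(self):
        cfg = SimulationConfig(seed=24,
                               strata=StrataSpec(medication_modifier=-2.5))
        exp, truth = simulate_exposure(cfg)
        tabs = simulate_age_strata(cfg, truth)
        labs = list(tabs)
        assert truth.stratum_thetas[labs[0]] > 0 > truth.stratum_thetas[labs[-1]]
        bx = exp.df["beta"].to_numpy()
        young = IVWEstimator().fit(bx, tabs[labs[0]].df["beta"].to_numpy(),
                                   y_se=tabs[labs[0]].df["se"].to_numpy())
        old = IVWEstimator().fit(bx, tabs[labs[-1]].df["beta"].to_numpy(),
                                 y_se=tabs[labs[-1]].df["se"].to_numpy())
        assert young.beta_ > 0 > old.beta_


class TestLdBlocks:
    def test_block_matrix_and_pruning_interplay(self):
        cfg = SimulationConfig(seed=25, n_snp=12, ld_n_blocks=3,
                               ld_within_r2=0.9)
        exp, truth = simulate_exposure(cfg)
        ld = make_ld_matrix(cfg, truth)
        kept = ld_prune(exp, ld, 0.001)
        assert len(kept) == 3
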