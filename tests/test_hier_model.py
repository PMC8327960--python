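"""Mixed-model recovery, diagnostics and model criticism."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from sexarch.core_data import (AnalysisConfig, TraitDataset, ValidationError,
                               standardize_and_prepare)
from sexarch.hier_model import (Diagnostics, PriorSpec, diagnostics,
                                fit_model, model_criticism,
                                posterior_predictive_check)
from sexarch.synthetic_data import SimulationConfig, simulate_trait

from conftest import make_draws


class TestFitModel:
    def test_rho_recovery(self, fitted_trait):
        """Posterior median of the correlation lands near the truth (0.65)."""
        rho = fitted_trait["draws"].stacked("rho")
        assert np.median(rho) == pytest.approx(0.65, abs=0.15)

    def test_fixed_effect_recovery_on_standardized_scale(self, fitted_trait):
        spec = fitted_trait["spec"]
        sim = fitted_trait["sim_config"]
        draws = fitted_trait["draws"]
        for name, truth in (("beta_sex", sim.beta_sex),
                            ("beta_mass", sim.beta_mass)):
            est = np.median(draws.stacked(name)) * spec.phenotype_sd
            assert est == pytest.approx(truth, abs=0.1 * spec.phenotype_sd)

    def test_determinism_under_seed(self, desk_config):
        cfg = SimulationConfig(seed=31, n_genotypes=20)
        data, _ = simulate_trait(cfg)
        acfg = dataclasses.replace(desk_config, iterations=400, warmup=200)
        std, _ = standardize_and_prepare(data, acfg)
        d1 = fit_model(std, config=acfg)
        d2 = fit_model(std, config=acfg)
        np.testing.assert_array_equal(d1.stacked("rho"), d2.stacked("rho"))
        np.testing.assert_array_equal(d1.u, d2.u)

    def test_env_terms_follow_available_columns(self, desk_config):
        cfg = SimulationConfig(seed=32, n_genotypes=20)
        data, _ = simulate_trait(cfg)
        acfg = dataclasses.replace(desk_config, iterations=400, warmup=200)
        bare = TraitDataset(
            "bare", data.table.drop(columns=["center", "meta_group", "date"]),
        )
        std, _ = standardize_and_prepare(bare, acfg)
        draws = fit_model(std, config=acfg)
        assert draws.env_effects == {}
        assert not any(k.startswith("sigma_center") for k in draws.params)
        full_std, _ = standardize_and_prepare(data, acfg)
        full = fit_model(full_std, config=acfg)
        assert set(full.env_effects) == {"center", "meta_group", "date"}

    def test_single_genotype_rejected(self, toy_table, desk_config):
        df = toy_table.assign(genotype_id="wt", is_control=True)
        data = TraitDataset("one", df)
        with pytest.raises(ValidationError, match="2 genotypes"):
            fit_model(data, config=desk_config)

    def test_weak_data_returns_prior_scale_intercept(self):
        """With an uninformative likelihood the intercept posterior ~ N(0,1) prior."""
        rng = np.random.default_rng(0)
        df = pd.DataFrame({
            "phenotype": rng.normal(0, 100, 12),
            "sex": ["female", "male"] * 6,
            "genotype_id": ["g1"] * 6 + ["wt"] * 6,
            "is_control": [False] * 6 + [True] * 6,
        })
        acfg = AnalysisConfig(seed=2, iterations=3000, warmup=1000)
        draws = fit_model(TraitDataset("weak", df), config=acfg)
        assert np.std(draws.stacked("mu")) == pytest.approx(1.0, rel=0.1)

    def test_sex_label_symmetry(self, desk_config):
        """Swapping sex labels swaps (sigma_f, sigma_m), negates beta_sex,
        and leaves rho invariant, within Monte-Carlo error."""
        from sexarch.hier_model import GeneticCovariance

        cfg = SimulationConfig(seed=33, n_genotypes=80,
                               true_g=GeneticCovariance(0.4, 0.7, 0.5))
        data, _ = simulate_trait(cfg)
        acfg = dataclasses.replace(desk_config, iterations=1500, warmup=700)
        std, _ = standardize_and_prepare(data, acfg)
        d1 = fit_model(std, config=acfg)
        swapped_table = std.table.assign(
            sex=std.table["sex"].map({"female": "male", "male": "female"}))
        d2 = fit_model(TraitDataset("swap", swapped_table), config=acfg)
        assert np.median(d1.stacked("sigma_f")) == pytest.approx(
            np.median(d2.stacked("sigma_m")), abs=0.07)
        assert np.median(d1.stacked("sigma_m")) == pytest.approx(
            np.median(d2.stacked("sigma_f")), abs=0.07)
        assert np.median(d1.stacked("rho")) == pytest.approx(
            np.median(d2.stacked("rho")), abs=0.1)
        # beta_sex flips sign up to the sign convention female -> male offset
        b1 = np.median(d1.stacked("beta_sex"))
        b2 = np.median(d2.stacked("beta_sex"))
        assert b1 == pytest.approx(-b2, abs=0.07)


class TestDiagnostics:
    def test_well_mixed_chains(self, rng):
        x = rng.standard_normal((2, 1000))
        draws = make_draws({"p": np.concatenate([x[0], x[1]])})
        diag = diagnostics(draws, include_group_effects=False)
        assert 1.0 <= diag.per_param_rhat["p"] <= 1.01

    def test_disjoint_chains_flagged(self, rng):
        x = np.concatenate([rng.normal(-5, 1, 500), rng.normal(5, 1, 500)])
        diag = diagnostics(make_draws({"p": x}),
                           include_group_effects=False)
        assert diag.max_rhat > 1.5

    def test_white_noise_ess_near_n(self, rng):
        x = rng.standard_normal(1000)
        diag = diagnostics(make_draws({"p": x}), include_group_effects=False)
        assert 800 <= diag.per_param_ess["p"] <= 1200

    def test_divergences_not_applicable(self, fitted_trait):
        diag = diagnostics(fitted_trait["draws"], include_group_effects=False)
        assert diag.divergent_frac is None
        assert diag.max_rhat < 1.05


class TestModelCriticism:
    def test_clean_diagnostics_pass(self):
        ok, reasons = model_criticism(
            Diagnostics(max_rhat=1.01, min_ess=900.0, divergent_frac=0.0))
        assert ok and reasons == []

    @pytest.mark.parametrize("diag,expected", [
        (Diagnostics(1.06, 900.0, 0.0), ["rhat"]),
        (Diagnostics(1.01, 399.0, 0.0), ["ess"]),
        (Diagnostics(1.01, 900.0, 0.03), ["divergences"]),
        (Diagnostics(1.2, 100.0, 0.5), ["rhat", "divergences", "ess"]),
    ])
    def test_each_threshold_triggers(self, diag, expected):
        ok, reasons = model_criticism(diag)
        assert not ok and reasons == expected

    def test_not_applicable_criteria_skipped(self):
        ok, reasons = model_criticism(
            Diagnostics(max_rhat=None, min_ess=500.0, divergent_frac=None))
        assert ok


class TestPosteriorPredictiveCheck:
    def test_well_specified_model_calibrated(self, fitted_trait):
        ppc = posterior_predictive_check(
            fitted_trait["draws"], fitted_trait["std"], n_rep=200)
        assert ((ppc["tail_prob"] > 0.01) & (ppc["tail_prob"] < 0.99)).all()

    def test_heavy_tails_detected(self, desk_config, rng):
        cfg = SimulationConfig(seed=34, n_genotypes=80)
        data, _ = simulate_trait(cfg)
        t = data.table.assign(
            phenotype=data.table["phenotype"] + 0.5 * rng.standard_t(2, len(data.table)))
        std, _ = standardize_and_prepare(TraitDataset("heavy", t), desk_config)
        draws = fit_model(std, config=desk_config)
        ppc = posterior_predictive_check(draws, std, n_rep=200)
        flagged = (ppc["tail_prob"] <= 0.01) | (ppc["tail_prob"] >= 0.99)
        assert flagged.any()

    def test_zero_replicates_rejected(self, fitted_trait):
        with pytest.raises(ValueError, match="n_rep"):
            posterior_predictive_check(fitted_trait["draws"],
                                       fitted_trait["std"], n_rep=0)


class TestPriorSpec:
    def test_invalid_scales_rejected(self):
        with pytest.raises(ValueError):
            PriorSpec(intercept_scale=-1.0)
        with pytest.raises(ValueError):
            PriorSpec(lkj_eta=0.0)
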