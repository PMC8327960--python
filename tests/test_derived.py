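"""Derived measures: Fisher z, variance ratios, Riemannian distance, SD/ROPE."""

import dataclasses

import numpy as np
import pytest
from scipy.linalg import eigh

from sexarch.core_data import AnalysisConfig, StandardizationSpec, TraitDataset
from sexarch.derived import (DIMORPHIC, MONOMORPHIC, NOT_COMPUTED,
                             UNCLASSIFIED, PosteriorSummary,
                             riemannian_distance, rope_classify,
                             summarize_rfmk, variance_ratio,
                             wildtype_sd_index)
from sexarch.synthetic_data import SimulationConfig, simulate_trait

from conftest import make_draws


def _brute_force_distance(sf, sm, rho, eps=1e-3):
    """Independent oracle: generalized-eigenvalue form via scipy.linalg.eigh."""
    G = np.array([[sf**2, rho * sf * sm], [rho * sf * sm, sm**2]])
    S = G / np.mean(np.diag(G))
    N = np.array([[1.0, 1 - eps], [1 - eps, 1.0]])
    lam = eigh(S, N, eigvals_only=True)
    return np.sqrt(np.sum(np.log(lam) ** 2))


class TestSummarizeRfmk:
    def test_zero_draws_map_to_zero(self):
        d = make_draws({"rho": np.zeros(100)})
        rho, z = summarize_rfmk(d)
        assert rho.median == 0.0 and z.median == 0.0

    def test_fisher_z_point_value(self):
        d = make_draws({"rho": np.full(100, 0.5)})
        _, z = summarize_rfmk(d)
        assert z.median == pytest.approx(0.5493, abs=1e-4)

    def test_ci_brackets_center_of_symmetric_draws(self, rng):
        draws = 0.65 + 0.1 * rng.standard_normal(2000)
        rho, _ = summarize_rfmk(make_draws({"rho": np.clip(draws, -1, 1)}))
        lo, hi = rho.ci(95)
        assert lo < 0.65 < hi

    def test_fisher_z_is_odd(self, rng):
        r = rng.uniform(-0.99, 0.99, 500)
        _, z_pos = summarize_rfmk(make_draws({"rho": r}))
        _, z_neg = summarize_rfmk(make_draws({"rho": -r}))
        assert z_pos.median == pytest.approx(-z_neg.median, abs=1e-12)


class TestVarianceRatio:
    def test_equal_variances_unit_ratio(self):
        d = make_draws({"sigma_f": np.full(100, 0.5),
                        "sigma_m": np.full(100, 0.5)})
        ratio, log_ratio = variance_ratio(d, "ordered")
        assert ratio.median == 1.0 and log_ratio.median == 0.0

    def test_m_over_f_squares_sd_ratio(self):
        d = make_draws({"sigma_f": np.full(100, 0.3),
                        "sigma_m": np.full(100, 0.6)})
        ratio, _ = variance_ratio(d, "m_over_f")
        assert ratio.median == pytest.approx(4.0, rel=1e-12)

    def test_ordered_dominates_absolute_log(self, rng):
        d = make_draws({"sigma_f": rng.uniform(0.1, 1, 400),
                        "sigma_m": rng.uniform(0.1, 1, 400)})
        ordered, log_ordered = variance_ratio(d, "ordered")
        _, log_mf = variance_ratio(d, "m_over_f")
        assert log_ordered.median >= abs(log_mf.median) - 1e-12
        vf = np.square(d.stacked("sigma_f"))
        vm = np.square(d.stacked("sigma_m"))
        assert np.all(np.maximum(vf, vm) / np.minimum(vf, vm) >= 1.0)


class TestRiemannianDistance:
    def test_zero_at_regularized_null(self):
        assert riemannian_distance(1.0, 1.0, 1 - 1e-3) == pytest.approx(
            0.0, abs=1e-10)

    def test_monotone_in_decreasing_correlation(self):
        d = [riemannian_distance(1.0, 1.0, r) for r in (0.9, 0.5, 0.0)]
        assert d[0] < d[1] < d[2]

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(50):
            sf, sm = rng.uniform(0.2, 2, 2)
            rho = rng.uniform(-0.95, 0.95)
            assert riemannian_distance(sf, sm, rho) == pytest.approx(
                _brute_force_distance(sf, sm, rho), abs=1e-8)

    def test_affine_invariance_of_metric(self, rng):
        """d(M A M', M N M') = d(A, N) for the affine-invariant metric."""
        def dist(A, B):
            lam = eigh(A, B, eigvals_only=True)
            return np.sqrt(np.sum(np.log(lam) ** 2))

        eps = 1e-3
        N = np.array([[1.0, 1 - eps], [1 - eps, 1.0]])
        for _ in range(20):
            sf, sm = rng.uniform(0.2, 2, 2)
            rho = rng.uniform(-0.9, 0.9)
            G = np.array([[sf**2, rho * sf * sm], [rho * sf * sm, sm**2]])
            S = G / np.mean(np.diag(G))
            M = rng.standard_normal((2, 2))
            while abs(np.linalg.det(M)) < 0.1:
                M = rng.standard_normal((2, 2))
            assert dist(M @ S @ M.T, M @ N @ M.T) == pytest.approx(
                dist(S, N), abs=1e-8)

    def test_degenerate_matrix_rejected(self):
        with pytest.raises(ValueError, match="positive definite"):
            riemannian_distance(1.0, 1.0, 1.0)


def _sd_draws(female_raw, male_raw, std, n=200):
    """Draws whose predicted means back-transform to the given raw values."""
    mu = (np.asarray(female_raw, float) - std.phenotype_mean) / std.phenotype_sd
    male_std = (np.asarray(male_raw, float) - std.phenotype_mean) / std.phenotype_sd
    return make_draws({
        "mu": np.full(n, mu), "beta_sex": np.full(n, male_std - mu),
    }, u=np.zeros((n, 2, 2)))


class TestWildtypeSDIndex:
    std = StandardizationSpec(10.0, 2.0)

    def _dataset(self, toy_table, ratio_scale=True):
        return TraitDataset("t", toy_table, ratio_scale=ratio_scale)

    def test_identical_means_zero_index(self, toy_table):
        res = wildtype_sd_index(_sd_draws(5.0, 5.0, self.std), None,
                                self.std, self._dataset(toy_table))
        assert res.sd_index.median == 0.0
        assert res.sd_ratio_fm.median == 1.0

    def test_definition_female_twice_male(self, toy_table):
        res = wildtype_sd_index(_sd_draws(2.0, 1.0, self.std), None,
                                self.std, self._dataset(toy_table))
        assert res.sd_index.median == pytest.approx(1.0)
        assert res.sd_ratio_fm.median == pytest.approx(2.0)

    def test_non_ratio_scale_skips_index(self, toy_table):
        res = wildtype_sd_index(_sd_draws(2.0, 1.0, self.std), None, self.std,
                                self._dataset(toy_table, ratio_scale=False))
        assert res.sd_index is None and not res.computed
        assert res.sd_ratio_fm.median == pytest.approx(2.0)

    def test_nonpositive_means_flagged_out(self, toy_table):
        res = wildtype_sd_index(_sd_draws(-1.0, 1.0, self.std), None,
                                self.std, self._dataset(toy_table))
        assert not res.computed and res.frac_flagged == 1.0

    def test_recovery_from_generator(self, desk_config):
        """True wild-type means 10 vs 11 give an SD index near 0.1."""
        from sexarch.pipeline import analyze_trait

        cfg = SimulationConfig(seed=7, intercept=10.0, beta_sex=1.0)
        data, _ = simulate_trait(cfg)
        res = analyze_trait(data, desk_config, use_transform=False,
                            run_diagnostics=False)
        assert res.summaries.sd.sd_index.median == pytest.approx(0.1, abs=0.03)

    def test_scale_invariance_end_to_end(self, desk_config):
        """Multiplying the raw trait by a constant leaves the index unchanged."""
        from sexarch.pipeline import analyze_trait

        acfg = dataclasses.replace(desk_config, iterations=800, warmup=400)
        cfg = SimulationConfig(seed=9, n_genotypes=40, intercept=10.0,
                               beta_sex=1.0)
        data, _ = simulate_trait(cfg)
        r1 = analyze_trait(data, acfg, use_transform=False,
                           run_diagnostics=False)
        scaled = TraitDataset(
            "scaled", data.table.assign(phenotype=data.table["phenotype"] * 3.7))
        r2 = analyze_trait(scaled, acfg, use_transform=False,
                           run_diagnostics=False)
        # identical up to Monte-Carlo error: scaling cancels exactly through
        # standardization and back-transform, but bit-level input differences
        # can decorrelate the chains
        assert r1.summaries.sd.sd_index.median == pytest.approx(
            r2.summaries.sd.sd_index.median, abs=0.01)


class TestRopeClassify:
    def _summary(self, lo, hi):
        med = (lo + hi) / 2
        return PosteriorSummary(med, {95: (lo, hi)})

    @pytest.mark.parametrize("lo,hi,expected", [
        (0.08, 0.12, DIMORPHIC),
        (0.00, 0.03, MONOMORPHIC),
        (0.03, 0.08, UNCLASSIFIED),
    ])
    def test_rope_rule(self, lo, hi, expected):
        assert rope_classify(self._summary(lo, hi)) == expected

    def test_missing_index_not_computed(self):
        assert rope_classify(None) == NOT_COMPUTED

    def test_custom_rope(self):
        assert rope_classify(self._summary(0.08, 0.12), (0, 0.2)) == MONOMORPHIC
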