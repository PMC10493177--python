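import numpy as np
import pandas as pd
import pytest

import mosaicsim as ms
from mosaicsim.phenotype_sim import (
    TraitModel,
    assemble_traits,
    compute_ld_scores,
    compute_maf,
    draw_cross_population_effects,
    draw_effect_sizes,
    read_phenotypes,
    sample_causal_set,
    simulate_traits,
    write_phenotypes,
)

from conftest import binomial_cohort, make_genotype_matrix


class TestMaf:
    @pytest.mark.parametrize("dosages,expected", [
        ([[0], [0], [2], [2]], 0.5),
        ([[0], [0], [0], [0]], 0.0),
        ([[1], [2], [2], [2]], 1 / 8),
    ])
    def test_hand_cases(self, dosages, expected):
        gm = make_genotype_matrix(np.array(dosages))
        assert compute_maf(gm)[0] == pytest.approx(expected)

    def test_empty_matrix_errors(self):
        gm = ms.GenotypeMatrix(np.zeros((0, 1), dtype=np.uint8), [],
                               make_genotype_matrix([[0]]).variants)
        with pytest.raises(ValueError):
            compute_maf(gm)


class TestLdScores:
    def test_single_snp_scores_one(self):
        gm = make_genotype_matrix([[0], [1], [2], [1]])
        assert compute_ld_scores(gm) == pytest.approx([1.0])

    def test_perfect_ld_pair_scores_two(self):
        col = np.array([0, 1, 2, 1, 0, 2])
        gm = make_genotype_matrix(np.column_stack([col, col]))
        np.testing.assert_allclose(compute_ld_scores(gm), [2.0, 2.0], atol=1e-12)

    def test_matches_bruteforce_on_toy_matrix(self):
        rng = np.random.default_rng(7)
        X = rng.integers(0, 3, size=(40, 5)).astype(float)
        gm = make_genotype_matrix(X.astype(np.uint8),
                                  positions=[1, 2, 3, 4, 5])
        got = compute_ld_scores(gm, window_cm=1.0)  # no map -> Mb window
        expected = np.ones(5)
        for i in range(5):
            for j in range(5):
                if i != j:
                    expected[i] += np.corrcoef(X[:, i], X[:, j])[0, 1] ** 2
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_monomorphic_scores_one(self):
        gm = make_genotype_matrix(np.column_stack([[0, 0, 0, 0], [0, 1, 2, 1]]))
        assert compute_ld_scores(gm)[0] == 1.0


class TestCausalSet:
    def test_saturation_rounding_and_eligibility(self):
        rng = np.random.default_rng(0)
        eligible = np.ones(10_000, dtype=bool)
        assert len(sample_causal_set(10_000, 1.0, eligible, rng)) == 10_000
        assert len(sample_causal_set(10_000, 0.005, eligible, rng)) == 50
        eligible[::2] = False
        chosen = sample_causal_set(10_000, 0.5, eligible, rng)
        assert np.all(chosen % 2 == 1)

    def test_no_eligible_errors(self):
        with pytest.raises(ValueError):
            sample_causal_set(5, 0.5, np.zeros(5, dtype=bool),
                              np.random.default_rng(0))


class TestEffectSizes:
    def _draw_var(self, p_val, a, n=100_000, mixture=None, seed=1):
        model = TraitModel(a=a, b=0.0, c=0.0, h2=0.5,
                           mixture=mixture or [(1.0, 1.0)])
        p = np.full(n, p_val)
        r = np.ones(n)
        s = np.ones(n)
        causal = np.arange(n)
        beta = draw_effect_sizes(p, r, s, model, causal,
                                 np.random.default_rng(seed))
        return beta.var()

    def test_flat_architecture_has_equal_variances(self):
        model = TraitModel(a=0.0, b=0.0, c=0.0)
        p = np.array([0.05, 0.2, 0.5])
        beta_sd = []
        for i in range(3):
            rng = np.random.default_rng(100)
            b = draw_effect_sizes(p, np.ones(3), np.ones(3), model,
                                  np.array([i]), rng)
            beta_sd.append(b[i])
        # same component, same underlying normal draw -> identical effects
        assert beta_sd[0] == beta_sd[1] == beta_sd[2]

    def test_maf_dependence_matches_closed_form(self):
        """a=-1: Var(beta) proportional to 1/[p(1-p)]."""
        v1 = self._draw_var(0.1, a=-1.0)
        v2 = self._draw_var(0.4, a=-1.0)
        expected_ratio = (0.1 * 0.9) ** -1 / (0.4 * 0.6) ** -1
        assert v1 / v2 == pytest.approx(expected_ratio, rel=0.03)

    def test_mixture_scales_variance(self):
        v_single = self._draw_var(0.2, a=0.0)
        v_mix = self._draw_var(0.2, a=0.0, mixture=[(0.5, 1.0), (0.5, 4.0)])
        assert v_mix / v_single == pytest.approx(2.5, rel=0.03)

    def test_noncausal_betas_are_zero(self):
        model = TraitModel()
        p = np.full(10, 0.3)
        beta = draw_effect_sizes(p, np.ones(10), np.ones(10), model,
                                 np.array([2, 5]), np.random.default_rng(0))
        assert np.all(beta[[0, 1, 3, 4, 6, 7, 8, 9]] == 0)
        assert np.all(beta[[2, 5]] != 0)

    def test_effect_variance_log_log_slope_recovers_a(self):
        """Binned Var(beta) vs p(1-p) has log-log slope ~ a."""
        rng = np.random.default_rng(3)
        n = 200_000
        p = rng.uniform(0.05, 0.5, n)
        model = TraitModel(a=-0.25, b=0.0, c=0.0)
        beta = draw_effect_sizes(p, np.ones(n), np.ones(n), model,
                                 np.arange(n), rng)
        x = p * (1 - p)
        bins = np.quantile(x, np.linspace(0, 1, 11))
        idx = np.clip(np.digitize(x, bins) - 1, 0, 9)
        bx = np.array([np.log(x[idx == b].mean()) for b in range(10)])
        bv = np.array([np.log(beta[idx == b].var()) for b in range(10)])
        slope = np.polyfit(bx, bv, 1)[0]
        assert slope == pytest.approx(-0.25, abs=0.1)


class TestCrossPopulationEffects:
    def _draw(self, off_diag, n=10_000, seed=11, p2=0.3):
        p = {"EUR": np.full(n, 0.3), "AFR": np.full(n, p2)}
        r = {"EUR": np.ones(n), "AFR": np.ones(n)}
        R = np.array([[1.0, off_diag], [off_diag, 1.0]])
        model = TraitModel(a=-0.25)
        out = draw_cross_population_effects(p, r, np.ones(n), model,
                                            np.arange(n), R,
                                            np.random.default_rng(seed))
        return out["EUR"], out["AFR"]

    def test_identity_correlation_is_near_zero(self):
        a, b = self._draw(0.0)
        assert abs(np.corrcoef(a, b)[0, 1]) < 0.03

    def test_perfect_correlation_equal_marginals_identical(self):
        a, b = self._draw(1.0)
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_intermediate_correlation_recovered(self):
        a, b = self._draw(0.6)
        assert np.corrcoef(a, b)[0, 1] == pytest.approx(0.6, abs=0.03)

    def test_non_psd_rejected(self):
        R = np.array([[1.0, 1.2], [1.2, 1.0]])
        with pytest.raises(ValueError):
            self_draw = draw_cross_population_effects(
                {"A": np.full(3, 0.3), "B": np.full(3, 0.3)},
                {"A": np.ones(3), "B": np.ones(3)}, np.ones(3),
                TraitModel(), np.arange(3), R, np.random.default_rng(0))


class TestAssembleTraits:
    def test_full_heritability_is_rank_identical_to_genetic_value(self):
        rng = np.random.default_rng(5)
        gm = binomial_cohort(rng, 300, 100)
        beta = rng.standard_normal(100) * (np.arange(100) < 10)
        model = TraitModel(h2=1.0, polygenicity=0.1)
        table = assemble_traits(gm, beta, model, rng)
        g = gm.dosages.astype(float) @ beta
        y = table.traits["trait1"].to_numpy()
        assert np.corrcoef(np.argsort(np.argsort(g)),
                           np.argsort(np.argsort(y)))[0, 1] > 0.999999

    @pytest.mark.parametrize("h2", [0.03, 0.1, 0.5])
    def test_realized_heritability_calibrated(self, h2):
        """Realized genetic-variance share within +-0.02 of target at N=5000."""
        rng = np.random.default_rng(17)
        gm = binomial_cohort(rng, 5000, 500)
        model = TraitModel(h2=h2, polygenicity=0.02, b=0.0)
        table, _ = simulate_traits(gm, model, rng)
        assert table.realized_h2("trait1") == pytest.approx(h2, abs=0.02)

    def test_binary_prevalence_exact(self):
        rng = np.random.default_rng(8)
        gm = binomial_cohort(rng, 1000, 50)
        model = TraitModel(h2=0.5, polygenicity=0.2, prevalence=0.1, b=0.0)
        table, _ = simulate_traits(gm, model, rng)
        coded = table.traits["trait1"].to_numpy()
        assert set(np.unique(coded)) == {1, 2}
        assert (coded == 2).sum() == 100

    def test_multi_trait_genetic_correlation_recovered(self):
        """Shared-causals multi-trait: configured rho recovered +-0.05."""
        rng = np.random.default_rng(12)
        gm = binomial_cohort(rng, 200, 12_000)
        rho = 0.7
        model = TraitModel(h2=0.5, polygenicity=0.9, b=0.0, n_traits=2,
                           trait_corr=np.array([[1.0, rho], [rho, 1.0]]))
        _, sidecar = simulate_traits(gm, model, rng)
        b1 = sidecar["beta_trait1"].to_numpy()
        b2 = sidecar["beta_trait2"].to_numpy()
        causal = b1 != 0
        assert causal.sum() > 5000
        got = np.corrcoef(b1[causal], b2[causal])[0, 1]
        assert got == pytest.approx(rho, abs=0.05)

    def test_invalid_variance_budget(self):
        with pytest.raises(ValueError):
            TraitModel(h2=0.8, covariate_fraction=0.3)

    def test_covariates_share_realized(self):
        rng = np.random.default_rng(9)
        gm = binomial_cohort(rng, 2000, 100)
        model = TraitModel(h2=0.4, covariate_fraction=0.2, polygenicity=0.2,
                           b=0.0)
        cov = rng.standard_normal((2000, 2))
        table, _ = simulate_traits(gm, model, rng, covariates=cov)
        comp = table.components["trait1"]
        y = comp["genetic"] + comp["noise"] + comp["covariate"]
        assert comp["covariate"].var() / y.var() == pytest.approx(0.2, abs=0.02)


class TestPhenotypeFile:
    def test_roundtrip_and_layout(self, tmp_path):
        rng = np.random.default_rng(2)
        gm = binomial_cohort(rng, 2, 20)
        table, _ = simulate_traits(gm, TraitModel(h2=0.3, polygenicity=0.5,
                                                  b=0.0), rng)
        path = tmp_path / "pheno.txt"
        write_phenotypes(table, path)
        lines = path.read_text().splitlines()
        assert len(lines) == 3
        assert lines[0].split()[:3] == ["FID", "IID", "trait1"]
        back = read_phenotypes(path)
        np.testing.assert_allclose(back["trait1"].to_numpy(),
                                   table.traits["trait1"].to_numpy(),
                                   atol=1e-12)

    def test_empty_trait_list_rejected(self, tmp_path):
        table = ms.PhenotypeTable(fid=["a"], iid=["a"],
                                  traits=pd.DataFrame(index=[0]))
        with pytest.raises(ValueError):
            write_phenotypes(table, tmp_path / "x.txt")
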