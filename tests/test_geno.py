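import numpy as np
import pytest
from scipy import linalg

from triepistasis.data_model import TraitVector
from triepistasis.errors import ConfigurationError, RankError, TriepistasisError
from triepistasis.geno import (
    ModelDesign,
    StepwiseTrace,
    TermDescriptor,
    build_design,
    contrast_aaa,
    estimate_aaa_genotypic,
    fit_ols,
    ols,
    significant_additive_markers,
    stage1_chromosome_select,
    stage2_combined_select,
    stage3_interaction_select,
    term,
    total_aaa_genotypic,
)
from triepistasis.simulate import (
    ChromosomeSpec,
    EffectSpec,
    SimulationConfig,
    make_full_factorial,
    simulate_population,
)

from conftest import anchor_config


def trait(pop, values):
    return TraitVector("T", "E", np.asarray(values, float), lines=pop.genotypes.lines)


class TestDesign:
    def test_term_canonicalisation(self, factorial3):
        ids = factorial3.map.marker_ids
        assert term((ids[2], ids[0], ids[1]), factorial3) == term(ids, factorial3)
        with pytest.raises(ConfigurationError):
            TermDescriptor(2, (ids[0],))

    def test_column_counts(self, factorial3):
        d3 = build_design(factorial3, factorial3.map.marker_ids)
        assert d3.n_columns == 1 + 3 + 3 + 1
        d2 = build_design(factorial3, factorial3.map.marker_ids[:2])
        assert d2.terms_of_order(3) == []
        assert d2.n_columns == 1 + 2 + 1

    def test_product_columns_stay_pm_one(self, factorial3):
        d = build_design(factorial3, factorial3.map.marker_ids)
        w = d.matrix[:, 1 + len(d.terms_of_order(1)) + len(d.terms_of_order(2)):]
        assert set(np.unique(w)) == {-1.0, 1.0}

    def test_product_marker_restriction(self, factorial3):
        ids = factorial3.map.marker_ids
        d = build_design(factorial3, ids, product_markers=ids[:2])
        assert len(d.terms_of_order(1)) == 3
        assert len(d.terms_of_order(2)) == 1
        assert d.terms_of_order(3) == []
        with pytest.raises(ConfigurationError):
            build_design(factorial3, ids[:2], product_markers=ids)


class TestFitOLS:
    def test_exact_triple_product_fit(self, factorial3):
        x = factorial3.genotypes.values
        y = x[:, 0] * x[:, 1] * x[:, 2]
        d = build_design(factorial3, factorial3.map.marker_ids)
        fit = fit_ols(d, trait(factorial3, y))
        w_term = term(factorial3.map.marker_ids, factorial3)
        for t, est in zip(fit.terms, fit.estimates):
            expected = 1.0 if t == w_term else 0.0
            assert est == pytest.approx(expected, abs=1e-12)
        assert fit.rss == pytest.approx(0.0, abs=1e-20)

    def test_exact_linear_fit(self, factorial3):
        x = factorial3.genotypes.values
        y = 2.0 + 1.5 * x[:, 0]
        d = build_design(factorial3, factorial3.map.marker_ids[:2])
        fit = fit_ols(d, trait(factorial3, y))
        assert fit.estimates[0] == pytest.approx(2.0, abs=1e-12)
        assert fit.coefficient(term((factorial3.map.marker_ids[0],), factorial3)) == pytest.approx(1.5, abs=1e-12)

    def test_matches_brute_force_normal_equations(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            G = np.column_stack([np.ones(150), rng.normal(size=(150, 9))])
            y = rng.normal(size=150)
            coef, se, rss, df, kept = ols(G, y)
            # independent oracle: solve G'G b = G'y directly
            brute = linalg.solve(G.T @ G, G.T @ y, assume_a="sym")
            np.testing.assert_allclose(coef, brute, rtol=1e-8, atol=1e-10)
            assert df == 150 - 10

    def test_inference_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(5)
        G = np.column_stack([np.ones(60), rng.choice([-1.0, 1.0], size=(60, 4))])
        y = rng.normal(size=60)
        coef, se, rss, df, _ = ols(G, y)
        ref = sm.OLS(y, G).fit()
        np.testing.assert_allclose(coef, ref.params, rtol=1e-10)
        np.testing.assert_allclose(se, ref.bse, rtol=1e-8)

    def test_aliased_column_dropped_first_kept(self, factorial3):
        x = factorial3.genotypes.values
        G = np.column_stack([np.ones(8), x[:, 0], x[:, 0]])
        coef, se, rss, df, kept = ols(G, x[:, 0] * 3.0)
        assert kept == [0, 1]
        assert np.isnan(coef[2])
        assert coef[1] == pytest.approx(3.0)

    def test_saturated_fit_has_nan_inference(self, factorial3):
        x = factorial3.genotypes.values
        y = x[:, 0] + 0.3 * x[:, 1] * x[:, 2]
        d = build_design(factorial3, factorial3.map.marker_ids)
        fit = fit_ols(d, trait(factorial3, y))
        assert fit.df_resid == 0
        assert np.isnan(fit.p_values).all()

    def test_more_columns_than_rows_rejected(self, factorial3):
        d = build_design(factorial3, factorial3.map.marker_ids)
        wide = ModelDesign(
            d.selected_markers,
            d.terms + d.terms,
            np.column_stack([d.matrix, d.matrix[:, 1:]]),
        )
        with pytest.raises(RankError):
            fit_ols(wide, trait(factorial3, np.zeros(8)))

    def test_factorial_orthogonality(self, factorial3):
        # dropping any one term leaves the other estimates unchanged
        x = factorial3.genotypes.values
        rng = np.random.default_rng(2)
        y = trait(factorial3, rng.normal(size=8))
        full = build_design(factorial3, factorial3.map.marker_ids)
        fit_full = fit_ols(full, y)
        for drop in range(len(full.terms)):
            terms = tuple(t for i, t in enumerate(full.terms) if i != drop)
            cols = np.delete(full.matrix, drop + 1, axis=1)
            fit_sub = fit_ols(ModelDesign(full.selected_markers, terms, cols), y)
            for t in terms:
                assert fit_sub.coefficient(t) == pytest.approx(fit_full.coefficient(t), abs=1e-10)


class TestStagedSelection:
    def test_strong_marker_survives_stage1(self):
        cfg = SimulationConfig(
            n_lines=150,
            chromosomes=[ChromosomeSpec("c1", 1, 10.0)],
            effects=[EffectSpec(("c1_m001",), 2.0)],
            sigma_e=0.5,
            seed=9,
        )
        pop = simulate_population(cfg)
        surv = stage1_chromosome_select(pop, pop.traits[0])
        assert surv["c1"] == ["c1_m001"]

    def test_null_chromosome_selects_few(self):
        # AIC admits noise markers at a known modest rate; on a pure-noise
        # chromosome of 10 markers the mean survivor count stays below 2
        total = 0
        reps = 200
        for rep in range(reps):
            cfg = SimulationConfig(
                n_lines=150,
                chromosomes=[ChromosomeSpec("c1", 10, 10.0)],
                effects=[],
                sigma_e=1.0,
                seed=200_000 + rep,
            )
            pop = simulate_population(cfg)
            total += len(stage1_chromosome_select(pop, pop.traits[0])["c1"])
        assert total / reps < 2.0

    def test_zero_variance_markers_yield_empty_set(self, factorial3):
        pop = factorial3
        vals = np.ones_like(pop.genotypes.values)
        flat = pop.with_genotypes(vals)
        surv = stage1_chromosome_select(flat, trait(flat, np.zeros(8)))
        assert all(v == [] for v in surv.values())

    def test_stage2_keeps_two_true_qtl_and_dedups_aliases(self):
        cfg = SimulationConfig(
            n_lines=200,
            chromosomes=[ChromosomeSpec("c1", 2, 0.0), ChromosomeSpec("c2", 1, 10.0)],
            effects=[EffectSpec(("c1_m001",), 1.5), EffectSpec(("c2_m001",), 1.5)],
            sigma_e=0.5,
            seed=21,
        )
        # c1_m001 and c1_m002 are 0 cM apart, i.e. identical columns
        pop = simulate_population(cfg)
        np.testing.assert_array_equal(pop.marker_column("c1_m001"), pop.marker_column("c1_m002"))
        surv = {"c1": ["c1_m001", "c1_m002"], "c2": ["c2_m001"]}
        selected = stage2_combined_select(pop, pop.traits[0], surv)
        assert "c2_m001" in selected
        assert len([m for m in selected if m.startswith("c1")]) == 1

    def test_stage2_empty_pool(self, factorial3):
        assert stage2_combined_select(factorial3, trait(factorial3, np.zeros(8)), {}) == []

    def test_stage3_recovers_noise_free_triple(self, factorial3):
        x = factorial3.genotypes.values
        y = trait(factorial3, 0.5 * x[:, 0] + x[:, 0] * x[:, 1] * x[:, 2])
        d = build_design(factorial3, factorial3.map.marker_ids)
        pruned, n_scored = stage3_interaction_select(d, y)
        w_term = term(factorial3.map.marker_ids, factorial3)
        assert w_term in pruned.terms
        assert n_scored == 4

    def test_stage3_without_candidates_is_identity(self, factorial3):
        d = build_design(factorial3, factorial3.map.marker_ids[:1])
        y = trait(factorial3, np.arange(8.0))
        pruned, n_scored = stage3_interaction_select(d, y)
        assert pruned is d and n_scored == 0

    def test_stage3_max_params_validation(self, factorial3):
        d = build_design(factorial3, factorial3.map.marker_ids)
        y = trait(factorial3, np.arange(8.0))
        with pytest.raises(ConfigurationError):
            stage3_interaction_select(d, y, max_params=2)

    def test_additive_screen_keeps_strong_loci_only(self):
        pop = simulate_population(anchor_config(33, delta=0.0))
        y = pop.traits[0]
        s1 = stage1_chromosome_select(pop, y)
        selected = stage2_combined_select(pop, y, s1)
        sig = significant_additive_markers(pop, y, selected)
        assert {"chr1_m010", "chr2_m010", "chr3_m010"} <= set(selected)
        assert set(sig) <= set(selected)

    def test_accepted_moves_strictly_decrease_aic(self):
        pop = simulate_population(anchor_config(44))
        trace = StepwiseTrace()
        y = pop.traits[0]
        stage1_chromosome_select(pop, y, trace=trace)
        assert trace.moves, "expected at least one accepted move"
        for _, _, before, after in trace.moves:
            assert after < before


class TestTotalAaa:
    def test_bonferroni_threshold_arithmetic(self, factorial3):
        x = factorial3.genotypes.values
        # strong triple plus mild noise so inference is defined
        rng = np.random.default_rng(8)
        y = trait(factorial3, 0.8 * x[:, 0] * x[:, 1] * x[:, 2] + 0.01 * rng.normal(size=8))
        ids = factorial3.map.marker_ids
        d = build_design(factorial3, ids, include_pairwise=False)
        # model: intercept + 3 additive + 1 triple -> df_resid = 3
        fit = fit_ols(d, y)
        est = total_aaa_genotypic(fit, alpha=0.05, m_tests=4)
        (t, e, p, sig), = est.per_triple
        assert sig == (p < 0.05 / 4)
        assert sig
        assert est.aaa_g == pytest.approx(e)
        assert not est.ns_flag

    def test_no_triples_is_ns(self, factorial3):
        d = build_design(factorial3, factorial3.map.marker_ids[:2])
        rng = np.random.default_rng(1)
        fit = fit_ols(d, trait(factorial3, rng.normal(size=8)))
        est = total_aaa_genotypic(fit)
        assert est.aaa_g == 0.0
        assert est.ns_flag and est.n_significant_aaa == 0

    def test_opposite_triples_cancel_in_sum(self):
        pop = make_full_factorial(4)
        x = pop.genotypes.values
        ids = pop.map.marker_ids
        y = trait(pop, 0.5 * x[:, 0] * x[:, 1] * x[:, 2] - 0.5 * x[:, 0] * x[:, 1] * x[:, 3])
        d = build_design(pop, ids)
        pruned, _ = stage3_interaction_select(d, y)
        fit = fit_ols(pruned, y)
        est = total_aaa_genotypic(fit)
        assert est.aaa_g == pytest.approx(0.0, abs=1e-10)

    def test_sum_invariant_under_term_order(self, factorial3):
        x = factorial3.genotypes.values
        rng = np.random.default_rng(3)
        y = trait(factorial3, 0.4 * x[:, 0] * x[:, 1] * x[:, 2] + 0.05 * rng.normal(size=8))
        d = build_design(factorial3, factorial3.map.marker_ids)
        fit = fit_ols(d, y)
        est = total_aaa_genotypic(fit)
        perm = ModelDesign(
            d.selected_markers,
            tuple(reversed(d.terms)),
            np.column_stack([d.matrix[:, :1], d.matrix[:, :0:-1]]),
        )
        est2 = total_aaa_genotypic(fit_ols(perm, y))
        assert est.aaa_g == pytest.approx(est2.aaa_g, abs=1e-10)


class TestContrast:
    def test_pure_triple_symmetric_vanishes_difference_does_not(self, factorial3):
        x = factorial3.genotypes.values
        y = x[:, 0] * x[:, 1] * x[:, 2]
        tri = term(factorial3.map.marker_ids, factorial3)
        c = contrast_aaa(factorial3, y, [tri])
        assert c.total_symmetric == pytest.approx(0.0, abs=1e-12)
        assert c.total_difference == pytest.approx(1.0, abs=1e-12)

    def test_pairwise_signal_leaks_into_symmetric_form(self, factorial3):
        x = factorial3.genotypes.values
        y = x[:, 0] * x[:, 1]
        tri = term(factorial3.map.marker_ids, factorial3)
        c = contrast_aaa(factorial3, y, [tri])
        assert c.total_symmetric == pytest.approx(1.0, abs=1e-12)

    def test_constant_trait_gives_zero(self, factorial3):
        tri = term(factorial3.map.marker_ids, factorial3)
        c = contrast_aaa(factorial3, np.full(8, 3.3), [tri])
        assert c.total_symmetric == pytest.approx(0.0, abs=1e-12)
        assert c.total_difference == pytest.approx(0.0, abs=1e-12)

    def test_empty_group_is_an_error_naming_the_triple(self, factorial3):
        tri = term(factorial3.map.marker_ids, factorial3)
        vals = factorial3.genotypes.values.copy()
        vals[(vals == 1).all(axis=1)] = -1  # remove the all-+1 line
        pop = factorial3.with_genotypes(vals)
        with pytest.raises(TriepistasisError, match="aaa"):
            contrast_aaa(pop, np.zeros(8), [tri])


class TestPipeline:
    def test_noise_free_architecture_recovered_exactly(self):
        cfg = anchor_config(77, delta=0.8, sigma_e=0.0)
        pop = simulate_population(cfg)
        run = estimate_aaa_genotypic(pop, pop.traits[0])
        assert run.estimate.aaa_g == pytest.approx(0.8, abs=1e-8)
        true = term(("chr1_m010", "chr2_m010", "chr3_m010"), pop)
        assert true in [t for t, *_ in run.estimate.per_triple]

    def test_empty_selection_yields_ns(self, factorial3):
        rng = np.random.default_rng(0)
        y = trait(factorial3, rng.normal(size=8) * 0.01)
        run = estimate_aaa_genotypic(factorial3, y)
        assert run.estimate.ns_flag

    def test_bonferroni_scope_config(self):
        pop = simulate_population(anchor_config(88))
        run_c = estimate_aaa_genotypic(pop, pop.traits[0], bonferroni_scope="candidates")
        run_m = estimate_aaa_genotypic(pop, pop.traits[0], bonferroni_scope="model")
        assert run_c.estimate.m_tests >= run_m.estimate.m_tests
        with pytest.raises(ConfigurationError):
            estimate_aaa_genotypic(pop, pop.traits[0], bonferroni_scope="fdr")
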