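import numpy as np
import pandas as pd
import pytest
from scipy import stats

from eigenchoice import (
    CANDIDATE_GENES,
    EigengeneMatrix,
    SimConfig,
    anova_type2,
    candidate_gene_models,
    de_test,
    estimate_size_factors,
    fit_interaction_model,
    module_contrasts,
    simulate_dataset,
    trait_pca,
    vst,
    welch_ttest,
)
from eigenchoice.datatypes import ExpressionMatrix
from eigenchoice.errors import DataError

from conftest import make_samples


class TestTraitPca:
    def test_perfectly_correlated_block(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=20)
        traits = pd.DataFrame(
            {"Fbehav_1": base, "Fbehav_2": 3 * base + 1},
            index=[f"s{i}" for i in range(20)],
        )
        pcs = trait_pca(traits)
        assert pcs.variance_explained["Fbehav"][0] == pytest.approx(1.0)

    def test_matches_svd_oracle(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(25, 5))
        traits = pd.DataFrame(
            X, columns=[f"Mmorph_{j}" for j in range(5)],
            index=[f"s{i}" for i in range(25)],
        )
        pcs = trait_pca(traits)
        Xs = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
        U, S, Vt = np.linalg.svd(Xs, full_matrices=False)
        for j in (0, 1):
            oracle = U[:, j] * S[j]
            mine = pcs.scores[f"Mmorph_PC{j + 1}"].to_numpy()
            agreement = abs(np.corrcoef(oracle, mine)[0, 1])
            assert agreement == pytest.approx(1.0, abs=1e-10)

    def test_control_rows_get_missing_male_scores(self):
        config = SimConfig(n_genes=40, module_sizes=(10,), n_per_cell=3, seed=2)
        _, samples, traits, _ = simulate_dataset(config)
        pcs = trait_pca(traits)
        control = samples.loc[samples["treatment"] == "female_control", "sample_id"]
        assert pcs.scores.loc[control, "Mmorph_PC1"].isna().all()
        assert pcs.scores.loc[control, "Fbehav_PC1"].notna().all()
        # each PC is centred over its analysis set
        assert abs(pcs.scores["Mmorph_PC1"].dropna().mean()) < 1e-10

    def test_too_few_nonconstant_columns(self):
        traits = pd.DataFrame(
            {"Fbehav_1": np.arange(10.0), "Fbehav_2": 1.0},
            index=[f"s{i}" for i in range(10)],
        )
        with pytest.raises(DataError, match="non-constant"):
            trait_pca(traits)


class TestWelch:
    def test_hand_computed_oracle(self):
        # frozen by hand: means 2.5 / 4.5, each variance 5/3,
        # se^2 = 2 * (5/3)/4 = 5/6, t = -2 / sqrt(5/6), df = 6 exactly
        t, df, p = welch_ttest([1, 2, 3, 4], [3, 4, 5, 6])
        assert t == pytest.approx(-2.190890, abs=1e-5)
        assert df == pytest.approx(6.0, abs=1e-9)
        assert 0.06 < p < 0.08

    def test_equal_samples(self):
        x = np.array([1.0, 2.0, 5.0])
        t, df, p = welch_ttest(x, x)
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_antisymmetry(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=10), rng.normal(1, 1, size=12)
        t1, df1, p1 = welch_ttest(x, y)
        t2, df2, p2 = welch_ttest(y, x)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)
        assert df1 == pytest.approx(df2)

    def test_tiny_group_error(self):
        with pytest.raises(DataError):
            welch_ttest([1.0], [2.0, 3.0])


class TestModuleContrasts:
    def _eigengenes(self, samples, shift_module=None, shift_pop=None, rng=None):
        rng = rng or np.random.default_rng(4)
        data = pd.DataFrame(
            rng.normal(size=(len(samples), 3)),
            index=samples["sample_id"],
            columns=["M1", "M2", "M3"],
        )
        if shift_module:
            in_pop = samples.set_index("sample_id")["population"] == shift_pop
            data.loc[in_pop, shift_module] += 3.0
        data -= data.mean(axis=0)
        return EigengeneMatrix(data, pd.Series(0.5, index=data.columns))

    def test_contrast_count(self):
        pops = ["a"] * 9 + ["b"] * 9 + ["c"] * 9
        treats = (["con"] * 3 + ["het"] * 3 + ["fem"] * 3) * 3
        samples = make_samples(pops, treats)
        eig = self._eigengenes(samples)
        table = module_contrasts(eig, samples)
        # 3 modules x (2 population contrasts + 3 treatment pairs x 3 pops)
        assert len(table) == 3 * (2 + 3 * 3)

    def test_planted_population_shift_detected(self):
        pops = ["a"] * 12 + ["b"] * 12 + ["c"] * 12
        samples = make_samples(pops)
        eig = self._eigengenes(samples, shift_module="M1", shift_pop="b")
        table = module_contrasts(eig, samples)
        hit = table[(table["module"] == "M1") & (table["contrast"] == "a vs b")]
        assert hit["p"].iloc[0] < 0.01
        others = table[~((table["module"] == "M1") & (table["contrast"].str.contains("b")))]
        assert (others["p"] > 1e-4).all()

    def test_empty_cells_skipped(self):
        pops = ["a"] * 6 + ["b"] * 6
        treats = ["con"] * 6 + ["het"] * 6  # no 'fem' anywhere, no cross cells
        samples = make_samples(pops, treats)
        eig = self._eigengenes(samples)
        table = module_contrasts(eig, samples)
        # within-population treatment contrasts all have an empty side
        assert (table["contrast_type"] == "population").all()


class TestInteractionModel:
    def _planted(self, b, n_per_pop=12, seed=0, sigma=1.0):
        rng = np.random.default_rng(seed)
        pops = ["a"] * n_per_pop + ["b"] * n_per_pop + ["c"] * n_per_pop
        trait = rng.normal(size=len(pops))
        slope = np.where(np.array(pops) == "a", b, np.where(np.array(pops) == "b", -b, 0.0))
        y = slope * trait + sigma * rng.normal(size=len(pops))
        samples = make_samples(pops)
        ids = samples["sample_id"]
        return (
            pd.Series(y, index=ids),
            samples,
            pd.Series(trait, index=ids),
        )

    def test_equal_slopes_zero_interaction_ss(self):
        rng = np.random.default_rng(5)
        pops = ["a"] * 8 + ["b"] * 8
        trait = rng.normal(size=16)
        y = 2.0 * trait  # identical slope, no noise, no population offset
        samples = make_samples(pops)
        fit = fit_interaction_model(
            pd.Series(y, index=samples["sample_id"]), samples,
            pd.Series(trait, index=samples["sample_id"]),
        )
        interaction = [r for r in anova_type2(fit) if r.term == "population:trait"][0]
        assert interaction.F == pytest.approx(0.0, abs=1e-8)

    def test_opposing_slopes_power(self):
        hits = 0
        for seed in range(10):
            y, samples, trait = self._planted(b=1.5, seed=seed)
            fit = fit_interaction_model(y, samples, trait)
            res = {r.term: r for r in anova_type2(fit)}
            hits += res["population:trait"].p_param < 0.01
        assert hits >= 8

    def test_coefficients_match_normal_equations(self):
        y, samples, trait = self._planted(b=1.0, n_per_pop=7, seed=9)
        fit = fit_interaction_model(y, samples, trait)
        # independent solve of the normal equations
        pops = samples["population"].to_numpy()
        t = trait.to_numpy()
        X = np.column_stack([
            np.ones(len(t)), pops == "b", pops == "c", t,
            (pops == "b") * t, (pops == "c") * t,
        ]).astype(float)
        beta = np.linalg.solve(X.T @ X, X.T @ y.to_numpy())
        np.testing.assert_allclose(fit.coefficients.to_numpy(), beta, atol=1e-10)

    def test_missing_trait_defines_analysis_set(self):
        y, samples, trait = self._planted(b=0.0, n_per_pop=6, seed=10)
        trait.iloc[:4] = np.nan
        fit = fit_interaction_model(y, samples, trait)
        assert fit.n == len(y) - 4
        assert set(fit.sample_ids) == set(trait.dropna().index)

    def test_single_sample_population_error(self):
        y, samples, trait = self._planted(b=0.0, n_per_pop=5, seed=11)
        samples.loc[samples.index[-1], "population"] = "lonely"
        with pytest.raises(DataError, match="lonely"):
            fit_interaction_model(y, samples, trait)


class TestAnovaTypeII:
    def test_matches_statsmodels_on_unbalanced_design(self):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(42)
        pops = np.repeat(["a", "b", "c"], [8, 11, 7])
        trait = rng.normal(size=len(pops))
        y = rng.normal(size=len(pops)) + 0.5 * trait + (pops == "b") * 1.0
        samples = make_samples(pops)
        ids = samples["sample_id"]
        fit = fit_interaction_model(
            pd.Series(y, index=ids), samples, pd.Series(trait, index=ids)
        )
        mine = {r.term: r for r in anova_type2(fit)}

        ref = sm.stats.anova_lm(
            smf.ols(
                "y ~ C(population) * trait",
                data=pd.DataFrame({"y": y, "population": pops, "trait": trait}),
            ).fit(),
            typ=2,
        )
        assert mine["population"].F == pytest.approx(ref.loc["C(population)", "F"], rel=1e-9)
        assert mine["trait"].F == pytest.approx(ref.loc["trait", "F"], rel=1e-9)
        assert mine["population:trait"].F == pytest.approx(
            ref.loc["C(population):trait", "F"], rel=1e-9
        )
        for term, row in (
            ("population", "C(population)"),
            ("trait", "trait"),
            ("population:trait", "C(population):trait"),
        ):
            assert mine[term].p_param == pytest.approx(ref.loc[row, "PR(>F)"], rel=1e-9)

    def test_balanced_orthogonal_equals_sequential(self):
        rng = np.random.default_rng(6)
        pops = np.repeat(["a", "b", "c"], 8)
        raw = rng.normal(size=24)
        # orthogonalize the covariate against population dummies
        trait = raw - pd.Series(raw).groupby(pops).transform("mean").to_numpy()
        y = rng.normal(size=24)
        samples = make_samples(pops)
        ids = samples["sample_id"]
        fit = fit_interaction_model(
            pd.Series(y, index=ids), samples, pd.Series(trait, index=ids)
        )
        mine = {r.term: r for r in anova_type2(fit)}

        # sequential RSS chain oracle
        from eigenchoice.models import _design_matrix, _rss

        rss1, _ = _rss(np.ones((24, 1)), y)
        rss_pop, _ = _rss(_design_matrix(pops, trait, "population"), y)
        rss_add, _ = _rss(_design_matrix(pops, trait, "additive"), y)
        seq_pop = rss1 - rss_pop
        seq_trait = rss_pop - rss_add
        mse = fit.rss / fit.df_resid
        assert mine["population"].F == pytest.approx((seq_pop / 2) / mse, rel=1e-9)
        assert mine["trait"].F == pytest.approx((seq_trait / 1) / mse, rel=1e-9)

    def test_null_calibration(self):
        rng = np.random.default_rng(7)
        pops = np.repeat(["a", "b", "c"], 12)
        samples = make_samples(pops)
        ids = samples["sample_id"]
        pvals = {"population": [], "trait": [], "population:trait": []}
        for _ in range(500):
            trait = rng.normal(size=36)
            y = rng.normal(size=36)
            fit = fit_interaction_model(
                pd.Series(y, index=ids), samples, pd.Series(trait, index=ids)
            )
            for r in anova_type2(fit):
                pvals[r.term].append(r.p_param)
        for term, ps in pvals.items():
            assert stats.kstest(ps, "uniform").pvalue > 0.01, term

    def test_population_label_permutation_invariance(self):
        rng = np.random.default_rng(8)
        pops = np.repeat(["a", "b", "c"], [6, 8, 10])
        trait = rng.normal(size=24)
        y = rng.normal(size=24)
        samples = make_samples(pops)
        ids = samples["sample_id"]
        relabel = {"a": "z_pop", "b": "m_pop", "c": "a_pop"}
        samples2 = samples.copy()
        samples2["population"] = samples2["population"].map(relabel)
        f1 = {
            r.term: r.F for r in anova_type2(
                fit_interaction_model(pd.Series(y, index=ids), samples, pd.Series(trait, index=ids))
            )
        }
        f2 = {
            r.term: r.F for r in anova_type2(
                fit_interaction_model(pd.Series(y, index=ids), samples2, pd.Series(trait, index=ids))
            )
        }
        for term in f1:
            assert f1[term] == pytest.approx(f2[term], rel=1e-9)

    def test_trait_centering_invariance(self):
        rng = np.random.default_rng(9)
        pops = np.repeat(["a", "b"], 10)
        trait = rng.normal(5.0, 1.0, size=20)
        y = rng.normal(size=20)
        samples = make_samples(pops)
        ids = samples["sample_id"]
        f_raw = {
            r.term: r.F for r in anova_type2(
                fit_interaction_model(pd.Series(y, index=ids), samples, pd.Series(trait, index=ids))
            )
        }
        f_centred = {
            r.term: r.F for r in anova_type2(
                fit_interaction_model(
                    pd.Series(y, index=ids), samples, pd.Series(trait - trait.mean(), index=ids)
                )
            )
        }
        assert f_raw["population:trait"] == pytest.approx(
            f_centred["population:trait"], rel=1e-9
        )


class TestCandidateGenes:
    def test_catalog_shape(self):
        symbols = [g for genes in CANDIDATE_GENES.values() for g in genes]
        assert len(symbols) == 24
        assert len(set(symbols)) == 24
        assert len(CANDIDATE_GENES) == 5

    def _dataset_with_alias(self):
        config = SimConfig(
            n_genes=150, module_sizes=(40,), n_per_cell=6, seed=30,
            within_module_cor=0.8,
            trait_slope={(0, "paxton_limnetic"): 1.5, (0, "paxton_benthic"): -1.5},
        )
        counts, samples, traits, truth = simulate_dataset(config)
        expr = vst(counts, estimate_size_factors(counts))
        # alias one planted-module gene to a candidate symbol
        renamed = expr.data.rename(index={expr.gene_ids[0]: "gnrh2"})
        expr = ExpressionMatrix(renamed, expr.transform_tag)
        return expr, samples, traits, truth

    def test_interaction_detected_for_aliased_gene(self):
        expr, samples, traits, truth = self._dataset_with_alias()
        pcs = trait_pca(traits)
        table, unmapped = candidate_gene_models(expr, samples, pcs)
        assert "gnrh2" not in unmapped
        # Mmorph PC1 tracks the simulated male trait, so the planted
        # opposing-slope interaction should surface for the aliased gene
        hit = table[
            (table["response"] == "gnrh2")
            & (table["trait"] == "Mmorph_PC1")
            & (table["term"] == "population:trait")
        ]
        assert hit["p_param"].iloc[0] < 0.01

    def test_unmapped_symbols_reported_and_counts(self):
        expr, samples, traits, _ = self._dataset_with_alias()
        pcs = trait_pca(traits)
        table, unmapped = candidate_gene_models(expr, samples, pcs)
        assert set(unmapped) == {
            g for genes in CANDIDATE_GENES.values() for g in genes
        } - {"gnrh2"}
        n_models = table[["response", "trait"]].drop_duplicates()
        assert len(n_models) == 1 * 6  # 1 mapped gene x 6 trait PCs
        assert len(table) == 6 * 3  # three terms per model


class TestDeTest:
    def test_identical_groups_near_zero_log2fc(self):
        config = SimConfig(
            n_genes=100, module_sizes=(10,), n_per_cell=6, seed=31,
            gene_log_sd=0.2, nb_dispersion=0.02,
        )
        counts, samples, *_ = simulate_dataset(config)
        table, _ = de_test(counts, samples)
        assert abs(table["log2fc"].mean()) < 0.05

    def test_bh_monotonicity(self):
        config = SimConfig(n_genes=150, module_sizes=(10,), n_per_cell=4, seed=32)
        counts, samples, *_ = simulate_dataset(config)
        table, _ = de_test(counts, samples)
        one = table[table["contrast"] == table["contrast"].iloc[0]].sort_values("p")
        assert (one["padj"].to_numpy() >= one["p"].to_numpy() - 1e-12).all()
        assert (np.diff(one["padj"].to_numpy()) >= -1e-12).all()

    def test_all_zero_gene_excluded(self):
        config = SimConfig(n_genes=60, module_sizes=(10,), n_per_cell=3, seed=33)
        counts, samples, *_ = simulate_dataset(config)
        data = counts.data.copy()
        data.iloc[5] = 0
        from eigenchoice import CountMatrix

        table, excluded = de_test(CountMatrix(data), samples)
        assert excluded == [counts.gene_ids[5]]
        assert counts.gene_ids[5] not in set(table["gene"])

    def test_planted_fold_change_recovered(self):
        config = SimConfig(
            n_genes=500, module_sizes=(25, 25), within_module_cor=0.3,
            n_per_cell=6, seed=34, gene_log_sd=0.3, nb_dispersion=0.05,
            treatment_effect={(0, "conspecific"): 2.0, (1, "conspecific"): -2.0},
        )
        counts, samples, _, truth = simulate_dataset(config)
        table, _ = de_test(counts, samples)
        con = table[table["contrast"] == "treatment: female_control vs conspecific"]
        sig = set(con.loc[con["significant"], "gene"])
        tp = sig & truth.true_de_genes
        assert len(tp) / len(truth.true_de_genes) >= 0.8
        assert (len(sig) - len(tp)) / max(len(sig), 1) <= 0.2
        planted_up = truth.module_of_gene.genes_in("M1")
        est = con.set_index("gene").loc[planted_up, "log2fc"]
        # control-minus-conspecific, so planted +2 appears as -2
        assert est.mean() == pytest.approx(-2.0, abs=0.25)
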