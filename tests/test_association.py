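import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from oracles import (
    best_two_partition,
    exact_fisher_two_sided,
    naive_benjamini_hochberg,
    spearman_rho_from_ranks,
)

from agewire.association import (
    associate_cohort,
    benjamini_hochberg,
    bin_ages,
    bin_means,
    call_significant,
    class_proportion_test,
    fit_covariance_model,
    hierarchical_clusters,
    merge_nonredundant,
    sex_difference_summary,
    spearman_with_age,
)
from agewire.errors import InputError


AGES6 = np.array([10.0, 20.0, 30.0, 40.0, 50.0, 60.0])
SEXES6 = np.array(["male", "female"] * 3)


class TestFitCovarianceModel:
    def test_affine_transform_of_y_leaves_pvalues_unchanged(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=12)
        ages = rng.uniform(1, 85, 12)
        sexes = np.array(["male"] * 6 + ["female"] * 6)
        assert fit_covariance_model(y, ages, sexes) == pytest.approx(
            fit_covariance_model(10 * y + 7, ages, sexes)
        )

    def test_strong_age_trend_on_fixed_vector(self):
        y = np.array([2.1, 3.9, 6.2, 7.8, 10.1, 11.9])
        p_age, p_sex = fit_covariance_model(y, AGES6, SEXES6)
        assert p_age < 0.001

    def test_matches_statsmodels_ols(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(1)
        ages = rng.uniform(1, 85, 40)
        sexes = np.where(rng.random(40) < 0.5, "male", "female")
        if len(set(sexes)) < 2:
            sexes[0] = "male" if sexes[0] == "female" else "female"
        y = 5 + 0.02 * ages + 0.3 * (sexes == "male") + rng.normal(0, 1, 40)
        p_age, p_sex = fit_covariance_model(y, ages, sexes)
        X = sm.add_constant(
            np.column_stack([ages, (sexes == "male").astype(float)])
        )
        fit = sm.OLS(y, X).fit()
        assert p_age == pytest.approx(fit.pvalues[1], rel=1e-9)
        assert p_sex == pytest.approx(fit.pvalues[2], rel=1e-9)

    def test_single_sex_design_is_singular(self):
        with pytest.raises(InputError, match="sex"):
            fit_covariance_model(
                np.arange(6.0), AGES6, np.array(["male"] * 6)
            )

    def test_constant_age_design_is_singular(self):
        with pytest.raises(InputError, match="age"):
            fit_covariance_model(np.arange(6.0), np.full(6, 40.0), SEXES6)

    def test_constant_expression_warns_and_returns_nan(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            p_age, p_sex = fit_covariance_model(np.full(6, 3.0), AGES6, SEXES6)
        assert np.isnan(p_age) and np.isnan(p_sex)


class TestBenjaminiHochberg:
    def test_step_up_worked_example(self):
        np.testing.assert_allclose(
            benjamini_hochberg([0.01, 0.02, 0.03, 0.04]), [0.04] * 4
        )

    def test_single_value_is_identity(self):
        np.testing.assert_allclose(benjamini_hochberg([0.5]), [0.5])

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            benjamini_hochberg([0.1, 1.2])

    def test_matches_naive_reference(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            p = rng.uniform(0, 1, rng.integers(1, 60))
            np.testing.assert_allclose(
                benjamini_hochberg(p), naive_benjamini_hochberg(p), atol=1e-12
            )

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(3)
        p = rng.uniform(0, 1, 200)
        np.testing.assert_allclose(
            benjamini_hochberg(p),
            multipletests(p, method="fdr_bh")[1],
            atol=1e-12,
        )

    @given(st.permutations(range(8)))
    def test_permutation_equivariance(self, perm):
        p = np.array([0.001, 0.2, 0.2, 0.04, 0.9, 0.5, 0.011, 0.33])
        perm = np.array(perm)
        np.testing.assert_allclose(
            benjamini_hochberg(p[perm]), benjamini_hochberg(p)[perm]
        )


class TestSpearmanWithAge:
    def test_perfect_monotone_directions(self):
        ages = np.array([1.0, 5.0, 9.0, 20.0, 40.0])
        inc = np.array([0.1, 0.4, 1.2, 3.3, 9.0])
        assert spearman_with_age(inc, ages)[0] == pytest.approx(1.0)
        assert spearman_with_age(inc[::-1], ages)[0] == pytest.approx(-1.0)

    def test_rank_formula_worked_example(self):
        ages = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([10.0, 30.0, 20.0, 40.0])
        rho, p = spearman_with_age(y, ages)
        assert rho == pytest.approx(0.8)
        assert rho == pytest.approx(spearman_rho_from_ranks(y, ages))
        # exact permutation p at n=4: sum(d^2) <= 2 or >= 18 in 8 of the 24
        # rank permutations, so P(|rho| >= 0.8) = 8/24
        assert p == pytest.approx(8 / 24)

    def test_agrees_with_scipy_at_large_n(self):
        rng = np.random.default_rng(4)
        ages = rng.uniform(1, 85, 60)
        y = 0.02 * ages + rng.normal(0, 1, 60)
        rho, p = spearman_with_age(y, ages)
        ref = stats.spearmanr(y, ages)
        assert rho == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_constant_vector_warns(self):
        with pytest.warns(UserWarning):
            rho, _ = spearman_with_age(np.ones(6), np.arange(6.0))
        assert np.isnan(rho)


def _mini_table(p_age, q_age, rho=0.5, p_sex=0.9, q_sex=0.9):
    return pd.DataFrame(
        {
            "beta_age": [0.01],
            "beta_sex": [0.0],
            "p_age": [p_age],
            "p_sex": [p_sex],
            "rho": [rho],
            "p_rho": [0.5],
            "q_age": [q_age],
            "q_sex": [q_sex],
            "q_rho": [0.5],
        },
        index=["G1"],
    )


class TestCallSignificant:
    @pytest.mark.parametrize(
        "p,q,expected",
        [
            (0.0005, 0.01, True),
            (0.0011, 0.01, False),
            (0.001, 0.01, False),  # strict inequality at the threshold
            (0.0005, 0.06, False),
        ],
    )
    def test_conjunctive_rule_and_boundary(self, p, q, expected):
        out = call_significant(_mini_table(p, q))
        assert bool(out["sig_age"].iloc[0]) is expected

    def test_direction_is_rho_sign_only_when_significant(self):
        sig = call_significant(_mini_table(0.0001, 0.01, rho=-0.7))
        assert sig["direction"].iloc[0] == -1
        insig = call_significant(_mini_table(0.5, 0.9, rho=-0.7))
        assert insig["direction"].iloc[0] == 0

    def test_monotone_in_p(self):
        """Lowering a gene's p-value never removes significance."""
        base = call_significant(_mini_table(0.0009, 0.04))
        lower = call_significant(_mini_table(0.0001, 0.04))
        assert bool(lower["sig_age"].iloc[0]) >= bool(base["sig_age"].iloc[0])


def _sig_table(genes_rho: dict, sig: bool = True):
    frame = pd.DataFrame(
        {
            "beta_age": 0.01,
            "beta_sex": 0.0,
            "p_age": 1e-5,
            "p_sex": 0.9,
            "rho": pd.Series(genes_rho),
            "p_rho": 1e-5,
            "q_age": 0.01,
            "q_sex": 0.9,
            "q_rho": 0.01,
        }
    )
    frame["sig_age"] = sig
    frame["sig_sex"] = False
    frame["direction"] = np.sign(frame["rho"]).astype(int)
    return frame


class TestMergeNonredundant:
    def test_union_over_cohorts(self):
        merged = merge_nonredundant(
            {
                "c1": _sig_table({"A": 0.5, "B": 0.4}),
                "c2": _sig_table({"B": 0.3, "C": 0.6}),
            }
        )
        assert sorted(merged["gene"]) == ["A", "B", "C"]
        b = merged.set_index("gene").loc["B"]
        assert b["cohorts"] == "c1,c2"

    def test_empty_cohorts_give_empty_set(self):
        merged = merge_nonredundant({"c1": _sig_table({"A": 0.5}, sig=False)})
        assert merged.empty

    def test_direction_conflict_resolved_by_larger_rho(self):
        merged = merge_nonredundant(
            {"c1": _sig_table({"A": 0.4}), "c2": _sig_table({"A": -0.2})}
        )
        assert merged["direction"].iloc[0] == 1
        assert merged["cohorts"].iloc[0] == "c1,c2"

    def test_exact_tie_warns_and_reports_zero(self):
        with pytest.warns(UserWarning, match="tie"):
            merged = merge_nonredundant(
                {"c1": _sig_table({"A": 0.4}), "c2": _sig_table({"A": -0.4})}
            )
        assert merged["direction"].iloc[0] == 0

    def test_idempotent_and_order_invariant(self):
        tables = {
            "c1": _sig_table({"A": 0.5, "B": -0.4}),
            "c2": _sig_table({"B": 0.3, "C": 0.6}),
        }
        forward = merge_nonredundant(tables)
        backward = merge_nonredundant(dict(reversed(list(tables.items()))))
        pd.testing.assert_frame_equal(forward, backward)
        again = merge_nonredundant({"c1": tables["c1"], "c1b": tables["c1"]})
        sub = merge_nonredundant({"c1": tables["c1"]})
        assert list(again["gene"]) == list(sub["gene"])
        assert list(again["direction"]) == list(sub["direction"])


class TestClassProportionTest:
    @staticmethod
    def _catalog(n_a, n_b):
        return pd.DataFrame(
            {
                "symbol": [f"A{i}" for i in range(n_a)] + [f"B{i}" for i in range(n_b)],
                "class": ["RBP"] * n_a + ["TF"] * n_b,
            }
        )

    def test_complete_separation(self):
        catalog = self._catalog(5, 5)
        merged = pd.DataFrame({"gene": [f"A{i}" for i in range(5)]})
        p = class_proportion_test(catalog, merged, "RBP", "TF")
        assert p == pytest.approx(2 / 252)

    def test_identical_proportions_give_p_one(self):
        catalog = self._catalog(10, 10)
        merged = pd.DataFrame(
            {"gene": [f"A{i}" for i in range(5)] + [f"B{i}" for i in range(5)]}
        )
        assert class_proportion_test(catalog, merged, "RBP", "TF") == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n_a, n_b = rng.integers(2, 11, 2)
            catalog = self._catalog(n_a, n_b)
            k_a = rng.integers(0, n_a + 1)
            k_b = rng.integers(0, n_b + 1)
            merged = pd.DataFrame(
                {
                    "gene": [f"A{i}" for i in range(k_a)]
                    + [f"B{i}" for i in range(k_b)]
                }
            )
            got = class_proportion_test(catalog, merged, "RBP", "TF")
            want = exact_fisher_two_sided([[k_a, n_a - k_a], [k_b, n_b - k_b]])
            assert got == pytest.approx(want, rel=1e-9)

    def test_empty_class_rejected(self):
        catalog = self._catalog(5, 5)
        with pytest.raises(InputError):
            class_proportion_test(catalog, pd.DataFrame({"gene": []}), "RBP", "other")


class TestSexDifferenceSummary:
    @staticmethod
    def _tiny(male_vals, female_vals):
        values = list(male_vals) + list(female_vals)
        cols = [f"s{i}" for i in range(len(values))]
        expr = pd.DataFrame([values], index=["G1"], columns=cols)
        meta = pd.DataFrame(
            {
                "sample_id": cols,
                "age": np.linspace(20, 60, len(values)),
                "sex": ["male"] * len(male_vals) + ["female"] * len(female_vals),
                "cohort": "c",
            }
        )
        return expr, meta

    def test_exact_separated_example(self):
        expr, meta = self._tiny([5, 6, 7], [1, 2, 3])
        out = sex_difference_summary(expr, meta, ["G1"])
        assert out.loc["G1", "p"] == pytest.approx(0.1)
        assert out.loc["G1", "median_male"] == 6
        assert out.loc["G1", "median_female"] == 2

    def test_identical_distributions_give_p_one(self):
        expr, meta = self._tiny([1, 2, 3], [1, 2, 3])
        out = sex_difference_summary(expr, meta, ["G1"])
        assert out.loc["G1", "p"] == pytest.approx(1.0)

    def test_shift_invariance_of_p(self):
        expr, meta = self._tiny([5.0, 6.5, 7.1], [1.2, 2.4, 3.3])
        p1 = sex_difference_summary(expr, meta, ["G1"]).loc["G1", "p"]
        p2 = sex_difference_summary(expr + 100.0, meta, ["G1"]).loc["G1", "p"]
        assert p1 == pytest.approx(p2)

    def test_tiny_sex_group_flagged(self):
        expr, meta = self._tiny([5, 6, 7], [1])
        out = sex_difference_summary(expr, meta, ["G1"])
        assert np.isnan(out.loc["G1", "p"])
        assert out.loc["G1", "flag"] == "sex_group_too_small"


class TestAgeBinning:
    @staticmethod
    def _meta(ages):
        sexes = (["male", "female"] * (len(ages) // 2 + 1))[: len(ages)]
        return pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(len(ages))],
                "age": ages,
                "sex": sexes,
            }
        )

    def test_half_open_boundary(self):
        bins = bin_ages(self._meta([19.9, 20.0]))
        assert bins.iloc[0] == "[0,20)"
        assert bins.iloc[1] == "[20,40)"

    def test_distinct_bins(self):
        bins = bin_ages(self._meta([5.0, 25.0, 45.0]))
        assert bins.nunique() == 3

    def test_age_120_falls_in_closed_last_bin(self):
        bins = bin_ages(self._meta([119.0, 120.0]))
        assert set(bins) == {"[100,120]"}

    def test_bin_means_of_constant_gene(self):
        meta = self._meta([5.0, 25.0, 45.0, 47.0])
        expr = pd.DataFrame(
            [[4.2, 4.2, 4.2, 4.2]], index=["G1"], columns=meta["sample_id"]
        )
        means = bin_means(expr, bin_ages(meta))
        assert (means.loc["G1"] == 4.2).all()
        assert list(means.columns) == ["[0,20)", "[20,40)", "[40,60)"]


class TestHierarchicalClusters:
    def test_duplicated_profiles_separate_perfectly(self):
        a = [1.0, 5.0, 2.0, 8.0]
        b = [9.0, 2.0, 7.0, 1.0]
        m = pd.DataFrame([a, a, a, b, b, b], index=list("abcdef"))
        labels = hierarchical_clusters(m, k=2)
        assert labels["a"] == labels["b"] == labels["c"]
        assert labels["d"] == labels["e"] == labels["f"]
        assert labels["a"] != labels["d"]

    def test_row_affine_transforms_do_not_change_labels(self):
        rng = np.random.default_rng(6)
        m = pd.DataFrame(rng.normal(size=(8, 5)), index=list("abcdefgh"))
        base = hierarchical_clusters(m, k=3)
        scaled = m.mul(np.arange(1, 9), axis=0).add(np.arange(8) * 10.0, axis=0)
        pd.testing.assert_series_equal(base, hierarchical_clusters(scaled, k=3))

    def test_two_block_structure_matches_exhaustive_partition(self):
        rng = np.random.default_rng(7)
        base1 = rng.normal(size=6)
        base2 = -base1
        rows = [base1 + rng.normal(0, 0.05, 6) for _ in range(3)]
        rows += [base2 + rng.normal(0, 0.05, 6) for _ in range(3)]
        m = pd.DataFrame(rows, index=list("abcdef"))
        labels = hierarchical_clusters(m, k=2)
        got = frozenset(
            frozenset(i for i, g in enumerate(m.index) if labels[g] == c)
            for c in set(labels)
        )
        z = m.to_numpy()
        z = (z - z.mean(1, keepdims=True)) / z.std(1, keepdims=True)
        dist = 1 - np.corrcoef(z)
        assert got == best_two_partition(dist)

    def test_constant_row_goes_to_residual_cluster(self):
        m = pd.DataFrame(
            [[1.0, 2.0, 3.0], [3.0, 1.0, 2.0], [5.0, 5.0, 5.0], [2, 3, 1]],
            index=list("abcd"),
        )
        with pytest.warns(UserWarning, match="constant"):
            labels = hierarchical_clusters(m, k=2)
        assert labels["c"] == 0
        assert set(labels[["a", "b", "d"]]) <= {1, 2}


class TestAssociateCohort:
    def test_recovers_planted_effects(self, small_cohort):
        expr, meta, truth = small_cohort
        table = associate_cohort(expr, meta)
        truth = truth.set_index("gene")
        age_true = set(truth.index[truth["age_effect"] != 0])
        called = set(table.index[table["sig_age"]])
        recall = len(called & age_true) / len(age_true)
        assert recall >= 0.9
        # directions agree with planted slope signs for recovered genes
        for gene in called & age_true:
            assert table.loc[gene, "direction"] == np.sign(
                truth.loc[gene, "age_effect"]
            )
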