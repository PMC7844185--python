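"""All-subsets enumeration, design coding, CV error, and the search."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import maternalcv as m
from maternalcv.model_search import (
    _sweep_gram,
    _sweep_naive,
    model_column_indices,
)


class TestEnumeration:
    def test_counts(self):
        assert len(m.enumerate_models(m.default_catalog())) == 32768
        sub = m.default_catalog(("resilience", "life_stress", "work_stress"))
        assert len(m.enumerate_models(sub)) == 8

    def test_canonical_order_starts_with_intercept_only(self):
        sub = m.default_catalog(("resilience", "life_stress"))
        models = m.enumerate_models(sub)
        assert models[0].mask == 0 and models[0].factors == ()
        assert [mm.mask for mm in models] == list(range(4))

    def test_formula_string(self):
        sub = m.default_catalog(("resilience", "life_stress"))
        models = m.enumerate_models(sub)
        assert models[3].formula() == "mental_health ~ 1 + resilience + life_stress"


class TestDesignMatrix:
    def test_full_catalog_column_count(self, cn_scored):
        # 4+2+3+2+3-level categoricals -> 3+1+2+1+2 dummies, plus 10
        # continuous/binary columns and the intercept
        X, blocks, names = m.build_design_matrix(cn_scored, m.default_catalog())
        assert X.shape[1] == 20
        assert names[0] == "intercept"
        sizes = {name: len(cols) for name, cols in blocks.items()}
        assert sizes["maternal_age"] == 3
        assert sizes["education"] == 2
        assert sizes["grandparental_support"] == 1
        all_cols = np.concatenate(list(blocks.values()))
        assert sorted(all_cols) == list(range(1, 20))  # disjoint blocks

    def test_unseen_level_is_schema_error(self, cn_scored):
        bad = cn_scored.copy()
        bad.loc[bad.index[0], "education"] = "doctorate"
        with pytest.raises(ValueError, match="doctorate"):
            m.build_design_matrix(bad, m.default_catalog())

    def test_categorical_block_enters_whole(self, cn_scored):
        X, blocks, _ = m.build_design_matrix(cn_scored, m.default_catalog())
        model = [mm for mm in m.enumerate_models(m.default_catalog())
                 if mm.factors == ("education",)][0]
        cols = model_column_indices(model, blocks)
        assert list(cols) == [0] + list(blocks["education"])


class TestFoldPartition:
    def test_balanced_folds(self):
        fold = m.make_fold_partition(900, 10, seed=1)
        assert np.bincount(fold).tolist() == [90] * 10

    def test_uneven_sizes_differ_by_at_most_one(self):
        sizes = np.bincount(m.make_fold_partition(23, 10, seed=2))
        assert sizes.sum() == 23 and set(sizes) <= {2, 3}

    def test_deterministic(self):
        np.testing.assert_array_equal(
            m.make_fold_partition(50, 5, seed=3),
            m.make_fold_partition(50, 5, seed=3),
        )

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            m.make_fold_partition(5, 10, seed=0)

    @given(st.integers(10, 200), st.integers(2, 10))
    def test_every_row_assigned_once(self, n, k):
        fold = m.make_fold_partition(n, k, seed=n * 31 + k)
        assert fold.shape == (n,)
        assert fold.min() >= 0 and fold.max() == k - 1
        assert np.ptp(np.bincount(fold)) <= 1


class TestCvRmse:
    def test_two_point_fit_predicts_heldout_exactly(self):
        # y = 2x: training pairs always contain both x levels
        y = np.array([0.0, 0.0, 2.0, 2.0])
        X = np.column_stack([np.ones(4), [0.0, 0.0, 1.0, 1.0]])
        partition = np.array([0, 1, 0, 1])
        assert m.cv_rmse(y, X, [0, 1], partition) == pytest.approx(0.0, abs=1e-12)

    def test_intercept_only_single_row_folds(self):
        # each training mean mispredicts the held-out row by 2
        y = np.array([0.0, 2.0])
        X = np.ones((2, 1))
        partition = np.array([0, 1])
        assert m.cv_rmse(y, X, [0], partition) == pytest.approx(2.0)

    def test_saturated_model_attains_zero(self):
        rng = np.random.default_rng(4)
        X = np.column_stack([np.ones(40), rng.standard_normal((40, 2))])
        beta = np.array([1.0, -2.0, 0.5])
        y = X @ beta
        partition = m.make_fold_partition(40, 5, seed=1)
        assert m.cv_rmse(y, X, [0, 1, 2], partition) == pytest.approx(0.0, abs=1e-10)

    def test_rank_deficient_training_fit_is_minimum_norm(self):
        # duplicated column: both engines fall back to minimum-norm LS
        rng = np.random.default_rng(5)
        x = rng.standard_normal(30)
        X = np.column_stack([np.ones(30), x, x])
        y = 2 * x + rng.standard_normal(30) * 0.1
        partition = m.make_fold_partition(30, 5, seed=2)
        naive = m.cv_rmse(y, X, [0, 1, 2], partition, engine="naive")
        gram = m.cv_rmse(y, X, [0, 1, 2], partition, engine="gram")
        assert naive == pytest.approx(gram, abs=1e-8)


class TestEngines:
    def test_gram_equals_naive_on_random_instances(self):
        rng = np.random.default_rng(12)
        for trial in range(10):
            n = int(rng.integers(30, 120))
            p = int(rng.integers(1, 6))
            X = np.column_stack([np.ones(n), rng.standard_normal((n, p))])
            y = rng.standard_normal(n)
            fold = m.make_fold_partition(n, 5, seed=trial)
            cols = [np.arange(j + 1) for j in range(p + 1)]
            a = _sweep_gram(X, y, fold, 5, cols)
            b = _sweep_naive(X, y, fold, 5, cols)
            np.testing.assert_allclose(a, b, atol=1e-8)

    def test_inverted_orientation_trains_on_one_fold(self):
        rng = np.random.default_rng(3)
        n = 60
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = X @ np.array([1.0, 0.5]) + rng.standard_normal(n)
        fold = m.make_fold_partition(n, 6, seed=0)
        a = _sweep_gram(X, y, fold, 6, [np.array([0, 1])], train_on_one=True)
        b = _sweep_naive(X, y, fold, 6, [np.array([0, 1])], train_on_one=True)
        np.testing.assert_allclose(a, b, atol=1e-8)
        standard = _sweep_gram(X, y, fold, 6, [np.array([0, 1])])
        assert a[0] > standard[0]  # training on one tenth predicts worse


class TestRunSearch:
    def test_zero_noise_true_model_always_wins(self):
        frame, catalog, true_mask = m.selection_scenario(
            n=400, p=8, noise_sd=0.0, seed=11
        )
        result = m.run_search(
            frame, catalog, m.CVConfig(folds=10, repeats=20, seed=4),
            outcome="outcome",
        )
        assert result.best_model().mask == true_mask
        assert result.win_pct[true_mask] == 100.0

    def test_winner_percentages_partition_the_repeats(self):
        frame, catalog, _ = m.selection_scenario(n=120, p=4, noise_sd=1.0, seed=6)
        result = m.run_search(
            frame, catalog, m.CVConfig(folds=6, repeats=17, seed=2),
            outcome="outcome",
        )
        assert result.win_counts.sum() == 17
        assert result.win_pct.sum() == pytest.approx(100.0)

    def test_irrelevant_predictor_loses_to_intercept_only(self):
        """Out-of-sample, a pure-noise predictor inflates prediction
        error, so the intercept-only model wins most repeats."""
        frame, catalog, _ = m.selection_scenario(
            n=2000, p=1, true_betas={}, noise_sd=1.0, seed=21
        )
        result = m.run_search(
            frame, catalog, m.CVConfig(folds=10, repeats=50, seed=3),
            outcome="outcome",
        )
        assert result.win_pct[0] > 50.0

    def test_seed_determinism(self):
        frame, catalog, _ = m.selection_scenario(n=150, p=5, noise_sd=1.0, seed=8)
        cv = m.CVConfig(folds=5, repeats=6, seed=14)
        a = m.run_search(frame, catalog, cv, outcome="outcome")
        b = m.run_search(frame, catalog, cv, outcome="outcome")
        np.testing.assert_array_equal(a.winners, b.winners)
        np.testing.assert_array_equal(a.mean_rmse, b.mean_rmse)

    def test_monotone_nesting_under_zero_noise(self):
        """Adding a true factor never worsens RMSEp when the outcome is
        an exact linear function of the factors (at a sample size where
        the expected improvement dominates CV sampling noise)."""
        frame, catalog, _ = m.selection_scenario(
            n=3000, p=4, true_betas={0: 0.8, 1: 0.5, 2: 0.3, 3: 0.2},
            noise_sd=0.0, seed=9,
        )
        result = m.run_search(
            frame, catalog, m.CVConfig(folds=5, repeats=5, seed=1),
            outcome="outcome",
        )
        for mask in range(16):
            for bit in range(4):
                if not mask >> bit & 1:
                    superset = mask | 1 << bit
                    assert (result.mean_rmse[superset]
                            <= result.mean_rmse[mask] + 1e-9)


class TestTopTable:
    def test_sorted_and_truncated(self):
        frame, catalog, _ = m.selection_scenario(n=150, p=3, noise_sd=1.0, seed=5)
        result = m.run_search(frame, catalog,
                              m.CVConfig(folds=5, repeats=11, seed=7),
                              outcome="outcome")
        top = m.top_models_table(result, 3)
        assert list(top["rank"]) == [1, 2, 3]
        assert top.win_pct.is_monotonic_decreasing

    def test_k_exceeding_model_count_warns(self):
        frame, catalog, _ = m.selection_scenario(
            n=80, p=1, true_betas={0: 0.5}, noise_sd=1.0, seed=5)
        result = m.run_search(frame, catalog,
                              m.CVConfig(folds=4, repeats=2, seed=1),
                              outcome="outcome")
        with pytest.warns(UserWarning, match="truncat"):
            top = m.top_models_table(result, 5)
        assert len(top) == 2

    def test_single_model_search_reports_hundred_percent(self):
        frame, catalog, _ = m.selection_scenario(
            n=80, p=1, true_betas={0: 0.5}, noise_sd=1.0, seed=5)
        models = m.enumerate_models(catalog)[:1]
        result = m.run_search(frame, catalog,
                              m.CVConfig(folds=4, repeats=5, seed=1),
                              outcome="outcome", models=models)
        top = m.top_models_table(result, 1)
        assert top.win_pct.iloc[0] == 100.0
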