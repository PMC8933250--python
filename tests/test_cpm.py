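"""Tests for edge selection, consensus, fitting, evaluation and permutation."""

import numpy as np
import pytest
from scipy import stats

from cpmnet import (
    ConfigError,
    ConstantInputError,
    ConnectivityMatrix,
    EdgeMask,
    SampleSizeError,
    SingularFitError,
    covariate_adjusted_evaluation,
    default_threshold_grid,
    evaluate,
    external_validate,
    fit_model,
    loocv_consensus,
    optimize_threshold,
    partial_rank_correlation,
    permutation_test,
    predict,
    predict_many,
    select_candidates,
    summed_strength,
    summed_strengths,
    train_model,
)
from cpmnet.cpm import as_edge_table, permutation_pvalue

from _oracles import ols_oracle, partial_spearman_oracle, summed_strength_oracle


def _matrix_from_edges(n_nodes, edge_values, sid="s"):
    z = np.zeros((n_nodes, n_nodes))
    i, j = np.triu_indices(n_nodes, k=1)
    z[i, j] = edge_values
    z += z.T
    return ConnectivityMatrix(sid, z)


class TestPartialRankCorrelation:
    def test_no_covariates_equals_plain_spearman(self, rng):
        x = rng.standard_normal(40)
        y = rng.standard_normal(40)
        rho, p = partial_rank_correlation(x, y)
        ref = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_monotone_function_gives_unit_correlation(self, rng):
        x = rng.standard_normal(20)
        rho, p = partial_rank_correlation(x, np.exp(x))
        assert rho == pytest.approx(1.0)

    def test_matches_brute_force_oracle_with_covariate(self, rng):
        x = np.array([2.1, 0.3, -1.2, 0.8, 1.9, -0.4, 0.0, 2.5])
        y = np.array([5.0, 1.2, 0.7, 3.3, 4.1, 2.2, 1.0, 6.0])
        cov = np.array([[0.5], [1.2], [-0.3], [0.9], [2.0], [0.1], [-1.1], [1.5]])
        rho, p = partial_rank_correlation(x, y, cov)
        o_rho, o_p = partial_spearman_oracle(x, y, cov)
        assert rho == pytest.approx(o_rho, abs=1e-10)
        assert p == pytest.approx(o_p, abs=1e-10)

    def test_matches_oracle_with_two_covariates(self, rng):
        x = rng.standard_normal(25)
        y = 0.4 * x + rng.standard_normal(25)
        cov = rng.standard_normal((25, 2))
        rho, p = partial_rank_correlation(x, y, cov)
        o_rho, o_p = partial_spearman_oracle(x, y, cov)
        assert rho == pytest.approx(o_rho, abs=1e-10)
        assert p == pytest.approx(o_p, abs=1e-10)

    def test_full_collinearity_with_covariate_degenerates_to_zero(self):
        z = np.arange(10.0)
        with pytest.warns(RuntimeWarning, match="collinear"):
            rho, p = partial_rank_correlation(z, z, z[:, None])
        assert rho == 0.0 and p == 1.0

    def test_constant_input_rejected(self):
        with pytest.raises(ConstantInputError):
            partial_rank_correlation(np.ones(10), np.arange(10.0))

    def test_sample_size_floor_enforced(self):
        with pytest.raises(SampleSizeError):
            partial_rank_correlation(
                np.arange(5.0), np.arange(5.0), np.ones((5, 2)) * np.arange(5)[:, None]
            )


class TestSelectCandidates:
    def test_constant_edge_never_selected(self, rng):
        n = 20
        table = rng.standard_normal((n, 6))
        table[:, 3] = 0.7  # dead edge
        y = table[:, 0] + 0.1 * rng.standard_normal(n)
        pos, neg = select_candidates(table, y, p_threshold=0.9999, n_nodes=4)
        flat = set(pos.flat_indices()) | set(neg.flat_indices())
        assert 3 not in flat

    def test_null_selection_rate_matches_threshold(self):
        # pooled over 5 null cohorts x 780 edges at threshold .009
        from cpmnet import SimulationConfig, generate_null_cohort

        total, selected = 0, 0
        for seed in range(5):
            cohort = generate_null_cohort(
                SimulationConfig(n_subjects=47, n_nodes=40, n_planted_positive=0,
                                 n_planted_negative=0, seed=100 + seed)
            )
            pos, neg = select_candidates(
                cohort.matrices, cohort.scores, cohort.covariates(), 0.009
            )
            selected += len(pos) + len(neg)
            total += 780
        rate = selected / total
        # binomial 99.7% band around .009 with n=3900
        assert abs(rate - 0.009) < 3 * np.sqrt(0.009 * 0.991 / total)

    def test_planted_edges_selected_with_correct_sign(self, recovery_cohort):
        pos, neg = select_candidates(
            recovery_cohort.matrices, recovery_cohort.scores,
            recovery_cohort.covariates(), 0.009,
        )
        assert recovery_cohort.truth_positive.as_set() <= pos.as_set()
        assert recovery_cohort.truth_negative.as_set() <= neg.as_set()


class TestLoocvConsensus:
    def test_consensus_equals_intersection_of_fold_sets(self, small_planted_cohort):
        co = small_planted_cohort
        pos, neg, folds = loocv_consensus(co.matrices, co.scores, co.covariates(), 0.05)
        pos_inter = frozenset.intersection(*[f[0] for f in folds])
        neg_inter = frozenset.intersection(*[f[1] for f in folds])
        assert pos.as_set() == pos_inter
        assert neg.as_set() == neg_inter

    def test_consensus_subset_of_every_fold(self, small_planted_cohort):
        co = small_planted_cohort
        pos, neg, folds = loocv_consensus(co.matrices, co.scores, co.covariates(), 0.05)
        for fold_pos, fold_neg in folds:
            assert pos.as_set() <= fold_pos
            assert neg.as_set() <= fold_neg

    def test_masks_disjoint(self, small_planted_cohort):
        co = small_planted_cohort
        pos, neg, _ = loocv_consensus(co.matrices, co.scores, co.covariates(), 0.05)
        assert not (pos.as_set() & neg.as_set())

    def test_too_few_subjects_rejected(self, rng):
        table = rng.standard_normal((6, 3))
        with pytest.raises(SampleSizeError):
            loocv_consensus(table, rng.standard_normal(6),
                            rng.standard_normal((6, 2)), 0.05, n_nodes=3)


class TestSummedStrength:
    def test_empty_mask_sums_to_zero(self):
        mat = _matrix_from_edges(4, np.arange(6.0))
        assert summed_strength(mat, EdgeMask(4, (), "positive")) == 0.0

    def test_two_edge_arithmetic(self):
        mat = _matrix_from_edges(4, np.array([0.3, 0, 0, -0.1, 0, 0]))
        mask = EdgeMask.from_pairs(4, [(0, 1), (1, 2)], "positive")
        assert summed_strength(mat, mask) == pytest.approx(0.2)

    def test_matches_exhaustive_loop_oracle(self, rng):
        n = 9
        values = rng.standard_normal(n * (n - 1) // 2)
        mat = _matrix_from_edges(n, values)
        all_pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
        chosen = [all_pairs[k] for k in rng.choice(len(all_pairs), 12, replace=False)]
        mask = EdgeMask.from_pairs(n, chosen, "negative")
        assert summed_strength(mat, mask) == pytest.approx(
            summed_strength_oracle(mat.z, chosen), abs=1e-12
        )

    def test_vectorized_matches_scalar(self, small_planted_cohort):
        co = small_planted_cohort
        mask = co.truth_positive
        vec = summed_strengths(co.matrices, mask)
        scalar = [summed_strength(m, mask) for m in co.matrices]
        np.testing.assert_allclose(vec, scalar)

    def test_dimension_mismatch_rejected(self):
        mat = _matrix_from_edges(4, np.arange(6.0))
        with pytest.raises(Exception):
            summed_strength(mat, EdgeMask(5, ((0, 1),), "positive"))


class TestFitAndPredict:
    def _exact_cohort(self, rng, n=12, n_nodes=6):
        m = n_nodes * (n_nodes - 1) // 2
        table = rng.standard_normal((n, m))
        pos = EdgeMask.from_pairs(n_nodes, [(0, 1), (2, 3)], "positive")
        neg = EdgeMask.from_pairs(n_nodes, [(0, 2), (1, 4)], "negative")
        x1 = summed_strengths(table, pos, n_nodes=n_nodes)
        x2 = summed_strengths(table, neg, n_nodes=n_nodes)
        scores = 2.0 * x1 - 1.0 * x2 + 5.0
        return table, scores, pos, neg, n_nodes

    def test_exact_linear_recovery(self, rng):
        table, scores, pos, neg, n_nodes = self._exact_cohort(rng)
        model = fit_model(table, scores, pos, neg, 0.01, n_nodes=n_nodes)
        assert model.a1 == pytest.approx(2.0, abs=1e-9)
        assert model.a2 == pytest.approx(-1.0, abs=1e-9)
        assert model.b == pytest.approx(5.0, abs=1e-9)

    def test_predict_reproduces_training_scores_in_exact_case(self, rng):
        table, scores, pos, neg, n_nodes = self._exact_cohort(rng)
        model = fit_model(table, scores, pos, neg, 0.01, n_nodes=n_nodes)
        preds = predict_many(model, table, n_nodes=n_nodes)
        np.testing.assert_allclose(preds, scores, atol=1e-9)

    def test_empty_negative_mask_dropped_with_warning(self, rng):
        table, scores, pos, _, n_nodes = self._exact_cohort(rng)
        empty = EdgeMask(n_nodes, (), "negative")
        with pytest.warns(RuntimeWarning, match="constant"):
            model = fit_model(table, scores, pos, empty, 0.01, n_nodes=n_nodes)
        assert model.a2 == 0.0

    def test_coefficients_match_normal_equations_oracle(self, rng):
        table, _, pos, neg, n_nodes = self._exact_cohort(rng, n=20)
        x1 = summed_strengths(table, pos, n_nodes=n_nodes)
        x2 = summed_strengths(table, neg, n_nodes=n_nodes)
        scores = 1.5 * x1 - 0.7 * x2 + 3.0 + rng.standard_normal(20)
        model = fit_model(table, scores, pos, neg, 0.01, n_nodes=n_nodes)
        beta = ols_oracle(list(scores), [list(x1), list(x2)])
        assert model.b == pytest.approx(beta[0], abs=1e-8)
        assert model.a1 == pytest.approx(beta[1], abs=1e-8)
        assert model.a2 == pytest.approx(beta[2], abs=1e-8)

    def test_collinear_features_rejected(self, rng):
        n_nodes = 4
        table = rng.standard_normal((10, 6))
        table[:, 1] = table[:, 0]  # edge (0,2) duplicates edge (0,1)
        pos = EdgeMask.from_pairs(n_nodes, [(0, 1)], "positive")
        neg = EdgeMask.from_pairs(n_nodes, [(0, 2)], "negative")
        with pytest.raises(SingularFitError):
            fit_model(table, rng.standard_normal(10), pos, neg, 0.01, n_nodes=n_nodes)

    def test_zero_slope_model_predicts_intercept(self):
        pos = EdgeMask(4, ((0, 1),), "positive")
        neg = EdgeMask(4, ((2, 3),), "negative")
        model_args = dict(a1=0.0, a2=0.0, b=7.5, p_threshold=0.01)
        from cpmnet import CpmModel

        model = CpmModel(pos, neg, **model_args)
        mat = _matrix_from_edges(4, np.arange(6.0))
        assert predict(model, mat) == 7.5

    def test_hand_built_four_node_prediction(self):
        from cpmnet import CpmModel

        # edges in row-major triu order: (0,1)=0.4, (0,2)=0.1, (0,3)=-0.2,
        #                                (1,2)=0.3, (1,3)=0.0, (2,3)=-0.5
        mat = _matrix_from_edges(4, np.array([0.4, 0.1, -0.2, 0.3, 0.0, -0.5]))
        pos = EdgeMask.from_pairs(4, [(0, 1), (1, 2)], "positive")  # x1 = 0.7
        neg = EdgeMask.from_pairs(4, [(2, 3)], "negative")          # x2 = -0.5
        model = CpmModel(pos, neg, a1=2.0, a2=3.0, b=1.0, p_threshold=0.01)
        assert predict(model, mat) == pytest.approx(2.0 * 0.7 + 3.0 * (-0.5) + 1.0)


class TestEvaluate:
    def test_perfect_prediction(self):
        y = np.array([3.0, 1.0, 4.0, 1.5, 9.0])
        res = evaluate(y, y)
        assert res.r_true == pytest.approx(1.0)
        assert res.mse == 0.0

    def test_rank_reversal(self):
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        res = evaluate(y[::-1], y)
        assert res.r_true == pytest.approx(-1.0)

    def test_hand_computed_fixture(self):
        pred = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        obs = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        res = evaluate(pred, obs)
        assert res.r_true == pytest.approx(0.8)  # 1 - 6*4/(5*24)
        assert res.mse == pytest.approx(0.8)

    def test_constant_prediction_raises_but_carries_mse(self):
        with pytest.raises(ConstantInputError) as exc:
            evaluate(np.full(5, 2.0), np.arange(5.0))
        assert exc.value.mse == pytest.approx(np.mean((2.0 - np.arange(5.0)) ** 2))


class TestPermutationTest:
    def test_pvalue_counting_is_strict_ge(self):
        null = np.array([0.1, 0.5, 0.5, 0.9])
        assert permutation_pvalue(0.5, null) == pytest.approx(3 / 4)
        assert permutation_pvalue(1.0, null) == 0.0
        assert permutation_pvalue(-1.0, null) == 1.0

    def test_seed_required(self, small_planted_cohort):
        co = small_planted_cohort
        with pytest.raises(ConfigError):
            permutation_test(co.matrices, co.scores, co.covariates(), 0.05, n_perm=10)

    def test_deterministic_under_seed(self, small_planted_cohort):
        co = small_planted_cohort
        a = permutation_test(co.matrices, co.scores, co.covariates(), 0.05,
                             n_perm=30, seed=4)
        b = permutation_test(co.matrices, co.scores, co.covariates(), 0.05,
                             n_perm=30, seed=4)
        np.testing.assert_array_equal(a.null_r, b.null_r)
        assert a.p_permu == b.p_permu

    def test_planted_effect_is_significant(self, small_planted_cohort):
        co = small_planted_cohort
        res = permutation_test(co.matrices, co.scores, co.covariates(), 0.05,
                               n_perm=100, seed=9)
        assert res.p_permu <= 0.05
        assert res.r_true > 0.5


class TestMonotoneInvariance:
    def test_strictly_increasing_score_transform_changes_nothing(
        self, small_planted_cohort
    ):
        co = small_planted_cohort
        pos_a, neg_a, _ = loocv_consensus(co.matrices, co.scores, co.covariates(), 0.05)
        transformed = np.exp(co.scores / 30.0)  # strictly increasing
        pos_b, neg_b, _ = loocv_consensus(co.matrices, transformed,
                                          co.covariates(), 0.05)
        assert pos_a.as_set() == pos_b.as_set()
        assert neg_a.as_set() == neg_b.as_set()
        # with the model held fixed, evaluation is exactly rank-invariant too
        model, ev_a, _ = train_model(co.matrices, co.scores, co.covariates(), 0.05)
        ev_b = external_validate(model, co.matrices, transformed)
        assert ev_b.r_true == pytest.approx(ev_a.r_true, abs=1e-12)


class TestOptimizeThreshold:
    def test_default_grid_has_fifty_values(self):
        grid = default_threshold_grid()
        assert grid.size == 50
        assert grid[0] == pytest.approx(0.001)
        assert grid[-1] == pytest.approx(0.050)

    def test_single_value_grid_returned(self, small_planted_cohort):
        co = small_planted_cohort
        best, table = optimize_threshold(co.matrices, co.scores, co.covariates(),
                                         grid=[0.03])
        assert best == pytest.approx(0.03)
        assert len(table) == 1

    def test_tie_breaks_toward_stricter_threshold(self, small_planted_cohort):
        co = small_planted_cohort
        # neighboring thresholds that select identical consensus sets tie on
        # r_true; the smaller threshold must win
        _, table = optimize_threshold(co.matrices, co.scores, co.covariates(),
                                      grid=np.round(np.arange(0.01, 0.051, 0.001), 3))
        r = table.set_index("p_threshold")["r_true"]
        dup = r[r == r.max()]
        best, _ = optimize_threshold(co.matrices, co.scores, co.covariates(),
                                     grid=np.round(np.arange(0.01, 0.051, 0.001), 3))
        assert best == pytest.approx(dup.index.min())

    def test_out_of_range_threshold_rejected(self, small_planted_cohort):
        co = small_planted_cohort
        with pytest.raises(Exception):
            optimize_threshold(co.matrices, co.scores, co.covariates(), grid=[1.5])


class TestExternalValidation:
    def test_identical_cohort_reproduces_training_evaluation(
        self, small_planted_cohort
    ):
        co = small_planted_cohort
        model, train_eval, _ = train_model(co.matrices, co.scores,
                                           co.covariates(), 0.05)
        val = external_validate(model, co.matrices, co.scores)
        assert val.r_true == pytest.approx(train_eval.r_true)
        assert val.mse == pytest.approx(train_eval.mse)

    def test_null_validation_cohort_gives_near_zero_r(self, small_planted_cohort):
        from cpmnet import SimulationConfig, generate_cohort

        co = small_planted_cohort
        model, _, _ = train_model(co.matrices, co.scores, co.covariates(), 0.05)
        rs = []
        for seed in range(10):
            null_val = generate_cohort(
                SimulationConfig(n_subjects=30, n_nodes=20, n_planted_positive=0,
                                 n_planted_negative=0, effect_size=0.0,
                                 seed=500 + seed)
            )
            rs.append(external_validate(model, null_val.matrices,
                                        null_val.scores).r_true)
        assert abs(np.mean(rs)) < 0.15

    def test_planted_validation_cohort_recovers_signal(self, small_planted_cohort):
        from cpmnet import SimulationConfig, generate_cohort

        co = small_planted_cohort
        model, _, _ = train_model(co.matrices, co.scores, co.covariates(), 0.05)
        val = generate_cohort(
            SimulationConfig(n_subjects=60, n_nodes=20, n_planted_positive=4,
                             n_planted_negative=4, effect_size=0.6, seed=900),
            truth=(co.truth_positive, co.truth_negative),
        )
        res = external_validate(model, val.matrices, val.scores)
        assert res.r_true > 0.4
        assert res.p < 0.01


class TestCovariateAdjustedEvaluation:
    def test_no_covariates_equals_plain_evaluation(self, rng):
        pred = rng.standard_normal(30)
        obs = 0.5 * pred + rng.standard_normal(30)
        rho, _ = covariate_adjusted_evaluation(pred, obs, None)
        assert rho == pytest.approx(evaluate(pred, obs).r_true, abs=1e-12)

    def test_matches_partial_oracle(self, rng):
        pred = rng.standard_normal(20)
        obs = 0.6 * pred + rng.standard_normal(20)
        cov = rng.standard_normal((20, 2))
        rho, p = covariate_adjusted_evaluation(pred, obs, cov)
        o_rho, o_p = partial_spearman_oracle(pred, obs, cov)
        assert rho == pytest.approx(o_rho, abs=1e-10)
        assert p == pytest.approx(o_p, abs=1e-10)

    def test_covariate_equal_to_observed_degenerates(self, rng):
        obs = rng.standard_normal(15)
        pred = obs + 0.1 * rng.standard_normal(15)
        with pytest.warns(RuntimeWarning, match="collinear"):
            rho, _ = covariate_adjusted_evaluation(pred, obs, obs[:, None])
        assert rho == 0.0


def test_edge_table_round_trips_matrices(small_planted_cohort):
    co = small_planted_cohort
    table, n = as_edge_table(co.matrices)
    assert n == 20
    np.testing.assert_allclose(table[0], co.matrices[0].upper_triangle())
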