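"""Edge weights, FC predictor, robust fit, CV schemes and summaries."""

import numpy as np
import pytest
from scipy import stats

import fcresponse as fr
from fcresponse.exceptions import DegenerateDataError
from fcresponse.prediction import WeightVector

from conftest import auc_pair_oracle, data_with_exact_corr, partial_corr_residual_oracle


class TestEdgeWeights:
    def test_known_correlations_scaled_by_sample_sd(self, rng):
        # two edges with |r| = (0.6, 0.2): sample SD 0.2828..., weights
        # 2.1213 and 0.7071
        R = np.array([
            [1.0, 0.0, 0.6],
            [0.0, 1.0, 0.2],
            [0.6, 0.2, 1.0],
        ])
        X = data_with_exact_corr(R, 60, rng)
        delta, score = X[:, :2], X[:, 2]
        wv = fr.edge_weights(delta, score)
        np.testing.assert_allclose(
            wv.weights, [2.12132034, 0.70710678], atol=1e-6
        )
        assert wv.scale_sd == pytest.approx(np.std([0.6, 0.2], ddof=1), abs=1e-10)

    def test_partial_correlation_matches_residual_oracle(self, rng):
        n = 50
        cov = rng.standard_normal((n, 2))
        score = rng.standard_normal(n) + cov @ [0.5, -0.3]
        delta = rng.standard_normal((n, 6)) + np.outer(cov[:, 0], np.ones(6)) * 0.4
        wv = fr.edge_weights(delta, score, covariates=cov)
        for e in range(6):
            oracle = partial_corr_residual_oracle(delta[:, e], score, cov)
            assert wv.r_partial[e] == pytest.approx(oracle, abs=1e-10)

    def test_covariate_identical_to_score_rejected(self, rng):
        n = 30
        score = rng.standard_normal(n)
        delta = rng.standard_normal((n, 4))
        with pytest.raises(DegenerateDataError, match="covariates"):
            fr.edge_weights(delta, score, covariates=score[:, None])

    def test_proportional_edge_unit_correlation(self, rng):
        n = 25
        score = rng.standard_normal(n)
        delta = np.column_stack([3.0 * score, rng.standard_normal(n)])
        wv = fr.edge_weights(delta, score)
        assert wv.r_partial[0] == pytest.approx(1.0, abs=1e-10)

    def test_zero_variance_score_rejected(self, rng):
        with pytest.raises(DegenerateDataError):
            fr.edge_weights(rng.standard_normal((20, 3)), np.ones(20))

    def test_signed_mode_keeps_sign(self, rng):
        n = 40
        score = rng.standard_normal(n)
        delta = np.column_stack([-score + 0.1 * rng.standard_normal(n),
                                 rng.standard_normal(n)])
        wv = fr.edge_weights(delta, score, signed=True)
        assert wv.weights[0] < 0


class TestSelectEdges:
    def test_all_edges_264_nodes(self):
        mask = fr.select_edges("all", fr.n_edges(264))
        assert mask.sum() == 34716

    def test_threshold_above_max_empty(self, rng):
        t = rng.uniform(-2, 2, 10)
        mask = fr.select_edges("threshold", 10, t_map=t, t_thresh=5.0)
        assert mask.sum() == 0

    def test_nbs_strategy_uses_component_edges(self):
        spec = fr.SyntheticSpec(
            n_subjects=30, n_nodes=15,
            planted_edges=fr.planted_component(3, 15), effect_rho=0.9,
            seed=3,
        )
        st = fr.gen_effect_study(spec)
        d = fr.design_from_study(st)
        res = fr.nbs_test(st.delta_stack, d, 15, n_perm=200, seed=1)
        mask = fr.select_edges("nbs", fr.n_edges(15), nbs_result=res)
        sig_edges = set()
        for i in res.significant("extent"):
            sig_edges |= set(res.components[i].edges)
        ids = fr.pairs_to_edge_ids(sorted(sig_edges), 15)
        expected = np.zeros(fr.n_edges(15), dtype=bool)
        expected[ids] = True
        np.testing.assert_array_equal(mask, expected)

    def test_nbs_strategy_requires_result(self):
        with pytest.raises(ValueError):
            fr.select_edges("nbs", 10)


class TestFcPredictor:
    def test_equal_weights_plain_mean(self, rng):
        delta = rng.standard_normal((5, 8))
        wv = WeightVector(
            weights=np.ones(8), mask=np.ones(8, bool),
            r_partial=np.zeros(8), scale_sd=1.0, signed=False,
        )
        np.testing.assert_allclose(
            fr.fc_predictor(delta, wv), delta.mean(axis=1), atol=1e-12
        )

    def test_worked_arithmetic_example(self):
        wv = WeightVector(
            weights=np.array([2.1213, 0.7071]), mask=np.ones(2, bool),
            r_partial=np.zeros(2), scale_sd=1.0, signed=False,
        )
        val = fr.fc_predictor(np.array([0.3, -0.1]), wv)
        assert val == pytest.approx(0.2, abs=1e-4)

    def test_single_edge_mask(self, rng):
        delta = rng.standard_normal((4, 6))
        mask = np.zeros(6, bool)
        mask[2] = True
        wv = WeightVector(
            weights=mask * 1.7, mask=mask,
            r_partial=np.zeros(6), scale_sd=1.0, signed=False,
        )
        np.testing.assert_allclose(fr.fc_predictor(delta, wv), delta[:, 2])

    def test_uniform_rescaling_invariance(self, rng):
        delta = rng.standard_normal((6, 9))
        w = np.abs(rng.standard_normal(9)) + 0.1
        base = WeightVector(w, np.ones(9, bool), np.zeros(9), 1.0, False)
        scaled = WeightVector(w * 7.3, np.ones(9, bool), np.zeros(9), 1.0, False)
        np.testing.assert_allclose(
            fr.fc_predictor(delta, base), fr.fc_predictor(delta, scaled),
            atol=1e-12,
        )

    def test_loop_oracle(self, rng):
        delta = rng.standard_normal((3, 12))
        w = np.abs(rng.standard_normal(12))
        mask = rng.random(12) < 0.6
        w[~mask] = 0.0
        wv = WeightVector(w, mask, np.zeros(12), 1.0, False)
        out = fr.fc_predictor(delta, wv)
        for s in range(3):
            num = sum(w[e] * delta[s, e] for e in range(12) if mask[e])
            den = sum(w[e] for e in range(12) if mask[e])
            assert out[s] == pytest.approx(num / den, abs=1e-12)

    def test_empty_mask_flagged(self, rng):
        wv = WeightVector(np.zeros(5), np.zeros(5, bool), np.zeros(5), 1.0, False)
        with pytest.raises(DegenerateDataError, match="empty"):
            fr.fc_predictor(rng.standard_normal((2, 5)), wv)


class TestRobustRegression:
    def test_clean_linear_data_equals_least_squares(self, rng):
        n = 30
        x = rng.standard_normal((n, 2))
        y = 1.5 + x @ [2.0, -0.7]
        m = fr.fit_response_model(x, y)
        np.testing.assert_allclose(m.coef, [1.5, 2.0, -0.7], atol=1e-8)
        assert m.converged

    def test_outlier_resistance_vs_least_squares_oracle(self, rng):
        n = 30
        x = np.linspace(-1, 1, n)
        y = 2.0 * x + 0.01 * rng.standard_normal(n)
        y[-1] += 30.0  # one gross outlier at the right edge
        m = fr.fit_response_model(x[:, None], y)
        A = np.column_stack([np.ones(n), x])
        ols = np.linalg.lstsq(A, y, rcond=None)[0]
        assert abs(m.coef[1] - 2.0) / 2.0 < 0.02
        assert abs(ols[1] - 2.0) / 2.0 > 0.10

    def test_constant_predictor_rejected(self):
        with pytest.raises(DegenerateDataError):
            fr.fit_response_model(np.ones((20, 1)), np.arange(20.0))

    def test_agrees_with_statsmodels_rlm(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        n = 60
        x = rng.standard_normal((n, 2))
        y = 0.5 + x @ [1.0, -2.0] + rng.standard_normal(n)
        y[:4] += np.array([8.0, -6.0, 9.0, -7.0])
        ours = fr.fit_response_model(x, y)
        X = sm.add_constant(x)
        theirs = sm.RLM(y, X, M=sm.robust.norms.TukeyBiweight(c=4.685)).fit(
            scale_est="mad"
        )
        np.testing.assert_allclose(ours.coef, theirs.params, atol=5e-2)


class TestCVSchemes:
    def _planted(self, seed=0, n=30, rho=0.6, nodes=15, k=4):
        spec = fr.SyntheticSpec(
            n_subjects=n, n_nodes=nodes,
            planted_edges=fr.planted_component(k, nodes), effect_rho=rho,
            seed=seed,
        )
        return fr.gen_effect_study(spec)

    def test_loocv_deterministic(self):
        st = self._planted(seed=1)
        a = fr.loocv(st, strategy="all")
        b = fr.loocv(st, strategy="all")
        np.testing.assert_array_equal(a.predictions, b.predictions)
        assert a.r == b.r

    def test_perfect_noiseless_relation_recovered(self, rng):
        n, nodes = 20, 10
        score = rng.standard_normal(n)
        delta_vec = rng.standard_normal((n, fr.n_edges(nodes))) * 1e-6
        delta_vec[:, 7] = score
        spec = fr.SyntheticSpec(n_subjects=n, n_nodes=nodes, seed=5)
        st = fr.gen_connectivity_study(spec, score)
        st.verum = st.placebo + fr.vec_to_matrix(delta_vec, nodes)
        cv = fr.loocv(st, strategy="all", with_covariates=False)
        assert cv.r > 0.99

    def test_repeated_3fold_deterministic_under_seed(self):
        st = self._planted(seed=2)
        a = fr.repeated_3fold(st, strategy="all", n_redraws=40, seed=7)
        b = fr.repeated_3fold(st, strategy="all", n_redraws=40, seed=7)
        np.testing.assert_array_equal(a.r_per_redraw, b.r_per_redraw)
        assert a.r == b.r

    def test_3cv_redraw_spread_wider_than_loocv_replicate_spread(self):
        # per-redraw 3CV correlations fluctuate more than LOOCV pooled
        # correlations across replicate null studies of the same design:
        # a third of the data is left out per redraw, so the scheme admits
        # more model variance
        loo = []
        spread3 = []
        for rep in range(8):
            spec = fr.SyntheticSpec(n_subjects=24, n_nodes=15, seed=900 + rep)
            st = fr.gen_null_study(spec)
            loo.append(fr.loocv(st, strategy="all").r)
            cv3 = fr.repeated_3fold(
                st, strategy="all", n_redraws=60, seed=rep,
                store_weights=False,
            )
            spread3.append(np.std(cv3.r_per_redraw))
        assert np.mean(spread3) > np.std(loo)

    def test_signed_equals_unsigned_when_effects_share_sign(self, rng):
        # every edge positively related to the score -> |r| == r, so the
        # two weighting modes give identical predictions
        n, nodes = 24, 5
        score = rng.standard_normal(n)
        delta_vec = 0.9 * score[:, None] + 0.2 * rng.standard_normal(
            (n, fr.n_edges(nodes))
        )
        spec = fr.SyntheticSpec(n_subjects=n, n_nodes=nodes, seed=9)
        st = fr.gen_connectivity_study(spec, score)
        st.verum = st.placebo + fr.vec_to_matrix(delta_vec, nodes)
        a = fr.loocv(st, strategy="all", with_covariates=False, signed=False)
        b = fr.loocv(st, strategy="all", with_covariates=False, signed=True)
        np.testing.assert_allclose(a.predictions, b.predictions, atol=1e-10)

    def test_circular_requires_nbs_result(self):
        st = self._planted(seed=3)
        with pytest.raises(ValueError):
            fr.insample_circular(st)

    def test_circular_with_empty_selection_flagged(self):
        st = fr.gen_null_study(fr.SyntheticSpec(n_subjects=30, n_nodes=15, seed=4))
        d = fr.design_from_study(st)
        res = fr.nbs_test(st.delta_stack, d, 15, p_thresh=1e-6, n_perm=100, seed=2)
        assert not res.components
        with pytest.raises(DegenerateDataError):
            fr.insample_circular(st, nbs_result=res)

    def test_loocv_too_small_rejected(self):
        st = self._planted(seed=6, n=8, nodes=10, k=3)
        with pytest.raises(DegenerateDataError):
            fr.loocv(st)


class TestSummaries:
    @pytest.mark.parametrize("p,m,expected", [
        (0.05, 7, 0.3017),
        (0.3, 1, 0.3),
        (0.0, 5, 0.0),
        (1.0, 3, 1.0),
    ])
    def test_sidak_closed_form(self, p, m, expected):
        assert fr.sidak_adjust(p, m) == pytest.approx(expected, abs=1e-4)

    def test_sidak_monotone_in_m(self):
        vals = [fr.sidak_adjust(0.04, m) for m in range(1, 10)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_median_weights_rare_edge_zero(self):
        stack = np.zeros((10, 3))
        stack[:4, 0] = 1.0   # selected in 40% of folds -> median 0
        stack[:, 1] = 2.5    # always selected
        cv = fr.CVResult(
            scheme="loocv", strategy="all", with_covariates=True,
            signed=False, predictions=np.zeros(3), actuals=np.zeros(3),
            r=0.0, p=1.0, weight_stack=stack,
        )
        W = fr.median_weight_matrix(cv, 3)
        assert W[0, 1] == 0.0
        assert W[0, 2] == 2.5

    def test_median_weights_match_sort_oracle(self, rng):
        stack = np.abs(rng.standard_normal((9, fr.n_edges(5))))
        cv = fr.CVResult(
            scheme="loocv", strategy="all", with_covariates=True,
            signed=False, predictions=np.zeros(5), actuals=np.zeros(5),
            r=0.0, p=1.0, weight_stack=stack,
        )
        W = fr.median_weight_matrix(cv, 5)
        iu, ju = fr.edge_index(5)
        for e in range(fr.n_edges(5)):
            vals = np.sort(stack[:, e])
            assert W[iu[e], ju[e]] == pytest.approx(vals[4], abs=1e-12)

    def test_top_nodes_star_hub_first(self):
        n = 6
        W = np.zeros((n, n))
        for j in range(1, n):
            W[0, j] = W[j, 0] = 1.0
        nodes, edges = fr.top_nodes_edges(W, k=3)
        assert nodes[0] == 0

    def test_top_ties_broken_by_index(self):
        W = np.ones((5, 5)) - np.eye(5)
        nodes, edges = fr.top_nodes_edges(W, k=3)
        np.testing.assert_array_equal(nodes, [0, 1, 2])
        assert [e for e, _ in edges] == [(0, 1), (0, 2), (0, 3)]

    def test_top_edges_match_sort_oracle(self, rng):
        W = fr.vec_to_matrix(np.abs(rng.standard_normal(fr.n_edges(7))), 7)
        _, edges = fr.top_nodes_edges(W, k=5)
        vals = sorted(
            ((W[i, j], (i, j)) for i in range(7) for j in range(i + 1, 7)),
            key=lambda t: -t[0],
        )
        assert [e for e, _ in edges] == [e for _, e in vals[:5]]


class TestRocMetrics:
    def test_perfect_ordering_auc_one(self):
        pred = np.array([10.0, 9.0, 8.0, 1.0, 0.5, 0.2])
        pre = np.full(6, 20.0)
        rem = np.array([1, 1, 1, 0, 0, 0], bool)
        m = fr.roc_metrics(pred, pre, rem, rem)
        assert m.auc_remission == 1.0

    def test_hand_counted_pairs(self):
        pred = np.array([3.0, 2.0, 1.0, 0.0])
        lab = np.array([1, 1, 0, 0], bool)
        m = fr.roc_metrics(pred, np.full(4, 20.0), lab, lab)
        assert m.auc_remission == 1.0
        # swap one adjacent pair: positives {3, 1}, negatives {2, 0}
        swapped = np.array([3.0, 1.0, 2.0, 0.0])
        m2 = fr.roc_metrics(swapped, np.full(4, 20.0), lab, lab)
        assert m2.auc_remission == 0.75

    def test_independent_predictions_auc_near_half(self, rng):
        n = 4000
        pred = rng.standard_normal(n)
        lab = rng.random(n) < 0.5
        m = fr.roc_metrics(pred, np.full(n, 20.0), lab, lab)
        assert abs(m.auc_remission - 0.5) < 0.05

    @pytest.mark.parametrize("seed", range(15))
    def test_auc_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 13))
        pred = np.round(rng.standard_normal(n), 1)  # provoke ties
        lab = rng.random(n) < 0.5
        if lab.all() or not lab.any():
            lab[0] = not lab[0]
        m = fr.roc_metrics(pred, np.full(n, 20.0), lab, lab)
        assert m.auc_remission == pytest.approx(
            auc_pair_oracle(pred, lab), abs=1e-12
        )

    def test_bac_applies_clinical_cutoffs(self):
        pre = np.array([20.0, 20.0, 30.0, 16.0])
        pred = np.array([14.0, 5.0, 24.0, 4.0])  # post: 6, 15, 6, 12
        rem = np.array([1, 0, 1, 0], bool)
        resp = np.array([1, 0, 1, 0], bool)
        m = fr.roc_metrics(pred, pre, rem, resp)
        assert m.bac_remission == 1.0   # predicted post <= 7 matches labels
        assert m.bac_response == 1.0    # reduction >= 50% matches labels

    def test_single_class_flagged_nan(self):
        pred = np.array([1.0, 2.0, 3.0])
        ones = np.ones(3, bool)
        m = fr.roc_metrics(pred, np.full(3, 20.0), ones, ~ones)
        assert np.isnan(m.auc_remission)
        assert np.isnan(m.auc_response)
        assert "auc_remission" in m.flags
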