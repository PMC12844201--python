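"""Permutation importance: oracle agreement, ranking rules, combination,
panel retraining and truth recovery."""

import numpy as np
import pandas as pd
import pytest

from omigrow import (
    LinearPredictor,
    RegressorConfig,
    combine_importance,
    evaluate,
    exhaustive_importance,
    fit_regressor,
    generate_design,
    generate_omics,
    permutation_importance,
    recovery_score,
    retrain_reduced,
    top_k,
)
from omigrow.errors import InputError, MappingError
from omigrow.importance import ImportanceResult
from omigrow.preprocess import IdMap, build_locus_map, match_layers, standardize
from omigrow.synthetic import SyntheticTruth


def _imp(scores):
    df = pd.DataFrame(
        {"mean_delta": list(scores.values()), "sd_delta": 0.0},
        index=pd.Index(list(scores), name="feature_id"),
    )
    df = df.sort_index().sort_values("mean_delta", ascending=False, kind="mergesort")
    df["rank"] = np.arange(1, len(df) + 1)
    return ImportanceResult(df, 1, "mse", 0.0)


class TestEstimator:
    def test_constant_column_importance_exactly_zero(self):
        X = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0], "const": [7.0] * 4})
        y = np.array([1.0, 2.0, 3.0, 4.0])
        imp = permutation_importance(LinearPredictor([1.0, 1.0]), X, y, n_repeats=5, seed=0)
        assert imp.table.loc["const", "mean_delta"] == 0.0
        assert imp.table.loc["const", "sd_delta"] == 0.0

    def test_unused_feature_importance_exactly_zero_for_linear_model(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.random((6, 2)), columns=["used", "noise"])
        y = 2.0 * X["used"].to_numpy()
        imp = permutation_importance(LinearPredictor([2.0, 0.0]), X, y, n_repeats=20, seed=1)
        assert imp.table.loc["noise", "mean_delta"] == 0.0
        assert imp.table.loc["used", "mean_delta"] > 0.0

    def test_monte_carlo_converges_to_exhaustive_oracle(self):
        # 3 rows: the exact importance averages all 3! = 6 column orders.
        X = pd.DataFrame({"x1": [0.0, 1.0, 2.0], "x2": [5.0, -3.0, 1.0]})
        y = np.array([0.0, 2.0, 4.0])
        model = LinearPredictor([2.0, 0.0])
        exact = exhaustive_importance(model, X, y)
        mc = permutation_importance(model, X, y, n_repeats=10_000, seed=0)
        e = exact.table.loc["x1", "mean_delta"]
        m = mc.table.loc["x1", "mean_delta"]
        assert abs(m - e) / e <= 0.02
        assert exact.table.loc["x2", "mean_delta"] == 0.0

    def test_agrees_with_sklearn_reference_on_trained_model(self, small_prot_std):
        from sklearn.inspection import permutation_importance as skl_pi

        X, y = small_prot_std
        model = fit_regressor(RegressorConfig.rf(n_estimators=60), X, y)
        ours = permutation_importance(model, X, y, n_repeats=60, seed=3)
        ref = skl_pi(
            model, X.values(), np.asarray(y), n_repeats=60, random_state=3,
            scoring="neg_mean_squared_error",
        )
        r = np.corrcoef(
            ours.table.reindex(X.feature_ids)["mean_delta"], ref.importances_mean
        )[0, 1]
        assert r > 0.99

    def test_independent_of_chunking(self, small_prot_std):
        X, y = small_prot_std
        model = LinearPredictor(np.linspace(-1, 1, X.n_features))
        a = permutation_importance(model, X, y, n_repeats=7, seed=5, max_block_rows=10**6)
        b = permutation_importance(model, X, y, n_repeats=7, seed=5, max_block_rows=50)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_exhaustive_guard_and_input_validation(self):
        X = pd.DataFrame(np.zeros((9, 2)), columns=["a", "b"])
        with pytest.raises(InputError):
            exhaustive_importance(LinearPredictor([1, 1]), X, np.zeros(9))
        with pytest.raises(InputError):
            permutation_importance(LinearPredictor([1, 1]), X, np.zeros(9), n_repeats=0)


class TestRanking:
    def test_top_k_orders_by_score_then_id(self):
        imp = _imp({"b": 3.0, "c": 1.0, "a": 3.0, "d": 2.0})
        assert top_k(imp, 3) == ["a", "b", "d"]
        assert top_k(imp, 4) == ["a", "b", "d", "c"]
        assert list(imp.table["rank"]) == [1, 2, 3, 4]

    def test_k_out_of_range_rejected(self):
        imp = _imp({"a": 1.0, "b": 0.5})
        for k in (0, 3):
            with pytest.raises(InputError):
                top_k(imp, k)


class TestCombination:
    def test_normalized_sum_arithmetic(self):
        trans = _imp({"g1": 10.0, "g2": 5.0, "g3": 0.0})
        prot = _imp({"P1": 2.0, "P2": 2.0, "P3": 0.0})
        id_map = IdMap((("g1", "P1"), ("g2", "P2"), ("g3", "P3")))
        comb = combine_importance(trans, prot, id_map).table
        assert comb.loc["P1", "norm_trans_score"] == pytest.approx(1.0)
        assert comb.loc["P2", "norm_trans_score"] == pytest.approx(0.5)
        assert comb.loc["P1", "combined_score"] == pytest.approx(2.0)
        assert comb.loc["P2", "combined_score"] == pytest.approx(1.5)
        assert comb.loc["P1", "rank"] == 1  # best in both layers dominates

    def test_constant_layer_normalizes_to_half_and_ranks_by_id(self):
        trans = _imp({"g1": 4.0, "g2": 4.0})
        prot = _imp({"P1": 4.0, "P2": 4.0})
        comb = combine_importance(trans, prot, IdMap((("g1", "P1"), ("g2", "P2")))).table
        assert (comb["norm_trans_score"] == 0.5).all()
        assert (comb["combined_score"] == 1.0).all()
        assert list(comb.index) == ["P1", "P2"]

    def test_misaligned_map_lists_offenders(self):
        trans = _imp({"g1": 1.0, "g2": 0.5})
        prot = _imp({"P1": 1.0})
        with pytest.raises(MappingError):
            combine_importance(trans, prot, IdMap((("g1", "P1"), ("g2", "P2"))))


class TestPanels:
    def test_identity_panel_reproduces_full_model(self, small_prot_std):
        X, y = small_prot_std
        cfg = RegressorConfig.rf(n_estimators=40)
        full = evaluate(fit_regressor(cfg, X, y), X, y)
        _, red = retrain_reduced(X, y, X.feature_ids, cfg)
        assert red.mae == pytest.approx(full.mae, abs=1e-12)
        assert red.mse == pytest.approx(full.mse, abs=1e-14)

    def test_empty_and_unknown_panels_rejected(self, small_prot_std):
        X, y = small_prot_std
        cfg = RegressorConfig.svr()
        with pytest.raises(InputError):
            retrain_reduced(X, y, [], cfg)
        with pytest.raises(InputError, match="NOPE"):
            retrain_reduced(X, y, ["NOPE"], cfg)

    def test_recovery_score_set_arithmetic(self):
        truth = SyntheticTruth(
            planted_features=[f"RPA{i}" for i in range(8)],
            layer_effects={}, oxygen_shifted_features=[], growth_function={},
            noise_sd=0.0, seed=0,
        )
        assert recovery_score(truth, truth.planted_features) == 1.0
        assert recovery_score(truth, ["X1", "X2"]) == 0.0
        six = truth.planted_features[:6] + ["X1", "X2"]
        assert recovery_score(truth, six) == 0.75
        # case-insensitive
        assert recovery_score(truth, [f.lower() for f in truth.planted_features]) == 1.0


class TestTruthRecovery:
    def test_combined_selection_recovers_planted_under_faithful_reliance(self):
        """With a model whose reliance tracks the signal (random forest),
        cross-layer combined top-20 selection recovers every planted driver."""
        seed = 1
        design = generate_design(14, seed=seed)
        trans, prot, rates, truth = generate_omics(
            design, n_features=100, n_planted=8, coupling=0.8, noise_sd=0.05, seed=seed
        )
        id_map = build_locus_map(trans.feature_ids, prot.feature_ids)
        t, p, id_map = match_layers(trans, prot, id_map)
        cfg = RegressorConfig.rf(n_estimators=200)
        imps = {}
        for key, m in (("t", t), ("p", p)):
            std = standardize(m)
            model = fit_regressor(cfg, std, rates)
            imps[key] = permutation_importance(model, std, rates, n_repeats=10, seed=seed)
        comb = combine_importance(imps["t"], imps["p"], id_map)
        assert recovery_score(truth, comb.top(20)) == 1.0
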