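"""Regressor configs, metric arithmetic, and fit reproducibility."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from omigrow import (
    RegressorConfig,
    benchmark,
    default_configs,
    evaluate,
    fit_regressor,
    generate_design,
    generate_omics,
)
from omigrow.errors import InputError, MetricDomainError
from omigrow.models import LinearPredictor
from omigrow.preprocess import standardize


class _Fixed:
    """Predictor returning canned values, for metric arithmetic tests."""

    def __init__(self, values):
        self.values = np.asarray(values, dtype=float)

    def predict(self, X):
        return self.values


class TestEvaluate:
    def test_hand_computed_metrics(self):
        X = np.zeros((2, 1))
        m = evaluate(_Fixed([2.0, 4.0]), X, [1.0, 2.0])
        assert (m.mae, m.mse, m.accuracy_pct) == (1.5, 2.5, pytest.approx(0.0))
        m = evaluate(_Fixed([1.1, 0.9]), X, [1.0, 1.0])
        assert m.mae == pytest.approx(0.1)
        assert m.mse == pytest.approx(0.01)
        assert m.accuracy_pct == pytest.approx(90.0)

    def test_perfect_fit_is_zero_error_full_accuracy(self):
        m = evaluate(_Fixed([1.0, 2.0]), np.zeros((2, 1)), [1.0, 2.0])
        assert (m.mae, m.mse, m.accuracy_pct) == (0.0, 0.0, 100.0)

    def test_non_positive_targets_rejected_for_accuracy(self):
        with pytest.raises(MetricDomainError):
            evaluate(_Fixed([1.0, 2.0]), np.zeros((2, 1)), [1.0, 0.0])
        m = evaluate(_Fixed([1.0, 2.0]), np.zeros((2, 1)), [1.0, 0.0], accuracy=False)
        assert m.accuracy_pct is None

    def test_mean_predictor_mse_is_population_variance(self):
        rng = np.random.default_rng(0)
        y = rng.random(20) + 0.5
        m = evaluate(_Fixed(np.full(20, y.mean())), np.zeros((20, 1)), y)
        assert m.mse == pytest.approx(y.var(ddof=0))

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(0.1, 10.0), min_size=2, max_size=12), st.randoms())
    def test_row_permutation_invariance(self, y, rnd):
        y = np.asarray(y)
        X = np.arange(y.size, dtype=float).reshape(-1, 1)
        model = LinearPredictor([0.3], 1.0)
        base = evaluate(model, X, y)
        perm = np.array(rnd.sample(range(y.size), y.size))
        permuted = evaluate(model, X[perm], y[perm])
        assert permuted.mae == pytest.approx(base.mae)
        assert permuted.mse == pytest.approx(base.mse)
        assert permuted.accuracy_pct == pytest.approx(base.accuracy_pct)

    @settings(max_examples=30, deadline=None)
    @given(
        st.lists(st.floats(0.1, 5.0), min_size=2, max_size=10),
        st.lists(st.floats(-5.0, 5.0), min_size=10, max_size=10),
    )
    def test_mae_squared_never_exceeds_mse(self, y, preds):
        y = np.asarray(y)
        m = evaluate(_Fixed(np.asarray(preds)[: y.size]), np.zeros((y.size, 1)), y)
        assert m.mae**2 <= m.mse + 1e-12


class TestFitting:
    def test_random_forest_bitwise_reproducible(self, small_prot_std):
        X, y = small_prot_std
        cfg = RegressorConfig.rf(n_estimators=50)
        p1 = fit_regressor(cfg, X, y).predict(X.values())
        p2 = fit_regressor(cfg, X, y).predict(X.values())
        assert np.array_equal(p1, p2)

    def test_svr_constant_target_within_epsilon(self):
        rng = np.random.default_rng(1)
        X = rng.random((10, 4))
        y = np.full(10, 3.0)
        model = fit_regressor(RegressorConfig.svr(), X, y)
        assert np.all(np.abs(model.predict(X) - 3.0) <= 0.01 + 1e-9)

    def test_ann_interpolates_noiseless_planted_signal(self):
        design = generate_design(14, seed=1)
        _, prot, rates, _ = generate_omics(
            design, n_features=50, n_planted=8, coupling=1.0, noise_sd=0.0, seed=1
        )
        X = standardize(prot)
        model = fit_regressor(RegressorConfig.ann(), X, rates)
        m = evaluate(model, X, rates)
        assert m.mae <= 0.01 * rates.mean()

    def test_row_mismatch_rejected(self):
        with pytest.raises(InputError):
            fit_regressor(RegressorConfig.svr(), np.zeros((3, 2)), [1.0, 2.0])

    @pytest.mark.parametrize(
        "kwargs", [dict(family="GBM"), dict(family="SVR", C=-1.0), dict(family="ANN", hidden_layers=0)]
    )
    def test_config_validation(self, kwargs):
        with pytest.raises(InputError):
            RegressorConfig(**kwargs)


class TestBenchmark:
    def test_three_families_times_two_layers_complete(self, small_omics):
        trans, prot, rates, _ = small_omics
        layers = {"transcriptomics": standardize(trans), "proteomics": standardize(prot)}
        quick = [
            RegressorConfig.ann(max_iterations=50),
            RegressorConfig.rf(n_estimators=30),
            RegressorConfig.svr(),
        ]
        table = benchmark(quick, layers, rates)
        assert len(table) == 6
        assert set(table.layer) == set(layers)
        assert set(table.family) == {"ANN", "RF", "SVR"}
        assert (table.mse >= 0).all() and (table.mae >= 0).all()

    def test_duplicate_config_flagged(self, small_prot_std):
        X, y = small_prot_std
        cfg = RegressorConfig.svr()
        with pytest.warns(UserWarning, match="duplicate"):
            table = benchmark([cfg, cfg], {"proteomics": X}, y)
        assert len(table) == 2

    def test_default_configs_match_published_protocol(self):
        ann, rf, svr = default_configs()
        assert (ann.hidden_layers, ann.neurons_per_layer) == (12, 200)
        assert (ann.max_iterations, ann.seed) == (1000, 42)
        assert rf.n_estimators == 1000
        assert (svr.kernel, svr.C, svr.epsilon) == ("rbf", 100.0, 0.01)
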