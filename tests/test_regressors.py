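import numpy as np
import pandas as pd
import pytest

from itaq.fileio import FEATURE_COLUMNS, TARGET_COLUMNS
from itaq.regressors import (
    MLPConfig,
    MLPModel,
    StandardizationSpec,
    VQCConfig,
    _init_layers,
    _masked_mse,
    fit_linear,
    fit_mlp,
    fit_vqc,
    kfold_splits,
    make_split,
    metrics,
)
from itaq.synth import SyntheticSpec, generate_table


def _table(n=60, seed=0, **kw):
    spec = SyntheticSpec(n_molecules=n, seed=seed,
                         missing_rate={t: 0.0 for t in TARGET_COLUMNS},
                         noise_sd={t: 0.0 for t in TARGET_COLUMNS}, **kw)
    return generate_table(spec)


class TestMetrics:
    def test_perfect_prediction(self):
        m = metrics([1.0, 2.0], [1.0, 2.0])
        assert m == {"rmse": 0.0, "mae": 0.0, "r2": 1.0}

    def test_direct_arithmetic(self):
        m = metrics([0.0, 0.0], [3.0, 4.0])
        assert m["rmse"] == pytest.approx(np.sqrt(12.5))
        assert m["mae"] == pytest.approx(3.5)

    def test_mean_predictor_r2_zero(self):
        obs = np.array([1.0, 2.0, 3.0, 6.0])
        m = metrics(np.full(4, obs.mean()), obs)
        assert m["r2"] == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_undefined(self):
        with pytest.raises(ValueError, match="variance"):
            metrics([1.0, 2.0], [5.0, 5.0])

    def test_masking(self):
        m = metrics([1.0, 2.0, 99.0], [1.0, 2.0, np.nan])
        assert m["mae"] == 0.0


class TestLinear:
    def test_exact_affine_recovery(self):
        x = np.linspace(-3, 3, 40)
        tab = pd.DataFrame({"x": x, "q1_mv": 2.0 * x + 1.0})
        model, rep = fit_linear(tab, feature_columns=["x"], target="q1_mv")
        assert model.coef[0] == pytest.approx(2.0, abs=1e-10)
        assert model.intercept == pytest.approx(1.0, abs=1e-10)
        assert rep.targets["q1_mv"]["train"]["r2"] == pytest.approx(1.0, abs=1e-12)

    def test_identity_slope(self):
        x = np.linspace(0, 5, 20)
        tab = pd.DataFrame({"x": x, "q1_mv": x})
        model, _ = fit_linear(tab, feature_columns=["x"], target="q1_mv")
        assert model.coef[0] == pytest.approx(1.0, abs=1e-12)

    def test_planted_recovery_within_3_se(self):
        spec = SyntheticSpec(n_molecules=500, seed=4,
                             missing_rate={t: 0.0 for t in TARGET_COLUMNS})
        tab, truth = generate_table(spec, return_truth=True)
        model, _ = fit_linear(tab, target="q1_mv")
        X = tab[FEATURE_COLUMNS].to_numpy()
        design = np.column_stack([X, np.ones(len(X))])
        resid = tab["q1_mv"].to_numpy() - model.predict(X)
        sigma2 = resid @ resid / (len(X) - design.shape[1])
        se = np.sqrt(np.diag(sigma2 * np.linalg.inv(design.T @ design)))[:-1]
        assert np.all(np.abs(model.coef - truth["coef"]["q1_mv"]) <= 3.0 * se)

    def test_collinear_columns_named(self):
        x = np.linspace(0, 1, 30)
        tab = pd.DataFrame({"a": x, "b": 2.0 * x, "q1_mv": x + 1.0})
        with pytest.raises(np.linalg.LinAlgError, match="b"):
            fit_linear(tab, feature_columns=["a", "b"], target="q1_mv")

    def test_too_few_rows(self):
        tab = pd.DataFrame({"a": [1.0, 2.0], "q1_mv": [np.nan, 1.0]})
        with pytest.raises(ValueError, match="non-missing"):
            fit_linear(tab, feature_columns=["a"], target="q1_mv")


class TestStandardization:
    def test_affine_roundtrip_exact(self):
        rng = np.random.default_rng(0)
        X = rng.normal(3.0, 2.0, size=(50, 4))
        Y = rng.normal(-600.0, 250.0, size=(50, 2))
        spec = StandardizationSpec.fit(X, Y, np.ones_like(Y, dtype=bool))
        assert np.allclose(spec.inverse_targets(spec.transform_targets(Y)), Y, atol=1e-10)

    def test_mean_model_predicts_training_mean(self):
        """Zero output weights de-standardize to the training-target mean."""
        tab = _table(n=50)
        X = tab[FEATURE_COLUMNS].to_numpy()
        Y = tab[TARGET_COLUMNS].to_numpy()
        spec = StandardizationSpec.fit(X, Y, np.isfinite(Y))
        Ws, bs = _init_layers([13, 6, 3], np.random.default_rng(0))
        Ws[-1][:] = 0.0
        bs[-1][:] = 0.0
        model = MLPModel(Ws, bs, spec, TARGET_COLUMNS)
        pred = model.predict(X)
        assert np.allclose(pred, Y.mean(axis=0), atol=1e-8)


class TestMLP:
    def test_zero_epoch_predictions_equal_initialization(self):
        tab = _table(n=40, seed=1)
        split = (np.arange(32), np.arange(32, 40))
        model, rep = fit_mlp(tab, MLPConfig(epochs=0, seed=9), split)
        # rebuild the seeded initial network and compare predictions
        X = tab[FEATURE_COLUMNS].to_numpy()
        Y = tab[TARGET_COLUMNS].to_numpy()
        spec = StandardizationSpec.fit(X[split[0]], Y[split[0]],
                                       np.isfinite(Y[split[0]]))
        rng = np.random.default_rng(9)
        Ws, bs = _init_layers([13, 6, 3], rng)
        twin = MLPModel(Ws, bs, spec, TARGET_COLUMNS)
        assert np.array_equal(model.predict(X), twin.predict(X))
        assert rep.loss_history == []

    def test_masked_rows_contribute_zero_gradient(self):
        pred = np.array([[1.0, 2.0], [3.0, 4.0]])
        Y = np.array([[0.0, 0.0], [0.0, 0.0]])
        mask = np.array([[True, False], [True, True]])
        loss, grad = _masked_mse(pred, Y, mask)
        assert grad[0, 1] == 0.0
        assert loss == pytest.approx((1.0 + 9.0 + 16.0) / 3.0)

    def test_all_missing_target_excluded_with_warning(self):
        tab = _table(n=40, seed=2)
        tab["sigma_p"] = np.nan
        split = (np.arange(32), np.arange(32, 40))
        with pytest.warns(RuntimeWarning, match="sigma_p"):
            model, rep = fit_mlp(tab, MLPConfig(epochs=1, seed=0), split)
        assert model.target_names == ["q1_mv", "q2_mv"]

    def test_bitwise_reproducible(self):
        tab = _table(n=60, seed=3)
        split = make_split(tab, seed=0)
        cfg = MLPConfig(epochs=30, seed=5)
        m1, r1 = fit_mlp(tab, cfg, split)
        m2, r2 = fit_mlp(tab, cfg, split)
        X = tab[FEATURE_COLUMNS].to_numpy()
        assert np.array_equal(m1.predict(X), m2.predict(X))
        assert r1.loss_history == r2.loss_history

    def test_report_in_original_units(self):
        tab = _table(n=80, seed=6)
        split = make_split(tab, seed=1)
        _, rep = fit_mlp(tab, MLPConfig(epochs=50, seed=0), split)
        # q1 lives on the few-hundred-mV scale; standardized RMSE would be ~1
        assert rep.targets["q1_mv"]["val"]["rmse"] > 5.0


class TestVQC:
    def test_degenerate_circuit_is_affine_in_cos_features(self):
        """With zero entangling layers the model is head(cos(encoder(x)))."""
        tab = _table(n=40, seed=7)
        split = (np.arange(32), np.arange(32, 40))
        cfg = VQCConfig(n_qubits=4, encoder_hidden=6, n_layers=0, epochs=0, seed=0)
        model, _ = fit_vqc(tab, cfg, split)
        X = tab[FEATURE_COLUMNS].to_numpy()
        Xs = model.spec.transform_features(X)
        _, a = model._encode(Xs)
        manual = np.cos(a) @ model.head_W + model.head_b
        assert np.allclose(model.spec.inverse_targets(manual), model.predict(X), atol=1e-8)

    def test_degenerate_circuit_converges_on_linear_target(self):
        rng = np.random.default_rng(0)
        n = 200
        X = rng.standard_normal((n, 13))
        w = rng.standard_normal(13)
        tab = pd.DataFrame(X, columns=FEATURE_COLUMNS)
        tab["family"] = "BQ"
        tab["molecule_id"] = [str(i) for i in range(n)]
        tab["q1_mv"] = X @ w
        tab["q2_mv"] = np.nan
        tab["sigma_p"] = np.nan
        split = (np.arange(160), np.arange(160, 200))
        cfg = VQCConfig(n_qubits=6, encoder_hidden=8, n_layers=0, epochs=150,
                        lr=2e-2, seed=0)
        with pytest.warns(RuntimeWarning):
            model, rep = fit_vqc(tab, cfg, split)
        # convergence, not exactness: the cos embedding approaches a linear
        # map only in the small-angle regime
        assert rep.targets["q1_mv"]["val"]["r2"] > 0.8
        assert rep.loss_history[-1] < 0.2 * rep.loss_history[0]

    def test_bitwise_reproducible_small(self):
        tab = _table(n=40, seed=8)
        split = (np.arange(32), np.arange(32, 40))
        cfg = VQCConfig(n_qubits=4, encoder_hidden=6, epochs=10, seed=3)
        m1, r1 = fit_vqc(tab, cfg, split)
        m2, r2 = fit_vqc(tab, cfg, split)
        X = tab[FEATURE_COLUMNS].to_numpy()
        assert np.array_equal(m1.predict(X), m2.predict(X))
        assert r1.loss_history == r2.loss_history


class TestSplits:
    def test_split_is_disjoint_and_stratified(self):
        tab = _table(n=100, seed=9)
        train, val = make_split(tab, seed=0, val_fraction=0.2)
        assert len(set(train) & set(val)) == 0
        assert len(train) + len(val) == 100
        # each family appears in both parts
        fams = set(tab["family"])
        assert set(tab["family"].iloc[train]) == fams
        assert set(tab["family"].iloc[val]) == fams

    def test_kfold_covers_everything(self):
        tab = _table(n=50, seed=10)
        seen = []
        for train, val in kfold_splits(tab, k=5, seed=1):
            assert len(set(train) & set(val)) == 0
            seen.extend(val.tolist())
        assert sorted(seen) == list(range(50))
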