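import numpy as np
import pandas as pd
import pytest

from thyrocad.data_io import BENIGN, MALIGNANT
from thyrocad.model import (
    MLP,
    MLPConfig,
    SplitSpec,
    load_model,
    predict,
    save_model,
    split,
    standardize,
    train_ann,
    train_svm,
)
from thyrocad.texture import FEATURE_NAMES


def make_table(X, y, start=0):
    """Feature table with 2-D data placed in the first two feature columns."""
    n = len(y)
    data = {"case_id": [f"c{start + i:04d}" for i in range(n)],
            "label": [MALIGNANT if v else BENIGN for v in y]}
    for j, name in enumerate(FEATURE_NAMES):
        data[name] = X[:, j] if j < X.shape[1] else np.zeros(n)
    return pd.DataFrame(data)


def blobs(n=40, sep=4.0, seed=0):
    rng = np.random.default_rng(seed)
    half = n // 2
    X = np.vstack([rng.normal(0.0, 1.0, size=(half, 2)),
                   rng.normal(sep, 1.0, size=(n - half, 2))])
    y = np.r_[np.zeros(half), np.ones(n - half)]
    return make_table(X, y)


def circles(n=80, seed=0):
    rng = np.random.default_rng(seed)
    half = n // 2
    r = np.r_[rng.uniform(0.0, 1.0, half), rng.uniform(2.0, 3.0, n - half)]
    t = rng.uniform(0, 2 * np.pi, n)
    X = np.c_[r * np.cos(t), r * np.sin(t)]
    y = np.r_[np.zeros(half), np.ones(n - half)]
    return make_table(X, y)


class TestSplit:
    def test_fraction_arithmetic(self):
        table = make_table(np.zeros((100, 2)), np.r_[np.zeros(50), np.ones(50)])
        train, test = split(table, SplitSpec(train_fraction=0.87, seed=1, stratified=False))
        assert len(train) == 87 and len(test) == 13

    def test_stratified_rounding_33_66(self):
        y = np.r_[np.zeros(33), np.ones(66)]
        table = make_table(np.zeros((99, 2)), y)
        train, test = split(table, SplitSpec(seed=5))
        assert (train["label"] == BENIGN).sum() == 29
        assert (train["label"] == MALIGNANT).sum() == 57
        assert (test["label"] == BENIGN).sum() == 4
        assert (test["label"] == MALIGNANT).sum() == 9

    def test_deterministic_under_seed(self):
        table = blobs(n=60)
        a = split(table, SplitSpec(seed=3))
        b = split(table, SplitSpec(seed=3))
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_single_label_stratified_errors(self):
        table = make_table(np.zeros((10, 2)), np.ones(10))
        with pytest.raises(ValueError):
            split(table, SplitSpec())

    def test_case_unit_keeps_images_together(self):
        table = blobs(n=40)
        table["case_id"] = [f"case{i // 2}" for i in range(40)]  # 2 images per case
        train, test = split(table, SplitSpec(seed=0, unit="case"))
        assert set(train["case_id"]) & set(test["case_id"]) == set()


class TestStandardize:
    def test_two_point_column(self):
        table = make_table(np.array([[1.0, 0.0], [3.0, 0.0]]), np.array([0, 1]))
        scaled, scaler = standardize(table)
        np.testing.assert_allclose(scaled[FEATURE_NAMES[0]], [-1.0, 1.0])
        assert scaler.mean[0] == pytest.approx(2.0)
        assert scaler.sd[0] == pytest.approx(1.0)  # population sd

    def test_constant_column_flagged_and_zeroed(self):
        table = make_table(np.array([[1.0, 5.0], [3.0, 5.0]]), np.array([0, 1]))
        scaled, scaler = standardize(table)
        assert scaler.constant[1]
        np.testing.assert_allclose(scaled[FEATURE_NAMES[1]], [0.0, 0.0])

    def test_self_application_gives_zero_mean_unit_sd(self, rng):
        X = rng.normal(size=(30, 7))
        table = make_table(X, rng.integers(0, 2, 30))
        _, scaler = standardize(table)
        Z = scaler.transform(X)
        np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(Z.std(axis=0), 1.0, atol=1e-12)


class TestMLP:
    def test_zero_weights_give_half_probability(self):
        net = MLP([2, 3, 1], "sigmoid", seed=0)
        net.W = [np.zeros_like(W) for W in net.W]
        net.b = [np.zeros_like(b) for b in net.b]
        np.testing.assert_allclose(net.forward(np.random.default_rng(0).normal(size=(5, 2))), 0.5)

    @pytest.mark.parametrize("activation", ["sigmoid", "tanh", "relu"])
    def test_gradients_match_finite_differences(self, activation, rng):
        net = MLP([3, 4, 1], activation, seed=1)
        X = rng.normal(size=(6, 3))
        y = rng.integers(0, 2, 6).astype(float)
        loss, gW, gb = net.loss_and_grads(X, y)
        eps = 1e-6
        for params, grads in ((net.W, gW), (net.b, gb)):
            for arr, grad in zip(params, grads):
                it = np.nditer(arr, flags=["multi_index"])
                for _ in it:
                    idx = it.multi_index
                    orig = arr[idx]
                    arr[idx] = orig + eps
                    lp = net.loss_and_grads(X, y)[0]
                    arr[idx] = orig - eps
                    lm = net.loss_and_grads(X, y)[0]
                    arr[idx] = orig
                    numeric = (lp - lm) / (2 * eps)
                    assert grad[idx] == pytest.approx(numeric, rel=1e-5, abs=1e-7)

    def test_xor_is_learned(self):
        X = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)
        y = np.array([0, 1, 1, 0], dtype=float)
        table = make_table(X, y)
        model = train_ann(table, MLPConfig(hidden_sizes=(4,), learning_rate=1.0,
                                           max_epochs=2000, tolerance=0.0, seed=2))
        preds = predict(model, table)
        assert (preds["label"].to_numpy() == table["label"].to_numpy()).all()

    def test_separable_blobs_fit_perfectly(self):
        table = blobs(n=40, sep=4.0, seed=1)
        model = train_ann(table, MLPConfig(seed=0))
        preds = predict(model, table)
        assert (preds["label"].to_numpy() == table["label"].to_numpy()).all()

    def test_ann_training_is_deterministic(self):
        table = blobs(n=30, seed=4)
        m1 = train_ann(table, MLPConfig(seed=9, max_epochs=200))
        m2 = train_ann(table, MLPConfig(seed=9, max_epochs=200))
        assert m1.parameters["weights"] == m2.parameters["weights"]


class TestSVM:
    def test_linear_kernel_on_separable_blobs(self):
        table = blobs(n=40, sep=4.0, seed=2)
        model = train_svm(table, kernel="linear")
        preds = predict(model, table)
        assert (preds["label"].to_numpy() == table["label"].to_numpy()).all()

    def test_rbf_solves_circles_where_linear_fails(self):
        table = circles(n=80, seed=3)
        rbf_acc = (predict(train_svm(table, kernel="rbf", C=1.0), table)["label"]
                   == table["label"]).mean()
        lin_acc = (predict(train_svm(table, kernel="linear", C=1.0), table)["label"]
                   == table["label"]).mean()
        assert rbf_acc >= 0.95
        assert lin_acc < rbf_acc

    def test_label_swap_negates_linear_scores(self):
        table = blobs(n=30, sep=3.0, seed=5)
        flipped = table.copy()
        flipped["label"] = np.where(table["label"] == MALIGNANT, BENIGN, MALIGNANT)
        s1 = predict(train_svm(table, kernel="linear"), table)["score"].to_numpy()
        s2 = predict(train_svm(flipped, kernel="linear"), table)["score"].to_numpy()
        np.testing.assert_allclose(s1, -s2, atol=5e-3)  # within libsvm solver tolerance

    def test_single_label_input_errors(self):
        table = make_table(np.zeros((10, 2)), np.ones(10))
        with pytest.raises(ValueError):
            train_svm(table)


class TestPredict:
    def test_schema_mismatch_names_missing_columns(self):
        table = blobs(n=20)
        model = train_svm(table)
        with pytest.raises(ValueError, match=FEATURE_NAMES[0]):
            predict(model, table.drop(columns=[FEATURE_NAMES[0]]))

    def test_infinite_threshold_predicts_all_benign(self):
        table = blobs(n=20, seed=6)
        model = train_svm(table)
        model.decision_threshold = np.inf
        assert (predict(model, table)["label"] == BENIGN).all()

    def test_default_threshold_roughly_balanced_on_symmetric_blobs(self):
        table = blobs(n=200, sep=2.0, seed=7)
        model = train_svm(table)
        frac = (predict(model, table)["label"] == MALIGNANT).mean()
        assert 0.35 < frac < 0.65

    def test_save_load_round_trip(self, tmp_path):
        table = blobs(n=30, seed=8)
        for trainer in (lambda t: train_svm(t), lambda t: train_ann(t, MLPConfig(max_epochs=100))):
            model = trainer(table)
            path = tmp_path / "model.json"
            save_model(model, path)
            loaded = load_model(path)
            np.testing.assert_allclose(predict(model, table)["score"],
                                       predict(loaded, table)["score"])


def test_training_class_criteria_on_phantom_features(phantom200_features):
    """Discriminatory features, reliable split, independent scaler."""
    table = phantom200_features
    # Discriminatory: class means separate on every feature vector overall
    mb = table[table["label"] == BENIGN].loc[:, list(FEATURE_NAMES)].mean()
    mm = table[table["label"] == MALIGNANT].loc[:, list(FEATURE_NAMES)].mean()
    assert np.abs(mb.to_numpy() - mm.to_numpy()).sum() > 0
    # Reliable: the split protocol is reproducible
    a = split(table, SplitSpec(seed=11))[0]["case_id"].tolist()
    b = split(table, SplitSpec(seed=11))[0]["case_id"].tolist()
    assert a == b
    # Independent: scaler statistics come from the training rows only
    train, test = split(table, SplitSpec(seed=11))
    _, scaler = standardize(train)
    expected = train.loc[:, list(FEATURE_NAMES)].to_numpy().mean(axis=0)
    np.testing.assert_allclose(scaler.mean, expected)
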