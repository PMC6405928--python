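import numpy as np
import pytest

from premir.evalmetrics import cross_validate
from premir.simulate import make_feature_cloud
from premir.svm import (
    KernelSpec,
    SVMModel,
    classify,
    decision_score,
    kernel,
    kernel_matrix,
    train,
)


class TestKernels:
    def test_linear(self):
        assert kernel([1, 2], [3, 4], KernelSpec("linear")) == 11.0

    def test_rbf_self_is_one(self):
        x = np.array([0.3, -1.2, 5.0])
        for gamma in (1e-4, 1.0, 10.0):
            assert kernel(x, x, KernelSpec("rbf", gamma=gamma)) == 1.0

    def test_polynomial(self):
        spec = KernelSpec("polynomial", gamma=1.0, degree=2, coef0=0.0)
        assert kernel([1, 1], [1, 1], spec) == 4.0

    def test_sigmoid(self):
        spec = KernelSpec("sigmoid", gamma=0.5, coef0=0.1)
        x, z = np.array([1.0, 2.0]), np.array([0.5, -1.0])
        assert kernel(x, z, spec) == pytest.approx(np.tanh(0.5 * (x @ z) + 0.1))

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            kernel([1, 2], [1, 2, 3], KernelSpec("linear"))

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            KernelSpec("rbf", gamma=-1.0)
        with pytest.raises(ValueError):
            KernelSpec("nope")

    def test_matrix_matches_pairwise(self, rng):
        nprng = np.random.default_rng(0)
        X = nprng.normal(size=(6, 4))
        Z = nprng.normal(size=(5, 4))
        for spec in (
            KernelSpec("linear"),
            KernelSpec("rbf", gamma=0.7),
            KernelSpec("polynomial", gamma=0.3, degree=3, coef0=1.0),
            KernelSpec("sigmoid", gamma=0.2, coef0=-0.5),
        ):
            K = kernel_matrix(X, Z, spec)
            for i in range(6):
                for j in range(5):
                    assert K[i, j] == pytest.approx(kernel(X[i], Z[j], spec), abs=1e-12)

    @pytest.mark.parametrize("kind", ["linear", "rbf"])
    def test_gram_positive_semidefinite(self, kind):
        nprng = np.random.default_rng(42)
        X = nprng.normal(size=(25, 6))
        spec = KernelSpec(kind, gamma=0.5)
        K = kernel_matrix(X, X, spec)
        assert np.allclose(K, K.T)
        eig = np.linalg.eigvalsh(K)
        assert eig.min() >= -1e-8


class TestTrain:
    def test_separable_linear(self):
        cloud = make_feature_cloud(40, dim=2, shift=10.0, seed=0)
        model = train(cloud, KernelSpec("linear"), seed=0)
        X, y = cloud.matrix(), cloud.y()
        pred = np.where(model.decision(X) > 0, 1, -1)
        assert (pred == y).mean() == 1.0

    def test_xor_rbf_beats_linear(self):
        nprng = np.random.default_rng(3)
        n = 50
        X = np.vstack([
            nprng.normal([1, 1], 0.2, (n, 2)),
            nprng.normal([-1, -1], 0.2, (n, 2)),
            nprng.normal([1, -1], 0.2, (n, 2)),
            nprng.normal([-1, 1], 0.2, (n, 2)),
        ])
        y = [1] * (2 * n) + [-1] * (2 * n)
        from premir.features import FeatureCatalog, FeatureVector, LabeledSet

        cat = FeatureCatalog((("x", "NORMALIZED", ""), ("y", "NORMALIZED", "")))
        labeled = LabeledSet(
            [FeatureVector(str(i), tuple(map(float, r))) for i, r in enumerate(X)],
            y,
            cat,
        )
        rbf = train(labeled, KernelSpec("rbf", gamma=1.0), seed=0)
        lin = train(labeled, KernelSpec("linear"), seed=0)
        acc = lambda m: (np.where(m.decision(X) > 0, 1, -1) == np.array(y)).mean()
        assert acc(rbf) >= 0.95
        assert acc(lin) <= 0.6

    def test_class_weight_boosts_positive_recall(self):
        # 1:5 imbalance; j=3 must not lower positive recall vs j=1
        nprng = np.random.default_rng(9)
        n_pos, n_neg = 20, 100
        X = np.vstack([
            nprng.normal(0.8, 1.0, (n_pos, 4)),
            nprng.normal(-0.8, 1.0, (n_neg, 4)),
        ])
        y = [1] * n_pos + [-1] * n_neg
        from premir.features import FeatureCatalog, FeatureVector, LabeledSet

        cat = FeatureCatalog(tuple((f"f{i}", "NORMALIZED", "") for i in range(4)))
        labeled = LabeledSet(
            [FeatureVector(str(i), tuple(map(float, r))) for i, r in enumerate(X)],
            y,
            cat,
        )
        spec = KernelSpec("rbf", gamma=0.5)
        m3 = train(labeled, spec, j=3.0, seed=0)
        m1 = train(labeled, spec, j=1.0, seed=0)
        pos = X[:n_pos]
        recall3 = (m3.decision(pos) > 0).mean()
        recall1 = (m1.decision(pos) > 0).mean()
        assert recall3 >= recall1

    def test_single_class_rejected(self):
        cloud = make_feature_cloud(30, dim=2, shift=1.0, seed=0)
        from premir.features import LabeledSet

        degenerate = LabeledSet(cloud.vectors, [1] * len(cloud.vectors), cloud.catalog)
        with pytest.raises(ValueError):
            train(degenerate)

    def test_dual_box_constraints(self):
        cloud = make_feature_cloud(50, dim=5, shift=1.0, seed=5)
        C, j = 5.0, 3.0
        model = train(cloud, KernelSpec("rbf", gamma=0.5), C=C, j=j, seed=0)
        # dual_coef = alpha_i * y_i with 0 <= alpha_i <= C * weight(y_i)
        for coef in model.dual_coef:
            if coef > 0:
                assert coef <= C * j + 1e-9
            else:
                assert -coef <= C + 1e-9

    def test_deterministic(self):
        cloud = make_feature_cloud(40, dim=3, shift=2.0, seed=1)
        a = train(cloud, seed=7)
        b = train(cloud, seed=7)
        assert np.array_equal(a.support_vectors, b.support_vectors)
        assert np.array_equal(a.dual_coef, b.dual_coef)
        assert a.bias == b.bias


class TestDecision:
    def test_classify_threshold(self):
        cloud = make_feature_cloud(40, dim=2, shift=8.0, seed=2)
        model = train(cloud, KernelSpec("linear"), seed=0)
        X, y = cloud.matrix(), cloud.y()
        for i in range(len(y)):
            assert classify(model, X[i]) == y[i]

    def test_training_points_reproducible(self):
        cloud = make_feature_cloud(30, dim=4, shift=3.0, seed=3)
        model = train(cloud, seed=0)
        X = cloud.matrix()
        d1 = model.decision(X)
        d2 = model.decision(X)
        assert np.max(np.abs(d1 - d2)) < 1e-9

    def test_decision_matches_sklearn(self):
        # dual-route check: our kernel expansion vs sklearn's internal one
        from sklearn.svm import SVC

        cloud = make_feature_cloud(40, dim=5, shift=2.0, seed=8)
        spec = KernelSpec("rbf", gamma=0.3)
        model = train(cloud, spec, C=5.0, j=3.0, seed=0, scale="minmax")
        Xs = model.scaler.transform(cloud.matrix())
        clf = SVC(kernel="rbf", C=5.0, gamma=0.3, class_weight={1: 3.0, -1: 1.0})
        clf.fit(Xs, cloud.y())
        ours = model.decision(cloud.matrix())
        theirs = clf.decision_function(Xs)
        assert np.max(np.abs(ours - theirs)) < 1e-9

    def test_catalog_hash_guard(self):
        cloud = make_feature_cloud(30, dim=3, shift=2.0, seed=4)
        model = train(cloud, seed=0)
        other = make_feature_cloud(30, dim=3, shift=2.0, seed=4)
        from premir.features import FeatureCatalog

        wrong = FeatureCatalog(tuple((f"g{i}", "COMP", "") for i in range(3)))
        with pytest.raises(ValueError, match="catalog"):
            decision_score(model, cloud.matrix()[0], wrong)
        assert decision_score(model, cloud.matrix()[0], other.catalog) == pytest.approx(
            decision_score(model, cloud.matrix()[0])
        )

    def test_dimension_guard(self):
        cloud = make_feature_cloud(30, dim=3, shift=2.0, seed=4)
        model = train(cloud, seed=0)
        with pytest.raises(ValueError):
            decision_score(model, np.zeros(5))


class TestScaler:
    def test_fit_on_train_only(self):
        cloud = make_feature_cloud(30, dim=3, shift=2.0, seed=6)
        model = train(cloud, seed=0, scale="minmax")
        mins = model.scaler.mins.copy()
        model.decision(np.array([[100.0, -100.0, 100.0]]))
        assert np.array_equal(model.scaler.mins, mins)

    def test_constant_feature_maps_to_zero(self):
        from premir.svm import MinMaxScaler01

        X = np.array([[1.0, 5.0], [2.0, 5.0]])
        sc = MinMaxScaler01.fit(X)
        out = sc.transform(np.array([[1.5, 123.0]]))
        assert out[0, 1] == 0.0
        assert out[0, 0] == pytest.approx(0.5)


class TestPersistence:
    def test_round_trip_scores_identical(self, tmp_path):
        cloud = make_feature_cloud(40, dim=6, shift=2.0, seed=10)
        model = train(cloud, KernelSpec("rbf", gamma=0.2), seed=0)
        path = tmp_path / "model.json"
        model.save(path)
        loaded = SVMModel.load(path)
        X = cloud.matrix()
        assert np.max(np.abs(model.decision(X) - loaded.decision(X))) < 1e-12
        assert loaded.catalog_hash == model.catalog_hash
        assert loaded.metadata["n_pos"] == 40

    def test_version_check(self, tmp_path):
        p = tmp_path / "bad.json"
        p.write_text('{"format_version": 99}')
        with pytest.raises(ValueError, match="version"):
            SVMModel.load(p)
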