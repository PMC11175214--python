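import numpy as np
import pandas as pd
import pytest
from sklearn.datasets import make_blobs

from fenceline.chemometrics import (
    fit_pca,
    flag_outliers,
    predict_class,
    predict_concentration,
    train_classifier,
    train_quantifier,
)
from fenceline.evaluation import multiclass_mcc


def _frame(arr):
    return pd.DataFrame(arr, columns=[f"f{i}" for i in range(arr.shape[1])])


class TestPca:
    def test_line_explains_everything(self, rng):
        t = rng.standard_normal(100)
        X = _frame(np.column_stack([t, 2 * t + 1e-9 * rng.standard_normal(100)]))
        model = fit_pca(X, n_pc=1)
        assert model.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-6)

    def test_full_reconstruction_is_identity(self, rng):
        X = _frame(rng.standard_normal((50, 5)))
        model = fit_pca(X, n_pc=5)
        scaled = model.scaler.transform(X.to_numpy())
        np.testing.assert_allclose(model.reconstruct(X), scaled, atol=1e-8)

    def test_training_scores_are_centred(self, rng):
        X = _frame(rng.standard_normal((80, 6)) + 5.0)
        model = fit_pca(X, n_pc=3)
        np.testing.assert_allclose(model.transform(X).mean(axis=0), 0.0, atol=1e-10)

    def test_isotropic_variance_ratios(self, rng):
        X = _frame(rng.standard_normal((4000, 5)))
        model = fit_pca(X, n_pc=5)
        np.testing.assert_allclose(
            model.pca.explained_variance_ratio_, 0.2, atol=0.05
        )

    def test_variance_target_selects_minimal_components(self, rng):
        X = _frame(rng.standard_normal((200, 6)) @ rng.standard_normal((6, 6)))
        model = fit_pca(X, variance_target=0.90)
        cum = np.cumsum(model.pca.explained_variance_ratio_)
        assert cum[model.n_pc - 1] >= 0.90
        assert model.n_pc == 1 or cum[model.n_pc - 2] < 0.90

    def test_zero_variance_column_named_in_error(self, rng):
        X = _frame(rng.standard_normal((30, 3)))
        X["f1"] = 2.0
        with pytest.raises(ValueError, match="f1"):
            fit_pca(X)


class TestOutliers:
    def test_leverage_outlier_flagged_by_t2(self, rng):
        X = rng.standard_normal((200, 6))
        X[0] += 10.0  # far out, inside the PC plane directions
        model = fit_pca(_frame(X), n_pc=3)
        report = flag_outliers(model, _frame(X))
        assert report.t2_flag[0]

    def test_offplane_outlier_flagged_by_q_not_t2(self, rng):
        # data living on a 3-D plane inside 6-D; one point displaced
        # orthogonally to that plane
        basis = np.linalg.qr(rng.standard_normal((6, 6)))[0]
        scores = rng.standard_normal((200, 3)) * [3.0, 2.0, 1.0]
        X = scores @ basis[:, :3].T + 0.01 * rng.standard_normal((200, 6))
        X[0] += 2.0 * basis[:, 5]
        model = fit_pca(_frame(X), n_pc=3)
        report = flag_outliers(model, _frame(X))
        assert report.q_flag[0]
        assert not report.t2_flag[0]

    def test_rank_deficient_q_rejected(self, rng):
        X = _frame(rng.standard_normal((20, 3)))
        model = fit_pca(X, n_pc=3)
        with pytest.raises(ValueError, match="Q"):
            flag_outliers(model, X)


class TestClassifier:
    @pytest.fixture(scope="class")
    def blobs(self):
        X, y = make_blobs(
            n_samples=150, centers=3, cluster_std=0.4, random_state=0
        )
        labels = np.array(["Air", "Biogas", "Organic odour"])[y]
        return X, labels

    def test_separated_blobs_reach_high_cv_mcc(self, blobs):
        X, labels = blobs
        model = train_classifier(X, labels, cv=10, seed=0)
        assert model.cv_mcc >= 0.95

    def test_shuffled_labels_give_null_mcc(self, blobs, rng):
        X, labels = blobs
        shuffled = rng.permutation(labels)
        model = train_classifier(X, shuffled, cv=10, seed=0)
        assert abs(model.cv_mcc) < 0.2

    def test_prediction_is_deterministic(self, blobs):
        X, labels = blobs
        model = train_classifier(X, labels, cv=10, seed=0)
        p1 = predict_class(model, X)
        p2 = predict_class(model, X)
        assert (p1 == p2).all()
        assert multiclass_mcc(pd.crosstab(labels, p1).to_numpy()) >= 0.95

    def test_dimension_mismatch_rejected(self, blobs):
        X, labels = blobs
        model = train_classifier(X, labels, cv=10, seed=0)
        with pytest.raises(ValueError, match="dimensionality"):
            predict_class(model, X[:, :1])

    def test_small_class_vs_cv_guard(self, blobs):
        X, labels = blobs
        with pytest.raises(ValueError, match="fewer than cv"):
            train_classifier(X[:12], labels[:12], cv=10)

    def test_feature_scaling_absorbed_by_autoscaling(self, blobs):
        """Multiplying a feature column by 1000 changes no prediction once
        autoscaled PCA is in front of the classifier."""
        X, labels = blobs
        Xdf = _frame(np.column_stack([X, X[:, 0] - X[:, 1]]))
        pca = fit_pca(Xdf, n_pc=2)
        model = train_classifier(pca.transform(Xdf), labels, cv=10, seed=0)
        Xdf2 = Xdf.copy()
        Xdf2["f0"] = Xdf2["f0"] * 1000.0
        pca2 = fit_pca(Xdf2, n_pc=2)
        model2 = train_classifier(pca2.transform(Xdf2), labels, cv=10, seed=0)
        assert (
            predict_class(model, pca.transform(Xdf))
            == predict_class(model2, pca2.transform(Xdf2))
        ).all()


class TestQuantifier:
    @pytest.fixture(scope="class")
    def synthetic_regression(self):
        rng = np.random.default_rng(1)
        n = 120
        logc = rng.uniform(np.log10(20), np.log10(1000), n)
        labels = np.where(np.arange(n) % 2 == 0, "Biogas", "Organic odour")
        gain = np.where(labels == "Biogas", 2.0, 0.8)
        scores = np.column_stack(
            [
                gain * (logc - 1.0),
                (labels == "Biogas").astype(float),
                0.05 * rng.standard_normal(n),
            ]
        )
        return scores, 10.0**logc, labels

    def test_noiseless_response_recovered(self, synthetic_regression):
        scores, conc, labels = synthetic_regression
        model = train_quantifier(scores, conc, labels, mode="QB", cv=10, seed=0)
        pred = predict_concentration(model, scores, labels)
        ratio = np.log10(pred / conc)
        assert np.sqrt(np.mean(ratio**2)) < 0.05

    def test_global_and_class_specific_structure(self, synthetic_regression):
        scores, conc, labels = synthetic_regression
        qa = train_quantifier(scores, conc, labels, mode="QA", cv=10, seed=0)
        qb = train_quantifier(scores, conc, labels, mode="QB", cv=10, seed=0)
        assert set(qa.regressors) == {"global"}
        assert set(qb.regressors) == {"Biogas", "Organic odour"}
        # routing: identical scores, different class -> different outputs
        point = scores[:1]
        out_b = predict_concentration(qb, point, ["Biogas"])
        out_o = predict_concentration(qb, point, ["Organic odour"])
        assert out_b != out_o

    def test_air_windows_report_floor(self, synthetic_regression):
        scores, conc, labels = synthetic_regression
        qb = train_quantifier(scores, conc, labels, mode="QB", cv=10, seed=0)
        out = predict_concentration(qb, scores[:3], ["Air", "Air", "Air"])
        np.testing.assert_allclose(out, qb.air_floor)

    def test_inverse_transform_is_power_of_ten(self, synthetic_regression):
        scores, conc, labels = synthetic_regression
        qa = train_quantifier(scores, conc, labels, mode="QA", cv=10, seed=0)
        log_pred = qa.predict_log10(scores)
        np.testing.assert_allclose(
            predict_concentration(qa, scores), 10.0**log_pred, rtol=1e-12
        )

    def test_constant_target_returns_constant(self):
        rng = np.random.default_rng(2)
        scores = rng.standard_normal((40, 3))
        labels = np.array(["Biogas"] * 40)
        model = train_quantifier(scores, np.full(40, 100.0), labels, mode="QB", cv=5)
        pred = predict_concentration(model, scores, labels)
        np.testing.assert_allclose(pred, 100.0, rtol=0.15)

    def test_nonpositive_concentration_rejected(self, synthetic_regression):
        scores, conc, labels = synthetic_regression
        bad = conc.copy()
        bad[0] = 0.0
        with pytest.raises(ValueError, match="positive"):
            train_quantifier(scores, bad, labels, mode="QA")

    def test_unseen_class_rejected(self, synthetic_regression):
        scores, conc, labels = synthetic_regression
        qb = train_quantifier(scores, conc, labels, mode="QB", cv=10, seed=0)
        with pytest.raises(ValueError, match="no trained regressor"):
            predict_concentration(qb, scores[:1], ["Sheds"])


class TestBundle:
    def test_save_load_roundtrip_and_hash(self, trained_bundle, tmp_path):
        path = tmp_path / "bundle.joblib"
        trained_bundle.save(path)
        from fenceline.chemometrics import TrainedIoms

        back = TrainedIoms.load(path)
        assert back.provenance_hash() == trained_bundle.provenance_hash()
        assert back.selected_features == trained_bundle.selected_features
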